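"""Simultaneous nonlinear least-squares fitting across reward magnitudes.

Each model is fitted *jointly* to all indifference points of one analysis
unit (a participant, or the group-median profile) within one effort domain:
a single residual vector stacks the amount blocks, each block evaluated with
its own magnitude-specific parameters.  This block-structured joint
estimation is mathematically identical to the classical dummy-variable
coding (one l and s variant per reward magnitude, dummies zeroing the
inactive variants): the objective separates over magnitudes, which the test
suite exploits as an independent oracle.

Goodness of fit follows the pooled-R² convention: SST is taken about the
grand mean of *all* points entering the joint fit, yielding one R² per
model x unit x domain.  When the grand mean outperforms the model (R² < 0),
R² is recorded as 0, the fit is flagged ``clamped`` and the parameter
estimates are set to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .design import DesignSpec
from .indifference import group_median_ips
from .models import ModelSpec, get_model, registry

__all__ = ["FitResult", "fit_joint", "fit_all", "r_squared",
           "L_START_GRID", "FIT_COLUMNS"]

log = logging.getLogger(__name__)

#: Multi-start grid for the rate parameter l (log-spaced, fixed).
L_START_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-6, 1))

#: Fractions of A used as asymptote starts for the two-parameter exponential.
EXP2_S_START_FRACTIONS: tuple[float, ...] = (-0.5, 0.0, 0.5)

# Jacobian-based variable scaling copes with the extreme scale disparity
# between rate and exponent parameters on ridge (cliff-data) solutions.
_LSQ_OPTS = dict(method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10,
                 max_nfev=500, x_scale="jac")

#: number of multi-start grid points actually polished by the optimiser
#: (the best-scoring starts by initial SSe; the full grid is always scored).
N_POLISHED_STARTS = 8

#: numerical ceiling for the rate parameter: at the smallest effort level of
#: the canonical design every model is fully saturated (SV at its floor or
#: asymptote) long before l reaches this, so the ceiling never binds a
#: meaningful estimate but keeps the optimiser's trust region finite.
L_MAX = 1e3

#: numerical floor for the two-parameter exponential's asymptote, as a
#: multiple of A.  The model is degenerate along s -> -inf, l -> 0 (it
#: approaches a straight line of finite slope (A - s) l), so an unbounded
#: asymptote sends the optimiser down an infinite ridge; an asymptote below
#: -4A has no behavioural reading and the floor leaves near-linear fits
#: attainable.
EXP2_S_MIN_FRACTION = -4.0

FIT_COLUMNS = ["unit", "domain", "model", "magnitude", "l", "s",
               "sse", "n", "p", "r2", "clamped", "converged"]


class IncompleteCellsError(ValueError):
    """IP rows do not cover the amount x effort grid exactly once."""


@dataclass
class FitResult:
    """Joint-fit output for one model x unit x domain."""

    model: str
    unit: str
    domain: str
    amounts: tuple[int, ...]
    params: dict = field(default_factory=dict)  # amount -> {"l":, "s":}
    sse: float = np.nan
    n: int = 0
    p: int = 0
    r2: float = 0.0
    clamped: bool = False
    converged: bool = False

    def rows(self) -> list[dict]:
        """Long-format rows (one per magnitude) for fits.csv."""
        out = []
        for amount in self.amounts:
            pars = self.params.get(amount, {})
            out.append({
                "unit": self.unit, "domain": self.domain, "model": self.model,
                "magnitude": amount,
                "l": pars.get("l", np.nan), "s": pars.get("s", np.nan),
                "sse": self.sse, "n": self.n, "p": self.p, "r2": self.r2,
                "clamped": self.clamped, "converged": self.converged,
            })
        return out


def r_squared(sse: float, ip_values) -> tuple[float, bool]:
    """Pooled R² with the mean-beats-model clamp.

    R² = 1 - SSe/SST, SST about the grand mean of all points of the joint
    fit.  Negative R² (or degenerate SST = 0) is clamped to 0 with the flag
    set, signalling that the grand mean explained more variance than the
    model.
    """
    y = np.asarray(ip_values, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0, True
    r2 = 1.0 - sse / sst
    if r2 < 0.0:
        return 0.0, True
    return float(min(r2, 1.0)), False


def _blocks(ip_rows: pd.DataFrame, spec: DesignSpec):
    """Split one unit x domain IP table into per-magnitude (E, y) blocks."""
    levels = np.asarray(spec.effort_levels, dtype=float)
    blocks = []
    for amount in spec.amounts:
        sub = ip_rows[ip_rows["amount"] == amount]
        if sorted(sub["effort_level"]) != sorted(spec.effort_levels):
            raise IncompleteCellsError(
                f"amount {amount}: effort levels "
                f"{sorted(sub['effort_level'])} != {sorted(spec.effort_levels)}")
        sub = sub.sort_values("effort_level")
        blocks.append((float(amount), levels,
                       sub["ip"].to_numpy(dtype=float)))
    return blocks


def _start_grid(model: ModelSpec, amounts) -> list[tuple]:
    """Fixed multi-start grid, identical for every dataset."""
    if model.n_params == 1:
        return [(l,) for l in L_START_GRID]
    if model.name == "exp2":
        return [(l, f) for l in L_START_GRID for f in EXP2_S_START_FRACTIONS]
    return [(l, s) for l in L_START_GRID for s in model.s_starts]


def _bounds(model: ModelSpec, amounts) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for amount in amounts:
        lo.append(0.0)
        hi.append(L_MAX)
        if model.n_params == 2:
            if model.name == "exp2":
                lo.append(EXP2_S_MIN_FRACTION * amount)
                hi.append(amount - 1e-9)
            else:
                s_lo, s_hi = model.s_bounds
                lo.append(s_lo)
                hi.append(s_hi)
    return np.asarray(lo), np.asarray(hi)


def _unpack(theta: np.ndarray, n_params: int):
    if n_params == 1:
        return [(l, None) for l in theta]
    return [(theta[2 * i], theta[2 * i + 1]) for i in range(len(theta) // 2)]


def fit_joint(model: ModelSpec | str, ip_rows: pd.DataFrame,
              spec: DesignSpec | None = None,
              unit: str = "", domain: str = "") -> FitResult:
    """Fit one model jointly across reward magnitudes for one unit x domain.

    ``ip_rows`` must cover every (amount, effort_level) cell of ``spec``
    exactly once (zero-effort rows already excluded).  Minimises the total
    SSe over the stacked parameter vector with a fixed multi-start grid of
    initial values; an additional data-driven start picks, per magnitude,
    the grid point with the lowest block SSe.
    """
    if isinstance(model, str):
        model = get_model(model)
    spec = spec or DesignSpec()
    blocks = _blocks(ip_rows, spec)
    amounts = spec.amounts
    y_all = np.concatenate([y for _, _, y in blocks])
    n = y_all.size
    p = model.n_params * len(amounts)

    def residuals(theta):
        parts = []
        for (A, E, y), (l, s) in zip(blocks, _unpack(theta, model.n_params)):
            # l may touch the lower bound exactly; evaluation accepts l = 0
            parts.append(model.fn(A, E, max(l, 0.0), s) - y)
        return np.concatenate(parts)

    def jacobian(theta):
        jac = np.zeros((n, len(theta)))
        row = 0
        for i, ((A, E, y), (l, s)) in enumerate(
                zip(blocks, _unpack(theta, model.n_params))):
            grads = model.grad(A, E, max(l, 0.0), s)
            col = i * model.n_params
            for j, g in enumerate(grads):
                jac[row:row + E.size, col + j] = g
            row += E.size
        return jac

    starts = _start_grid(model, amounts)
    lo, hi = _bounds(model, amounts)

    def assemble(start) -> np.ndarray:
        theta = []
        for amount in amounts:
            theta.append(start[0])
            if model.n_params == 2:
                s0 = start[1] * amount if model.name == "exp2" else start[1]
                theta.append(s0)
        return np.clip(np.asarray(theta, dtype=float), lo, hi)

    # Data-driven start: per magnitude, the grid point with lowest block SSe.
    extra = []
    for (A, E, y) in blocks:
        best, best_sse = None, np.inf
        for start in starts:
            l = start[0]
            s = None
            if model.n_params == 2:
                s = start[1] * A if model.name == "exp2" else start[1]
            block_sse = float(np.sum((model.fn(A, E, l, s) - y) ** 2))
            if block_sse < best_sse:
                best, best_sse = (l, s), block_sse
        extra.append(best[0])
        if model.n_params == 2:
            extra.append(best[1])
    # Score every grid start by its initial SSe and polish the best-scoring
    # ones (plus the data-driven start).  Low-dimensional problems (a single
    # magnitude) are cheap enough to polish from every grid point, which
    # also hardens the per-magnitude decomposition oracle.
    n_polished = len(starts) if len(lo) <= 2 else N_POLISHED_STARTS
    scored = sorted((float(np.sum(residuals(c) ** 2)), k, c)
                    for k, c in enumerate(assemble(s) for s in starts))
    candidates = [c for _, _, c in scored[:n_polished]]
    candidates.append(np.clip(np.asarray(extra, dtype=float), lo, hi))

    best_theta, best_sse, converged = None, np.inf, False
    for theta0 in candidates:
        try:
            res = least_squares(residuals, theta0, jac=jacobian,
                                bounds=(lo, hi), **_LSQ_OPTS)
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(2.0 * res.cost)
        if res.success:
            converged = True
        if sse < best_sse:
            best_theta, best_sse = res.x, sse

    # Restart polishing: re-running from the incumbent resets the trust
    # region, which finishes off slow ridge crawls (e.g. cliff-shaped data
    # pushing an exponent to its bound) that trf otherwise abandons early.
    for _ in range(5):
        if best_theta is None:
            break
        res = least_squares(residuals, best_theta, jac=jacobian,
                            bounds=(lo, hi), **_LSQ_OPTS)
        sse = float(2.0 * res.cost)
        if sse >= best_sse * (1.0 - 1e-12):
            if sse < best_sse:
                best_theta, best_sse = res.x, sse
            break
        best_theta, best_sse = res.x, sse

    result = FitResult(model=model.name, unit=unit, domain=domain,
                       amounts=amounts, n=n, p=p)
    if best_theta is None or not converged:
        result.converged = False
        result.r2 = 0.0
        return result

    result.converged = True
    result.sse = best_sse
    result.r2, result.clamped = r_squared(best_sse, y_all)
    if result.clamped:
        result.params = {a: {"l": np.nan, "s": np.nan} for a in amounts}
    else:
        for amount, (l, s) in zip(amounts, _unpack(best_theta, model.n_params)):
            result.params[amount] = {
                "l": float(l),
                "s": float(s) if s is not None else np.nan,
            }
    return result


def fit_all(ip_table: pd.DataFrame,
            models=None,
            spec: DesignSpec | None = None,
            units: str = "both") -> pd.DataFrame:
    """Fit every model per (unit, domain) over an IP table.

    ``units`` selects ``"individual"``, ``"median"`` (group-median profile),
    or ``"both"``.  Per-unit failures are logged and skipped rather than
    aborting the batch.  Deterministic: the multi-start grid is fixed.
    """
    spec = spec or DesignSpec()
    if models is None:
        models = registry()
    models = [get_model(m) if isinstance(m, str) else m for m in models]

    tables = []
    if units in ("individual", "both"):
        tables.append(ip_table)
    if units in ("median", "both"):
        tables.append(group_median_ips(ip_table))
    if not tables:
        raise ValueError(f"units must be individual|median|both, got {units!r}")
    data = pd.concat(tables, ignore_index=True)

    rows = []
    for (unit, domain), grp in data.groupby(["participant_id", "domain"],
                                            sort=False):
        for model in models:
            try:
                fit = fit_joint(model, grp, spec, unit=str(unit),
                                domain=str(domain))
            except IncompleteCellsError as exc:
                log.warning("skipping %s/%s/%s: %s",
                            unit, domain, model.name, exc)
                continue
            rows.extend(fit.rows())
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
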