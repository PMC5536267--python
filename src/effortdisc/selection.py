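"""Information-criterion model selection (AIC, small-sample AICc, BIC).

All criteria are computed from the residual sum of squares of the joint fit:

    AIC  = n ln(SSe/n) + 2p
    AICc = AIC + 2p(p+1)/(n - p - 1)
    BIC  = n ln(SSe/n) + ln(n) p

with n the number of indifference points and p the number of free regression
parameters (3 for one-parameter models, 6 for two-parameter models, one
variant per reward magnitude).  Lower is better; within any comparison set
the criteria are reported as deltas from the best model (delta = 0).  Group
level selection is done both on the fit to median indifference points and on
criterion values summed across subjects (a fixed-effects aggregation).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

__all__ = ["aic", "aicc", "bic", "deltas", "selection_table",
           "aggregate_sum", "best_model_frequencies",
           "UndefinedCriterionError"]

log = logging.getLogger(__name__)


class UndefinedCriterionError(ValueError):
    """AICc is undefined when n <= p + 1."""


def aic(n: int, p: int, sse: float) -> float:
    """Akaike Information Criterion from SSe.

    A perfect fit (SSe = 0) has no finite least-squares AIC; a -inf sentinel
    is returned with a warning so that orderings remain well defined.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if sse < 0:
        raise ValueError(f"sse must be non-negative, got {sse}")
    if sse == 0.0:
        warnings.warn("SSe = 0 (perfect fit): AIC reported as -inf",
                      RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(sse / n) + 2.0 * p


def aicc(n: int, p: int, sse: float) -> float:
    """Second-order (small-sample) AIC."""
    if n - p - 1 <= 0:
        raise UndefinedCriterionError(
            f"AICc undefined for n={n}, p={p} (needs n > p + 1)")
    return aic(n, p, sse) + 2.0 * p * (p + 1) / (n - p - 1)


def bic(n: int, p: int, sse: float) -> float:
    """Bayesian Information Criterion from SSe."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if sse < 0:
        raise ValueError(f"sse must be non-negative, got {sse}")
    if sse == 0.0:
        warnings.warn("SSe = 0 (perfect fit): BIC reported as -inf",
                      RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(sse / n) + math.log(n) * p


def deltas(values) -> pd.Series:
    """Criterion deltas: value minus the best (lowest) value in the set."""
    s = pd.Series(values, dtype=float)
    if s.notna().sum() < 1:
        raise ValueError("deltas need at least one finite criterion value")
    best = s.min()
    if np.isneginf(best):
        # perfect-fit sentinel: that model is best (delta 0), every finite
        # competitor is infinitely worse; ordering is preserved
        return pd.Series(np.where(np.isneginf(s), 0.0, np.inf),
                         index=s.index)
    return s - best


def selection_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Per (unit, domain, model) criterion values from a long fits table.

    Rows with non-converged fits get NaN criteria.  Clamped fits (mean beat
    the model) keep their SSe-based criteria: the criterion is a property of
    the residuals, and excluding such subjects is the aggregation step's
    decision.
    """
    per_fit = (fits
               .drop_duplicates(subset=["unit", "domain", "model"])
               .loc[:, ["unit", "domain", "model", "sse", "n", "p",
                        "clamped", "converged"]]
               .reset_index(drop=True))
    out = []
    for row in per_fit.itertuples(index=False):
        if not row.converged or not np.isfinite(row.sse):
            a = c = b = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                a = aic(row.n, row.p, row.sse)
                c = aicc(row.n, row.p, row.sse)
                b = bic(row.n, row.p, row.sse)
        out.append({"unit": row.unit, "domain": row.domain,
                    "model": row.model, "aic": a, "aicc": c, "bic": b,
                    "clamped": bool(row.clamped),
                    "converged": bool(row.converged)})
    return pd.DataFrame(out)


def _usable(sel: pd.DataFrame, criterion: str) -> pd.DataFrame:
    """Listwise-complete unit x model criterion matrix for one domain.

    Units with any missing, infinite, clamped or non-converged entry are
    dropped (and logged): the paper-style summed comparison needs a finite
    value for every model.
    """
    wide = sel.pivot(index="unit", columns="model", values=criterion)
    flags = (sel.assign(bad=(~sel["converged"]) | sel["clamped"])
             .pivot(index="unit", columns="model", values="bad"))
    ok = wide.notna().all(axis=1) & np.isfinite(wide).all(axis=1) \
        & ~flags.fillna(True).any(axis=1)
    dropped = wide.index[~ok].tolist()
    if dropped:
        log.info("%s aggregation: dropping %d unit(s) listwise: %s",
                 criterion, len(dropped), dropped[:10])
    return wide.loc[ok]


def aggregate_sum(sel: pd.DataFrame, criterion: str = "aicc") -> pd.Series:
    """Summed-criterion deltas across subjects (fixed-effects aggregation).

    Sums the criterion per model over listwise-complete subjects, then
    converts to deltas from the best model.
    """
    wide = _usable(sel, criterion)
    if wide.empty:
        raise ValueError("no listwise-complete subjects to aggregate")
    return deltas(wide.sum(axis=0))


def best_model_frequencies(sel: pd.DataFrame,
                           criterion: str = "aicc") -> pd.DataFrame:
    """Counts and ratios of subjects for which each model fit best.

    Every model attaining a subject's minimum is credited (ties credited to
    all tied models and logged), so counts sum to >= the number of subjects,
    with equality iff there are no ties.
    """
    wide = _usable(sel, criterion)
    n_units = len(wide)
    if n_units == 0:
        raise ValueError("no listwise-complete subjects to count")
    mins = wide.min(axis=1)
    is_best = wide.eq(mins, axis=0)
    n_ties = int((is_best.sum(axis=1) > 1).sum())
    if n_ties:
        log.info("%s best-model count: %d subject(s) with ties", criterion,
                 n_ties)
    counts = is_best.sum(axis=0)
    return pd.DataFrame({
        "count": counts.astype(int),
        "ratio": counts / n_units,
    }).rename_axis("model")
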