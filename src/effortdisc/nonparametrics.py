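"""Nonparametric comparison suite for fit indices, parameters and non-fit counts.

The analysis mirrors standard discounting practice: omnibus Friedman tests
over related samples (model R² values, or one parameter across reward
magnitudes), pairwise Wilcoxon signed-rank tests with Šidák-corrected
p-values and the matched-pairs effect size r = |Z|/sqrt(N_obs) (N_obs = the
total observation count across both paired samples, i.e. 2 x pairs),
Cochran's Q with McNemar follow-ups for the counts of R² = 0 cases, and
Spearman rank correlations for parameter coherence across magnitudes and
effort domains.

The Friedman statistic is computed with mid-ranks and the tie-corrected
formula; the Wilcoxon Z uses the normal approximation with tie correction
and no continuity correction, dropping zero differences (classical
signed-rank convention).  The McNemar χ² is continuity-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "friedman", "wilcoxon_paired", "sidak",
           "cochran_q", "mcnemar", "spearman", "run_comparison_suite",
           "flatten_report"]

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One statistical test: statistic, p-values, effect size, extras."""

    name: str
    statistic: float
    p_raw: float
    df: int | None = None
    p_adjusted: float | None = None
    r: float | None = None
    mean_ranks: dict | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"name": self.name, "statistic": self.statistic,
               "p_raw": self.p_raw}
        if self.df is not None:
            out["df"] = self.df
        if self.p_adjusted is not None:
            out["p_adjusted"] = self.p_adjusted
        if self.r is not None:
            out["r"] = self.r
        if self.mean_ranks is not None:
            out["mean_ranks"] = self.mean_ranks
        out.update(self.extra)
        return out


def _complete_rows(matrix: pd.DataFrame, context: str) -> pd.DataFrame:
    complete = matrix.dropna(axis=0)
    dropped = len(matrix) - len(complete)
    if dropped:
        log.info("%s: dropped %d incomplete row(s) listwise", context, dropped)
    return complete


def friedman(matrix: pd.DataFrame) -> TestResult:
    """Friedman χ² over a units x conditions matrix, with mean ranks.

    Mid-ranks for ties; the tie-corrected statistic.  A matrix in which every
    row is fully tied carries no ordering information and yields χ² = 0.
    Incomplete rows are dropped listwise (logged).
    """
    matrix = _complete_rows(pd.DataFrame(matrix), "friedman")
    n, k = matrix.shape
    if k < 2 or n < 2:
        raise ValueError(f"friedman needs >=2 conditions and >=2 complete "
                         f"rows, got {matrix.shape}")
    ranks = np.apply_along_axis(sps.rankdata, 1, matrix.to_numpy(dtype=float))
    col_sums = ranks.sum(axis=0)
    mean_ranks = dict(zip(matrix.columns, (col_sums / n).round(10)))
    a = float((ranks ** 2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every row fully tied
        return TestResult("friedman", 0.0, 1.0, df=k - 1,
                          mean_ranks=mean_ranks, extra={"n": n})
    chi2 = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult("friedman", chi2, p, df=k - 1, mean_ranks=mean_ranks,
                      extra={"n": n})


def wilcoxon_paired(x, y) -> TestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; |differences| are mid-ranked; Z uses the
    tie-corrected normal approximation without continuity correction.  The
    effect size is r = |Z| / sqrt(2 * n_pairs) with n_pairs the original
    number of pairs.  Also reports counts of x > y / x = y / x < y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n_pairs = x.size
    d = x - y
    counts = {"better": int((d > 0).sum()), "tied": int((d == 0).sum()),
              "worse": int((d < 0).sum())}
    pct = {f"{k}_pct": 100.0 * v / n_pairs for k, v in counts.items()}
    if np.all(d == 0):
        return TestResult("wilcoxon", 0.0, 1.0, r=0.0,
                          extra={**counts, **pct, "n_pairs": n_pairs})
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                       method="approx")
    # sign convention: Z > 0 when x tends to exceed y
    z = -float(res.zstatistic)
    r = abs(z) / np.sqrt(2.0 * n_pairs)
    return TestResult("wilcoxon", z, float(res.pvalue), r=float(r),
                      extra={**counts, **pct, "n_pairs": n_pairs})


def sidak(p_raw: float, m: int) -> float:
    """Šidák correction for m comparisons: 1 - (1 - p)^m, capped at 1."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p_raw}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if p_raw == 1.0:
        return 1.0
    # -expm1(m log1p(-p)) keeps precision for tiny p (plain powering
    # underflows to 0 below p ~ 1e-16); the outer max guards the one-ulp
    # rounding that could otherwise push the adjusted p below the raw p
    return float(min(1.0, max(p_raw, -np.expm1(m * np.log1p(-p_raw)))))


def cochran_q(matrix: pd.DataFrame) -> TestResult:
    """Cochran's Q over a binary units x conditions matrix (1 = non-fit)."""
    matrix = _complete_rows(pd.DataFrame(matrix), "cochran_q")
    x = matrix.to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("cochran_q needs a binary matrix")
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - float((row ** 2).sum())
    if denom == 0.0:
        return TestResult("cochran_q", 0.0, 1.0, df=k - 1, extra={"n": n})
    q = k * (k - 1) * float(((col - col.mean()) ** 2).sum()) / denom
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult("cochran_q", q, p, df=k - 1, extra={"n": n})


def mcnemar(b: int, c: int) -> TestResult:
    """Continuity-corrected McNemar χ² from the discordant-pair counts.

    ``b`` and ``c`` are the two discordant cell counts of the paired 2x2
    table.  χ² = (|b - c| - 1)² / (b + c), df = 1.  With no discordant pairs
    the test is undefined and a flagged null result is returned.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return TestResult("mcnemar", np.nan, np.nan, df=1,
                          extra={"b": b, "c": c, "undefined": True})
    chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult("mcnemar", float(chi2), p, df=1,
                      extra={"b": int(b), "c": int(c)})


def spearman(x, y) -> TestResult:
    """Spearman rank correlation ρ with its p-value (mid-ranked ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("spearman needs n >= 3")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p),
                      extra={"n": int(x.size)})


# ---------------------------------------------------------------------------
# Full comparison suite
# ---------------------------------------------------------------------------

ONE_PARAM_SET = ("hyperbolic", "exponential", "parabolic")
TWO_PARAM_SET = ("myerson_green", "rachlin", "exp2", "power")


def _pivot(fits: pd.DataFrame, domain: str, value: str,
           model: str | None = None) -> pd.DataFrame:
    sub = fits[(fits["domain"] == domain)
               & (fits["unit"] != "MEDIAN")]
    if model is not None:
        sub = sub[sub["model"] == model]
        return sub.pivot_table(index="unit", columns="magnitude",
                               values=value, aggfunc="first")
    sub = sub.drop_duplicates(subset=["unit", "model"])
    return sub.pivot(index="unit", columns="model", values=value)


def _pairwise_wilcoxon(matrix: pd.DataFrame) -> dict:
    cols = list(matrix.columns)
    m = len(cols) * (len(cols) - 1) // 2
    out = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = matrix[[a, b]].dropna()
            res = wilcoxon_paired(pair[a], pair[b])
            res.p_adjusted = sidak(res.p_raw, m)
            out[f"{a}_vs_{b}"] = res.to_dict()
    return out


def _pairwise_mcnemar(binary: pd.DataFrame) -> dict:
    cols = list(binary.columns)
    m = len(cols) * (len(cols) - 1) // 2
    out = {}
    for i, a in enumerate(cols):
        for b_col in cols[i + 1:]:
            pair = binary[[a, b_col]].dropna()
            b = int(((pair[a] == 1) & (pair[b_col] == 0)).sum())
            c = int(((pair[a] == 0) & (pair[b_col] == 1)).sum())
            res = mcnemar(b, c)
            if np.isfinite(res.p_raw):
                res.p_adjusted = sidak(res.p_raw, m)
            out[f"{a}_vs_{b_col}"] = res.to_dict()
    return out


def _spearman_matrix(wide: pd.DataFrame) -> dict:
    cols = list(wide.columns)
    out = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                continue
            out[f"{a}_vs_{b}"] = spearman(pair[a], pair[b]).to_dict()
    return out


def run_comparison_suite(fits: pd.DataFrame,
                    reference_model: str = "power") -> dict:
    """Run the full comparison suite on a long fits table.

    Emits, per effort domain: Friedman + pairwise Wilcoxon (Šidák) over the
    R² of the one- and two-parameter model sets; Friedman + pairwise
    Wilcoxon over l (and s) of ``reference_model`` across reward magnitudes;
    Cochran's Q + pairwise McNemar over the R² = 0 indicators; Spearman
    matrices for l and s across magnitudes.  Cross-domain Spearman
    correlations of l and s per magnitude close the report.
    """
    report: dict = {"reference_model": reference_model, "domains": {},
                    "cross_domain": {}}
    domains = sorted(d for d in fits["domain"].unique())
    for domain in domains:
        dom: dict = {}
        for label, model_set in (("one_parameter", ONE_PARAM_SET),
                                 ("two_parameter", TWO_PARAM_SET)):
            r2 = _pivot(fits, domain, "r2")
            present = [m for m in model_set if m in r2.columns]
            if len(present) < 2:
                continue
            r2 = r2[present].dropna()
            block = {"friedman": friedman(r2).to_dict(),
                     "pairwise_wilcoxon": _pairwise_wilcoxon(r2)}
            clamped = _pivot(fits, domain, "clamped")[present].dropna()
            block["nonfit_counts"] = {
                m: int(clamped[m].sum()) for m in present}
            block["cochran_q"] = cochran_q(clamped.astype(int)).to_dict()
            block["pairwise_mcnemar"] = _pairwise_mcnemar(clamped.astype(int))
            dom[f"{label}_models"] = block

        for param in ("l", "s"):
            wide = _pivot(fits, domain, param, model=reference_model).dropna()
            if wide.empty or wide.shape[1] < 2:
                continue
            wide.columns = [f"{param}_{int(c)}" for c in wide.columns]
            dom[f"magnitude_effect_{param}"] = {
                "friedman": friedman(wide).to_dict(),
                "pairwise_wilcoxon": _pairwise_wilcoxon(wide),
            }
            dom[f"{param}_correlations"] = _spearman_matrix(wide)
        report["domains"][domain] = dom

    if len(domains) == 2:
        d1, d2 = domains
        for param in ("l", "s"):
            w1 = _pivot(fits, d1, param, model=reference_model)
            w2 = _pivot(fits, d2, param, model=reference_model)
            block = {}
            for mag in [c for c in w1.columns if c in w2.columns]:
                pair = pd.concat([w1[mag], w2[mag]], axis=1,
                                 keys=[d1, d2]).dropna()
                if len(pair) < 3:
                    continue
                block[f"{param}_{int(mag)}"] = spearman(
                    pair[d1], pair[d2]).to_dict()
            report["cross_domain"][param] = block
    return report


def flatten_report(report: dict) -> pd.DataFrame:
    """Flatten the nested suite report into a tidy table for stats.csv."""
    rows: list[dict] = []

    def walk(prefix: list[str], node) -> None:
        if isinstance(node, dict):
            if "name" in node and "statistic" in node:
                rows.append({
                    "context": "/".join(prefix),
                    "test": node.get("name"),
                    "statistic": node.get("statistic"),
                    "df": node.get("df"),
                    "p_raw": node.get("p_raw"),
                    "p_adjusted": node.get("p_adjusted"),
                    "r": node.get("r"),
                })
            else:
                for key, value in node.items():
                    walk(prefix + [str(key)], value)

    walk([], report)
    return pd.DataFrame(rows)
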