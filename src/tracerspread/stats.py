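"""Statistical tests behind one uniform TestOutcome contract.

All routines are two-sided and assess significance at alpha = 0.05. Where a
vetted scipy/statsmodels routine exists it is used internally; Dunn's post
hoc test (rank-based pairwise z after Kruskal-Wallis, Bonferroni-corrected)
is implemented here directly.

Exact vs approximate conventions, recorded in each outcome's ``notes``:

* Wilcoxon signed-rank: zeros dropped; exact null distribution when the
  number of nonzero differences is <= 25 and their absolute values are
  untied, otherwise normal approximation with tie/zero handling.
* Mann-Whitney U: exact when the pooled sample is <= 12 without ties,
  otherwise normal approximation with tie correction.
* Kolmogorov-Smirnov normality uses estimated mean/sd with the Lilliefors
  small-sample correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

ALPHA = 0.05

__all__ = [
    "TestOutcome",
    "test_normality",
    "kruskal_wallis",
    "dunn_bonferroni",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "paired_t_test",
]


@dataclass
class TestOutcome:
    """Uniform result record for every statistical test in the pipeline."""

    name: str
    statistic: float
    pvalue: float
    df: float | None = None
    pairwise: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < ALPHA)


def _asarray(x, name="values") -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size and not np.isfinite(a).all():
        raise ValueError(f"{name} contain non-finite entries")
    return a


def test_normality(values, method: str = "shapiro-wilk") -> TestOutcome:
    """Test departure from normality (Shapiro-Wilk or KS/Lilliefors)."""
    v = _asarray(values)
    if v.size < 3:
        raise ValueError("need at least 3 values for a normality test")
    if v.std() == 0:
        raise ValueError("constant values: normality test undefined")
    if method == "shapiro-wilk":
        res = sps.shapiro(v)
        return TestOutcome(name="shapiro-wilk", statistic=float(res.statistic),
                           pvalue=float(res.pvalue))
    if method == "kolmogorov-smirnov":
        stat, p = lilliefors(v, dist="norm")
        return TestOutcome(
            name="kolmogorov-smirnov", statistic=float(stat), pvalue=float(p),
            notes={"variant": "estimated mean/sd (Lilliefors correction)"})
    raise ValueError(f"unknown normality test {method!r}")


def kruskal_wallis(groups, labels=None) -> TestOutcome:
    """Kruskal-Wallis rank test with tie correction, chi-square p with k-1 df."""
    gs = [_asarray(g, "group") for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    pooled = np.concatenate(gs)
    df = len(gs) - 1
    if np.ptp(pooled) == 0:
        # all values identical: H = 0 after tie correction, p -> 1
        return TestOutcome(name="kruskal-wallis", statistic=0.0, pvalue=1.0,
                           df=df, notes={"degenerate": "all values tied"})
    res = sps.kruskal(*gs)
    return TestOutcome(name="kruskal-wallis", statistic=float(res.statistic),
                       pvalue=float(res.pvalue), df=df,
                       notes={"labels": labels})


def dunn_bonferroni(groups, labels=None) -> TestOutcome:
    """Dunn's pairwise post hoc z tests on mean ranks, Bonferroni-corrected.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); raw two-sided p from the normal
    tail; corrected p = min(1, raw * k(k-1)/2).
    """
    gs = [_asarray(g, "group") for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(gs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1)) \
        if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom == 0:
            z, raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / denom
            raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p_raw": float(raw),
                     "p_corrected": float(min(1.0, raw * m)),
                     "significant": bool(min(1.0, raw * m) < ALPHA)})
    table = pd.DataFrame(rows)
    min_p = float(table["p_corrected"].min())
    return TestOutcome(name="dunn-bonferroni",
                       statistic=float(table["z"].abs().max()),
                       pvalue=min_p, pairwise=table,
                       notes={"n_comparisons": m})


def wilcoxon_signed_rank(x, y=None) -> TestOutcome:
    """Wilcoxon signed-rank test on paired data (or one-sample differences).

    Reports W+ (sum of ranks of positive differences). Zeros are dropped
    before ranking; exact p when the nonzero differences are <= 25 and their
    absolute values untied, else normal approximation.
    """
    x = _asarray(x, "x")
    d = x - _asarray(y, "y") if y is not None else x
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 3:
        raise ValueError("need at least 3 nonzero differences")
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    exact = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    res = sps.wilcoxon(nz, alternative="two-sided",
                       method="exact" if exact else "approx",
                       zero_method="wilcox")
    return TestOutcome(name="wilcoxon-signed-rank", statistic=w_plus,
                       pvalue=float(res.pvalue),
                       notes={"n_nonzero": int(nz.size),
                              "method": "exact" if exact else
                              "normal approximation"})


def mann_whitney_u(x, y) -> TestOutcome:
    """Mann-Whitney U test (unpaired two-sample rank test).

    Reports U of the first sample. Exact p for small untied samples
    (pooled n <= 12), asymptotic with tie correction otherwise.
    """
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size + y.size < 3:
        raise ValueError("combined sample too small")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestOutcome(name="mann-whitney-u", statistic=float(res.statistic),
                       pvalue=float(res.pvalue),
                       notes={"method": "exact" if exact else
                              "normal approximation with tie correction"})


def paired_t_test(x, y) -> TestOutcome:
    """Paired t test on x - y; t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = sps.ttest_rel(x, y)
    return TestOutcome(name="paired-t", statistic=float(res.statistic),
                       pvalue=float(res.pvalue), df=float(x.size - 1),
                       notes={"mean_difference": float(d.mean())})
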