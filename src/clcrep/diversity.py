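"""Repertoire diversity statistics and group comparisons.

Gini coefficient and D50 summarise the inequality of a count vector
(clonotype sizes or V-gene usage).  Gini uses the population mean-absolute-
difference form, G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² μ), including zero categories and
without small-sample correction, so a one-hot vector scores (n−1)/n.  D50 is
the smallest number of categories whose (descending) counts reach at least
half the total.  Both are permutation- and scale-invariant.

Group comparisons follow the analysis conventions of the study design:
two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment across
a batch, and Pearson chi-squared (no continuity correction) for usage
vectors over a shared, zero-filled label space.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, UndefinedStatisticError

DEFAULT_TOPN_RANGES = ((1, 10), (11, 50), (51, 500))


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ParameterError("counts must be a non-empty 1-D vector")
    if (arr < 0).any():
        raise ParameterError("counts must be non-negative")
    if arr.sum() == 0:
        raise UndefinedStatisticError("statistic undefined for an all-zero count vector")
    return arr


def gini(counts) -> float:
    """Gini coefficient of a count vector (0 = even, (n−1)/n = one-hot)."""
    x = np.sort(_as_counts(counts))
    n = x.size
    # Σᵢⱼ|xᵢ−xⱼ| / (2n²μ) via the sorted identity Σᵢ (2i−n−1) x₍ᵢ₎ / (n Σx)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * x.sum()))


def d50(counts) -> int:
    """Smallest k such that the k largest counts reach >= 50% of the total."""
    x = np.sort(_as_counts(counts))[::-1]
    cum = np.cumsum(x)
    return int(np.searchsorted(cum, 0.5 * cum[-1]) + 1)


def topn_fraction(counts, ranges=DEFAULT_TOPN_RANGES) -> dict[tuple[int, int], float]:
    """Fraction of the repertoire held by rank ranges of the sorted counts.

    ``ranges`` are inclusive 1-based rank intervals (e.g. (1, 10) = the ten
    largest categories); ranks beyond the number of categories contribute 0.
    """
    x = np.sort(_as_counts(counts))[::-1]
    prev_end = 0
    for start, end in ranges:
        if start <= prev_end or end < start:
            raise ParameterError("ranges must be disjoint ascending rank intervals")
        prev_end = end
    total = x.sum()
    return {
        (start, end): float(x[start - 1 : min(end, x.size)].sum() / total)
        for start, end in ranges
    }


@dataclasses.dataclass
class DiversitySummary:
    n_categories: int
    gini: float
    d50: int
    topn_fractions: dict[tuple[int, int], float]

    def to_dict(self) -> dict:
        return {
            "n_categories": self.n_categories,
            "gini": self.gini,
            "d50": self.d50,
            "topn_fractions": {f"{a}-{b}": v for (a, b), v in self.topn_fractions.items()},
        }


def summarize(counts, ranges=DEFAULT_TOPN_RANGES) -> DiversitySummary:
    x = _as_counts(counts)
    return DiversitySummary(
        n_categories=int(x.size),
        gini=gini(x),
        d50=d50(x),
        topn_fractions=topn_fraction(x, ranges),
    )


def downsample(cells: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n`` cells without replacement; deterministic by seed.

    Clonotypes must be re-assigned on the subsample, so any existing
    ``clonotype_id`` column is dropped.
    """
    if n > len(cells):
        raise ParameterError(f"cannot downsample {len(cells)} cells to {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    out = cells.iloc[np.sort(idx)].reset_index(drop=True)
    return out.drop(columns=["clonotype_id"], errors="ignore")


_USAGE_FIELDS = {"v_call_heavy", "v_call_light", "c_call", "locus"}


def usage_table(records: pd.DataFrame, field: str = "v_call_heavy") -> pd.Series:
    """Gene-level usage counts from a long rearrangement table."""
    if field not in _USAGE_FIELDS:
        raise ParameterError(f"unknown usage field {field!r}; one of {sorted(_USAGE_FIELDS)}")
    if field == "v_call_heavy":
        sub = records[records["locus"] == "IGH"]["v_call"]
    elif field == "v_call_light":
        sub = records[records["locus"].isin(["IGK", "IGL"])]["v_call"]
    else:
        sub = records[field]
    counts = sub[sub != ""].value_counts().sort_index()
    counts.name = field
    return counts


def align_usage(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Zero-fill two usage vectors onto the union of their labels."""
    labels = sorted(set(a.index) | set(b.index))
    return a.reindex(labels, fill_value=0), b.reindex(labels, fill_value=0)


def compare_usage_chisq(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """Pearson chi-squared comparing two usage vectors.

    The vectors are zero-filled onto their shared label space, categories
    with pooled count zero are dropped, and the standard (uncorrected)
    Pearson statistic is computed on the resulting 2×K table.
    """
    a, b = align_usage(a, b)
    table = np.vstack([a.to_numpy(float), b.to_numpy(float)])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ParameterError("chi-squared needs at least 2 informative categories")
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact when both samples are small and tie-free, otherwise the
    tie-corrected normal approximation.  Two identical degenerate samples
    (all values tied across both groups) return p = 1 by the documented
    exact-tie policy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (not has_ties and x.size <= 25 and y.size <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values for a batch of tests."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def compare_groups_wilcoxon(x, y, adjust: str | None = None,
                            batch_pvalues=None) -> tuple[float, float]:
    """Rank-sum p-value for one comparison, optionally BH-adjusted in a batch.

    When ``adjust="bh"``, the returned adjusted p is computed across
    ``batch_pvalues`` plus this comparison's p (a single comparison adjusts
    to itself).
    """
    p = wilcoxon_rank_sum(x, y)
    if adjust is None:
        return p, p
    if adjust != "bh":
        raise ParameterError(f"unknown adjustment {adjust!r} (only 'bh')")
    batch = list(batch_pvalues or []) + [p]
    return p, float(benjamini_hochberg(batch)[-1])


def wilcoxon_batch(pairs, adjust: str = "bh") -> pd.DataFrame:
    """Rank-sum tests for a batch of (x, y) pairs with joint BH adjustment."""
    ps = [wilcoxon_rank_sum(x, y) for x, y in pairs]
    adj = benjamini_hochberg(ps) if adjust == "bh" else np.asarray(ps)
    return pd.DataFrame({"p_value": ps, "adjusted_p": adj})
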