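"""Competitive epitope binning from bead-fluorescence geometric means.

The competition statistic is the net geomean: the total fluorescence of a
(reference antibody + panel antibody) bead minus the reference antibody's
single-bead control.  Each panel antibody's net geomeans across the
reference set form its competitive binding profile; profiles are compared
by Pearson correlation, and antibodies are grouped into epitope bins by
single-linkage agglomeration at a configurable correlation threshold
(default r >= 0.8).  Negative net geomeans are kept (clipping would distort
the correlations) but logged.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["reference_id", "panel_id", "total_geomean", "reference_alone_geomean"]


@dataclasses.dataclass
class BeadGeomeanTable:
    """Complete reference × panel total-geomean matrix plus single-bead controls."""

    total_geomean: pd.DataFrame      # index: reference ids, columns: panel ids
    reference_alone: pd.Series       # index: reference ids

    def __post_init__(self) -> None:
        if self.total_geomean.isna().any().any():
            raise FormatError("total_geomean matrix has missing cells")
        missing = [r for r in self.total_geomean.index if r not in self.reference_alone.index]
        if missing:
            raise FormatError(
                f"missing reference_alone entry for reference(s): {', '.join(map(str, missing))}"
            )
        if (self.total_geomean.to_numpy() < 0).any() or (self.reference_alone < 0).any():
            raise FormatError("geomeans must be non-negative")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "BeadGeomeanTable":
        """Build from a long table (reference_id, panel_id, total_geomean,
        reference_alone_geomean)."""
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"long binning table missing column(s): {', '.join(missing)}")
        total = df.pivot(index="reference_id", columns="panel_id", values="total_geomean")
        alone = df.groupby("reference_id")["reference_alone_geomean"].first()
        return cls(total_geomean=total.astype(float), reference_alone=alone.astype(float))

    def to_long(self) -> pd.DataFrame:
        long = self.total_geomean.stack().rename("total_geomean").reset_index()
        long["reference_alone_geomean"] = long["reference_id"].map(self.reference_alone)
        return long[LONG_COLUMNS]


def net_geomean(table: BeadGeomeanTable) -> pd.DataFrame:
    """net[r, p] = total_geomean[r, p] − reference_alone[r] (not clipped)."""
    net = table.total_geomean.sub(table.reference_alone, axis=0)
    n_neg = int((net.to_numpy() < 0).sum())
    if n_neg:
        logger.info("net geomean: %d negative value(s) retained", n_neg)
    return net


def correlate_profiles(net: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between panel-antibody competition profiles.

    Profiles are the columns of the net matrix (one value per reference; at
    least two references are required).  Zero-variance profiles have no
    defined correlation: they are excluded and returned as flagged ids.
    """
    if net.shape[0] < 2:
        raise ParameterError("correlation needs profiles over >= 2 references")
    variances = net.var(axis=0, ddof=0)
    flagged = [str(c) for c in net.columns[variances == 0]]
    if flagged:
        logger.warning("zero-variance profile(s) excluded from binning: %s", flagged)
    valid = net.loc[:, variances > 0]
    r = np.corrcoef(valid.to_numpy(), rowvar=False)
    r = np.atleast_2d(r)
    r_matrix = pd.DataFrame(r, index=valid.columns, columns=valid.columns)
    return r_matrix, flagged


@dataclasses.dataclass
class BinAssignment:
    r_matrix: pd.DataFrame
    threshold: float
    bins: dict[str, str]                 # antibody id -> bin label
    excluded: list[str] = dataclasses.field(default_factory=list)

    def bin_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for ab, label in self.bins.items():
            members.setdefault(label, []).append(ab)
        return {k: sorted(v) for k, v in sorted(members.items())}


def _bin_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — spreadsheet-style labels."""
    labels = []
    for i in range(n):
        label, j = "", i
        while True:
            label = chr(ord("A") + j % 26) + label
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(label)
    return labels


def assign_bins(r_matrix: pd.DataFrame, threshold: float = 0.8,
                excluded: list[str] | None = None) -> BinAssignment:
    """Group antibodies into epitope bins by single-linkage at ``threshold``.

    Two antibodies share a bin iff they are connected by a chain of profile
    pairs with r >= threshold.  Bins are labelled A, B, ... by decreasing
    size, ties broken by the lexicographically first member, so the output
    is deterministic and invariant to input permutation up to renaming.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    ids = [str(c) for c in r_matrix.columns]
    adjacency = (r_matrix.to_numpy() >= threshold).astype(int)
    n_comp, membership = connected_components(csr_matrix(adjacency), directed=False)
    groups: dict[int, list[str]] = {}
    for ab, comp in zip(ids, membership):
        groups.setdefault(int(comp), []).append(ab)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))
    labels = _bin_labels(len(ordered))
    bins = {ab: lab for lab, group in zip(labels, ordered) for ab in group}
    return BinAssignment(
        r_matrix=r_matrix,
        threshold=threshold,
        bins={ab: bins[ab] for ab in ids},
        excluded=list(excluded or []),
    )


def benchmark_binning(
    net: pd.DataFrame,
    panel_ids: list[str],
    benchmark_bins: dict[str, str],
    threshold: float = 0.8,
    min_suppression: float = 0.5,
) -> pd.DataFrame:
    """Assign panel antibodies to benchmark bins or flag them as novel.

    ``net`` must contain both the panel and the benchmark antibodies as
    columns (profiles over the same references).  A panel antibody matches
    a benchmark's bin iff (a) it shows real competition somewhere on the
    reference set — its minimum net geomean falls below ``min_suppression``
    times its maximum, the dark-cell criterion a binning heatmap is read
    by — and (b) its profile correlation with that benchmark is
    >= ``threshold`` (best-correlated benchmark wins).  Without the
    suppression gate a flat, non-competing profile can correlate with a
    benchmark through measurement noise alone on a short reference panel.
    Antibodies matching no benchmark are flagged novel.
    """
    if not benchmark_bins:
        raise ParameterError("benchmark set is empty")
    missing = [b for b in benchmark_bins if b not in net.columns]
    if missing:
        raise ParameterError(f"benchmark profile(s) missing from net matrix: {missing}")
    rows = []
    bench_ids = list(benchmark_bins)
    bench = net[bench_ids].to_numpy()
    for ab in panel_ids:
        prof = net[ab].to_numpy()
        competes = prof.min() < min_suppression * prof.max()
        rs = [float(np.corrcoef(prof, bench[:, j])[0, 1]) for j in range(len(bench_ids))]
        best = int(np.argmax(rs))
        matched = bool(competes and rs[best] >= threshold)
        rows.append({
            "panel_id": ab,
            "best_benchmark": bench_ids[best],
            "best_r": rs[best],
            "competes": bool(competes),
            "bin": benchmark_bins[bench_ids[best]] if matched else "novel",
            "novel": not matched,
        })
    return pd.DataFrame(rows)
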