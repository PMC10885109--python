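"""Amino-acid mutation profiling of light chains against the prearranged germline.

Each light chain is compared position-by-position with the germline: equal
lengths give a direct positional comparison; length differences trigger a
global alignment (match +2, mismatch −1, gap open −8, gap extend −0.5) in
which gap columns are flagged as indels and excluded from substitution
counting.  A record whose aligned identity falls below 50% is rejected with
a logged reason.  Per-position mutation frequencies are reported on the
Chothia labels of the germline; region summaries use the packaged CDR/FR
label ranges.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from . import germlines as gl
from .errors import AlignmentRejected, ParameterError

logger = logging.getLogger(__name__)

MIN_ALIGNED_IDENTITY = 0.5


@dataclasses.dataclass
class AlignedPair:
    """Column-wise comparison of a sequence against its germline.

    ``germ_res``/``seq_res`` hold one character per alignment column ("-"
    for a gap); ``germ_index`` is the germline index of each column (-1 in
    germline gaps).
    """

    germ_index: list[int]
    germ_res: list[str]
    seq_res: list[str]

    @property
    def n_indel_columns(self) -> int:
        return sum(g == "-" or s == "-" for g, s in zip(self.germ_res, self.seq_res))

    def mismatched_germ_indices(self) -> list[int]:
        """Germline indices of substituted (non-gap, mismatching) columns."""
        return [
            gi
            for gi, g, s in zip(self.germ_index, self.germ_res, self.seq_res)
            if g != "-" and s != "-" and g != s
        ]

    def covered_germ_indices(self) -> list[int]:
        """Germline indices aligned to a residue (not deleted)."""
        return [
            gi
            for gi, g, s in zip(self.germ_index, self.germ_res, self.seq_res)
            if g != "-" and s != "-"
        ]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_to_germline(seq_aa: str, germline_aa: str) -> AlignedPair:
    """Position-wise comparison of a light chain against its germline."""
    if not seq_aa or not germline_aa:
        raise ParameterError("both sequences must be non-empty")
    if len(seq_aa) == len(germline_aa):
        pair = AlignedPair(
            germ_index=list(range(len(germline_aa))),
            germ_res=list(germline_aa),
            seq_res=list(seq_aa),
        )
    else:
        alignment = _aligner().align(germline_aa, seq_aa)[0]
        germ_aligned, seq_aligned = str(alignment[0]), str(alignment[1])
        germ_index, gi = [], 0
        for ch in germ_aligned:
            germ_index.append(gi if ch != "-" else -1)
            if ch != "-":
                gi += 1
        pair = AlignedPair(
            germ_index=germ_index,
            germ_res=list(germ_aligned),
            seq_res=list(seq_aligned),
        )
    covered = pair.covered_germ_indices()
    if covered:
        identity = 1.0 - len(pair.mismatched_germ_indices()) / len(covered)
    else:
        identity = 0.0
    if identity < MIN_ALIGNED_IDENTITY:
        raise AlignmentRejected(
            f"aligned identity {identity:.2f} below floor {MIN_ALIGNED_IDENTITY}"
        )
    return pair


def mutation_count(seq_aa: str, germline_aa: str) -> int:
    """Number of substituted positions (indel columns excluded)."""
    return len(align_to_germline(seq_aa, germline_aa).mismatched_germ_indices())


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment amino-acid identity over aligned non-gap columns."""
    if not a or not b:
        raise ParameterError("both sequences must be non-empty")
    alignment = _aligner().align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    pairs = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


@dataclasses.dataclass
class MutationProfile:
    """Aggregated SHM profile of a light-chain repertoire."""

    labels: list[str]
    per_position_freq: dict[str, float]
    per_position_covered: dict[str, int]
    per_sequence_counts: dict[int, int]
    mean_mutations: float
    region_defs: dict[str, list[str]]
    region_any_mutation_fraction: dict[str, float]
    no_cdr_mutation_fraction: float
    n_records: int
    n_rejected: int

    def to_frame(self):
        import pandas as pd

        label_region = {}
        for region, labs in self.region_defs.items():
            for lab in labs:
                label_region[lab] = region
        return pd.DataFrame({
            "label": self.labels,
            "region": [label_region.get(lab, "") for lab in self.labels],
            "n_covered": [self.per_position_covered[lab] for lab in self.labels],
            "freq": [self.per_position_freq[lab] for lab in self.labels],
        })


def profile(
    sequences: Sequence[str],
    germline_set: gl.GermlineSet | None = None,
    regions: Mapping[str, list[str]] | None = None,
) -> MutationProfile:
    """Profile light-chain amino-acid mutations against the prearranged germline.

    ``sequences`` are kappa V-domains assigned to the prearranged germline.
    Records that align below the identity floor are dropped (counted in
    ``n_rejected``); records with indels contribute only at non-gap labels.
    """
    germline_set = germline_set or gl.default_germlines()
    regions = dict(regions) if regions is not None else gl.load_regions()
    if len(sequences) == 0:
        raise ParameterError("cannot profile an empty set of light chains")

    germ = germline_set.prearranged_lc
    labels = germline_set.labels
    n_pos = len(labels)
    mutated = np.zeros(n_pos, dtype=int)
    covered = np.zeros(n_pos, dtype=int)
    per_seq_counts: Counter[int] = Counter()
    cdr_label_set = {
        lab for name, labs in regions.items() if name.startswith("CDR") for lab in labs
    }
    region_any = {name: 0 for name in regions}
    n_no_cdr_mut = 0
    n_rejected = 0

    for seq in sequences:
        try:
            pair = align_to_germline(seq, germ)
        except AlignmentRejected as exc:
            logger.info("record rejected: %s", exc)
            n_rejected += 1
            continue
        hits = pair.mismatched_germ_indices()
        cov = pair.covered_germ_indices()
        mutated[hits] += 1
        covered[cov] += 1
        per_seq_counts[len(hits)] += 1
        hit_labels = {labels[i] for i in hits}
        for name, labs in regions.items():
            if hit_labels & set(labs):
                region_any[name] += 1
        if not (hit_labels & cdr_label_set):
            n_no_cdr_mut += 1

    n_ok = sum(per_seq_counts.values())
    if n_ok == 0:
        raise ParameterError("all records were rejected by the alignment floor")

    freq = {
        lab: (mutated[i] / covered[i] if covered[i] else 0.0)
        for i, lab in enumerate(labels)
    }
    mean_mut = sum(k * v for k, v in per_seq_counts.items()) / n_ok
    return MutationProfile(
        labels=labels,
        per_position_freq=freq,
        per_position_covered={lab: int(covered[i]) for i, lab in enumerate(labels)},
        per_sequence_counts=dict(sorted(per_seq_counts.items())),
        mean_mutations=mean_mut,
        region_defs=dict(regions),
        region_any_mutation_fraction={
            name: region_any[name] / n_ok for name in regions
        },
        no_cdr_mutation_fraction=n_no_cdr_mut / n_ok,
        n_records=n_ok,
        n_rejected=n_rejected,
    )


def hotspot_report(prof: MutationProfile, k: int) -> list[dict]:
    """Top-``k`` positions by mutation frequency, annotated with their region.

    Ties are broken by label order (the germline numbering order).  If ``k``
    exceeds the number of labels the report is truncated with a warning.
    """
    if k > len(prof.labels):
        logger.warning("k = %d exceeds %d labels; truncating", k, len(prof.labels))
        k = len(prof.labels)
    label_region = {}
    for region, labs in prof.region_defs.items():
        for lab in labs:
            label_region[lab] = region
    order = {lab: i for i, lab in enumerate(prof.labels)}
    ranked = sorted(
        prof.labels, key=lambda lab: (-prof.per_position_freq[lab], order[lab])
    )
    return [
        {
            "label": lab,
            "freq": prof.per_position_freq[lab],
            "region": label_region.get(lab, ""),
        }
        for lab in ranked[:k]
    ]
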