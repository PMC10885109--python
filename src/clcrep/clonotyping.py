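"""Clonotype assignment, consensus, liability flags and clone selection.

A clonotype is the set of paired cells sharing the same heavy V gene, the
same CDR-H3 length and at least ``threshold`` (default 0.8) CDR-H3
amino-acid identity to the cluster representative.  Clustering is greedy and
incremental in the CD-HIT style: within each (V gene, CDR-H3 length) block,
unique CDR-H3s are processed in descending multiplicity (ties broken
lexicographically); each joins the first existing cluster whose
representative it matches at or above the threshold, otherwise it founds a
new cluster.  The ordering rule makes the output deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections import Counter

import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

_SEQUON = re.compile(r"N[^P][ST]")
_AA_ONLY = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]*$")


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of positions with equal residues; sequences must align 1:1."""
    if len(a) != len(b) or not a:
        raise ParameterError(
            f"cdr3_identity requires equal non-zero lengths (got {len(a)} and {len(b)}); "
            "partition sequences by CDR-H3 length first"
        )
    return sum(x == y for x, y in zip(a, b)) / len(a)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ParameterError(f"hamming requires equal lengths (got {len(a)} and {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def consensus_sequence(members: list[str]) -> str:
    """Per-position modal residue; ties go to the lexicographically smallest."""
    if not members:
        raise ParameterError("consensus of an empty member list is undefined")
    length = len(members[0])
    if any(len(m) != length for m in members):
        raise ParameterError(
            "consensus requires equal-length sequences; align members upstream"
        )
    out = []
    for i in range(length):
        counts = Counter(m[i] for m in members)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        # max count, then smallest residue: invert ordinal for the tie-break
        out.append(best[0])
    return "".join(out)


def greedy_cluster(cdr3s: list[str], threshold: float) -> list[int]:
    """Cluster equal-length CDR-H3s; returns a cluster index per input sequence.

    Implements the documented ordering: unique sequences sorted by
    (multiplicity descending, sequence ascending); each joins the first
    cluster whose *representative* (founder) matches at >= threshold.
    """
    counts = Counter(cdr3s)
    order = sorted(counts, key=lambda s: (-counts[s], s))
    representatives: list[str] = []
    assignment: dict[str, int] = {}
    for seq in order:
        for idx, rep in enumerate(representatives):
            if cdr3_identity(seq, rep) >= threshold:
                assignment[seq] = idx
                break
        else:
            assignment[seq] = len(representatives)
            representatives.append(seq)
    return [assignment[s] for s in cdr3s]


def assign_clonotypes(
    paired: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition paired cells into clonotypes.

    Parameters
    ----------
    paired
        Wide per-cell table from :func:`clcrep.io.pair_cells` (needs
        ``heavy_v_call`` and ``heavy_cdr3_aa``).
    threshold
        Minimum CDR-H3 identity to the cluster representative, in (0, 1].

    Returns
    -------
    (clonotypes, membership)
        ``clonotypes``: one row per clonotype (id, v_gene, cdr3_length,
        size, representative_cdr3).  ``membership``: the input table plus a
        ``clonotype_id`` column.  Clonotype ids are ordered by size
        descending, then (v_gene, representative CDR-H3).
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    if paired.empty:
        raise ParameterError("cannot clonotype an empty cell table")

    paired = paired.reset_index(drop=True)
    keys = pd.DataFrame({
        "v_gene": paired["heavy_v_call"],
        "cdr3": paired["heavy_cdr3_aa"],
        "cdr3_length": paired["heavy_cdr3_aa"].str.len(),
    })

    cluster_of_row = [None] * len(paired)
    clusters: list[dict] = []
    for (v_gene, length), block in keys.groupby(["v_gene", "cdr3_length"], sort=True):
        labels = greedy_cluster(block["cdr3"].tolist(), threshold)
        # representative = founder = first sequence (in greedy order) that
        # created the cluster
        counts = Counter(block["cdr3"])
        greedy_order = sorted(counts, key=lambda s: (-counts[s], s))
        local_by_seq = dict(zip(block["cdr3"], labels))
        founder_by_local: dict[int, str] = {}
        for seq in greedy_order:
            founder_by_local.setdefault(local_by_seq[seq], seq)
        base = len(clusters)
        n_local = max(labels) + 1 if labels else 0
        for local in range(n_local):
            clusters.append({
                "v_gene": v_gene,
                "cdr3_length": int(length),
                "representative_cdr3": founder_by_local[local],
                "size": 0,
            })
        for row_idx, local in zip(block.index, labels):
            cluster_of_row[row_idx] = base + local
            clusters[base + local]["size"] += 1

    order = sorted(
        range(len(clusters)),
        key=lambda i: (-clusters[i]["size"], clusters[i]["v_gene"], clusters[i]["representative_cdr3"]),
    )
    id_of_cluster = {old: f"CT{rank + 1:05d}" for rank, old in enumerate(order)}

    clonotypes = pd.DataFrame([
        {
            "clonotype_id": id_of_cluster[i],
            "v_gene": clusters[i]["v_gene"],
            "cdr3_length": clusters[i]["cdr3_length"],
            "size": clusters[i]["size"],
            "representative_cdr3": clusters[i]["representative_cdr3"],
        }
        for i in order
    ])
    membership = paired.copy()
    membership["clonotype_id"] = [id_of_cluster[c] for c in cluster_of_row]
    assert membership["clonotype_id"].notna().all()
    assert clonotypes["size"].sum() == len(paired)
    return clonotypes, membership


def flag_liabilities(cdr1: str = "", cdr2: str = "", cdr3: str = "",
                     flank3: str = "") -> set[str]:
    """Scan CDRs for sequence liabilities.

    ``nglyc_cdr``: an N-X-[S/T] sequon (X != P) in any CDR, also checked
    across the CDR3's two-residue right flank when provided.
    ``unpaired_cys_cdr``: any cysteine inside a CDR (CDR cysteines lack the
    conserved framework pairing partner).
    """
    flags: set[str] = set()
    for name, cdr in (("cdr1", cdr1), ("cdr2", cdr2), ("cdr3", cdr3)):
        if not _AA_ONLY.match(cdr):
            bad = next(i for i, ch in enumerate(cdr) if ch not in "ACDEFGHIKLMNPQRSTVWY")
            raise ParameterError(f"{name} contains invalid character at position {bad}")
        if "C" in cdr:
            flags.add("unpaired_cys_cdr")
    if _SEQUON.search(cdr1) or _SEQUON.search(cdr2) or _SEQUON.search(cdr3 + flank3[:2]):
        flags.add("nglyc_cdr")
    return flags


@dataclasses.dataclass
class CloneScore:
    """Ranking record for one member of a consensus-bearing clonotype."""

    cell_id: str
    sequence_id: str
    clonotype_id: str
    clonotype_size: int
    hamming_to_consensus: int
    liabilities: set[str]


def score_members(
    clonotypes: pd.DataFrame,
    membership: pd.DataFrame,
    min_consensus_size: int = 5,
    liability_cdrs: str = "both",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Consensus sequences and per-member scores for clonotypes of size >= 5.

    Consensus and hamming distance use the full heavy V-domain amino-acid
    sequence when all members share one length; otherwise the clonotype
    falls back to CDR-H3 (equal by construction) with a logged downgrade.
    Liability flags cover the heavy CDRs and, when ``liability_cdrs`` is
    ``"both"``, the light CDRs of the paired cell.

    Returns a score table and {clonotype_id: consensus sequence}.
    """
    big = clonotypes[clonotypes["size"] >= min_consensus_size]
    scores = []
    consensus_of: dict[str, str] = {}
    for _, clono in big.iterrows():
        cid = clono["clonotype_id"]
        members = membership[membership["clonotype_id"] == cid]
        seqs = members["heavy_sequence_aa"].tolist()
        if len({len(s) for s in seqs}) == 1:
            region = "heavy_sequence_aa"
        else:
            region = "heavy_cdr3_aa"
            seqs = members["heavy_cdr3_aa"].tolist()
            logger.info(
                "clonotype %s: unequal VH lengths, consensus downgraded to CDR-H3", cid
            )
        cons = consensus_sequence(seqs)
        consensus_of[cid] = cons
        for _, m in members.iterrows():
            liab = flag_liabilities(
                m["heavy_cdr1_aa"], m["heavy_cdr2_aa"], m["heavy_cdr3_aa"]
            )
            if liability_cdrs == "both":
                liab |= flag_liabilities(
                    m.get("light_cdr1_aa", ""), m.get("light_cdr2_aa", ""),
                    m.get("light_cdr3_aa", ""),
                )
            scores.append({
                "cell_id": m["cell_id"],
                "sequence_id": m["heavy_sequence_id"],
                "clonotype_id": cid,
                "clonotype_size": int(clono["size"]),
                "hamming_to_consensus": hamming(m[region], cons),
                "liabilities": ";".join(sorted(liab)),
            })
    columns = ["cell_id", "sequence_id", "clonotype_id", "clonotype_size",
               "hamming_to_consensus", "liabilities"]
    return pd.DataFrame(scores, columns=columns), consensus_of


def select_clones(scores: pd.DataFrame, k: int) -> pd.DataFrame:
    """Pick the top-``k`` clones for expression.

    Candidates are liability-free members of consensus-bearing clonotypes.
    Clonotypes are visited by size descending (ties: clonotype id); each
    round takes at most one clone per clonotype — the member with the
    smallest hamming distance to consensus (ties: sequence id) — so
    clonotype coverage is maximised before any clonotype repeats.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    eligible = scores[scores["liabilities"] == ""]
    if eligible.empty:
        logger.warning("no liability-free candidates in consensus-bearing clonotypes")
        return eligible.assign(rank=pd.Series(dtype=int))

    ranked = eligible.sort_values(
        ["hamming_to_consensus", "sequence_id"], kind="stable"
    )
    by_clonotype = {
        cid: grp.to_dict("records")
        for cid, grp in ranked.groupby("clonotype_id", sort=False)
    }
    clonotype_order = sorted(
        by_clonotype,
        key=lambda cid: (-by_clonotype[cid][0]["clonotype_size"], cid),
    )
    picks: list[dict] = []
    round_idx = 0
    while len(picks) < k:
        took_any = False
        for cid in clonotype_order:
            if len(picks) >= k:
                break
            members = by_clonotype[cid]
            if round_idx < len(members):
                picks.append(members[round_idx])
                took_any = True
        if not took_any:
            break
        round_idx += 1
    out = pd.DataFrame(picks)
    out["rank"] = range(1, len(out) + 1)
    return out
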