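"""Germline reference sequences and light-chain numbering.

The package ships small synthetic stand-in germlines (realistic lengths and
layout, clearly labelled in their FASTA headers) so that every downstream
stage is testable without downloads.  Real IMGT reference sequences can be
supplied as drop-in replacements through the same loaders.

The common-light-chain design joins a kappa V segment (Chothia positions
1-95) to a J segment (96-107) and replaces the tryptophan at Chothia
position 96 — an oxidation-prone liability in CDR-L3 — with leucine.
Numbering for the fixture chain is a static index→label table: the fixture
carries no insertions, so the map is a bijection onto labels "1".."107".
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: One (arbitrary but fixed) codon per amino acid, used to derive nucleotide
#: fixtures from amino-acid fixtures deterministically.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

# Fixture heavy V-regions share one layout: FR1 1-25, CDR-H1 26-35,
# FR2 36-49, CDR-H2 50-66, FR3 67-98 (0-based python slices below).
HEAVY_CDR1_SLICE = slice(25, 35)
HEAVY_CDR2_SLICE = slice(49, 66)
HEAVY_J_SUFFIX = "WGQGTLVTVSS"

#: Chothia label (string) of the CDR-L3 position carrying the W→L
#: substitution in the prearranged light chain.
POSITION_96 = "96"


def validate_aa(seq: str, context: str = "sequence") -> str:
    """Return ``seq`` if it is uppercase over the 20-letter alphabet."""
    bad = [i for i, ch in enumerate(seq) if ch not in AA_ALPHABET]
    if bad:
        raise ConfigurationError(
            f"{context} contains invalid residue {seq[bad[0]]!r} at position {bad[0]}"
        )
    return seq


def reverse_translate(aa: str) -> str:
    """Deterministic nucleotide sequence encoding ``aa`` (one codon per residue)."""
    return "".join(_CODON[ch] for ch in validate_aa(aa))


@dataclasses.dataclass(frozen=True)
class GermlineGene:
    name: str
    aa: str
    nt: str

    @classmethod
    def from_aa(cls, name: str, aa: str) -> "GermlineGene":
        return cls(name=name, aa=validate_aa(aa, name), nt=reverse_translate(aa))


@dataclasses.dataclass
class GermlineSet:
    """Reference germlines for simulation and mutation profiling.

    ``prearranged_lc`` is the joined kappa V/J light chain with the
    position-96 substitution applied; ``numbering_map`` sends each index of
    that sequence to its Chothia label.
    """

    heavy_v: dict[str, GermlineGene]
    light_v: dict[str, GermlineGene]
    light_j: dict[str, GermlineGene]
    prearranged_lc: str
    numbering_map: dict[int, str]

    def __post_init__(self) -> None:
        validate_aa(self.prearranged_lc, "prearranged_lc")
        if sorted(self.numbering_map) != list(range(len(self.prearranged_lc))):
            raise ConfigurationError(
                "numbering_map must cover every index of prearranged_lc exactly once"
            )
        labels = list(self.numbering_map.values())
        if len(set(labels)) != len(labels):
            raise ConfigurationError("numbering_map labels must be unique (injective)")
        pos96 = self.label_to_index(POSITION_96)
        if self.prearranged_lc[pos96] != "L":
            raise ConfigurationError(
                "prearranged light chain must carry leucine at Chothia position 96"
            )

    def label_to_index(self, label: str) -> int:
        for idx, lab in self.numbering_map.items():
            if lab == label:
                return idx
        raise KeyError(f"Chothia label {label!r} not present in numbering map")

    @property
    def labels(self) -> list[str]:
        return [self.numbering_map[i] for i in range(len(self.prearranged_lc))]


def read_fasta(path) -> dict[str, str]:
    """Minimal ordered FASTA reader returning {first header token: sequence}."""
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            else:
                if name is None:
                    raise ConfigurationError(f"{path}: sequence before first header")
                seqs[name] += line
    return seqs


def build_prearranged_lc(
    light_v_aa: str, light_j_aa: str, position96_residue: str = "L"
) -> tuple[str, dict[int, str]]:
    """Join a kappa V segment and J segment into the prearranged light chain.

    The V segment covers Chothia 1-95 and the J segment 96 onwards; the
    residue at label 96 (the first J residue) is replaced by
    ``position96_residue``.  Returns the joined sequence and its
    index→Chothia-label map.
    """
    if not light_v_aa or not light_j_aa:
        raise ConfigurationError("V and J segments must be non-empty")
    validate_aa(light_v_aa, "light V segment")
    validate_aa(light_j_aa, "light J segment")
    if position96_residue not in AA_ALPHABET:
        raise ConfigurationError(
            f"position-96 residue {position96_residue!r} is not a standard amino acid"
        )
    joined = light_v_aa + position96_residue + light_j_aa[1:]
    numbering = {i: str(i + 1) for i in range(len(joined))}
    return joined, numbering


def _data_path(name: str) -> Path:
    return Path(resources.files("clcrep.data") / name)


def load_numbering(path=None) -> dict[int, str]:
    """Load an index→Chothia-label table (TSV: index, chothia_label)."""
    path = path or _data_path("chothia_numbering.tsv")
    numbering: dict[int, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["index", "chothia_label"]:
            raise ConfigurationError(f"{path}: expected columns index, chothia_label")
        for line in fh:
            idx, label = line.rstrip("\n").split("\t")[:2]
            numbering[int(idx)] = label
    return numbering


def load_regions(path=None) -> dict[str, list[str]]:
    """Load Chothia region definitions as {region: [labels]}.

    The packaged table defines CDR-L1 24-34, CDR-L2 50-56, CDR-L3 89-97 and
    the four framework regions for the fixture light chain; callers may
    supply their own table for other numbering schemes.
    """
    path = path or _data_path("chothia_regions.tsv")
    regions: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["region", "start", "end"]:
            raise ConfigurationError(f"{path}: expected columns region, start, end")
        for line in fh:
            region, start, end = line.rstrip("\n").split("\t")[:3]
            regions[region] = [str(p) for p in range(int(start), int(end) + 1)]
    return regions


def cdr_labels(regions: Mapping[str, list[str]] | None = None) -> dict[str, list[str]]:
    regions = regions or load_regions()
    return {name: labs for name, labs in regions.items() if name.startswith("CDR")}


def default_germlines() -> GermlineSet:
    """The packaged synthetic germline set with the prearranged kappa chain."""
    heavy = {n: GermlineGene.from_aa(n, s) for n, s in read_fasta(_data_path("synthetic_heavy_v.fasta")).items()}
    light_v = {n: GermlineGene.from_aa(n, s) for n, s in read_fasta(_data_path("synthetic_light_v.fasta")).items()}
    light_j = {n: GermlineGene.from_aa(n, s) for n, s in read_fasta(_data_path("synthetic_light_j.fasta")).items()}
    prearranged, numbering = build_prearranged_lc(
        light_v["IGKV10-96"].aa, light_j["IGKJ1"].aa, "L"
    )
    return GermlineSet(
        heavy_v=heavy,
        light_v=light_v,
        light_j=light_j,
        prearranged_lc=prearranged,
        numbering_map=numbering,
    )
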