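"""Synthetic paired-BCR repertoires and bead-competition panels.

The generator emulates the *post-annotation* tables of a single-cell V(D)J
experiment on a common-light-chain (cLC) mouse: every B cell carries a heavy
chain drawn from a clonally expanded repertoire with diverse IGHV usage, and
a kappa light chain descended from one prearranged germline that accumulates
somatic hypermutation (SHM) at position-specific rates with hotspots in
CDR-L1 (30-32), CDR-L3 (92-94) and framework position 83.  Clone sizes
follow a configurable skewed law; isotypes, rare lambda chains, residual
receptor editing, cell multiplets and light-chain dropout are all planted so
the downstream pairing filter, clonotyping and diversity statistics can be
checked against ground truth.

Homozygous cLC animals express both prearranged alleles; sequencing cannot
separate the two near-identical light chains, so with probability
``dual_allele_fraction`` the reported light chain is drawn from a second,
independently mutated lineage of the same cell.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import germlines as gl
from .errors import ConfigurationError

AA_LIST = sorted(gl.AA_ALPHABET)

RECORD_COLUMNS = [
    "cell_id", "sequence_id", "locus", "v_call", "j_call", "c_call",
    "productive", "cdr1_aa", "cdr2_aa", "cdr3_aa", "sequence_aa", "sequence",
]

ISOTYPES = ("IGHG1", "IGHG2B", "IGHG2C", "IGHA", "IGHD", "IGHM")


def _check_prob_vector(probs: Mapping[str, float], name: str) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")
    for key, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name}[{key!r}] = {p} outside [0, 1]")


def _check_rate(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} = {value} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class CloneSizeLaw:
    """Clone-size distribution: how many cells each true clonotype holds.

    Families:

    - ``ranked_zipf``: deterministic ranked profile, size(r) ∝ r^-exponent
      over ``n_clonotypes`` ranks, scaled by largest remainder so sizes sum
      to the cell count with every clonotype holding at least one cell.
    - ``lognormal``: sizes drawn from exp(N(mu, sigma)) until the cell count
      is exhausted.
    - ``fixed``: an explicit size list (must sum to the cell count).
    """

    family: str = "ranked_zipf"
    n_clonotypes: int = 515
    exponent: float = 2.0
    mu: float = 1.0
    sigma: float = 1.0
    sizes_list: tuple[int, ...] | None = None

    def sizes(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "ranked_zipf":
            if self.n_clonotypes > n_cells:
                raise ConfigurationError(
                    f"n_clonotypes ({self.n_clonotypes}) exceeds n_cells ({n_cells})"
                )
            ranks = np.arange(1, self.n_clonotypes + 1, dtype=float)
            weights = ranks ** -self.exponent
            spare = n_cells - self.n_clonotypes
            raw = weights / weights.sum() * spare
            base = np.floor(raw).astype(int)
            remainder = spare - int(base.sum())
            order = np.argsort(-(raw - base), kind="stable")
            base[order[:remainder]] += 1
            out = np.sort(base + 1)[::-1]
        elif self.family == "lognormal":
            out_list: list[int] = []
            remaining = n_cells
            while remaining > 0:
                size = max(1, int(round(float(rng.lognormal(self.mu, self.sigma)))))
                size = min(size, remaining)
                out_list.append(size)
                remaining -= size
            out = np.sort(np.asarray(out_list, dtype=int))[::-1]
        elif self.family == "fixed":
            if self.sizes_list is None:
                raise ConfigurationError("fixed clone-size law requires sizes_list")
            out = np.sort(np.asarray(self.sizes_list, dtype=int))[::-1]
            if out.sum() != n_cells:
                raise ConfigurationError(
                    f"fixed sizes sum to {out.sum()}, expected n_cells = {n_cells}"
                )
            if (out < 1).any():
                raise ConfigurationError("fixed clone sizes must all be >= 1")
        else:
            raise ConfigurationError(f"unknown clone-size family {self.family!r}")
        assert out.sum() == n_cells
        return out


def default_shm_rates(numbering: Mapping[int, str] | None = None) -> dict[str, float]:
    """Per-Chothia-position substitution rates for the light chain.

    Hotspots sit at CDR-L1 30-32, CDR-L3 92-94 and framework 83; the flat
    background over the remaining positions is set so the expected number of
    amino-acid mutations per light chain is 4.9 — the repertoire-average
    mutation load the analysis is designed to resolve.
    """
    numbering = numbering or gl.load_numbering()
    labels = [numbering[i] for i in sorted(numbering)]
    hotspots = {
        "30": 0.40, "31": 0.40, "32": 0.25,
        "92": 0.50, "93": 0.50, "94": 0.25,
        "83": 0.30,
    }
    target_mean = 4.9
    background_positions = [lab for lab in labels if lab not in hotspots]
    background = (target_mean - sum(hotspots.values())) / len(background_positions)
    rates = {lab: background for lab in background_positions}
    rates.update(hotspots)
    return {lab: rates[lab] for lab in labels}


def default_heavy_usage(genes: Sequence[str], dominant: str = "IGHV1-64") -> dict[str, float]:
    """Skewed heavy V-gene usage with a configurable dominant gene."""
    genes = list(genes)
    if dominant not in genes:
        raise ConfigurationError(f"dominant gene {dominant!r} not in germline set")
    ordered = [dominant] + sorted(g for g in genes if g != dominant)
    weights = np.array([1.0 / (r + 1.5) for r in range(len(ordered))])
    probs = weights / weights.sum()
    return dict(zip(ordered, probs.tolist()))


@dataclasses.dataclass
class SimConfig:
    """Conditions for one simulated single-cell repertoire."""

    n_cells: int = 2884
    clone_size_law: CloneSizeLaw = dataclasses.field(
        default_factory=lambda: CloneSizeLaw("ranked_zipf", n_clonotypes=515, exponent=0.85)
    )
    heavy_v_usage: dict[str, float] | None = None  # None -> default_heavy_usage
    shm_rates: dict[str, float] | None = None      # None -> default_shm_rates
    heavy_shm_rate: float = 2.0                    # mean substitutions per VH (Poisson)
    cdrh3_shm_rate: float = 0.005                  # per-position CDR-H3 substitution rate
    dual_allele_fraction: float = 0.5
    isotype_probs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "IGHG2B": 0.35, "IGHG2C": 0.33, "IGHG1": 0.10,
            "IGHM": 0.09, "IGHA": 0.07, "IGHD": 0.06,
        }
    )
    lambda_fraction: float = 0.0002
    editing_fraction: float = 0.0028  # residual second-kappa lineages
    multiplet_rate: float = 0.08
    light_dropout_rate: float = 0.10
    cdr3_length_range: tuple[int, int] = (10, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        for name in ("heavy_shm_rate",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in (
            "cdrh3_shm_rate", "dual_allele_fraction", "lambda_fraction",
            "editing_fraction", "multiplet_rate", "light_dropout_rate",
        ):
            _check_rate(getattr(self, name), name)
        _check_prob_vector(self.isotype_probs, "isotype_probs")
        if self.heavy_v_usage is not None:
            _check_prob_vector(self.heavy_v_usage, "heavy_v_usage")
        if self.shm_rates is not None:
            for lab, r in self.shm_rates.items():
                _check_rate(r, f"shm_rates[{lab!r}]")


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA_LIST, size=length))


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        choices = [aa for aa in AA_LIST if aa != current]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def generate_repertoire(
    config: SimConfig, germline_set: gl.GermlineSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an annotated rearrangement table plus ground truth.

    Returns ``(records, truth)``: ``records`` has one row per emitted chain
    with the full AIRR-style column set; ``truth`` has one row per cell with
    its true clonotype, planted light-chain mutations and emission flags.
    Deterministic given ``config.seed``.
    """
    germline_set = germline_set or gl.default_germlines()
    rng = np.random.default_rng(config.seed)

    usage = config.heavy_v_usage or default_heavy_usage(germline_set.heavy_v)
    unknown = [g for g in usage if g not in germline_set.heavy_v]
    if unknown:
        raise ConfigurationError(
            f"heavy_v_usage names unknown germline gene(s): {', '.join(sorted(unknown))}"
        )
    genes = list(usage)
    gene_probs = np.array([usage[g] for g in genes])

    numbering = germline_set.numbering_map
    labels = germline_set.labels
    shm_rates = config.shm_rates or default_shm_rates(numbering)
    missing = [lab for lab in labels if lab not in shm_rates]
    if missing:
        raise ConfigurationError(f"shm_rates missing labels: {missing[:5]}")
    rate_vector = np.array([shm_rates[lab] for lab in labels])

    prearranged = germline_set.prearranged_lc
    regions = gl.load_regions()
    light_cdr_idx = {
        name: [germline_set.label_to_index(lab) for lab in labs if lab in set(labels)]
        for name, labs in gl.cdr_labels(regions).items()
    }

    edited_lc = (
        germline_set.light_v["IGKV14-111"].aa + germline_set.light_j["IGKJ1"].aa
        if "IGKV14-111" in germline_set.light_v else None
    )
    lambda_lc = (
        germline_set.light_v["IGLV1"].aa + germline_set.light_j["IGLJ1"].aa
        if "IGLV1" in germline_set.light_v else None
    )

    sizes = config.clone_size_law.sizes(config.n_cells, rng)

    # Plant clonotypes: draw V gene and CDR-H3, rejecting CDR-H3s that are
    # >=50% identical to an earlier clonotype in the same (gene, length)
    # block so planted clonotypes stay unambiguously separable.
    lo, hi = config.cdr3_length_range
    clone_gene, clone_cdr3 = [], []
    block_seen: dict[tuple[str, int], list[str]] = {}
    for _ in range(len(sizes)):
        gene = genes[int(rng.choice(len(genes), p=gene_probs))]
        while True:
            length = int(rng.integers(lo, hi + 1))
            cdr3 = _random_cdr3(rng, length)
            peers = block_seen.setdefault((gene, length), [])
            if all(
                sum(a == b for a, b in zip(cdr3, p)) / length < 0.5 for p in peers
            ):
                peers.append(cdr3)
                break
        clone_gene.append(gene)
        clone_cdr3.append(cdr3)

    isotypes = list(config.isotype_probs)
    isotype_probs = np.array([config.isotype_probs[i] for i in isotypes])

    records: list[dict] = []
    truth: list[dict] = []
    seq_counter = 0

    def new_seq_id() -> str:
        nonlocal seq_counter
        seq_counter += 1
        return f"SEQ{seq_counter:07d}"

    cell_index = 0
    for clone_idx in range(len(sizes)):
        v_gene = clone_gene[clone_idx]
        germ_v = germline_set.heavy_v[v_gene].aa
        cdr3_germ = clone_cdr3[clone_idx]
        for _ in range(int(sizes[clone_idx])):
            cell_index += 1
            cell_id = f"CELL{cell_index:06d}"
            isotype = isotypes[int(rng.choice(len(isotypes), p=isotype_probs))]

            # heavy chain: framework/CDR1-2 SHM + light-touch CDR-H3 SHM
            n_heavy_mut = int(rng.poisson(config.heavy_shm_rate))
            n_heavy_mut = min(n_heavy_mut, len(germ_v))
            heavy_pos = rng.choice(len(germ_v), size=n_heavy_mut, replace=False)
            v_mut = _mutate(germ_v, heavy_pos, rng)
            cdr3_hits = np.flatnonzero(rng.random(len(cdr3_germ)) < config.cdrh3_shm_rate)
            cdr3_mut = _mutate(cdr3_germ, cdr3_hits, rng)
            heavy_aa = v_mut + cdr3_mut + gl.HEAVY_J_SUFFIX
            records.append({
                "cell_id": cell_id, "sequence_id": new_seq_id(), "locus": "IGH",
                "v_call": f"{v_gene}*01", "j_call": "IGHJ2*01", "c_call": isotype,
                "productive": True,
                "cdr1_aa": v_mut[gl.HEAVY_CDR1_SLICE],
                "cdr2_aa": v_mut[gl.HEAVY_CDR2_SLICE],
                "cdr3_aa": cdr3_mut,
                "sequence_aa": heavy_aa,
                "sequence": gl.reverse_translate(heavy_aa),
            })

            # light chain lineage
            u = rng.random()
            dual = rng.random() < config.dual_allele_fraction
            allele = "B" if (dual and rng.random() < 0.5) else "A"
            light_mut_labels: list[str] = []
            if lambda_lc is not None and u < config.lambda_fraction:
                light_type, light_aa = "lambda", lambda_lc
                locus, v_call, j_call, c_call = "IGL", "IGLV1*01", "IGLJ1*01", "IGLC1"
                cdrs = {"cdr1_aa": "", "cdr2_aa": "", "cdr3_aa": ""}
            elif edited_lc is not None and u < config.lambda_fraction + config.editing_fraction:
                light_type, light_aa = "edited", edited_lc
                locus, v_call, j_call, c_call = "IGK", "IGKV14-111*01", "IGKJ1*01", "IGKC"
                cdrs = {"cdr1_aa": "", "cdr2_aa": "", "cdr3_aa": ""}
            else:
                light_type = "kappa"
                hits = np.flatnonzero(rng.random(len(prearranged)) < rate_vector)
                light_aa = _mutate(prearranged, hits, rng)
                light_mut_labels = [labels[i] for i in hits]
                locus, v_call, j_call, c_call = "IGK", "IGKV10-96*01", "IGKJ1*01", "IGKC"
                cdrs = {
                    f"cdr{k}_aa": "".join(light_aa[i] for i in light_cdr_idx[f"CDR-L{k}"])
                    for k in (1, 2, 3)
                }

            light_dropped = rng.random() < config.light_dropout_rate
            if not light_dropped:
                records.append({
                    "cell_id": cell_id, "sequence_id": new_seq_id(), "locus": locus,
                    "v_call": v_call, "j_call": j_call, "c_call": c_call,
                    "productive": True,
                    **cdrs,
                    "sequence_aa": light_aa,
                    "sequence": gl.reverse_translate(light_aa),
                })

            # multiplet: an extra chain makes the cell fail the 1H+1L filter
            is_multiplet = rng.random() < config.multiplet_rate
            if is_multiplet:
                if rng.random() < 0.5:
                    extra_gene = genes[int(rng.choice(len(genes), p=gene_probs))]
                    extra_cdr3 = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
                    extra_aa = germline_set.heavy_v[extra_gene].aa + extra_cdr3 + gl.HEAVY_J_SUFFIX
                    records.append({
                        "cell_id": cell_id, "sequence_id": new_seq_id(), "locus": "IGH",
                        "v_call": f"{extra_gene}*01", "j_call": "IGHJ2*01",
                        "c_call": "IGHM", "productive": True,
                        "cdr1_aa": germline_set.heavy_v[extra_gene].aa[gl.HEAVY_CDR1_SLICE],
                        "cdr2_aa": germline_set.heavy_v[extra_gene].aa[gl.HEAVY_CDR2_SLICE],
                        "cdr3_aa": extra_cdr3,
                        "sequence_aa": extra_aa,
                        "sequence": gl.reverse_translate(extra_aa),
                    })
                else:
                    records.append({
                        "cell_id": cell_id, "sequence_id": new_seq_id(), "locus": "IGK",
                        "v_call": "IGKV10-96*01", "j_call": "IGKJ1*01", "c_call": "IGKC",
                        "productive": True,
                        "cdr1_aa": "", "cdr2_aa": "", "cdr3_aa": "",
                        "sequence_aa": prearranged,
                        "sequence": gl.reverse_translate(prearranged),
                    })

            truth.append({
                "cell_id": cell_id,
                "true_clonotype": f"TC{clone_idx + 1:05d}",
                "v_gene": v_gene,
                "cdr3_length": len(cdr3_germ),
                "true_cdr3": cdr3_germ,
                "observed_cdr3": cdr3_mut,
                "isotype": isotype,
                "light_type": light_type,
                "allele": allele,
                "light_mut_labels": ";".join(light_mut_labels),
                "n_light_mut": len(light_mut_labels),
                "n_heavy_mut": n_heavy_mut,
                "light_dropped": light_dropped,
                "multiplet": is_multiplet,
            })

    records_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    truth_df = pd.DataFrame(truth)
    return records_df, truth_df


def pairing_survival_probability(config: SimConfig) -> float:
    """Analytic probability that a simulated cell passes the 1H+1L filter."""
    return (1.0 - config.multiplet_rate) * (1.0 - config.light_dropout_rate)


def _scaled_law(overrides: dict, n_clonotypes: int, exponent: float,
                reference_cells: int = 2884) -> CloneSizeLaw:
    """Preset clone-size law, with the clonotype count scaled proportionally
    when the caller overrides n_cells without overriding the law."""
    n_cells = overrides.get("n_cells", reference_cells)
    scaled = max(1, round(n_clonotypes * n_cells / reference_cells))
    return CloneSizeLaw("ranked_zipf", n_clonotypes=min(scaled, n_cells), exponent=exponent)


def clcm_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Study conditions shaped like the cLC-mouse pool: 515 clonotypes over
    2884 paired cells, top-10 clonotypes holding ~26% of the repertoire."""
    params = dict(
        n_cells=2884,
        clone_size_law=_scaled_law(overrides, 515, 0.85),
        lambda_fraction=0.0002,
        editing_fraction=0.0028,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def wildtype_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Study conditions shaped like the wildtype pool: 704 clonotypes, a more
    even clone-size profile (~15% top-10 occupancy), diverse light chains and
    a dominant IGHV5-17."""
    germ = gl.default_germlines()
    # wildtype IGKV10-96/J1 light chains carry a heavier mutation load than
    # the dual-allele-diluted cLC pool: scale the default rates to mean 6.4
    rates = {lab: r * (6.4 / 4.9) for lab, r in default_shm_rates(germ.numbering_map).items()}
    params = dict(
        n_cells=2884,
        clone_size_law=_scaled_law(overrides, 704, 0.70),
        heavy_v_usage=default_heavy_usage(germ.heavy_v, dominant="IGHV5-17"),
        shm_rates=rates,
        lambda_fraction=0.02,
        editing_fraction=0.60,  # wildtype light chains mostly NOT the cLC germline
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclasses.dataclass
class BinSimConfig:
    """Conditions for one simulated bead-competition (epitope binning) panel."""

    n_references: int = 7
    n_panel: int = 43
    n_bins: int = 3
    bin_assignment: dict[str, str] | None = None  # antibody id -> planted bin
    signal_geomean: float = 1500.0
    competition_factor: float = 0.05
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_references < 2:
            raise ConfigurationError(
                "n_references must be >= 2 (competition profiles need length >= 2)"
            )
        if self.n_panel < 1:
            raise ConfigurationError("n_panel must be >= 1")
        if not 0.0 <= self.competition_factor < 1.0:
            raise ConfigurationError("competition_factor must be in [0, 1)")
        if self.signal_geomean <= 0:
            raise ConfigurationError("signal_geomean must be positive")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")

    def reference_ids(self) -> list[str]:
        return [f"REF{i + 1:02d}" for i in range(self.n_references)]

    def panel_ids(self) -> list[str]:
        return [f"AB{i + 1:02d}" for i in range(self.n_panel)]

    def resolved_bins(self) -> dict[str, str]:
        if self.bin_assignment is not None:
            return dict(self.bin_assignment)
        labels = [chr(ord("A") + i) for i in range(self.n_bins)]
        bins = {}
        for i, ref in enumerate(self.reference_ids()):
            bins[ref] = labels[i % self.n_bins]
        for i, ab in enumerate(self.panel_ids()):
            bins[ab] = labels[i % self.n_bins]
        return bins


def generate_binning_panel(config: BinSimConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a reference × panel bead-fluorescence table.

    Each well holds antigen-coated beads pre-bound with one reference
    antibody, then exposed to one panel antibody.  The total geometric mean
    is the reference baseline plus the panel antibody's signal, which is
    suppressed by ``competition_factor`` when the two antibodies share a
    planted epitope bin.  Log-normal noise with the requested CV multiplies
    every measured geomean.  Returns the long-format table and the planted
    bin labels (references and panel).
    """
    rng = np.random.default_rng(config.seed)
    bins = config.resolved_bins()
    refs, panel = config.reference_ids(), config.panel_ids()
    for ab in refs + panel:
        if ab not in bins:
            raise ConfigurationError(f"bin_assignment missing antibody {ab!r}")

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        noise = lambda: float(rng.lognormal(-sigma ** 2 / 2.0, sigma))  # mean 1
    else:
        noise = lambda: 1.0

    rows = []
    ref_alone = {r: config.signal_geomean * noise() for r in refs}
    for r in refs:
        for p in panel:
            factor = config.competition_factor if bins[r] == bins[p] else 1.0
            total = ref_alone[r] + config.signal_geomean * factor * noise()
            rows.append({
                "reference_id": r, "panel_id": p,
                "total_geomean": total,
                "reference_alone_geomean": ref_alone[r],
            })
    return pd.DataFrame(rows), bins
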