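"""Reading, writing and pairing of annotated rearrangement tables.

Two dialects are supported: AIRR Rearrangement TSV (AIRR Community column
names) and 10x-style ``filtered_contig_annotations.csv``.  Gene calls are
normalized to gene level by stripping allele suffixes (``IGHV1-64*01`` →
``IGHV1-64``); the raw calls are retained in ``*_call_raw`` columns because
all germline comparisons downstream are done at gene level.

The pairing filter keeps a cell only if it has exactly one productive heavy
(IGH) and exactly one productive light (IGK/IGL) chain.  Non-productive
chains are excluded before counting, and a cell with one kappa plus one
lambda chain is dropped as multi-light.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

VALID_LOCI = ("IGH", "IGK", "IGL")
HEAVY_LOCI = ("IGH",)
LIGHT_LOCI = ("IGK", "IGL")

#: Columns every parsed record table carries (cell_id may be empty for bulk).
CORE_COLUMNS = [
    "cell_id", "sequence_id", "locus", "v_call", "j_call", "c_call",
    "productive", "cdr1_aa", "cdr2_aa", "cdr3_aa", "sequence_aa", "sequence",
]
RAW_CALL_COLUMNS = ["v_call_raw", "j_call_raw", "c_call_raw"]

_REQUIRED = ["sequence_id", "locus", "v_call", "cdr3_aa"]

_TENX_RENAME = {
    "barcode": "cell_id",
    "contig_id": "sequence_id",
    "chain": "locus",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "c_gene": "c_call",
    "cdr1": "cdr1_aa",
    "cdr2": "cdr2_aa",
    "cdr3": "cdr3_aa",
}

#: Fields carried per chain when a record table is widened to one row per cell.
PAIR_FIELDS = [
    "sequence_id", "v_call", "v_call_raw", "j_call", "c_call",
    "cdr1_aa", "cdr2_aa", "cdr3_aa", "sequence_aa", "sequence",
]


def strip_allele(call: str) -> str:
    """``IGHV1-64*01`` → ``IGHV1-64``; empty/NaN-safe."""
    if not isinstance(call, str):
        return ""
    return call.split("*")[0].strip()


def _parse_productive(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() in {"t", "true", "productive", "yes", "1"}


def read_rearrangements(path, dialect: str = "airr-tsv") -> pd.DataFrame:
    """Read an annotated rearrangement table.

    Rows whose locus is not an immunoglobulin locus (e.g. TRB contigs) are
    rejected; their count is logged and stored in ``df.attrs["n_skipped_locus"]``.
    """
    if dialect == "airr-tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif dialect == "10x-csv":
        df = pd.read_csv(path, sep=",", dtype=str, keep_default_na=False)
        df = df.rename(columns=_TENX_RENAME)
        if "is_cell" in df.columns:
            df = df[df["is_cell"].str.lower().isin(["true", "t", "1"])]
    else:
        raise FormatError(f"unknown dialect {dialect!r} (use 'airr-tsv' or '10x-csv')")

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)} for dialect {dialect!r}"
        )
    if df.empty:
        logger.warning("%s: empty rearrangement table", path)

    for col in CORE_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    n_in = len(df)
    df = df[df["locus"].isin(VALID_LOCI)].copy()
    n_skipped = n_in - len(df)
    if n_skipped:
        logger.info("%s: skipped %d non-IG records", path, n_skipped)

    if df["sequence_id"].duplicated().any():
        dup = df.loc[df["sequence_id"].duplicated(), "sequence_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sequence_id {dup!r}")

    df = normalize_records(df)
    df.attrs["n_skipped_locus"] = n_skipped
    return df


def normalize_records(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a record table in place of parsing: gene-level calls with raw
    calls retained, boolean productive flags, uppercase amino-acid fields."""
    df = df.copy()
    df["productive"] = df["productive"].map(_parse_productive)
    for call in ("v_call", "j_call", "c_call"):
        raw = f"{call}_raw"
        if raw not in df.columns:
            df[raw] = df[call]
        df[call] = df[raw].map(strip_allele)
    for col in ("cdr1_aa", "cdr2_aa", "cdr3_aa", "sequence_aa"):
        df[col] = df[col].astype(str).str.upper()
    return df[CORE_COLUMNS + RAW_CALL_COLUMNS].reset_index(drop=True)


def write_rearrangements(df: pd.DataFrame, path, dialect: str = "airr-tsv") -> None:
    out = df.copy()
    # restore raw allele-level calls on write so a round trip is lossless
    for call in ("v_call", "j_call", "c_call"):
        raw = f"{call}_raw"
        if raw in out.columns:
            out[call] = out[raw]
            out = out.drop(columns=[raw])
    out = out[[c for c in CORE_COLUMNS if c in out.columns]]
    if dialect == "airr-tsv":
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "10x-csv":
        inverse = {v: k for k, v in _TENX_RENAME.items()}
        out.rename(columns=inverse).to_csv(path, sep=",", index=False)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


@dataclasses.dataclass
class PairingReport:
    """Partition of input cells by the exactly-one-heavy/one-light filter."""

    n_cells_in: int
    n_heavy: int
    n_light: int
    n_paired: int
    n_dropped_multi: int
    n_dropped_unpaired: int

    def __post_init__(self) -> None:
        assert self.n_paired + self.n_dropped_multi + self.n_dropped_unpaired == self.n_cells_in

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def pair_cells(records: pd.DataFrame) -> tuple[pd.DataFrame, PairingReport]:
    """Keep cells with exactly one productive heavy and one productive light chain.

    Returns a wide table (one row per kept cell, ``heavy_*``/``light_*``
    columns) and a :class:`PairingReport` partitioning all input cells.
    """
    if "cell_id" not in records.columns or (records["cell_id"] == "").all():
        raise FormatError(
            "records carry no cell barcodes; use the bulk (unpaired) workflow instead"
        )
    productive = records[records["productive"].astype(bool)]
    heavy = productive[productive["locus"].isin(HEAVY_LOCI)]
    light = productive[productive["locus"].isin(LIGHT_LOCI)]

    cells = records["cell_id"].unique()
    n_h = heavy.groupby("cell_id").size()
    n_l = light.groupby("cell_id").size()

    paired_rows = []
    n_multi = n_unpaired = 0
    heavy_by_cell = {c: g for c, g in heavy.groupby("cell_id")}
    light_by_cell = {c: g for c, g in light.groupby("cell_id")}
    for cell in cells:
        nh = int(n_h.get(cell, 0))
        nl = int(n_l.get(cell, 0))
        if nh == 1 and nl == 1:
            row = {"cell_id": cell}
            hrec = heavy_by_cell[cell].iloc[0]
            lrec = light_by_cell[cell].iloc[0]
            for field in PAIR_FIELDS:
                row[f"heavy_{field}"] = hrec.get(field, "")
                row[f"light_{field}"] = lrec.get(field, "")
            row["light_locus"] = lrec["locus"]
            paired_rows.append(row)
        elif nh > 1 or nl > 1:
            n_multi += 1
        else:
            n_unpaired += 1

    columns = (
        ["cell_id"]
        + [f"{side}_{f}" for side in ("heavy", "light") for f in PAIR_FIELDS]
        + ["light_locus"]
    )
    paired = pd.DataFrame(paired_rows, columns=columns)
    report = PairingReport(
        n_cells_in=len(cells),
        n_heavy=len(heavy),
        n_light=len(light),
        n_paired=len(paired),
        n_dropped_multi=n_multi,
        n_dropped_unpaired=n_unpaired,
    )
    logger.info("pairing: %s", report.to_json())
    return paired, report
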