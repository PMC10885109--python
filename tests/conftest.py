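import pandas as pd
import pytest

from clcrep import germlines as gl
from clcrep import simulate as sim


@pytest.fixture(scope="session")
def germ() -> gl.GermlineSet:
    return gl.default_germlines()


@pytest.fixture
def clean_config():
    """Simulation conditions with every nuisance process switched off."""
    zero_rates = {lab: 0.0 for lab in gl.default_germlines().labels}

    def factory(**overrides):
        params = dict(
            n_cells=200,
            clone_size_law=sim.CloneSizeLaw("ranked_zipf", n_clonotypes=40, exponent=0.85),
            heavy_shm_rate=0.0,
            cdrh3_shm_rate=0.0,
            shm_rates=zero_rates,
            dual_allele_fraction=0.0,
            lambda_fraction=0.0,
            editing_fraction=0.0,
            multiplet_rate=0.0,
            light_dropout_rate=0.0,
            seed=11,
        )
        params.update(overrides)
        return sim.SimConfig(**params)

    return factory


def make_records(rows) -> pd.DataFrame:
    """Build a normalized-record table from compact row dicts."""
    defaults = {
        "cell_id": "", "sequence_id": "", "locus": "IGH", "v_call": "",
        "j_call": "", "c_call": "", "productive": True,
        "cdr1_aa": "", "cdr2_aa": "", "cdr3_aa": "", "sequence_aa": "",
        "sequence": "", "v_call_raw": "", "j_call_raw": "", "c_call_raw": "",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["sequence_id"] = f"S{i + 1:03d}"
        rec.update(row)
        if not rec["v_call_raw"]:
            rec["v_call_raw"] = rec["v_call"]
        out.append(rec)
    return pd.DataFrame(out)


def make_paired(rows) -> pd.DataFrame:
    """Build a wide paired-cell table from compact row dicts.

    Each row needs at least heavy_v_call and heavy_cdr3_aa; sequence-level
    fields default to CDR-H3 so consensus/hamming operate on it.
    """
    out = []
    for i, row in enumerate(rows):
        rec = {
            "cell_id": f"C{i + 1:03d}",
            "heavy_sequence_id": f"H{i + 1:03d}",
            "heavy_v_call": "IGHV1-64",
            "heavy_cdr1_aa": "", "heavy_cdr2_aa": "",
            "light_cdr1_aa": "", "light_cdr2_aa": "", "light_cdr3_aa": "",
            "light_v_call": "IGKV10-96",
        }
        rec.update(row)
        rec.setdefault("heavy_sequence_aa", rec["heavy_cdr3_aa"])
        out.append(rec)
    return pd.DataFrame(out)
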