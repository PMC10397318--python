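import numpy as np
import pandas as pd
import pytest

from cardiomr.instruments import HarmonizedVariant
from cardiomr.sumstats import SummaryStats


def make_variants(bx, by, sx=None, sy=None, ids=None):
    """Build a harmonized instrument set from plain arrays."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    sy = np.full_like(by, 0.01) if sy is None else np.asarray(sy, float)
    ids = ids or [f"rs{i+1}" for i in range(len(bx))]
    return [
        HarmonizedVariant(
            variant_id=ids[i], effect_allele="A", other_allele="G",
            beta_exp=bx[i], se_exp=sx[i], beta_out=by[i], se_out=sy[i],
            eaf=0.3, n_exp=50_000, n_out=50_000,
        )
        for i in range(len(bx))
    ]


def make_sumstats(records, provenance="test"):
    """records: list of dicts with at least SNP/BETA/SE; the rest defaulted."""
    rows = []
    for i, r in enumerate(records):
        row = dict(SNP=f"rs{i+1}", CHR="1", POS=(i + 1) * 1_000_000, EA="A", OA="G",
                   EAF=0.3, BETA=0.1, SE=0.01, N=10_000.0, INFO=1.0)
        row.update(r)
        row.setdefault("P", None)
        rows.append(row)
    df = pd.DataFrame(rows)
    from cardiomr.statsutil import p_from_z

    missing = df["P"].isna()
    df.loc[missing, "P"] = p_from_z(df.loc[missing, "BETA"] / df.loc[missing, "SE"])
    return SummaryStats(df, provenance=provenance)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
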