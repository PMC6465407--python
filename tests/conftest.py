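"""Shared fixtures: tiny hand-built panels and summary tables."""

import numpy as np
import pandas as pd
import pytest

from eqtlink.ld import ReferencePanel


def make_panel(dosage_columns, positions=None, chrom="1", ids=None,
               effect_allele="A", other_allele="G"):
    """Panel from explicit dosage columns (list of per-variant lists)."""
    dos = np.array(dosage_columns, dtype=float).T
    m = dos.shape[1]
    ids = ids or [f"v{j}" for j in range(m)]
    positions = positions if positions is not None \
        else [1_000_000 + 10_000 * j for j in range(m)]
    meta = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": positions,
        "effect_allele": effect_allele, "other_allele": other_allele,
    })
    return ReferencePanel(meta, dos)


@pytest.fixture
def four_variant_panel():
    """Four correlated variants, 6 individuals, known dosages."""
    return make_panel([
        [0, 0, 1, 2, 1, 0],   # v0
        [1, 0, 1, 2, 0, 0],   # v1
        [0, 0, 1, 2, 1, 0],   # v2: duplicate of v0
        [2, 2, 1, 0, 1, 2],   # v3: reflection of v0
    ])


def gwas_frame(rows):
    """Canonical GWAS frame from (vid, chrom, pos, a1, a2, eaf, b, se, p, n)
    tuples; p=None means recompute downstream."""
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "p", "n"]
    return pd.DataFrame(rows, columns=cols)
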