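import numpy as np
import pandas as pd
import pytest

from tfap.expression import CONTROL, ExpressionMatrix
from tfap.libraries import LibraryCollection, TFLibrary


def make_expression(values, gene_ids, meta_rows):
    """meta_rows: list of (sample_id, drug_id, cell_line, replicate)."""
    sample_ids = [r[0] for r in meta_rows]
    return ExpressionMatrix(
        values=pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(gene_ids, name="gene_id"),
            columns=sample_ids,
        ),
        sample_meta=pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=pd.Index(sample_ids, name="sample_id"),
            columns=["drug_id", "cell_line", "replicate"],
        ),
    )


@pytest.fixture
def two_group_expr():
    """One drug (3 samples) vs 3 controls, 4 genes, one cell line."""
    rng = np.random.default_rng(42)
    values = rng.normal(7, 1, (4, 6))
    meta = [
        ("t1", "drugA", "HL60", 1),
        ("t2", "drugA", "HL60", 2),
        ("t3", "drugA", "HL60", 3),
        ("c1", CONTROL, "HL60", 1),
        ("c2", CONTROL, "HL60", 2),
        ("c3", CONTROL, "HL60", 3),
    ]
    return make_expression(values, ["g1", "g2", "g3", "g4"], meta)


@pytest.fixture
def tiny_collection():
    """Two small libraries over a 6-gene universe."""
    universe = frozenset({"G1", "G2", "G3", "G4", "G5", "G6"})
    lib1 = TFLibrary(
        name="libA",
        sets={"TFX": frozenset({"G1", "G2"}), "TFY": frozenset({"G3", "G4"})},
        universe=universe,
    )
    lib2 = TFLibrary(
        name="libB",
        sets={"TFX": frozenset({"G1", "G5"}), "TFY": frozenset({"G3", "G6"})},
        universe=universe,
    )
    return LibraryCollection(libraries=(lib1, lib2))
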