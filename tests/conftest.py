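import numpy as np
import pandas as pd
import pytest

from pathflux.annotation import EnzymeMap
from pathflux.io import ExpressionStudy


@pytest.fixture
def tiny_emap() -> EnzymeMap:
    """Hand-built three-layer map exercising every mapping pattern.

    - GENE_A: two probesets, single EC (2.7.1.1)
    - GENE_B: isozyme of GENE_A (shares 2.7.1.1)
    - GENE_C: multifunctional, two ECs (1.1.1.1 and 1.1.1.2)
    - PS_NO_UG: probeset without a UniGene entry
    - Hs.404: UniGene cluster without a gene symbol
    - GENE_D: gene symbol without an EC
    """
    return EnzymeMap(
        probeset_to_unigene={
            "PS_A1": "Hs.1", "PS_A2": "Hs.1",
            "PS_B1": "Hs.2",
            "PS_C1": "Hs.3",
            "PS_D1": "Hs.5",
            "PS_NO_SYM": "Hs.404",
        },
        unigene_to_symbol={"Hs.1": "GENE_A", "Hs.2": "GENE_B", "Hs.3": "GENE_C",
                           "Hs.5": "GENE_D"},
        symbol_to_ecs={
            "GENE_A": frozenset({"2.7.1.1"}),
            "GENE_B": frozenset({"2.7.1.1"}),
            "GENE_C": frozenset({"1.1.1.1", "1.1.1.2"}),
        },
    )


@pytest.fixture
def small_study() -> ExpressionStudy:
    """3v3 study with a constant-difference probe and a flat probe."""
    rng = np.random.default_rng(42)
    samples = ["T1", "T2", "T3", "C1", "C2", "C3"]
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(10, 6)),
        index=[f"PS{i:02d}" for i in range(10)],
        columns=samples,
    )
    values.loc["PS00"] = [2.0, 2.0, 2.0, 1.0, 1.0, 1.0]
    values.loc["PS01"] = [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]
    return ExpressionStudy(
        values=values,
        labels=pd.Series(["T", "T", "T", "C", "C", "C"], index=samples),
        classes=("T", "C"),
    )
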