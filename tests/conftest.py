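import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import depmarker as dm

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def toy_matrix() -> dm.GeneEffectMatrix:
    scores = pd.DataFrame(
        {
            "TGT": [-0.6, -0.5, -0.4, -0.9, np.nan],
            "OTH": [0.1, -0.2, 0.0, -1.1, -0.7],
        },
        index=pd.Index([f"ACH-{i:06d}" for i in range(5)], name="DepMap_ID"),
    )
    labels = [dm.GeneLabel("TGT", 1), dm.GeneLabel("OTH", 2)]
    return dm.GeneEffectMatrix(scores, labels)


@pytest.fixture
def mutation_records() -> dm.MutationTable:
    frame = pd.DataFrame(
        {
            "cell_line_id": ["ACH-000000", "ACH-000000", "ACH-000001",
                            "ACH-000003", "ACH-000009"],
            "gene_symbol": ["MARK", "MARK", "MARK", "QUIET", "MARK"],
            "variant_classification": ["Missense_Mutation", "Frame_Shift_Del",
                                       "Silent", "Nonsense_Mutation", "Splice_Site"],
            "entrez_id": pd.array([10, 10, 10, 11, 10], dtype="Int64"),
        }
    )
    return dm.MutationTable(frame)


@pytest.fixture
def planted_screen():
    """A 777-line screen with one selective target and one planted marker."""
    effect_spec = dm.EffectSimSpec(
        n_lines=777, selective_genes={"TGT": 0.3}, n_background_genes=5, seed=11
    )
    matrix, truth = dm.simulate_gene_effect(effect_spec)
    marker_spec = dm.MarkerSimSpec(
        marker_gene="MARK", target_gene="TGT", q1=0.5, q0=0.05,
        n_background_genes=200, seed=12,
    )
    mutations = dm.simulate_mutations(marker_spec, truth)
    return matrix, truth, mutations
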