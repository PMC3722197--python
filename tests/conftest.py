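import numpy as np
import pandas as pd
import pytest

from stressnet.boosting import (
    KmerFeatures,
    PromoterSet,
    RegulatorPanel,
    build_examples,
    extract_kmer_features,
)
from stressnet.expression import IntensityMatrix
from stressnet.simulate import NetworkSimConfig, generate_planted_network


@pytest.fixture(scope="session")
def small_planted():
    """A compact planted network: 3 TFs x 10 targets, 10 conditions."""
    cfg = NetworkSimConfig(
        n_tfs=3, targets_per_tf=10, n_decoy_genes=6, n_conditions=10,
        promoter_len=300, motif_len=6, eta=0.05,
    )
    proms, panel, dem, truth = generate_planted_network(cfg, seed=7)
    features = extract_kmer_features(proms)
    examples = build_examples(dem.calls)
    return {
        "promoters": proms,
        "panel": panel,
        "calls": dem,
        "truth": truth,
        "features": features,
        "examples": examples,
    }


@pytest.fixture()
def toy_intensity():
    """6 samples, 2 genes, log2 scale: control vs treated with clear shifts."""
    values = pd.DataFrame(
        {
            "c1": [10.0, 8.0],
            "c2": [10.1, 8.1],
            "c3": [9.9, 7.9],
            "t1": [11.0, 7.0],
            "t2": [11.1, 7.1],
            "t3": [10.9, 6.9],
        },
        index=["gA", "gB"],
    )
    groups = pd.Series(
        {"c1": "control", "c2": "control", "c3": "control",
         "t1": "treated", "t2": "treated", "t3": "treated"}
    )
    reps = pd.Series({s: s[-1] for s in values.columns})
    return IntensityMatrix(values, groups, reps)


def random_boost_instance(rng, n_genes=8, n_conditions=5, n_tfs=2, seq_len=30):
    """A small random training instance for bound/property checks."""
    proms = PromoterSet(
        {f"g{i}": "".join(rng.choice(list("ACGT"), size=seq_len)) for i in range(n_genes)}
    )
    feats = extract_kmer_features(proms, k_list=(3,))
    states = rng.choice([-1, 1], size=(n_tfs, n_conditions))
    panel = RegulatorPanel(
        pd.DataFrame(states, index=[f"t{j}" for j in range(n_tfs)],
                     columns=[f"c{j}" for j in range(n_conditions)])
    )
    calls = pd.DataFrame(
        rng.choice([-1, 0, 1], size=(n_genes, n_conditions)),
        index=list(proms.sequences), columns=panel.conditions,
    )
    if (calls != 0).sum().sum() == 0:
        calls.iloc[0, 0] = 1
    examples = build_examples(calls)
    return examples, feats, panel
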