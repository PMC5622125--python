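import numpy as np
import pandas as pd
import pytest

from msapkit import MsapDataset, MsapSimConfig, simulate_msap


def make_dataset(hpa, msp, groups, replicate_pairs=()):
    """Build an MsapDataset from 0/1/np.nan arrays (samples x loci)."""
    hpa = np.asarray(hpa, dtype=float)
    n, L = hpa.shape
    samples = [f"S{i + 1}" for i in range(n)]
    loci = [f"L{j + 1:04d}" for j in range(L)]
    return MsapDataset(
        sample_ids=samples,
        group_labels=list(groups),
        locus_ids=loci,
        presence_hpa=pd.DataFrame(hpa, index=samples, columns=loci),
        presence_msp=pd.DataFrame(np.asarray(msp, dtype=float), index=samples,
                                  columns=loci),
        replicate_pairs=list(replicate_pairs),
    )


@pytest.fixture
def tiny_dataset():
    """Six samples, two groups, four loci, no missing calls."""
    hpa = [
        [1, 1, 0, 1],
        [1, 0, 0, 1],
        [1, 1, 0, 0],
        [0, 1, 1, 1],
        [0, 0, 1, 1],
        [0, 1, 1, 0],
    ]
    msp = [
        [1, 1, 1, 0],
        [1, 1, 1, 0],
        [1, 0, 1, 1],
        [0, 1, 0, 0],
        [0, 1, 0, 1],
        [0, 0, 0, 1],
    ]
    return make_dataset(hpa, msp, ["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def sim_dataset():
    """Differentiated two-group simulation, seeded."""
    cfg = MsapSimConfig(group_sizes=[12, 12], n_loci=150, diff_fraction=0.3,
                        effect_size=0.5, error_rate=0.0, missing_rate=0.0,
                        seed=42)
    dataset, truth = simulate_msap(cfg)
    return dataset, truth
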