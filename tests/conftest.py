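import numpy as np
import pandas as pd
import pytest

from methbin import (
    MethylomeSample,
    SampleProfile,
    build_reference,
    plant_dmrs,
    simulate_sample,
)


@pytest.fixture(scope="session")
def small_ref():
    """A 60-kb single-chromosome reference with all three compartments."""
    return build_reference({"chr1": 60_000}, seed=7)


@pytest.fixture(scope="session")
def roster_profiles():
    """Two mutants and two paired controls at study-like coverage."""
    rng = np.random.default_rng(123)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    return [
        SampleProfile("mutA", "mutant", seed=int(seeds[0])),
        SampleProfile("mutB", "mutant", seed=int(seeds[1])),
        SampleProfile("ctlA", "control", seed=int(seeds[2])),
        SampleProfile("ctlB", "control", seed=int(seeds[3])),
    ]


@pytest.fixture(scope="session")
def small_truth(small_ref, roster_profiles):
    from methbin import DmrRequest

    return plant_dmrs(
        [
            DmrRequest(6, "CG", "hyper", 0.5),
            DmrRequest(2, "CG", "hyper", 0.5, affected=("mutA",)),
        ],
        small_ref,
        roster_profiles,
        seed=11,
    )


@pytest.fixture(scope="session")
def simulated_samples(small_ref, roster_profiles, small_truth):
    return {
        p.sample_id: simulate_sample(small_ref, p, small_truth)
        for p in roster_profiles
    }


def make_sample(rows, sample_id="toy", genotype="control"):
    """Build a MethylomeSample from (chrom, pos, strand, context, m, n) rows."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m", "n"])
    return MethylomeSample(sample_id, df, genotype_label=genotype)
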