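import numpy as np
import pandas as pd
import pytest

import pcascope as p


def make_counts(arr, genes=None, samples=None) -> p.CountMatrix:
    arr = np.asarray(arr, dtype=np.int64)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    return p.CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def unit_size_factors(sample_ids) -> p.SizeFactors:
    return p.SizeFactors(pd.Series(1.0, index=list(sample_ids)))


@pytest.fixture
def tiny_counts() -> p.CountMatrix:
    """The hand-computable 3x2 matrix: second column doubles the first."""
    return make_counts([[2, 4], [4, 8], [6, 12]])


@pytest.fixture(scope="session")
def sim():
    """Default two-group simulation shared by the recovery tests.

    Generator defaults: 2000 genes, 2x6 samples, 10% planted at |log2FC|=2,
    trend (0.1, 5), seed 0.
    """
    design = p.SimulationDesign()
    bundle, truth = p.simulate_counts(design)
    sf = p.estimate_size_factors(bundle.counts)
    trend = p.fit_dispersion_trend(bundle.counts, sf)
    transformed = p.vst(bundle.counts, sf, trend)
    return {
        "design": design,
        "bundle": bundle,
        "truth": truth,
        "sf": sf,
        "trend": trend,
        "transformed": transformed,
        "affected": list(truth["genes"].index[truth["genes"]["affected"]]),
    }
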