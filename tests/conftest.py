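import numpy as np
import pandas as pd
import pytest

from h3turnover.genome import ChromSizes
from h3turnover.synthio import (
    GeneratorParams, build_annotation, simulate_reads, default_chroms,
)


@pytest.fixture(scope="session")
def chroms():
    return ChromSizes({"chrT": 100_000})


@pytest.fixture(scope="session")
def annotation_truth():
    """Default synthetic annotation + ground truth (fixed seed)."""
    return build_annotation(default_chroms(), GeneratorParams(), seed=0)


@pytest.fixture(scope="session")
def synthetic_reads(annotation_truth):
    annotation, truth = annotation_truth
    return simulate_reads(truth, annotation.chroms, timepoints=(0, 6),
                          seed=0, n_replicates=2)


def make_reads(chrom, positions, strands):
    return pd.DataFrame({
        "chrom": chrom,
        "five_prime": np.asarray(positions, dtype=int),
        "strand": list(strands),
    })
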