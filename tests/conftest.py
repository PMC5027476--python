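import numpy as np
import pandas as pd
import pytest

import methrecover as mr


@pytest.fixture
def toy_regions() -> mr.RegionSet:
    return mr.RegionSet(
        [
            mr.GenomicRegion("chr1", 100, 1100, "P1", "promoter"),
            mr.GenomicRegion("chr1", 2000, 4000, "G1", "gene_body"),
            mr.GenomicRegion("chr1", 5000, 5500, "I1", "intergenic", invariant=True),
            mr.GenomicRegion("chr2", 0, 2500, "R1", "repeat:IAP"),
            mr.GenomicRegion("chr2", 3000, 3800, "I2", "intergenic", invariant=True),
            mr.GenomicRegion("chr2", 4000, 4400, "I3", "intergenic", invariant=True),
        ]
    )


@pytest.fixture
def toy_manifest() -> mr.SampleManifest:
    return mr.SampleManifest(
        [
            mr.Sample("WT", "reference", "wild-type"),
            mr.Sample("MSCV", "baseline", "empty vector"),
            mr.Sample("LSH", "test", "rescue"),
        ]
    )


@pytest.fixture
def toy_counts(toy_regions, toy_manifest) -> mr.CountTable:
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(5, 500, size=(len(toy_regions), 3)),
        index=pd.Index(toy_regions.ids, name="region_id"),
        columns=toy_manifest.sample_ids,
    )
    return mr.CountTable(counts=counts)


def small_params(**overrides) -> mr.SimulationParams:
    """A fast, fully specified simulation: 2 test samples, 4 classes."""
    defaults = dict(
        n_regions={
            "promoter": 60,
            "gene_body": 60,
            "intergenic": 60,
            "repeat:IAP": 40,
        },
        region_length={
            "promoter": (500, 2000),
            "gene_body": (2000, 8000),
            "intergenic": (1000, 5000),
            "repeat:IAP": (2000, 6000),
        },
        samples=[
            mr.SampleSim("WT", "reference"),
            mr.SampleSim("MSCV", "baseline"),
            mr.SampleSim("LSH", "test", rho=0.6),
            mr.SampleSim("K237Q", "test", rho=0.1),
        ],
        fraction_lsh_dependent={"default": 0.5},
        n_invariant=60,
    )
    defaults.update(overrides)
    return mr.SimulationParams(**defaults)


@pytest.fixture
def small_dataset() -> mr.SimulatedDataset:
    return mr.simulate_dataset(small_params(), seed=11)
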