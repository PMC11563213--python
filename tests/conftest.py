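import numpy as np
import pytest

from pathnet.io_formats import (
    GenotypeDataset,
    PathwayCollection,
    PathwayRecord,
    PPINetwork,
)


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """3 cases + 3 controls x 4 SNPs, no missing data."""
    genotypes = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [2, 0, 1, 0],
            [0, 0, 1, 1],
            [1, 0, 0, 1],
            [2, 1, 0, 2],
        ],
        dtype=float,
    )
    return GenotypeDataset(
        sample_ids=[f"S{i}" for i in range(6)],
        phenotypes=np.array(["case"] * 3 + ["control"] * 3, dtype=object),
        snp_ids=["rs1", "rs2", "rs3", "rs4"],
        chrom=np.array(["1", "1", "2", "Y"], dtype=object),
        pos=np.array([100, 200, 100, 100]),
        genotypes=genotypes,
    )


@pytest.fixture
def path_graph() -> PPINetwork:
    """A--B--C path used in subnetwork-growth examples."""
    return PPINetwork(
        nodes={"A", "B", "C"},
        edges={frozenset(("A", "B")), frozenset(("B", "C"))},
    )


@pytest.fixture
def small_pathways() -> PathwayCollection:
    return PathwayCollection(
        [
            PathwayRecord("pw1", "first", frozenset({"A", "B", "C", "D"})),
            PathwayRecord("pw2", "second", frozenset({"C", "D", "E"})),
            PathwayRecord("pw3", "third", frozenset({"F", "G"})),
        ]
    )
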