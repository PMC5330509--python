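import numpy as np
import pytest

from isotroph.core import DistanceMatrix, IsotopeMeasurement, Phylogeny, TrophicCoding


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def simple_coding():
    return TrophicCoding({"Isoptera": 2, "Araneae": 3.5, "Formicidae": 3, "Vertebrates": 5})


@pytest.fixture
def two_site_measurements():
    """Two species at two sites, two individuals each, fixed values."""
    rows = [
        ("s1", "A", "north", -18.0, 7.0),
        ("s2", "A", "north", -19.0, 9.0),
        ("s3", "B", "north", -17.0, 10.0),
        ("s4", "B", "north", -17.5, 12.0),
        ("s5", "A", "south", -20.0, 6.0),
        ("s6", "A", "south", -21.0, 8.0),
        ("s7", "B", "south", -16.0, 11.0),
        ("s8", "B", "south", -16.5, 13.0),
    ]
    return [IsotopeMeasurement(*r) for r in rows]


def random_distance_matrix(rng, labels, ndim=3):
    pts = rng.standard_normal((len(labels), ndim))
    return DistanceMatrix.from_points(labels, pts)
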