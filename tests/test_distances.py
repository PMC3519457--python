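import math

import mpmath
import numpy as np
import pytest

from crossmeta.distances import (
    dist_minimum,
    dist_reads,
    dist_shot,
    dist_wootters,
    distance_matrix,
)
from crossmeta.io_ace import InputError
from crossmeta.profile import PairwiseCounts, abundance_vectors, pairwise_counts

from conftest import make_profile

mpmath.mp.dps = 50


# ---------------------------------------------------------------------------
# high-precision oracles (mpmath, independent of the implementation)


def oracle_shot(c_i, c_j, c_ij):
    ci, cj, cij = map(mpmath.mpf, (c_i, c_j, c_ij))
    sim = cij * mpmath.sqrt((ci**2 + cj**2) / (2 * ci**2 * cj**2))
    return float(1 - sim)


def oracle_minimum(c_i, c_j, c_ij):
    return float(1 - mpmath.mpf(c_ij) / min(mpmath.mpf(c_i), mpmath.mpf(c_j)))


def oracle_wootters(p, q):
    bha = mpmath.fsum(mpmath.sqrt(mpmath.mpf(a) * mpmath.mpf(b)) for a, b in zip(p, q))
    bha = min(max(bha, mpmath.mpf(0)), mpmath.mpf(1))
    return float(2 / mpmath.pi * mpmath.acos(bha))


def oracle_reads(r_i, r_j, r_ij, r_ji):
    fi = mpmath.mpf(r_ij) / mpmath.mpf(r_i)
    fj = mpmath.mpf(r_ji) / mpmath.mpf(r_j)
    return float(1 - mpmath.sqrt((fi**2 + fj**2) / 2))


def random_pairwise_counts(rng):
    c_i, c_j = int(rng.integers(1, 200)), int(rng.integers(1, 200))
    c_ij = int(rng.integers(0, min(c_i, c_j) + 1))
    r_i = int(rng.integers(c_i, 4 * c_i + 1))
    r_j = int(rng.integers(c_j, 4 * c_j + 1))
    r_ij = int(rng.integers(c_ij, max(c_ij, min(r_i, 3 * max(c_ij, 1))) + 1))
    r_ji = int(rng.integers(c_ij, max(c_ij, min(r_j, 3 * max(c_ij, 1))) + 1))
    return PairwiseCounts("i", "j", c_i, c_j, c_ij, r_i, r_j, min(r_ij, r_i),
                          min(r_ji, r_j))


def random_probability_vector(rng, n):
    v = rng.gamma(0.5, size=n)
    v[rng.random(n) < 0.3] = 0.0  # sparse support, like contig profiles
    if v.sum() == 0:
        v[0] = 1.0
    return v / v.sum()


# ---------------------------------------------------------------------------
# frozen hand examples


def test_shot_hand_examples():
    assert dist_shot(PairwiseCounts("i", "j", 5, 5, 5, 5, 5, 5, 5)) == pytest.approx(0.0, abs=1e-15)
    assert dist_shot(PairwiseCounts("i", "j", 4, 9, 0, 9, 9, 0, 0)) == 1.0
    d = dist_shot(PairwiseCounts("i", "j", 4, 9, 3, 9, 9, 3, 3))
    assert d == pytest.approx(0.41965, abs=5e-6)
    # equals 1 - RMS of the separately normalized fractions
    assert d == pytest.approx(1 - math.sqrt(((3 / 4) ** 2 + (3 / 9) ** 2) / 2), abs=1e-12)


def test_minimum_hand_examples():
    assert dist_minimum(PairwiseCounts("i", "j", 4, 9, 3, 9, 9, 3, 3)) == pytest.approx(0.25)
    assert dist_minimum(PairwiseCounts("i", "j", 4, 9, 4, 9, 9, 4, 4)) == 0.0
    assert dist_minimum(PairwiseCounts("i", "j", 4, 9, 0, 9, 9, 0, 0)) == 1.0


def test_wootters_hand_examples():
    p = [0.5, 0.5, 0.0]
    assert dist_wootters(p, p) == pytest.approx(0.0, abs=1e-12)
    assert dist_wootters([1, 0, 0], [0, 0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)
    assert dist_wootters([0.5, 0.5, 0], [0.5, 0, 0.5]) == pytest.approx(2 / 3, abs=1e-12)
    # unscaled variant returns radians
    assert dist_wootters([0.5, 0.5, 0], [0.5, 0, 0.5], scaled=False) == pytest.approx(
        math.acos(0.5), abs=1e-12
    )


def test_reads_hand_examples():
    assert dist_reads(PairwiseCounts("i", "j", 2, 2, 2, 100, 200, 100, 200)) == pytest.approx(0.0, abs=1e-15)
    assert dist_reads(PairwiseCounts("i", "j", 2, 2, 0, 100, 200, 0, 0)) == 1.0
    assert dist_reads(PairwiseCounts("i", "j", 9, 9, 5, 100, 200, 50, 80)) == pytest.approx(
        0.54723, abs=5e-6
    )


def test_wootters_input_validation():
    with pytest.raises(InputError):
        dist_wootters([0.5, 0.5], [0.5, 0.25, 0.25])
    with pytest.raises(InputError):
        dist_wootters([0.7, 0.7], [0.5, 0.5])


# ---------------------------------------------------------------------------
# oracle agreement and the shot >= minimum inequality


def test_formulas_match_high_precision_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        pc = random_pairwise_counts(rng)
        assert dist_shot(pc) == pytest.approx(oracle_shot(pc.c_i, pc.c_j, pc.c_ij), abs=1e-12)
        assert dist_minimum(pc) == pytest.approx(
            oracle_minimum(pc.c_i, pc.c_j, pc.c_ij), abs=1e-12
        )
        assert dist_reads(pc) == pytest.approx(
            oracle_reads(pc.r_i, pc.r_j, pc.r_ij, pc.r_ji), abs=1e-12
        )
    for _ in range(200):
        p = random_probability_vector(rng, 20)
        q = random_probability_vector(rng, 20)
        assert dist_wootters(p, q) == pytest.approx(oracle_wootters(p, q), abs=1e-12)


def test_shot_dominates_minimum():
    """RMS-normalized similarity <= c_ij/min similarity, strict off-diagonal."""
    rng = np.random.default_rng(11)
    for _ in range(1000):
        pc = random_pairwise_counts(rng)
        d_shot, d_min = dist_shot(pc), dist_minimum(pc)
        assert d_shot >= d_min - 1e-12
        if pc.c_i != pc.c_j and pc.c_ij > 0:
            assert d_shot > d_min


def test_distances_lie_in_unit_interval():
    rng = np.random.default_rng(13)
    for _ in range(500):
        pc = random_pairwise_counts(rng)
        for f in (dist_shot, dist_minimum, dist_reads):
            assert -1e-12 <= f(pc) <= 1.0 + 1e-12
        p = random_probability_vector(rng, 15)
        q = random_probability_vector(rng, 15)
        assert -1e-12 <= dist_wootters(p, q) <= 1.0 + 1e-12


def test_wootters_is_a_metric_on_random_triples():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        p, q, r = (random_probability_vector(rng, 10) for _ in range(3))
        dpq, dqr, dpr = dist_wootters(p, q), dist_wootters(q, r), dist_wootters(p, r)
        assert dpq == pytest.approx(dist_wootters(q, p), abs=1e-15)
        assert dpr <= dpq + dqr + 1e-9


# ---------------------------------------------------------------------------
# full matrices


@pytest.mark.parametrize("formula", ["shot", "minimum", "wootters", "reads"])
def test_matrix_cells_equal_single_pair_operations(random_profile, formula):
    dm = distance_matrix(random_profile, formula)
    labels = random_profile.samples
    p = abundance_vectors(random_profile)
    for a in range(len(labels)):
        assert dm.values[a, a] == 0.0
        for b in range(a + 1, len(labels)):
            if formula == "wootters":
                expected = dist_wootters(p[:, a], p[:, b])
            else:
                pc = pairwise_counts(random_profile, labels[a], labels[b])
                expected = {"shot": dist_shot, "minimum": dist_minimum,
                            "reads": dist_reads}[formula](pc)
            assert dm.values[a, b] == expected == dm.values[b, a]


@pytest.mark.parametrize("formula", ["shot", "minimum", "wootters", "reads"])
def test_identical_samples_are_at_distance_zero(formula):
    profile = make_profile([[2, 2, 1], [3, 3, 0], [1, 1, 4]])
    dm = distance_matrix(profile, formula)
    assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)


def test_unknown_formula_rejected(random_profile):
    with pytest.raises(InputError, match="unknown formula"):
        distance_matrix(random_profile, "euclid")


def test_matrix_writers_round_trip(tmp_path, random_profile):
    dm = distance_matrix(random_profile, "wootters")
    tsv = dm.write_tsv(tmp_path / "d.tsv")
    lines = tsv.read_text().splitlines()
    assert lines[0].split("\t")[1:] == list(dm.labels)
    parsed = np.array([[float(x) for x in l.split("\t")[1:]] for l in lines[1:]])
    assert np.allclose(parsed, dm.values, atol=1e-6)

    phy = dm.write_phylip(tmp_path / "d.phylip")
    plines = phy.read_text().splitlines()
    assert plines[0].strip() == str(len(dm.labels))
    assert plines[1].split()[0] == dm.labels[0]
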