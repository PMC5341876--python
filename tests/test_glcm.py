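"""Co-occurrence matrices against brute-force oracles and closed forms."""
import numpy as np
import pytest

from heterorad.errors import FeatureSetMissingError
from heterorad.glcm import (
    DIRECTIONS,
    FEATURE_NAMES,
    Glcm,
    aggregate_glcm_features,
    build_glcm,
    glcm_features,
)
from heterorad.imaging import QuantizedRoi


def qroi_from_levels(levels: np.ndarray, n_levels: int) -> QuantizedRoi:
    return QuantizedRoi(
        levels=np.asarray(levels, dtype=np.int64),
        n_levels=n_levels,
        bin_edges=np.linspace(0, 1, n_levels + 1),
    )


def brute_force_glcm(levels: np.ndarray, offset) -> np.ndarray:
    """Double loop over every voxel pair; the independent pair-count oracle."""
    n = int(levels.max())
    counts = np.zeros((n, n))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                xx, yy, zz = x + offset[0], y + offset[1], z + offset[2]
                if not (0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]):
                    continue
                b = levels[xx, yy, zz]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def literal_features(p: np.ndarray) -> dict:
    """Second, literal-sum implementation of the 12 statistics (test oracle)."""
    n = p.shape[0]
    out = {}
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(n) for j in range(n))
    out["energy"] = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    out["entropy"] = -sum(
        p[i, j] * np.log2(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
    )
    out["contrast"] = sum(
        abs(i - j) * p[i, j] for i in range(n) for j in range(n)
    )
    out["variance"] = var
    out["inertia"] = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    out["cluster_shade"] = sum(
        (i + j + 2 - 2 * mu) ** 3 * p[i, j] for i in range(n) for j in range(n)
    )
    out["cluster_tendency"] = sum(
        (i + j + 2 - 2 * mu) ** 2 * p[i, j] for i in range(n) for j in range(n)
    )
    out["homogeneity"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n)
    )
    out["maximum_probability"] = p.max()
    out["sum_mean"] = sum(
        (i + j + 2) * p[i, j] for i in range(n) for j in range(n)
    )
    if var > 0:
        out["correlation"] = (
            sum(
                (i + 1 - mu) * (j + 1 - mu) * p[i, j]
                for i in range(n)
                for j in range(n)
            )
            / var
        )
    else:
        out["correlation"] = float("nan")
    out["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(n) for j in range(n) if i != j
    )
    return out


def checkerboard(shape=(4, 4, 4)) -> np.ndarray:
    idx = np.indices(shape).sum(axis=0)
    return (idx % 2) + 1


class TestBuildGlcm:
    def test_checkerboard_d1_all_discordant(self):
        q = qroi_from_levels(checkerboard(), 2)
        g = build_glcm(q, (1, 0, 0), 1)
        assert g.p[0, 1] == pytest.approx(0.5)
        assert g.p[1, 0] == pytest.approx(0.5)
        assert g.p[0, 0] == g.p[1, 1] == 0.0

    def test_checkerboard_d2_all_concordant(self):
        q = qroi_from_levels(checkerboard(), 2)
        g = build_glcm(q, (1, 0, 0), 2)
        assert g.p[0, 0] == pytest.approx(0.5)
        assert g.p[1, 1] == pytest.approx(0.5)
        assert g.p[0, 1] == g.p[1, 0] == 0.0

    @pytest.mark.parametrize("distance", [1, 2, 3])
    def test_matches_brute_force(self, rng, distance):
        for _ in range(20):
            levels = rng.integers(0, 5, size=(5, 5, 5))
            q = qroi_from_levels(levels, 4)
            direction = DIRECTIONS[rng.integers(0, 13)]
            g = build_glcm(q, direction, distance)
            offset = tuple(distance * d for d in direction)
            counts = brute_force_glcm(levels, offset)[: q.n_levels, : q.n_levels]
            oracle = np.zeros((4, 4))
            oracle[: counts.shape[0], : counts.shape[1]] = counts
            if oracle.sum() == 0:
                assert g.n_pairs == 0
            else:
                np.testing.assert_allclose(g.p, oracle / oracle.sum(), atol=1e-15)
                assert g.n_pairs == int(oracle.sum())

    def test_symmetry_and_unit_mass(self, rng):
        for _ in range(30):
            levels = rng.integers(0, 7, size=(6, 6, 6))
            q = qroi_from_levels(levels, 6)
            g = build_glcm(q, DIRECTIONS[rng.integers(0, 13)], int(rng.integers(1, 4)))
            if g.n_pairs:
                np.testing.assert_allclose(g.p, g.p.T, atol=0)
                assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
                assert (g.p >= 0).all()

    def test_invalid_direction(self):
        q = qroi_from_levels(checkerboard(), 2)
        with pytest.raises(ValueError):
            build_glcm(q, (2, 0, 0), 1)


class TestGlcmFeatures:
    def test_checkerboard_closed_forms(self):
        g = build_glcm(qroi_from_levels(checkerboard(), 2), (1, 0, 0), 1)
        f = glcm_features(g)
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.0)  # one bit
        assert f["inertia"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["maximum_probability"] == pytest.approx(0.5)
        assert f["cluster_tendency"] == pytest.approx(0.0)
        assert f["cluster_shade"] == pytest.approx(0.0)
        assert f["sum_mean"] == pytest.approx(3.0)
        assert f["inverse_variance"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_single_level_point_mass(self):
        g = build_glcm(qroi_from_levels(np.ones((3, 3, 3), int), 2), (1, 0, 0), 1)
        f = glcm_features(g)
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["inertia"] == 0.0
        assert f["homogeneity"] == 1.0
        assert np.isnan(f["correlation"])

    def test_matches_literal_formulas(self, rng):
        for _ in range(40):
            levels = rng.integers(0, 6, size=(5, 5, 5))
            q = qroi_from_levels(levels, 5)
            g = build_glcm(q, DIRECTIONS[rng.integers(0, 13)], int(rng.integers(1, 4)))
            if g.n_pairs == 0:
                continue
            got = glcm_features(g)
            want = literal_features(g.p)
            for name in FEATURE_NAMES:
                if np.isnan(want[name]):
                    assert np.isnan(got[name])
                else:
                    assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_relabel_invariance(self, rng):
        """Level flip i -> n+1-i preserves symmetric stats, negates shade."""
        levels = rng.integers(1, 5, size=(5, 5, 5))
        n = 4
        a = glcm_features(build_glcm(qroi_from_levels(levels, n), (0, 1, 0), 1))
        flipped = n + 1 - levels
        b = glcm_features(build_glcm(qroi_from_levels(flipped, n), (0, 1, 0), 1))
        for name in ("energy", "entropy", "inertia", "homogeneity",
                     "maximum_probability", "contrast", "variance"):
            assert a[name] == pytest.approx(b[name], abs=1e-12), name
        assert a["cluster_shade"] == pytest.approx(-b["cluster_shade"], abs=1e-9)

    def test_inertia_at_least_contrast_squared(self, rng):
        # Jensen: E[D^2] >= (E[D])^2 for D = |i-j|
        for _ in range(20):
            levels = rng.integers(0, 9, size=(5, 5, 5))
            g = build_glcm(qroi_from_levels(levels, 8), (1, 0, 0), 1)
            if g.n_pairs:
                f = glcm_features(g)
                assert f["inertia"] >= f["contrast"] ** 2 - 1e-12

    def test_homogeneity_one_iff_diagonal(self):
        diag = np.zeros((3, 3))
        diag[0, 0] = diag[2, 2] = 0.5
        f = glcm_features(Glcm(p=diag, offset=(1, 0, 0), n_pairs=4))
        assert f["homogeneity"] == pytest.approx(1.0)
        off = np.array([[0.0, 0.5], [0.5, 0.0]])
        f2 = glcm_features(Glcm(p=off, offset=(1, 0, 0), n_pairs=4))
        assert f2["homogeneity"] < 1.0


class TestAggregate:
    def test_isotropic_constant_roi(self):
        q = qroi_from_levels(np.ones((4, 4, 4), int), 2)
        agg = aggregate_glcm_features(q, 1)
        single = glcm_features(build_glcm(q, (1, 0, 0), 1))
        assert agg["n_directions"] == 13
        for name in FEATURE_NAMES:
            if name == "correlation":
                continue
            assert agg[name] == pytest.approx(single[name])

    def test_thin_slab_drops_exiting_directions(self):
        # 2 voxels thick along z: any direction with a z-component exits at d=3
        levels = np.ones((6, 6, 2), int)
        agg = aggregate_glcm_features(qroi_from_levels(levels, 2), 3)
        assert agg["n_directions"] == 4  # the 4 purely in-plane directions

    def test_aggregate_is_mean_of_directions(self, rng):
        levels = rng.integers(1, 5, size=(6, 6, 6))
        q = qroi_from_levels(levels, 4)
        agg = aggregate_glcm_features(q, 2)
        per_dir = [glcm_features(build_glcm(q, d, 2)) for d in DIRECTIONS]
        for name in FEATURE_NAMES:
            vals = [f[name] for f in per_dir if not np.isnan(f[name])]
            assert agg[name] == pytest.approx(np.mean(vals), abs=1e-12), name

    def test_no_pairs_raises(self):
        levels = np.zeros((5, 5, 5), int)
        levels[0, 0, 0] = 1  # single voxel: no pair at any offset
        with pytest.raises(FeatureSetMissingError):
            aggregate_glcm_features(qroi_from_levels(levels, 2), 1)

    def test_mixing_raises_entropy_lowers_homogeneity(self, rng):
        """Two-compartment phantom is more entropic than a single compartment."""
        one = rng.integers(4, 7, size=(8, 8, 8))
        two = one.copy()
        two[4:] = rng.integers(10, 13, size=(4, 8, 8))
        f1 = aggregate_glcm_features(qroi_from_levels(one, 16), 1)
        f2 = aggregate_glcm_features(qroi_from_levels(two, 16), 1)
        assert f2["entropy"] > f1["entropy"]
        assert f2["homogeneity"] < f1["homogeneity"]
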