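"""Dice/ASSD against brute-force oracles, clinical quantities on phantoms,
and the statistics layer."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import mammoseg as ms
from mammoseg.metrics import surface_voxels

from conftest import make_phantom


def _mask(arr, spacing=(1, 1, 1)):
    return ms.MaskVolume(np.asarray(arr, dtype=np.uint8), spacing)


def brute_force_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Voxel-by-voxel loop; independent of the vectorized implementation."""
    inter = na = nb = 0
    for ia, ib in zip(a.flat, b.flat):
        na += ia == 1
        nb += ib == 1
        inter += (ia == 1) and (ib == 1)
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def brute_force_surface(mask: np.ndarray) -> np.ndarray:
    """6-neighbourhood border voxels by explicit looping."""
    out = np.zeros_like(mask, dtype=bool)
    R, C, S = mask.shape
    for i in range(R):
        for j in range(C):
            for k in range(S):
                if not mask[i, j, k]:
                    continue
                border = False
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < R and 0 <= nj < C and 0 <= nk < S):
                        border = True
                    elif not mask[ni, nj, nk]:
                        border = True
                out[i, j, k] = border
    return out


def brute_force_assd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """All-pairs nearest surface distances, pooled over both directions."""
    sa = np.argwhere(brute_force_surface(a)) * np.asarray(spacing)
    sb = np.argwhere(brute_force_surface(b)) * np.asarray(spacing)
    d = cdist(sa, sb)
    return float(np.concatenate([d.min(axis=1), d.min(axis=0)]).mean())


class TestDice:
    def test_equal_masks(self):
        m = _mask(np.random.default_rng(0).random((5, 5, 5)) > 0.5)
        assert ms.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert ms.dice(_mask(a), _mask(b)) == 0.0

    def test_hand_counted_example(self):
        # |A| = 4, |B| = 6, |A∩B| = 3 -> 2*3/10 = 0.6
        a = np.zeros((3, 3, 3))
        b = np.zeros((3, 3, 3))
        a.flat[:4] = 1
        b.flat[1:7] = 1
        assert ms.dice(_mask(a), _mask(b)) == pytest.approx(0.6)

    def test_both_empty_defined_as_one(self):
        z = _mask(np.zeros((3, 3, 3)))
        assert ms.dice(z, z) == 1.0
        assert ms.dice(z, _mask(np.eye(3)[None].repeat(3, 0)[:3, :3, :3])) == 0.0

    def test_matches_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            shape = tuple(rng.integers(3, 9, 3))
            a = (rng.random(shape) > rng.uniform(0.3, 0.8)).astype(np.uint8)
            b = (rng.random(shape) > rng.uniform(0.3, 0.8)).astype(np.uint8)
            assert ms.dice(_mask(a), _mask(b)) == pytest.approx(
                brute_force_dice(a, b), abs=0)


class TestASSD:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6))
        m[2:4, 2:4, 2:4] = 1
        assert ms.assd(_mask(m), _mask(m)) == 0.0

    def test_parallel_slabs_reference(self):
        """Unit-thickness slabs two voxels apart along an axis with 3 mm
        spacing: every surface voxel is 6 mm from the other surface."""
        a = np.zeros((8, 4, 4))
        b = np.zeros((8, 4, 4))
        a[2] = 1
        b[4] = 1
        got = ms.assd(_mask(a, (3.0, 1.0, 1.0)), _mask(b, (3.0, 1.0, 1.0)))
        assert got == pytest.approx(6.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = (rng.random((7, 7, 7)) > 0.6).astype(np.uint8)
        b = (rng.random((7, 7, 7)) > 0.6).astype(np.uint8)
        sa, sb = _mask(a, (1.4, 1.4, 3)), _mask(b, (1.4, 1.4, 3))
        assert ms.assd(sa, sb) == pytest.approx(ms.assd(sb, sa), abs=1e-12)

    def test_empty_mask_raises(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = 1
        with pytest.raises(ValueError):
            ms.assd(_mask(m), _mask(np.zeros((4, 4, 4))))

    def test_matches_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(1)
        done = 0
        while done < 15:
            shape = tuple(rng.integers(4, 9, 3))
            a = (rng.random(shape) > 0.6).astype(np.uint8)
            b = (rng.random(shape) > 0.6).astype(np.uint8)
            if not a.any() or not b.any():
                continue
            spacing = tuple(rng.uniform(0.5, 3.0, 3))
            got = ms.assd(_mask(a, spacing), _mask(b, spacing))
            want = brute_force_assd(a, b, spacing)
            assert got == pytest.approx(want, abs=1e-9)
            done += 1

    def test_surface_definition_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        m = (rng.random((6, 7, 5)) > 0.5).astype(np.uint8)
        assert np.array_equal(surface_voxels(m), brute_force_surface(m))


class TestVolumesAndDensity:
    def test_unit_spacing_volume(self):
        m = np.zeros((5, 5, 5))
        m.flat[:10] = 1
        assert ms.volume_mm3(_mask(m)) == 10.0

    def test_anisotropic_spacing_volume(self):
        m = np.zeros((5, 5, 5))
        m.flat[:10] = 1
        assert ms.volume_mm3(_mask(m, (0.7, 0.7, 3.0))) == pytest.approx(14.7)

    def test_empty_volume_zero(self):
        assert ms.volume_mm3(_mask(np.zeros((3, 3, 3)))) == 0.0

    def test_density_limits(self):
        b = np.ones((4, 4, 4))
        assert ms.breast_density(_mask(b), _mask(b)) == 100.0
        assert ms.breast_density(_mask(np.zeros_like(b)), _mask(b)) == 0.0

    def test_density_recovers_phantom_target(self, phantom_case):
        got = ms.breast_density(phantom_case.fgt_mask, phantom_case.breast_mask)
        assert got == pytest.approx(100 * phantom_case.realized_density)
        assert abs(got - 18.0) <= 0.2 * 18.0

    def test_empty_breast_rejected(self):
        z = _mask(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            ms.breast_density(z, z)

    def test_fgt_outside_breast_warns(self):
        fgt = np.zeros((4, 4, 4))
        fgt[0, 0, 0] = 1
        breast = np.zeros((4, 4, 4))
        breast[2:, 2:, 2:] = 1
        with pytest.warns(UserWarning):
            ms.breast_density(_mask(fgt), _mask(breast))


class TestBPE:
    def test_no_enhancement_zero(self, phantom_case):
        assert ms.bpe(phantom_case.pre_t1, phantom_case.pre_t1,
                      phantom_case.fgt_mask) == 0.0

    def test_doubled_signal_hundred_percent(self, phantom_case):
        doubled = ms.Volume3D(2.0 * phantom_case.pre_t1.values,
                              phantom_case.pre_t1.spacing_mm)
        got = ms.bpe(phantom_case.pre_t1, doubled, phantom_case.fgt_mask)
        assert got == pytest.approx(100.0, abs=1e-4)

    def test_recovers_phantom_enhancement_factor(self, phantom_case):
        got = ms.bpe(phantom_case.pre_t1, phantom_case.post_t1,
                     phantom_case.fgt_mask)
        assert got == pytest.approx(50.0, abs=1e-3)

    def test_enhanced_fraction_mode(self, phantom_case):
        frac = ms.bpe(phantom_case.pre_t1, phantom_case.post_t1,
                      phantom_case.fgt_mask, mode="enhanced_fraction")
        assert frac == pytest.approx(100.0)  # every FGT voxel enhances by 50%

    def test_empty_fgt_rejected(self, phantom_case):
        empty = _mask(np.zeros(phantom_case.pre_t1.shape), (2.8, 2.8, 6.0))
        with pytest.raises(ValueError):
            ms.bpe(phantom_case.pre_t1, phantom_case.post_t1, empty)


class TestStatistics:
    def test_pearson_reference_values(self):
        x = np.arange(10.0)
        assert ms.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert ms.pearson(x, -x) == pytest.approx(-1.0)
        assert ms.pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_pearson_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ms.pearson([1, 1, 1], [1, 2, 3])

    def test_bootstrap_constant_zero_width(self):
        lo, hi = ms.bootstrap_ci([2.0] * 10, np.mean, n_boot=200, seed=0)
        assert lo == hi == 2.0

    def test_bootstrap_contains_point_estimate_of_mean(self):
        rng = np.random.default_rng(0)
        for rep in range(50):
            vals = rng.normal(size=12)
            lo, hi = ms.bootstrap_ci(vals, np.mean, n_boot=500, seed=rep)
            assert lo <= vals.mean() <= hi

    def test_bootstrap_deterministic_per_seed(self):
        vals = np.random.default_rng(1).normal(size=20)
        assert ms.bootstrap_ci(vals, np.mean, seed=3) == \
            ms.bootstrap_ci(vals, np.mean, seed=3)

    def test_permutation_identical_pairs(self):
        assert ms.paired_permutation_test([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_permutation_exact_enumeration_reference(self):
        # ten pairs all differing by +1: only the two all-same-sign flips
        # reach |mean| = 1, so p = 2 / 2^10
        a = np.ones(10)
        b = np.zeros(10)
        p = ms.paired_permutation_test(a, b)
        assert p == pytest.approx(2 / 1024, abs=0)

    def test_permutation_p_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            p = ms.paired_permutation_test(a, b)
            assert 0 < p <= 1


class TestStratifiedReport:
    @staticmethod
    def _case(i, dens, dice_val, assd_val=1.0):
        return ms.CaseMetrics(case_id=f"c{i}", dice=dice_val, assd_mm=assd_val,
                              fgt_volume_mm3=1.0, breast_volume_mm3=10.0,
                              density_pct=dens, bpe_pct=50.0)

    def test_single_bin_is_global_mean(self):
        cases = [self._case(i, 10 + i, 0.8 + 0.01 * i) for i in range(5)]
        table = ms.density_stratified_report(cases, bins=[0, 100])
        assert len(table) == 1
        assert table.dice_mean[0] == pytest.approx(
            np.mean([c.dice for c in cases]))

    def test_row_count_equals_bin_count(self):
        cases = [self._case(i, d, 0.9) for i, d in enumerate((5, 15, 25, 35))]
        table = ms.density_stratified_report(cases, bins=[0, 10, 20, 30, 40])
        assert len(table) == 4
        assert table.n.tolist() == [1, 1, 1, 1]

    def test_empty_bin_flagged_not_dropped(self):
        cases = [self._case(0, 5, 0.9), self._case(1, 35, 0.95)]
        with pytest.warns(UserWarning, match="empty"):
            table = ms.density_stratified_report(cases, bins=[0, 10, 20, 40])
        assert len(table) == 3
        assert table.n.tolist() == [1, 0, 1]


# ---------------------------------------------------------------------------
# property-based checks

from hypothesis import given, settings, strategies as st


@st.composite
def mask_pairs(draw):
    shape = tuple(draw(st.integers(2, 6)) for _ in range(3))
    n = int(np.prod(shape))
    a = np.array(draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    b = np.array(draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    return a.reshape(shape), b.reshape(shape)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(mask_pairs())
def test_dice_bounds_symmetry_identity(pair):
    a, b = pair
    d = ms.dice(_mask(a), _mask(b))
    assert 0.0 <= d <= 1.0
    assert d == ms.dice(_mask(b), _mask(a))
    if a.any():
        assert ms.dice(_mask(a), _mask(a)) == 1.0
        # Dice is 1 iff the masks are identical (for nonempty masks)
        assert (d == 1.0) == np.array_equal(a, b)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(mask_pairs())
def test_assd_nonnegative_symmetric_zero_on_equal(pair):
    a, b = pair
    if not (a.any() and b.any()):
        return
    sa, sb = _mask(a, (1.4, 1.4, 3.0)), _mask(b, (1.4, 1.4, 3.0))
    d = ms.assd(sa, sb)
    assert d >= 0.0
    assert d == pytest.approx(ms.assd(sb, sa), abs=1e-12)
    assert ms.assd(sa, sa) == 0.0
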