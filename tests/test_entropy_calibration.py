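"""Tests for the CSF-based (m, r) acceptability grid and condition averaging."""

import numpy as np
import pytest

from boldvar.entropy_calibration import (
    CsfVoxelSet,
    DEFAULT_R_VALUES,
    DEFAULT_SELECTED_CONDITIONS,
    _se_from_entropies,
    average_over_conditions,
    build_grid,
    entropy_se,
)
from boldvar.signal_metrics import EntropyParams, sample_entropy
from conftest import ar1_series


@pytest.fixture(scope="module")
def white_noise_csf():
    rng = np.random.default_rng(7)
    return [
        CsfVoxelSet(f"s{i}", rng.standard_normal((15, 180))) for i in range(4)
    ]


@pytest.fixture(scope="module")
def noise_grid(white_noise_csf):
    return build_grid(white_noise_csf, m_values=(1, 2, 3, 4),
                      r_values=(0.05, 0.1, 0.2, 0.4, 0.6, 0.8))


class TestEntropySe:
    def test_identical_voxels_zero_se(self, rng):
        x = ar1_series(rng, 0.3, 120)
        csf = CsfVoxelSet("s", np.tile(x, (4, 1)))
        se, fails = entropy_se(csf, EntropyParams(2, 0.5))
        assert se == pytest.approx(0.0, abs=1e-12)
        assert fails == 0

    def test_hand_arithmetic(self):
        """Voxel entropies {1,1,2,2}: SE = 1.96 * (SD/1.5)^2."""
        ent = np.array([1.0, 1.0, 2.0, 2.0])
        se, fails = _se_from_entropies(ent)
        expected = 1.96 * (np.std(ent, ddof=1) / 1.5) ** 2
        assert se == pytest.approx(expected, abs=1e-12)
        assert fails == 0

    def test_unsquared_variant(self):
        ent = np.array([1.0, 1.0, 2.0, 2.0])
        se_sq, _ = _se_from_entropies(ent, squared=True)
        se_lin, _ = _se_from_entropies(ent, squared=False)
        assert se_sq == pytest.approx(1.96 * (se_lin / 1.96) ** 2, abs=1e-12)

    def test_all_failed_marker(self):
        se, fails = _se_from_entropies(np.full(5, np.nan))
        assert np.isnan(se)
        assert fails == 5

    def test_white_noise_stable(self):
        """White noise is entropy-stable: SE stays below 0.1 at m=2, r=0.5."""
        count_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            csf = CsfVoxelSet("s", rng.standard_normal((15, 180)))
            se, fails = entropy_se(csf, EntropyParams(2, 0.5))
            if se < 0.1 and fails == 0:
                count_ok += 1
        assert count_ok == 20


class TestBuildGrid:
    def test_failure_invalidates_cell(self, noise_grid):
        """A cell with any estimation failure is unacceptable even at SE 0."""
        for row in noise_grid.cells:
            for cell in row:
                if cell.failure_count > 0:
                    assert not cell.acceptable

    def test_acceptable_requires_low_median(self, noise_grid):
        for row in noise_grid.cells:
            for cell in row:
                if cell.acceptable:
                    assert cell.median_se < noise_grid.se_threshold
                    assert cell.failure_count == 0

    def test_m1_all_acceptable(self, noise_grid):
        assert all(c.acceptable for c in noise_grid.cells[0])

    def test_failures_monotone_in_m(self, noise_grid):
        """For fixed r, failure counts never drop as m grows."""
        fails = np.array(
            [[c.failure_count for c in row] for row in noise_grid.cells]
        )
        assert np.all(np.diff(fails, axis=0) >= 0)
        # and failures do appear at the large-m small-r corner
        assert fails[-1, 0] > 0

    def test_failure_count_matches_independent_recount(self, white_noise_csf,
                                                       noise_grid):
        """Grid failure counts equal per-voxel recounts via scalar calls."""
        m, r = 4, 0.05
        expected = 0
        for csf in white_noise_csf:
            for v in range(csf.n_voxels):
                val = sample_entropy(csf.voxel_series[v], EntropyParams(m, r))
                expected += int(np.isnan(val))
        assert noise_grid.cell(4, 0.05).failure_count == expected

    def test_threshold_monotonicity(self, white_noise_csf):
        """Raising the SE threshold never removes an acceptable cell."""
        lo = build_grid(white_noise_csf, m_values=(1, 2), r_values=(0.2, 0.5),
                        se_threshold=0.05)
        hi = build_grid(white_noise_csf, m_values=(1, 2), r_values=(0.2, 0.5),
                        se_threshold=0.2)
        assert set(lo.acceptable_conditions()) <= set(hi.acceptable_conditions())

    def test_degenerate_all_constant_unacceptable(self):
        """Constant voxels give entropy 0 everywhere; the zero-mean SE is
        undefined and the cell is marked unacceptable rather than raising."""
        csf = [CsfVoxelSet("s", np.full((3, 30), 2.5))]
        grid = build_grid(csf, m_values=(1,), r_values=(0.5,))
        cell = grid.cells[0][0]
        assert np.isnan(cell.median_se)
        assert not cell.acceptable

    def test_empty_inputs_raise(self, white_noise_csf):
        with pytest.raises(ValueError):
            build_grid([])
        with pytest.raises(ValueError):
            build_grid(white_noise_csf, m_values=(), r_values=(0.2,))


class TestAverageOverConditions:
    def test_single_condition_identity(self):
        t = np.arange(24.0).reshape(2, 4, 3)
        out = average_over_conditions(t, [(2, 0.2), (2, 0.3), (2, 0.4)],
                                      [(2, 0.3)])
        assert np.array_equal(out, t[:, :, 1])

    def test_two_condition_mean(self):
        t = np.zeros((1, 1, 2))
        t[0, 0] = [1.0, 2.0]
        out = average_over_conditions(t, [(2, 0.2), (2, 0.3)],
                                      [(2, 0.2), (2, 0.3)])
        assert out[0, 0] == pytest.approx(1.5)

    def test_failed_cells_excluded_pairwise(self):
        t = np.zeros((1, 2, 2))
        t[0, 0] = [1.0, np.nan]
        t[0, 1] = [2.0, 4.0]
        out = average_over_conditions(t, [(2, 0.2), (2, 0.3)],
                                      [(2, 0.2), (2, 0.3)])
        assert out[0, 0] == pytest.approx(1.0)   # NaN dropped, subject kept
        assert out[0, 1] == pytest.approx(3.0)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            average_over_conditions(np.zeros((1, 1, 1)), [(2, 0.2)], [])

    def test_unacceptable_selection_guarded(self, white_noise_csf):
        grid = build_grid(white_noise_csf, m_values=(4,), r_values=(0.05,))
        t = np.zeros((1, 1, 1))
        with pytest.raises(ValueError, match="not acceptable"):
            average_over_conditions(t, [(4, 0.05)], [(4, 0.05)], grid=grid)
        out = average_over_conditions(t, [(4, 0.05)], [(4, 0.05)], grid=grid,
                                      allow_unacceptable=True)
        assert out.shape == (1, 1)

    def test_default_selection_is_m2_without_r20(self):
        ms = {m for m, _ in DEFAULT_SELECTED_CONDITIONS}
        rs = sorted(r for _, r in DEFAULT_SELECTED_CONDITIONS)
        assert ms == {2}
        assert 0.2 not in rs
        assert rs[0] == 0.25 and rs[-1] == 0.65
        assert set(rs) <= set(DEFAULT_R_VALUES)
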