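"""Contractility programs: spatial profiles, ramps, noise, variants."""

import numpy as np
import pytest

import furrowsim as fs
from furrowsim.contractility import (
    ContractilityProgram,
    alternative_gradient_weight,
    contractility_at,
    gamma_field,
    sample_noise,
    spatial_profile,
    temporal_ramp,
)
from furrowsim.mesh import build_hex_sheet


@pytest.fixture()
def sheet():
    return build_hex_sheet(15, 24, 1.0)


class TestSpatialProfile:
    def test_gradient_midline_weight_one(self, sheet):
        prog = ContractilityProgram(variant="gradient_static")
        w = spatial_profile(prog, sheet)
        rows = sheet.row_of_cells()
        margin = sheet.margin_mask()
        mid = (rows == sheet.midline_row) & ~margin
        assert np.allclose(w[mid], 1.0)
        # so the static gradient peaks at Gamma_mid = 15
        g = gamma_field(prog, sheet, None, 0, 0.05)
        assert np.allclose(g[mid], 15.0)

    def test_gradient_gaussian_decay(self, sheet):
        prog = ContractilityProgram(variant="gradient_static", sigma_width=2.0)
        w = spatial_profile(prog, sheet)
        rows = sheet.row_of_cells()
        margin = sheet.margin_mask()
        two_rows_off = (np.abs(rows - sheet.midline_row) == 2) & ~margin
        # |i - Z| = sigma -> exp(-1/2)
        assert np.allclose(w[two_rows_off], np.exp(-0.5))
        far = (np.abs(rows - sheet.midline_row) == 7) & ~margin
        assert np.all(w[far] < 0.003)

    def test_monotone_decay_in_row_distance(self, sheet):
        prog = ContractilityProgram(variant="gradient_static")
        w = spatial_profile(prog, sheet)
        rows = sheet.row_of_cells()
        margin = sheet.margin_mask()
        means = [w[(np.abs(rows - sheet.midline_row) == d) & ~margin].mean() for d in range(8)]
        assert np.all(np.diff(means) < 0)

    def test_cutoff_band(self, sheet):
        prog = ContractilityProgram(variant="cutoff", n_central_rows=5)
        w = spatial_profile(prog, sheet)
        rows = sheet.row_of_cells()
        margin = sheet.margin_mask()
        inside = (np.abs(rows - sheet.midline_row) <= 2) & ~margin
        outside = np.abs(rows - sheet.midline_row) > 2
        assert np.all(w[inside] == 1.0)
        assert np.all(w[outside] == 0.0)

    def test_margin_cells_zero(self, sheet):
        for variant in ("cutoff", "gradient_static"):
            prog = ContractilityProgram(variant=variant)
            w = spatial_profile(prog, sheet)
            assert np.all(w[sheet.margin_mask()] == 0.0)


class TestTemporalRamp:
    def test_values(self):
        prog = ContractilityProgram()
        assert temporal_ramp(prog, 0.0) == 0.0
        assert temporal_ramp(prog, 100.0) == pytest.approx(15.0)
        assert temporal_ramp(prog, 1000.0) == 25.0  # capped at Gamma_max

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            temporal_ramp(ContractilityProgram(), -1.0)


class TestNoise:
    def test_wiener_starts_at_zero(self, sheet):
        noise = sample_noise(3, sheet, 50, 0.05)
        assert np.all(noise.wiener[:, 0] == 0.0)

    def test_increment_variance(self, sheet):
        # pooled increments follow N(0, dt)
        dt = 0.05
        noise = sample_noise(7, sheet, 400, dt)
        pooled = noise.increments.ravel()  # 360 * 400 = 144k draws
        assert pooled.var() == pytest.approx(dt, rel=0.03)
        assert abs(pooled.mean()) < 3 * np.sqrt(dt / pooled.size) * 2

    def test_reproducible_from_seed(self, sheet):
        a = sample_noise(11, sheet, 100, 0.05)
        b = sample_noise(11, sheet, 100, 0.05)
        assert np.array_equal(a.increments, b.increments)
        assert np.array_equal(a.attenuation, b.attenuation)
        c = sample_noise(12, sheet, 100, 0.05)
        assert not np.array_equal(a.increments, c.increments)

    def test_streams_keyed_on_row_col(self):
        # the same cell keeps its path when the sheet grows
        small = build_hex_sheet(5, 6, 1.0)
        large = build_hex_sheet(7, 9, 1.0)
        na = sample_noise(5, small, 64, 0.05)
        nb = sample_noise(5, large, 64, 0.05)
        idx_small = {(c.row, c.col): i for i, c in enumerate(small.cells)}
        idx_large = {(c.row, c.col): i for i, c in enumerate(large.cells)}
        for key in [(0, 0), (2, 3), (4, 5)]:
            assert np.array_equal(
                na.increments[idx_small[key]], nb.increments[idx_large[key]]
            )

    def test_attenuation_range(self, sheet):
        noise = sample_noise(4, sheet, 10, 0.05, twi_umax=0.5)
        assert np.all(noise.attenuation >= 0.0)
        assert np.all(noise.attenuation <= 0.5)
        assert noise.attenuation.std() > 0.05  # genuinely variable


class TestVariantDispatch:
    def test_stochastic_reduces_to_timed_without_noise(self, sheet):
        dt = 0.05
        noise = sample_noise(9, sheet, 200, dt)
        timed = ContractilityProgram(variant="gradient_timed", sigma_wiener=0.0)
        stoch = ContractilityProgram(variant="gradient_stochastic", sigma_wiener=0.0)
        for step in (0, 50, 199):
            gt = gamma_field(timed, sheet, noise, step, dt)
            gs = gamma_field(stoch, sheet, noise, step, dt)
            assert np.array_equal(gt, gs)

    def test_twi_bounded_by_half_wildtype(self, sheet):
        dt = 0.05
        noise = sample_noise(9, sheet, 200, dt, twi_umax=0.5)
        wt = ContractilityProgram(variant="gradient_stochastic")
        twi = ContractilityProgram(variant="twi", twi_umax=0.5)
        for step in (10, 100, 199):
            g_wt = gamma_field(wt, sheet, noise, step, dt)
            g_twi = gamma_field(twi, sheet, noise, step, dt)
            assert np.all(g_twi <= 0.5 * g_wt + 1e-15)

    def test_gamma_nonnegative_and_zero_in_margins(self, sheet):
        dt = 0.05
        noise = sample_noise(2, sheet, 300, dt)
        margin = sheet.margin_mask()
        for variant in ("cutoff", "gradient_static", "cutoff_timed",
                        "gradient_timed", "gradient_stochastic", "twi"):
            prog = ContractilityProgram(variant=variant)
            for step in (0, 150, 299):
                g = gamma_field(prog, sheet, noise, step, dt)
                assert np.all(g >= 0.0)
                assert np.all(g[margin] == 0.0)

    def test_scalar_wrapper_matches_field(self, sheet):
        dt = 0.05
        noise = sample_noise(2, sheet, 50, dt)
        prog = ContractilityProgram(variant="gradient_stochastic")
        g = gamma_field(prog, sheet, noise, 30, dt)
        assert contractility_at(prog, noise, sheet, 100, 30, dt) == g[100]

    def test_expected_gamma_nonincreasing_off_midline(self, sheet):
        # average over seeds: E[Gamma] decays with |i - Z| at fixed time
        dt = 0.05
        prog = ContractilityProgram(variant="gradient_stochastic")
        rows = sheet.row_of_cells()
        margin = sheet.margin_mask()
        acc = np.zeros(sheet.n_cells)
        for seed in range(5):
            noise = sample_noise(seed, sheet, 300, dt)
            acc += gamma_field(prog, sheet, noise, 299, dt)
        means = [acc[(np.abs(rows - sheet.midline_row) == d) & ~margin].mean()
                 for d in range(6)]
        assert np.all(np.diff(means) < 0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ContractilityProgram(variant="bogus")


class TestAlternativeGradient:
    def test_weight_one_at_midline(self):
        prog = ContractilityProgram(variant="gradient_alternative")
        assert alternative_gradient_weight(prog, 5.0, 5.0, 1.5) == pytest.approx(1.0)

    def test_symmetric_about_midline(self):
        prog = ContractilityProgram(variant="gradient_alternative")
        up = alternative_gradient_weight(prog, 7.0, 5.0, 1.5)
        down = alternative_gradient_weight(prog, 3.0, 5.0, 1.5)
        assert up == pytest.approx(down)

    def test_weight_increases_as_cell_approaches_midline(self, archive_factory):
        # on a recorded run, lateral-cell weights grow as centroids move in
        archive = archive_factory("gradient_alternative", 1)
        sheet = archive.sheet_initial
        prog = archive.config.contractility
        rows = sheet.row_of_cells()
        margin = sheet.margin_mask()
        pick = np.flatnonzero((np.abs(rows - sheet.midline_row) == 3) & ~margin)[:5]
        y_mid = archive.y_mid
        pitch = sheet.row_pitch
        for c in pick:
            cy = archive.traces["centroid_y"][:, c]
            w0 = alternative_gradient_weight(prog, cy[0], y_mid, pitch)
            w1 = alternative_gradient_weight(prog, cy[-1], y_mid, pitch)
            d0, d1 = abs(cy[0] - y_mid), abs(cy[-1] - y_mid)
            assert d1 < d0  # the cell moved toward the midline
            assert w1 > w0


class TestProgramValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ContractilityProgram(gamma_mid=-1.0)
        with pytest.raises(ValueError):
            ContractilityProgram(sigma_width=0.0)
        with pytest.raises(ValueError):
            ContractilityProgram(n_central_rows=4)
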