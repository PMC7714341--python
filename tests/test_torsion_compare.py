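import numpy as np
import pytest
from scipy import stats

from turnprop.dihedrals import wrap_angle
from turnprop.reference_data import get_dft_geometry
from turnprop.torsion_compare import (
    GaussianPeak,
    deviation_series,
    fit_deviations,
    fit_nearest_peak,
    histogram_deviations,
    ideal_comparison_table,
    outlier_table,
    zscore,
)
from turnprop.trajectory_io import TorsionSeries


def _series(values):
    values = np.asarray(values, dtype=float)[:, None]
    return TorsionSeries(residue_ids=[1], phi=values, psi=values)


class TestDeviationSeries:
    def test_constant_series_gives_zeros(self):
        devs = deviation_series(_series([40.0] * 5), 1, "phi", 40.0)
        assert np.array_equal(devs, np.zeros(5))

    def test_wraps_across_180(self):
        devs = deviation_series(_series([-170.0]), 1, "phi", 170.0)
        assert devs[0] == 20.0

    def test_subset_equals_filtered_full_call(self, rng):
        values = rng.uniform(-180, 179.9, size=100)
        full = deviation_series(_series(values), 1, "phi", 25.0)
        members = [3, 17, 42, 99]
        sub = deviation_series(_series(values), 1, "phi", 25.0, frames=members)
        assert np.array_equal(sub, full[members])

    def test_undefined_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            deviation_series(_series([0.0]), 1, "phi", np.nan)


class TestPeakFit:
    def test_recovers_von_mises_peak_against_circular_oracle(self, rng):
        # kappa equivalent to sigma ~ 10 deg
        kappa = 1.0 / np.radians(10.0) ** 2
        devs = wrap_angle(15.0 + np.degrees(rng.vonmises(0.0, kappa, size=100_000)))
        peak = fit_deviations(devs)
        # independent oracle: circular mean and resultant-length dispersion
        rad = np.radians(devs)
        mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
        r = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
        sigma_circ = np.degrees(np.sqrt(-2.0 * np.log(r)))
        assert peak.mu == pytest.approx(mean, abs=0.5)
        assert peak.mu == pytest.approx(15.0, abs=0.5)
        assert peak.sigma == pytest.approx(sigma_circ, abs=0.5)
        assert peak.sigma == pytest.approx(10.0, abs=0.5)

    def test_symmetric_bimodal_tie_breaks_negative(self, rng):
        a = rng.normal(-90.0, 8.0, size=50_000)
        b = rng.normal(90.0, 8.0, size=50_000)
        peak = fit_deviations(wrap_angle(np.concatenate([a, b])))
        assert abs(abs(peak.mu) - 90.0) < 1.0
        assert peak.mu < 0

    def test_single_spike_gives_smallest_sigma(self):
        devs = np.zeros(1000) + 0.1
        peak = fit_deviations(devs)
        assert abs(peak.mu) < 2.5
        assert peak.sigma == pytest.approx(1.0, abs=0.2)

    def test_shift_moves_mu_not_sigma(self, rng):
        base = rng.normal(0.0, 12.0, size=80_000)
        p0 = fit_deviations(wrap_angle(base))
        p1 = fit_deviations(wrap_angle(base + 20.0))
        assert p1.mu - p0.mu == pytest.approx(20.0, abs=0.5)
        assert p1.sigma == pytest.approx(p0.sigma, abs=0.3)

    def test_peak_near_seam_is_handled_circularly(self, rng):
        devs = wrap_angle(175.0 + rng.normal(0.0, 8.0, size=60_000))
        hist = histogram_deviations(devs)
        peak = fit_nearest_peak(hist)
        assert abs(wrap_angle(peak.mu - 175.0)) < 1.0
        assert peak.sigma == pytest.approx(8.0, abs=1.0)

    def test_too_few_deviations_raises(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_deviations(np.zeros(20))

    def test_flat_histogram_raises_no_peak(self):
        edges = np.arange(-180.0, 181.0, 5.0)
        from turnprop.torsion_compare import DeviationHistogram

        hist = DeviationHistogram(bin_edges=edges,
                                  counts=np.full(72, 100), n=7200)
        with pytest.raises(ValueError, match="no peak"):
            fit_nearest_peak(hist)


class TestZScore:
    def test_zero_mean_full_probability(self):
        z = zscore(GaussianPeak(0.0, 10.0, 1.0, 0.0, 1))
        assert z.z == 0.0 and z.probability == 1.0

    def test_one_sigma(self):
        z = zscore(GaussianPeak(10.0, 10.0, 1.0, 0.0, 1))
        assert abs(z.z) == 1.0
        assert z.probability == pytest.approx(0.3173, abs=1e-4)

    def test_matches_normal_cdf_oracle(self):
        peak = GaussianPeak(-33.0, 15.0, 1.0, 0.0, 1)
        z = zscore(peak)
        assert z.z == pytest.approx(2.2, abs=1e-12)
        assert z.probability == pytest.approx(2 * stats.norm.sf(2.2), abs=1e-10)
        assert z.probability == pytest.approx(0.0278, abs=5e-4)

    def test_zero_sigma_raises(self):
        with pytest.raises(ValueError):
            zscore(GaussianPeak(1.0, 0.0, 1.0, 0.0, 1))


class TestTables:
    def _peak(self, mu):
        return GaussianPeak(mu, 10.0, 1.0, 0.0, 1)

    def test_outlier_table_empty_when_all_within_30(self):
        peaks = {("hpNG-1", "I", "phi_i+1"): self._peak(-12.0)}
        assert outlier_table(peaks).empty

    def test_outlier_table_reports_absolute_mu(self):
        peaks = {
            ("hpNG-1", "I'", "psi_i+1"): self._peak(-33.0),
            ("hpNG-1", "I", "phi_i+1"): self._peak(10.0),
        }
        table = outlier_table(peaks)
        assert len(table) == 1
        assert table.loc[0, "abs_deviation"] == pytest.approx(33.0)

    def test_ideal_comparison_zero_when_dft_equals_ideal(self):
        from turnprop.reference_data import DFTReferenceGeometry

        geo = DFTReferenceGeometry("x", "I", (-60, 150, -60, -30, -90, 0.1, -80, 150))
        peaks = {"I": {("i+1", "phi"): self._peak(0.0)}}
        table = ideal_comparison_table(peaks, {"I": geo})
        assert table.loc[0, "abs_difference"] == pytest.approx(0.0)

    def test_ideal_comparison_arithmetic(self):
        # DFT psi(i+1) of hpNG-1 I' is 41.5; with mu = 10 the ensemble mean
        # is 51.5, i.e. 21.5 deg from the ideal 30.
        geo = get_dft_geometry("hpNG-1", "I'")
        peaks = {"I'": {("i+1", "psi"): self._peak(10.0)}}
        table = ideal_comparison_table(peaks, {"I'": geo})
        assert table.loc[0, "abs_difference"] == pytest.approx(21.5)

    def test_ideal_comparison_type_iv_raises(self):
        peaks = {"IV": {("i+1", "phi"): self._peak(0.0)}}
        with pytest.raises(ValueError, match="no ideal angles"):
            ideal_comparison_table(peaks, {})
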