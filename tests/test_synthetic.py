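"""Simulator: spectral construction, determinism, cohort structure."""

import numpy as np
import pytest
import scipy.stats

from stnpower.recording import assessments_to_frame
from stnpower.spectral import CANONICAL_BANDS, band_power, to_relative, welch_psd
from stnpower.synthetic import (
    CohortSpec,
    SimPeak,
    SimulationSpec,
    SCENARIOS,
    scenario,
    simulate_cohort,
    simulate_recording,
)

from conftest import welch_expectation


class TestSimulateRecording:
    def test_sample_count_matches_duration_and_rate(self):
        rec = simulate_recording(SimulationSpec(exponent=1.0, seed=0))
        assert rec.n_samples == 432_000  # 180 s x 2400 Hz

    def test_white_noise_limit_has_flat_loglog_slope(self):
        rec = simulate_recording(SimulationSpec(exponent=0.0, offset=0.01, seed=1))
        sp = welch_psd(rec)
        sel = (sp.frequencies >= 2) & (sp.frequencies <= 200)
        slope = np.polyfit(np.log10(sp.frequencies[sel]), np.log10(sp.power[sel]), 1)[0]
        assert abs(slope) < 0.05

    def test_seed_determinism(self):
        spec = SimulationSpec(exponent=1.5, peaks=(SimPeak(15, 0.05, 1.5),), seed=7)
        a = simulate_recording(spec).data
        b = simulate_recording(spec).data
        np.testing.assert_array_equal(a, b)

    def test_output_is_real_and_zero_mean(self):
        rec = simulate_recording(SimulationSpec(exponent=1.0, seed=3))
        assert np.isrealobj(rec.data)
        assert abs(rec.data.mean()) < 1e-9  # DC bin zeroed

    def test_low_sample_rate_rejected_naming_peak(self):
        with pytest.raises(ValueError, match="60"):
            SimulationSpec(sample_rate=100.0, peaks=(SimPeak(60.0, 0.1, 3.0),))

    def test_mean_welch_matches_window_convolved_target(self):
        """Mean over seeds equals the textbook Welch expectation within 2%."""
        spec = SimulationSpec(exponent=1.5, offset=1.0, peaks=(SimPeak(15, 0.2, 1.5),))
        acc = None
        n_seeds = 50
        for s in range(n_seeds):
            sp = welch_psd(
                simulate_recording(
                    SimulationSpec(
                        exponent=spec.exponent, offset=spec.offset, peaks=spec.peaks,
                        duration_s=60.0, seed=1000 + s,
                    )
                )
            )
            acc = sp.power if acc is None else acc + sp.power
        mean = acc / n_seeds
        freqs, expected = welch_expectation(spec)
        sel = (freqs >= 2) & (freqs <= 200)
        rel = np.abs(mean[sel] - expected[sel]) / expected[sel]
        assert rel.max() < 0.02

    def test_mean_welch_matches_analytic_target_for_smooth_spectra(self):
        """For smooth spectra the raw analytic target holds to 5% (3-200 Hz)."""
        base = dict(exponent=1.0, offset=1.0, peaks=(SimPeak(15, 0.1, 3.0),), duration_s=60.0)
        acc = None
        for s in range(50):
            sp = welch_psd(simulate_recording(SimulationSpec(**base, seed=2000 + s)))
            acc = sp.power if acc is None else acc + sp.power
        mean = acc / 50
        target = SimulationSpec(**base).analytic_psd(sp.frequencies)
        sel = (sp.frequencies >= 3) & (sp.frequencies <= 200)
        rel = np.abs(mean[sel] - target[sel]) / target[sel]
        assert rel.max() < 0.05

    def test_variance_matches_spectrum_integral(self):
        spec = SimulationSpec(exponent=0.0, offset=0.01, duration_s=30.0, seed=5)
        rec = simulate_recording(spec)
        # white spectrum: variance = offset x bandwidth
        expected = spec.offset * spec.sample_rate / 2.0
        assert rec.data.var() == pytest.approx(expected, rel=0.01)


class TestScenarios:
    @pytest.mark.parametrize("name", SCENARIOS)
    def test_pairs_differ_in_exactly_one_parameter(self, name):
        base, pert = scenario(name)
        diffs = []
        if base.exponent != pert.exponent:
            diffs.append("exponent")
        if base.offset != pert.offset:
            diffs.append("offset")
        for pb, pp in zip(base.peaks, pert.peaks):
            for fld in ("centre_frequency", "amplitude", "sigma_f"):
                if getattr(pb, fld) != getattr(pp, fld):
                    diffs.append(fld)
        assert len(diffs) == 1

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("nonsense")

    def test_theta_increase_changes_only_theta_amplitude(self):
        base, pert = scenario("theta_increase")
        assert pert.peaks[0].amplitude > base.peaks[0].amplitude
        assert pert.peaks[1] == base.peaks[1]

    def test_beta_narrowing_shrinks_beta_width(self):
        base, pert = scenario("beta_narrowing")
        assert pert.peaks[1].sigma_f < base.peaks[1].sigma_f


def _fast_cohort_spec(**kw):
    defaults = dict(n_patients=20, duration_s=10.0, sample_rate=500.0,
                    full_montage=False, seed=11)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestCohort:
    def test_every_patient_has_two_hemispheres_and_conditions(self, small_cohort):
        keys = {(r.patient_id, r.hemisphere, r.condition) for r in small_cohort.recordings}
        for pid in small_cohort.patient_ids:
            for h in ("left", "right"):
                for c in ("off", "on"):
                    assert (pid, h, c) in keys

    def test_subscore_sums_never_exceed_total(self, small_cohort):
        for a in small_cohort.assessments:
            parts = (
                a.brady_rigidity_left_body
                + a.brady_rigidity_right_body
                + a.tremor_left_body
                + a.tremor_right_body
            )
            assert parts <= a.updrs_total
            assert 0 <= a.brady_rigidity_left_body <= 40
            assert 0 <= a.updrs_total <= 108

    def test_cohort_seed_determinism(self):
        spec = _fast_cohort_spec(n_patients=3)
        a = simulate_cohort(spec)[0]
        b = simulate_cohort(spec)[0]
        np.testing.assert_array_equal(a.recordings[0].data, b.recordings[0].data)
        assert assessments_to_frame(a.assessments).equals(
            assessments_to_frame(b.assessments)
        )

    def test_extending_cohort_preserves_existing_patients(self):
        small = simulate_cohort(_fast_cohort_spec(n_patients=3))[0]
        large = simulate_cohort(_fast_cohort_spec(n_patients=5))[0]
        np.testing.assert_array_equal(
            small.recording(small.patient_ids[1], "left", "off").data,
            large.recording(large.patient_ids[1], "left", "off").data,
        )

    def test_null_cohort_has_no_spurious_band_score_correlation(self):
        """With zero planted effects the band-score Spearman stays near 0."""
        spec = _fast_cohort_spec(n_patients=50, effect_map={}, asymmetry_log10=0.0, seed=23)
        cohort = simulate_cohort(spec)[0]
        rows = []
        for pid in cohort.patient_ids:
            specs = []
            for h in ("left", "right"):
                sp = welch_psd(cohort.recording(pid, h, "off"))
                specs.append(sp)
            mean_beta = np.mean([band_power(s, CANONICAL_BANDS[3]) for s in specs])
            rows.append((mean_beta, cohort.assessment(pid, "off").updrs_total))
        x, y = zip(*rows)
        rho = scipy.stats.spearmanr(x, y).statistic
        assert abs(rho) < 2.0 / np.sqrt(len(x))

    def test_planted_asymmetry_elevates_more_affected_broadband(self):
        """+0.3 log10 offset shows up in 2-60 Hz total power of most patients."""
        spec = _fast_cohort_spec(
            n_patients=40, asymmetry_log10=0.3, frac_symmetric=0.0,
            frac_inconsistent=0.0, duration_s=15.0, seed=31,
        )
        cohort = simulate_cohort(spec)[0]
        truth = cohort.truth
        n_correct = n_total = 0
        for pid in cohort.patient_ids:
            t = truth[(truth.patient_id == pid) & (truth.condition == "off")]
            more = t[t.more_affected]["hemisphere"]
            if more.empty:
                continue
            more = more.iloc[0]
            less = "left" if more == "right" else "right"
            powers = {}
            for h in (more, less):
                sp = welch_psd(cohort.recording(pid, h, "off"))
                sel = (sp.frequencies >= 2) & (sp.frequencies <= 60)
                powers[h] = sp.power[sel].sum()
            n_total += 1
            n_correct += powers[more] > powers[less]
        assert n_total >= 30
        assert n_correct / n_total >= 0.90

    def test_planted_correlation_recovered_at_large_n(self):
        """Planted low-beta/UPDRS rho = 0.4 recovered within sampling error.

        Measured on relative band power, the framework the planted effect
        targets; absolute band power attenuates the correlation because the
        across-patient broadband scale variation multiplies every band.
        """
        spec = _fast_cohort_spec(
            n_patients=200, duration_s=10.0, effect_map={"low_beta": 0.4}, seed=47,
        )
        cohort = simulate_cohort(spec)[0]
        x, y = [], []
        for pid in cohort.patient_ids:
            vals = [
                band_power(
                    to_relative(welch_psd(cohort.recording(pid, h, "off"))),
                    CANONICAL_BANDS[3],
                )
                for h in ("left", "right")
            ]
            x.append(np.mean(vals))
            y.append(cohort.assessment(pid, "off").updrs_total)
        rho = scipy.stats.spearmanr(x, y).statistic
        assert 0.25 <= rho <= 0.55

    def test_infeasible_correlation_target_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CohortSpec(effect_map={"low_beta": 1.4})

    def test_unknown_band_in_effect_map_rejected(self):
        with pytest.raises(ValueError, match="unknown band"):
            CohortSpec(effect_map={"ripple": 0.2})
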