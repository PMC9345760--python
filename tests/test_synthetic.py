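"""Synthetic generator: sampling, rate profiles, presets, optomotor sessions."""

import numpy as np
import pytest

from rdretina import (
    draw_truth,
    electrical_rate_profile,
    generate_optomotor_session,
    generate_population,
    light_rate_profile,
    optomotor_preset,
    sample_inhomogeneous_poisson,
    stage_preset,
)
from rdretina.synthetic import BURST_CENTER_S, LIGHT_TAU_S, PresetError, amplitude_gain


class TestPoissonSampler:
    def test_constant_rate_mean_count_within_3_sd(self):
        rng = np.random.default_rng(7)
        counts = [
            len(sample_inhomogeneous_poisson(lambda t: np.full_like(t, 5.0),
                                             100.0, 5.0, rng))
            for _ in range(200)
        ]
        assert abs(np.mean(counts) - 500.0) < 3 * np.sqrt(500.0) / np.sqrt(200)

    def test_zero_rate_gives_empty_train(self):
        out = sample_inhomogeneous_poisson(lambda t: np.zeros_like(t), 10.0, 0.0, 1)
        assert out.size == 0

    def test_same_seed_same_train(self):
        fn = lambda t: 2.0 + np.sin(t) + 1.0
        a = sample_inhomogeneous_poisson(fn, 50.0, 4.0, 42)
        b = sample_inhomogeneous_poisson(fn, 50.0, 4.0, 42)
        assert np.array_equal(a, b)

    def test_negative_rate_rejected(self):
        with pytest.raises(PresetError):
            sample_inhomogeneous_poisson(lambda t: -np.ones_like(t), 10.0, 5.0, 0)

    def test_thinning_tracks_a_time_varying_profile(self):
        rng = np.random.default_rng(3)
        fn = lambda t: np.where(t < 50.0, 10.0, 1.0)
        times = np.concatenate(
            [sample_inhomogeneous_poisson(fn, 100.0, 10.0, rng) for _ in range(50)]
        )
        early = np.sum(times < 50.0) / 50
        late = np.sum(times >= 50.0) / 50
        assert abs(early - 500.0) < 3 * np.sqrt(500.0 / 50)
        assert abs(late - 50.0) < 3 * np.sqrt(50.0 / 50)


class TestLightProfile:
    def test_unresponsive_is_flat_baseline(self):
        p = stage_preset("WT_P70")
        t = np.linspace(0, 8, 100, endpoint=False)
        assert np.allclose(light_rate_profile("unresponsive", t, 5.0, p), 5.0)

    def test_on_transient_decays_by_mid_cycle(self):
        p = stage_preset("WT_P70")
        assert light_rate_profile("ON", 2.0, 5.0, p) == pytest.approx(5.0, abs=1e-6)

    def test_most_transient_mass_within_100ms(self):
        # closed form: alpha-function CDF is 1 - (1 + x) e^{-x}, x = t/tau
        x = 0.1 / LIGHT_TAU_S
        analytic = 1.0 - (1.0 + x) * np.exp(-x)
        assert analytic >= 0.9
        p = stage_preset("WT_P70")
        t = np.linspace(0, 4, 40001)
        added = light_rate_profile("ON", t, 0.0, p)
        mass_100 = np.trapezoid(added[t <= 0.1], t[t <= 0.1])
        mass_all = np.trapezoid(added, t)
        assert mass_100 / mass_all == pytest.approx(analytic, abs=5e-3)
        assert mass_100 / mass_all >= 0.9

    def test_off_cell_transient_sits_after_light_offset(self):
        p = stage_preset("WT_P70")
        assert light_rate_profile("OFF", 4.0 + LIGHT_TAU_S, 0.0, p) > 0
        assert light_rate_profile("OFF", 2.0, 0.0, p) == pytest.approx(0.0)

    def test_unknown_type_rejected(self):
        with pytest.raises(PresetError):
            light_rate_profile("weird", 1.0, 5.0, stage_preset("WT_P70"))


class TestElectricalProfile:
    def test_subthreshold_amplitude_leaves_profile_near_baseline(self):
        p = stage_preset("RD_P45")
        t = np.linspace(0, 1, 1000, endpoint=False)
        r = electrical_rate_profile("single", t, 1.0, p, 10.0)
        # gain at 1 uA is ~0 -> added mass a tiny fraction of the 50 uA burst
        assert float(amplitude_gain(1.0, p)) < 0.06
        baseline = 10.0 * np.where((t > 0.1) & (t <= 0.5), p.er_suppression, 1.0)
        assert np.trapezoid(np.clip(r - baseline, 0, None), t) < 0.1

    def test_multiple_peak_crest_spacing_matches_oscillation_period(self):
        p = stage_preset("RD_P45", osc_decay_tau_s=5.0)  # negligible damping
        t = np.linspace(0, 0.5, 50001)
        r = electrical_rate_profile("multiple", t, 50.0, p, 0.0, f_osc_hz=8.7)
        # crest locations = local maxima of the profile
        idx = np.where((r[1:-1] > r[:-2]) & (r[1:-1] >= r[2:]) & (r[1:-1] > 1))[0] + 1
        crests = t[idx]
        assert np.allclose(np.diff(crests), 1.0 / 8.7, atol=1e-3)
        assert crests[0] == pytest.approx(BURST_CENTER_S, abs=1e-3)

    def test_single_burst_tail_at_5ms_is_small(self):
        p = stage_preset("RD_P45")
        peak = electrical_rate_profile("single", BURST_CENTER_S, 50.0, p, 0.0)
        early = electrical_rate_profile("single", 0.005, 50.0, p, 0.0)
        assert early / peak < 0.07

    def test_amplitude_outside_ladder_rejected(self):
        with pytest.raises(PresetError):
            electrical_rate_profile("single", 0.05, 15.0, stage_preset("RD_P45"), 5.0)

    def test_gain_is_monotone_in_amplitude(self):
        p = stage_preset("RD_P45")
        g = amplitude_gain(np.array([1, 5, 10, 20, 30, 40, 50], float), p)
        assert np.all(np.diff(g) > 0)
        assert g[-1] == pytest.approx(1.0)


class TestPresets:
    def test_all_stage_presets_validate(self):
        for stage in ("WT_P70", "RD_P45", "RD_P70", "RD_P140", "RD_P238"):
            p = stage_preset(stage)
            assert abs(sum(p.light_fractions) - 1.0) < 1e-9

    def test_multi_peak_fractions_derive_from_count_ratios(self):
        for stage, ratio in (("RD_P45", 0.70), ("RD_P70", 1.78),
                             ("RD_P140", 1.80), ("RD_P238", 8.98)):
            p = stage_preset(stage)
            assert p.multi_peak_fraction == pytest.approx(ratio / (1 + ratio))

    def test_bad_fractions_rejected(self):
        with pytest.raises(PresetError):
            stage_preset("WT_P70", light_fractions=(0.5, 0.5, 0.5, -0.5))


class TestGeneratePopulation:
    def test_determinism_same_preset_same_dataset(self):
        p = stage_preset("RD_P45", n_cells=5, seed=9)
        a = generate_population(p, protocol="electrical")
        b = generate_population(p, protocol="electrical")
        assert a.truth.equals(b.truth)
        for ta, tb in zip(a.electrical_trains, b.electrical_trains):
            assert np.array_equal(ta.times, tb.times)

    def test_single_cell_population_has_one_truth_record(self):
        ds = generate_population(stage_preset("RD_P45", n_cells=1, seed=0),
                                 protocol="light")
        assert len(ds.truth) == 1
        assert len(ds.light_trains) == 1

    def test_truth_covers_every_cell_exactly_once(self):
        ds = generate_population(stage_preset("RD_P70", n_cells=40, seed=1),
                                 protocol="light")
        ids = [t.cell_id for t in ds.light_trains]
        assert sorted(ds.truth.cell_id) == sorted(ids)
        assert not ds.truth.cell_id.duplicated().any()

    def test_first_pulse_preceded_by_25s_silence(self):
        ds = generate_population(stage_preset("RD_P45", n_cells=1, seed=0),
                                 protocol="electrical")
        assert ds.electrical_events.onsets[0] >= 25.0

    def test_label_proportions_converge_to_preset_fractions(self):
        # same label-seeding path as generate_population
        p = stage_preset("WT_P70", n_cells=10000, seed=4)
        label_ss = np.random.SeedSequence(p.seed).spawn(3)[0]
        truth = draw_truth(p, np.random.default_rng(label_ss))
        responsive = 1.0 - np.mean(truth.light_type == "unresponsive")
        assert abs(responsive - 0.73) < 2 * np.sqrt(0.73 * 0.27 / 10000)
        assert abs(truth.er.mean() - 0.40) < 2 * np.sqrt(0.4 * 0.6 / 10000)

    def test_mean_rate_of_constant_cell_calibrated(self):
        # unresponsive, non-ER cell over the light protocol: pure baseline
        p = stage_preset("RD_P45", n_cells=1, seed=12, spont_rate_log_sd=1e-9)
        truth = draw_truth(p, np.random.default_rng(5))
        truth["light_type"] = "unresponsive"
        ds = generate_population(p, protocol="light", truth=truth)
        n = ds.light_trains[0].n_spikes
        expect = 10.0 * ds.light_trains[0].duration
        assert abs(n - expect) < 3 * np.sqrt(expect)


class TestOptomotorSession:
    def test_noiseless_frontier_at_full_contrast_equals_true_acuity(self):
        p = optomotor_preset("WT", n_animals=1, seed=0,
                             frontier_noise_sd_cpd=0.0, resolution_step_cpd=0.001)
        trials = generate_optomotor_session(p)
        full = trials[(trials.contrast_pct == 100.0) & trials.success]
        assert full.spatial_resolution_cpd.max() == pytest.approx(0.53, abs=1e-3)

    def test_noiseless_frontier_monotone_in_contrast(self):
        p = optomotor_preset("RD_P45", n_animals=1, seed=0,
                             frontier_noise_sd_cpd=0.0)
        trials = generate_optomotor_session(p)
        fr = trials[trials.success].groupby("contrast_pct").spatial_resolution_cpd.max()
        assert np.all(np.diff(fr.to_numpy()) >= 0)

    def test_zero_acuity_group_has_no_successful_trials(self):
        trials = generate_optomotor_session(optomotor_preset("RD_LATE", seed=3))
        assert not trials.success.any()

    def test_session_is_reproducible(self):
        p = optomotor_preset("WT", seed=11)
        assert generate_optomotor_session(p).equals(generate_optomotor_session(p))
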