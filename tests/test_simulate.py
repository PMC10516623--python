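"""Simulator correctness: exact CTMC statistics, archetype draws,
rendering arithmetic, determinism, and scenario-specific behavior."""

import numpy as np
import pytest
from scipy import stats

from rsfret.preprocess import preprocess_trace
from rsfret.simulate import (ConfigError, KineticScheme, PhotophysicsConfig,
                             ScenarioConfig, StateModel, bound_fraction_isotherm,
                             draw_molecule, simulate_competition,
                             simulate_ensemble, simulate_state_path,
                             simulate_static_population, simulate_titration,
                             simulate_vectorial, stationary_occupancy,
                             render_trace)


class TestDrawMolecule:
    def test_zero_sigma_gives_base_rates(self, rng):
        scheme = KineticScheme.default(heterogeneity_sigma=0.0,
                                       archetype_weights=(0, 0, 1))
        for _ in range(10):
            p = draw_molecule(scheme, rng)
            assert p.rate_factor == 1.0
            assert p.rates[("open", "closed")] == pytest.approx(1 / 3)

    def test_degenerate_weights_force_archetype(self, rng):
        scheme = KineticScheme.default(archetype_weights=(1.0, 0.0, 0.0))
        for _ in range(10):
            p = draw_molecule(scheme, rng)
            assert p.archetype == "static_mid"
            assert p.rates[("open", "closed")] == 0.0

    def test_lognormal_rate_quantiles(self, rng):
        """With sigma = ln(10) the per-molecule rate factors follow the
        log-normal closed form: check deciles of 10^4 draws."""
        sigma = np.log(10)
        scheme = KineticScheme.default(heterogeneity_sigma=sigma,
                                       archetype_weights=(0, 0, 1))
        factors = np.array([draw_molecule(scheme, rng).rate_factor
                            for _ in range(10_000)])
        for q in (0.1, 0.5, 0.9):
            expected = float(np.exp(stats.norm.ppf(q) * sigma))
            observed = np.quantile(factors, q)
            assert observed == pytest.approx(expected, rel=0.12)
        # inter-decile ratio spans the analytic 10^(2*1.2816*log10(e)*sigma...)
        idr = np.quantile(factors, 0.9) / np.quantile(factors, 0.1)
        assert idr == pytest.approx(np.exp(2 * stats.norm.ppf(0.9) * sigma),
                                    rel=0.25)


class TestGillespie:
    def test_absorbing_initial_state_single_segment(self, rng):
        path = simulate_state_path({("open", "closed"): 1.0}, "closed",
                                   10.0, rng)
        assert path == [("closed", 0.0)]

    def test_symmetric_two_state_dwell_and_occupancy(self, rng):
        """k12 = k21 = 1/s over 10^4 s: mean dwell 1 s and occupancy 0.5,
        each within 3 standard errors (exponential dwells, CTMC
        stationarity)."""
        rates = {("open", "closed"): 1.0, ("closed", "open"): 1.0}
        path = simulate_state_path(rates, "open", 10_000.0, rng)
        times = np.array([t for _, t in path] + [10_000.0])
        dwells = np.diff(times)[:-1]  # last dwell censored
        n = len(dwells)
        assert n > 5000
        se = 1.0 / np.sqrt(n)  # exponential sd equals its mean
        assert abs(dwells.mean() - 1.0) < 3 * se
        states = np.array([s for s, _ in path])
        occ_open = np.diff(times)[states == "open"].sum() / 10_000.0
        assert abs(occ_open - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_dwell_means_match_exit_rates_random_schemes(self, rng):
        """SSA holding times average 1/(total exit rate) per state across
        randomized two-state schemes (3 SE)."""
        for _ in range(5):
            k1, k2 = rng.uniform(0.2, 5.0, size=2)
            rates = {("open", "closed"): k1, ("closed", "open"): k2}
            path = simulate_state_path(rates, "open", 3000.0 / min(k1, k2), rng)
            times = np.array([t for _, t in path] + [3000.0 / min(k1, k2)])
            states = np.array([s for s, _ in path])
            dwells = np.diff(times)[:-1]
            for state, k in (("open", k1), ("closed", k2)):
                d = dwells[states[:-1] == state]
                se = (1 / k) / np.sqrt(len(d))
                assert abs(d.mean() - 1 / k) < 3 * se

    def test_zero_exit_rate_never_leaves(self, rng):
        path = simulate_state_path({("closed", "open"): 1.0}, "open", 50.0, rng)
        assert path == [("open", 0.0)]

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ConfigError, match="negative"):
            simulate_state_path({("open", "closed"): -1.0}, "open", 1.0, rng)

    def test_stationary_occupancy_closed_form(self):
        occ = stationary_occupancy({("open", "closed"): 0.25,
                                    ("closed", "open"): 0.75})
        assert occ["closed"] == pytest.approx(0.25)
        assert occ["open"] == pytest.approx(0.75)


class TestRenderTrace:
    def test_pure_state_frame_inverts_exactly(self, quiet_photo, default_model):
        """With zero noise/crosstalk/background, a frame spent entirely in
        the closed state inverts to E = 0.84 exactly."""
        model = StateModel.default()
        for s in model.states.values():
            s.fret_sd = 1e-12  # suppress conformational spread
        sc = ScenarioConfig(duration=0.75)
        tr = render_trace([("closed", 0.0)], model, quiet_photo, sc,
                          np.random.default_rng(0))
        e = tr.acceptor / (tr.donor + tr.acceptor)
        np.testing.assert_allclose(e, 0.84, atol=1e-9)

    def test_mid_frame_jump_blurs_to_average(self, quiet_photo):
        """A jump at mid-frame yields frame FRET (0.4+0.84)/2 = 0.62."""
        model = StateModel.default()
        for s in model.states.values():
            s.fret_sd = 1e-12
        sc = ScenarioConfig(duration=0.075, frame_interval=0.075)
        path = [("open", 0.0), ("closed", 0.075 / 2)]
        tr = render_trace(path, model, quiet_photo, sc, np.random.default_rng(0))
        e = tr.acceptor[0] / (tr.donor[0] + tr.acceptor[0])
        assert e == pytest.approx(0.62, abs=1e-9)

    def test_pife_scales_total_counts(self, quiet_photo):
        model = StateModel.default()
        for s in model.states.values():
            s.fret_sd = 1e-12
        sc = ScenarioConfig(duration=0.15, frame_interval=0.075)
        tr = render_trace([("heteroduplex", 0.0)], model, quiet_photo, sc,
                          np.random.default_rng(0),
                          pife_window=(0.075, 0.15))
        assert tr.total[1] == pytest.approx(1.5 * tr.total[0])

    def test_occupancy_weighted_inversion_to_1e12(self, crosstalk_photo):
        """Rendered frames, inverted with the exact crosstalk parameters at
        zero noise, equal the occupancy-weighted state mean to 1e-12."""
        model = StateModel.default()
        for s in model.states.values():
            s.fret_sd = 1e-12
        sc = ScenarioConfig(duration=3.0)
        rng = np.random.default_rng(3)
        path = simulate_state_path({("open", "closed"): 2.0,
                                    ("closed", "open"): 2.0}, "open",
                                   sc.n_frames * sc.frame_interval, rng)
        tr = render_trace(path, model, crosstalk_photo, sc, rng)
        p = crosstalk_photo
        d = tr.donor - p.background_donor
        a = (tr.acceptor - p.background_acceptor - p.leakage_beta * d
             - p.direct_excitation_delta)
        e = a / (d + a)
        from rsfret.simulate import _frame_occupancy
        means = {s: em.fret_mean for s, em in model.states.items()}
        expected = _frame_occupancy(path, sc.n_frames, sc.frame_interval, means)
        np.testing.assert_allclose(e, expected, atol=1e-12)


class TestEnsembles:
    def test_seed_determinism_byte_identical(self, default_photo,
                                             minute_scenario, default_model):
        scheme = KineticScheme.default()
        a = simulate_ensemble(scheme, default_model, default_photo,
                              minute_scenario, n=5, seed=11)
        b = simulate_ensemble(scheme, default_model, default_photo,
                              minute_scenario, n=5, seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.donor, y.donor)
            np.testing.assert_array_equal(x.acceptor, y.acceptor)

    def test_static_high_ensemble_constant_high(self, quiet_photo,
                                                short_scenario):
        scheme = KineticScheme.default(archetype_weights=(0, 1, 0))
        model = StateModel.default()
        for s in model.states.values():
            s.fret_sd = 1e-12
        ens = simulate_ensemble(scheme, model, quiet_photo, short_scenario,
                                n=5, seed=2)
        for tr in ens:
            e = tr.acceptor / (tr.donor + tr.acceptor)
            np.testing.assert_allclose(e, 0.84, atol=1e-9)

    def test_high_frame_fraction_matches_mixture_expectation(self, quiet_photo):
        """Fraction of frames near the high state matches the archetype
        mixture + stationary occupancy closed form."""
        weights = (0.3, 0.2, 0.5)
        scheme = KineticScheme.default(archetype_weights=weights,
                                       heterogeneity_sigma=0.0)
        sc = ScenarioConfig(duration=30.0)
        ens = simulate_ensemble(scheme, StateModel.default(), quiet_photo, sc,
                                n=400, seed=3)
        e_all = np.concatenate([tr.acceptor / tr.total for tr in ens])
        frac_high = float(np.mean(e_all > 0.62))
        occ_closed = stationary_occupancy(scheme.base_rates)["closed"]
        expected = weights[1] + weights[2] * occ_closed
        # binomial error over molecules dominates (frames correlate)
        assert frac_high == pytest.approx(expected, abs=0.05)


class TestIsotherm:
    @pytest.mark.parametrize("c,expected", [
        (0.0, 0.30),
        (10.0, (0.30 + 0.75) / 2),   # c = Kd is the half-saturation point
        (1e7, 0.75),
    ])
    def test_limits_and_midpoint(self, c, expected):
        assert bound_fraction_isotherm(c, 10.0, 0.30, 0.75) == \
            pytest.approx(expected, abs=1e-5)

    def test_invalid_kd_rejected(self):
        with pytest.raises(ConfigError):
            bound_fraction_isotherm(1.0, 0.0, 0.0, 1.0)

    def test_titration_weights_converge_to_isotherm(self, quiet_photo):
        """Phenomenological generator: empirical high-state weight at each
        concentration matches the isotherm within binomial error."""
        conc = [0.0, 10.0, 100.0]
        ens = simulate_titration(conc, Kd=10.0, f0=0.2, fmax=0.9,
                                 n_per_point=800, seed=6, photo=quiet_photo)
        for c in conc:
            highs = sum((tr.acceptor / tr.total).mean() > 0.62
                        for tr in ens[c])
            p = bound_fraction_isotherm(c, 10.0, 0.2, 0.9)
            se = np.sqrt(p * (1 - p) / 800)
            assert abs(highs / 800 - p) < 4 * se


class TestVectorial:
    def test_unwinding_time_arithmetic(self):
        sc = ScenarioConfig(mode="vectorial", duplex_length=66,
                            unwind_speed=60.0)
        assert sc.duplex_length / sc.unwind_speed == pytest.approx(1.1)

    def test_no_ligand_no_locking(self, quiet_photo, default_model):
        scheme = KineticScheme.default(archetype_weights=(0, 0, 1))
        sc = ScenarioConfig(mode="vectorial", duration=30.0,
                            ligand_concentration=0.0)
        ens = simulate_vectorial(scheme, default_model, quiet_photo, sc,
                                 n=30, seed=4)
        for tr in ens:
            assert tr.truth["path"][-1][0] != "closed_liganded"

    def test_commit_probability_recovered_in_truth(self, quiet_photo,
                                                   default_model):
        p = 0.4
        scheme = KineticScheme.default()
        sc = ScenarioConfig(mode="vectorial", duration=20.0,
                            commit_probability=p)
        ens = simulate_vectorial(scheme, default_model, quiet_photo, sc,
                                 n=300, seed=5)
        frac = np.mean([tr.truth["committed"] for tr in ens])
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / 300)


class TestCompetition:
    def test_zero_oligo_rejected(self, quiet_photo, default_model):
        scheme = KineticScheme.default()
        sc = ScenarioConfig(mode="competition", duration=10.0)
        with pytest.raises(ConfigError, match="oligo"):
            simulate_competition(scheme, default_model, quiet_photo, sc,
                                 n=5, seed=1)

    def test_all_dynamic_eventually_oligo_bound(self, quiet_photo,
                                                default_model):
        """Without ligand the oligo-bound state is the only absorbing state;
        every dynamic molecule reaches it given enough time."""
        scheme = KineticScheme.default(archetype_weights=(0, 0, 1),
                                       heterogeneity_sigma=0.0,
                                       oligo_kon=1e-3)
        sc = ScenarioConfig(mode="competition", duration=200.0,
                            oligo_length=9, oligo_concentration=500.0)
        ens = simulate_competition(scheme, default_model, quiet_photo, sc,
                                   n=40, seed=7)
        assert all(tr.truth["on_off"] == "ON" for tr in ens)

    def test_equal_race_splits_on_off_evenly(self, quiet_photo, default_model):
        """With the locking and oligo-binding rates equal out of the open
        state (and instant lock commitment), competing exponentials give a
        1:1 ON:OFF split."""
        k = 0.5
        scheme = KineticScheme(
            base_rates={("closed", "open"): 10.0},  # stationary start = open
            ligand_kon=k / 1000.0, ligand_koff=0.0,
            ligand_binds_from="open", oligo_kon=k / 500.0,
            heterogeneity_sigma=0.0, archetype_weights=(0, 0, 1))
        sc = ScenarioConfig(mode="competition", duration=400.0,
                            oligo_length=9, oligo_concentration=500.0,
                            ligand_concentration=1000.0)
        ens = simulate_competition(scheme, default_model, quiet_photo, sc,
                                   n=400, seed=8)
        labels = [tr.truth["on_off"] for tr in ens]
        assert labels.count("undecided") == 0
        frac_on = labels.count("ON") / len(labels)
        assert abs(frac_on - 0.5) < 4 * np.sqrt(0.25 / 400)
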