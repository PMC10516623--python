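"""Two-state HMM: forward algorithm vs exhaustive enumeration, EM
monotonicity, Viterbi decoding and tie-breaking, dwell extraction, and
rate recovery on simulated ground truth."""

import itertools
import math

import numpy as np
import pytest

from rsfret import hmm as hm
from rsfret.hmm import (HIGH, MID, HmmModel, Dwell, dwell_summary,
                        extract_dwells, fit_hmm, forward_backward,
                        log_likelihood, merge_short_runs, viterbi)
from rsfret.preprocess import FretTrace, preprocess_ensemble
from rsfret.simulate import (KineticScheme, PhotophysicsConfig, ScenarioConfig,
                             StateModel, simulate_ensemble)


def fret_trace(values, valid=None, dt=0.075, mid="m0"):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    eff = np.where(valid, values, np.nan)
    return FretTrace(mid, eff, np.asarray(valid, bool), dt)


def brute_force_loglik(model: HmmModel, eff, valid):
    """Independent oracle: sum the joint probability over all 2^L paths."""
    L = len(eff)
    total = 0.0
    for path in itertools.product(range(2), repeat=L):
        p = model.startprob[path[0]]
        for t in range(1, L):
            p *= model.transmat[path[t - 1], path[t]]
        for t in range(L):
            if valid[t]:
                s = model.sds[path[t]]
                p *= math.exp(-0.5 * ((eff[t] - model.means[path[t]]) / s) ** 2) \
                    / (s * math.sqrt(2 * math.pi))
        total += p
    return math.log(total)


def random_model(rng):
    a, b = sorted(rng.uniform(0.2, 0.9, size=2))
    t01, t10 = rng.uniform(0.02, 0.4, size=2)
    pi = rng.dirichlet([1, 1])
    return HmmModel(np.array([a, b + 0.1]), rng.uniform(0.03, 0.1, size=2),
                    np.array([[1 - t01, t01], [t10, 1 - t10]]), pi)


class TestForwardOracle:
    @pytest.mark.parametrize("L", [1, 2, 4, 6, 8])
    def test_forward_equals_enumeration(self, L, rng):
        """Scaled forward recursion matches the exhaustive 2^L path sum to
        1e-9 in log-likelihood, over randomized models and data."""
        for _ in range(3):
            model = random_model(rng)
            eff = rng.uniform(0.2, 1.0, size=L)
            valid = np.ones(L, bool)
            tr = fret_trace(eff, valid)
            assert log_likelihood(model, tr) == pytest.approx(
                brute_force_loglik(model, eff, valid), abs=1e-9)

    def test_masked_frames_bridged(self, rng):
        """A masked frame contributes no emission term; the enumeration
        oracle with that term skipped agrees to 1e-9."""
        model = random_model(rng)
        eff = rng.uniform(0.2, 1.0, size=6)
        valid = np.array([1, 1, 0, 0, 1, 1], bool)
        tr = fret_trace(eff, valid)
        assert log_likelihood(model, tr) == pytest.approx(
            brute_force_loglik(model, eff, valid), abs=1e-9)

    def test_posterior_rows_sum_to_one(self, rng):
        model = random_model(rng)
        eff = rng.uniform(0.2, 1.0, size=50)
        _, gamma, _, _ = forward_backward(model, eff, np.ones(50, bool))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestViterbi:
    def default_model(self):
        return HmmModel(np.array([0.4, 0.84]), np.array([0.05, 0.05]),
                        np.array([[0.95, 0.05], [0.05, 0.95]]),
                        np.array([0.5, 0.5]))

    def test_constant_mid_decodes_all_mid(self):
        tr = fret_trace([0.4] * 20)
        assert (viterbi(self.default_model(), tr) == MID).all()

    def test_single_midpoint_frame_tie_to_start_argmax(self):
        """A lone frame exactly between the means under a symmetric model
        ties; the documented rule sends it to the initial-distribution
        argmax."""
        model = HmmModel(np.array([0.4, 0.84]), np.array([0.05, 0.05]),
                         np.array([[0.9, 0.1], [0.1, 0.9]]),
                         np.array([0.3, 0.7]))
        tr = fret_trace([0.62])
        assert viterbi(model, tr)[0] == HIGH

    def test_noiseless_path_equals_truth(self, quiet_photo):
        model_sm = StateModel.default()
        for s in model_sm.states.values():
            s.fret_sd = 1e-12
        scheme = KineticScheme.default(archetype_weights=(0, 0, 1),
                                       heterogeneity_sigma=0.0)
        sc = ScenarioConfig(duration=30.0)
        ens = simulate_ensemble(scheme, model_sm, quiet_photo, sc, n=3, seed=21)
        fret = preprocess_ensemble(ens, quiet_photo)
        fits = fit_hmm(fret)
        by_id = {f.molecule_id: f for f in fits}
        for tr, ft in zip(ens, fret):
            truth_states = _truth_frame_states(tr, sc)
            fit = by_id[ft.molecule_id]
            pure = truth_states >= 0
            agree = (fit.viterbi_path[pure] == truth_states[pure]).mean()
            assert agree > 0.99

    def test_viterbi_likelihood_bounded_by_total(self, rng):
        model = random_model(rng)
        eff = rng.uniform(0.2, 1.0, size=30)
        tr = fret_trace(eff)
        path = viterbi(model, tr)
        logp = math.log(model.startprob[path[0]])
        for t in range(1, 30):
            logp += math.log(model.transmat[path[t - 1], path[t]])
        for t in range(30):
            s = model.sds[path[t]]
            logp += (-0.5 * ((eff[t] - model.means[path[t]]) / s) ** 2
                     - math.log(s * math.sqrt(2 * math.pi)))
        assert logp <= log_likelihood(model, tr) + 1e-9


def _truth_frame_states(tr, sc):
    """Frame-level truth labels: MID/HIGH for frames fully inside one
    state, -1 for blurred frames."""
    path = tr.truth["path"]
    dt = sc.frame_interval
    out = np.full(sc.n_frames, -1)
    times = [t for _, t in path] + [np.inf]
    for i, (state, t0) in enumerate(path):
        lo = int(np.ceil(t0 / dt))
        t1 = times[i + 1]
        hi = sc.n_frames if not np.isfinite(t1) else min(int(t1 / dt),
                                                         sc.n_frames)
        if state in ("open",):
            out[lo:hi] = MID
        elif state in ("closed", "closed_liganded"):
            out[lo:hi] = HIGH
    return out


class TestEmFitting:
    def test_noiseless_alternating_trace_exact(self):
        """A noiseless 0.4/0.84 alternating-block trace is fitted with the
        means exactly and the truth path recovered."""
        eff = np.array(([0.4] * 10 + [0.84] * 10) * 4)
        tr = fret_trace(eff)
        fit = fit_hmm([tr])[0]
        assert fit.model.means == pytest.approx([0.4, 0.84], abs=1e-6)
        expected = np.array(([MID] * 10 + [HIGH] * 10) * 4)
        np.testing.assert_array_equal(fit.viterbi_path, expected)

    def test_em_loglik_monotone(self, rng):
        """EM log-likelihood never decreases across iterations."""
        eff = np.r_[rng.normal(0.4, 0.06, 60), rng.normal(0.84, 0.06, 60)]
        rng.shuffle(eff)
        fit = fit_hmm([fret_trace(eff)])[0]
        traj = np.array(fit.ll_trajectory)
        assert (np.diff(traj) >= -1e-8).all()

    def test_short_traces_skipped_with_warning(self, caplog):
        short = fret_trace([0.4] * 5)
        with caplog.at_level("WARNING"):
            fits = fit_hmm([short])
        assert fits == []
        assert "valid frames" in caplog.text

    def test_transition_probability_recovery(self, default_photo):
        """Pooled per-frame transition estimates from 120 simulated traces
        land within 20% relative error of the generating probabilities."""
        k_oc, k_co = 0.27, 0.68  # per-frame p ≈ 0.02 and 0.05 at 75 ms
        scheme = KineticScheme(base_rates={("open", "closed"): k_oc,
                                           ("closed", "open"): k_co},
                               heterogeneity_sigma=0.0,
                               archetype_weights=(0, 0, 1))
        photo = PhotophysicsConfig(donor_bleach_rate=0.0,
                                   acceptor_bleach_rate=0.0)
        sc = ScenarioConfig(duration=60.0)
        ens = simulate_ensemble(scheme, StateModel.default(), photo, sc,
                                n=120, seed=22)
        fret = preprocess_ensemble(ens, photo)
        fits = fit_hmm(fret, shared_emissions=True)
        dt = sc.frame_interval
        p_oc = np.mean([f.model.transmat[MID, HIGH] for f in fits])
        p_co = np.mean([f.model.transmat[HIGH, MID] for f in fits])
        assert p_oc == pytest.approx(1 - np.exp(-k_oc * dt), rel=0.20)
        assert p_co == pytest.approx(1 - np.exp(-k_co * dt), rel=0.20)

    def test_cross_check_against_hmmlearn(self, rng):
        """Independent-package cross-check: our forward log-likelihood
        matches hmmlearn's scoring of the same model and data."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        model = random_model(rng)
        eff = rng.uniform(0.2, 1.0, size=200)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.means.reshape(-1, 1)
        ref.covars_ = (model.sds ** 2).reshape(-1, 1)
        expected = ref.score(eff.reshape(-1, 1))
        assert log_likelihood(model, fret_trace(eff)) == \
            pytest.approx(expected, abs=1e-8)


class TestDwells:
    def test_worked_example(self):
        """[mid,mid,high,high,high,mid] at 75 ms gives one uncensored high
        dwell of 0.225 s."""
        path = np.array([MID, MID, HIGH, HIGH, HIGH, MID])
        dwells = extract_dwells(path, 0.075, min_dwell_frames=2)
        unc = [d for d in dwells if not d.censored]
        assert len(unc) == 1
        assert unc[0].state == HIGH
        assert unc[0].duration == pytest.approx(0.225)

    def test_constant_path_no_uncensored(self):
        dwells = extract_dwells(np.zeros(50, int), 0.075)
        assert all(d.censored for d in dwells)

    def test_short_run_merge_reduces_count(self):
        path = np.array([MID] * 5 + [HIGH] + [MID] * 5)
        before = extract_dwells(path, 0.075, min_dwell_frames=1)
        after = extract_dwells(path, 0.075, min_dwell_frames=2)
        assert len(before) - len(after) == 2
        assert len(after) == 1  # all-mid after merge

    def test_merge_shortest_first(self):
        path = np.array([MID] * 4 + [HIGH] * 1 + [MID] * 1 + [HIGH] * 4)
        merged = merge_short_runs(path, 2)
        # both 1-frame runs dissolve; result is two clean runs
        runs = hm._runs(merged)
        assert len(runs) == 2

    def test_dwell_means_match_exponential_rates(self):
        """Simulated k(open→closed)=0.1, k(closed→open)=1.0: mean high
        dwell ≈ 1 s, mean mid dwell ≈ 10 s."""
        scheme = KineticScheme(base_rates={("open", "closed"): 0.1,
                                           ("closed", "open"): 1.0},
                               heterogeneity_sigma=0.0,
                               archetype_weights=(0, 0, 1))
        photo = PhotophysicsConfig(donor_bleach_rate=0.0,
                                   acceptor_bleach_rate=0.0)
        sc = ScenarioConfig(duration=300.0)
        ens = simulate_ensemble(scheme, StateModel.default(), photo, sc,
                                n=25, seed=23)
        fret = preprocess_ensemble(ens, photo)
        fits = fit_hmm(fret, shared_emissions=True)
        rows = dwell_summary(fret, fits)
        high = [r.mean_dwell_high for r in rows if r.mean_dwell_high]
        mid = [r.mean_dwell_mid for r in rows if r.mean_dwell_mid]
        assert np.mean(high) == pytest.approx(1.0, rel=0.25)
        assert np.mean(mid) == pytest.approx(10.0, rel=0.25)

    def test_heterogeneity_spreads_dwells_two_decades(self):
        """With log-normal sigma = ln(10), per-molecule mean dwell times
        (both states, as plotted on the log-scale scatter) span at least
        two orders of magnitude across the ensemble."""
        scheme = KineticScheme.default(heterogeneity_sigma=np.log(10),
                                       archetype_weights=(0, 0, 1))
        photo = PhotophysicsConfig(donor_bleach_rate=0.0,
                                   acceptor_bleach_rate=0.0)
        sc = ScenarioConfig(duration=120.0)
        ens = simulate_ensemble(scheme, StateModel.default(), photo, sc,
                                n=60, seed=24)
        fret = preprocess_ensemble(ens, photo)
        fits = fit_hmm(fret, shared_emissions=True)
        rows = dwell_summary(fret, fits)
        dwells = np.array([d for r in rows
                           for d in (r.mean_dwell_mid, r.mean_dwell_high)
                           if d])
        assert len(dwells) > 40
        assert dwells.max() / dwells.min() >= 100.0

    def test_symmetric_rates_give_half_occupancy(self):
        scheme = KineticScheme(base_rates={("open", "closed"): 0.5,
                                           ("closed", "open"): 0.5},
                               heterogeneity_sigma=0.0,
                               archetype_weights=(0, 0, 1))
        photo = PhotophysicsConfig(donor_bleach_rate=0.0,
                                   acceptor_bleach_rate=0.0)
        sc = ScenarioConfig(duration=120.0)
        ens = simulate_ensemble(scheme, StateModel.default(), photo, sc,
                                n=40, seed=25)
        fret = preprocess_ensemble(ens, photo)
        fits = fit_hmm(fret, shared_emissions=True)
        rows = dwell_summary(fret, fits)
        occ = np.mean([r.occupancy_high for r in rows])
        assert occ == pytest.approx(0.5, abs=0.05)
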