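"""Synthetic two-color TIRF trace generator for riboswitch folding.

The conformational model follows the SAM/SAH translational riboswitch: an
*open* stem-loop conformation (mid FRET, Shine–Dalgarno site exposed), a
*closed* H-type pseudoknot (high FRET), the ligand-stabilized closed state
(FRET-indistinguishable from closed), the RNA:DNA *heteroduplex* prior to
helicase release (low FRET), and the ribosome-mimic *oligo-bound* state
(low FRET, slightly lower for the longer 15-nt mimic).

Conformational dynamics are an exact continuous-time Markov chain
(Gillespie simulation).  Molecule-to-molecule "static heterogeneity" is
modeled with archetypes — molecules locked in the mid or high state plus a
dynamic archetype whose folding/unfolding rates carry a shared per-molecule
log-normal factor spanning orders of magnitude.  Rendering integrates the
state path over camera frames (occupancy-weighted motion blur), applies
donor→acceptor leakage, acceptor direct excitation, backgrounds, Gaussian
read noise, photobleaching of either dye, and a transient PIFE intensity
spike as the helicase approaches the donor dye in the vectorial assay.

A phenomenological generator (state weights set directly by a binding
isotherm) complements the mechanistic one for equilibrium titrations,
because equilibrium high-FRET fractions — not microscopic ligand on/off
rates — are what the titration analysis consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace_io import IntensityTrace, TraceEnsemble

STATE_NAMES = ("heteroduplex", "open", "closed", "closed_liganded", "oligo_bound")
ARCHETYPES = ("static_mid", "static_high", "dynamic")

# Ligand-free prefolded population weights (static_mid, static_high, dynamic)
# and the 1 mM SAM weights: constant-high grows 0.16 -> 0.43 at the expense
# of the dynamic pool while constant-mid stays put.
LIGAND_FREE_WEIGHTS = (0.29, 0.16, 0.55)
SAM_1MM_WEIGHTS = (0.29, 0.43, 0.28)


class ConfigError(ValueError):
    """Raised for invalid kinetic/scenario configuration."""


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class StateEmission:
    fret_mean: float
    fret_sd: float = 0.02
    intensity_scale: float = 1.0
    absorbing: bool = False


@dataclass
class StateModel:
    """FRET emission parameters per conformational state."""

    states: dict[str, StateEmission]

    def __post_init__(self):
        for name, s in self.states.items():
            if name not in STATE_NAMES:
                raise ConfigError(f"unknown state {name!r}")
            if not (0.0 <= s.fret_mean <= 1.0):
                raise ConfigError(f"{name}: fret_mean outside [0, 1]")
            if s.fret_sd <= 0 or s.intensity_scale <= 0:
                raise ConfigError(f"{name}: fret_sd and intensity_scale must be > 0")
        if "closed" in self.states and "closed_liganded" in self.states:
            if self.states["closed"].fret_mean != self.states["closed_liganded"].fret_mean:
                raise ConfigError(
                    "closed and closed_liganded must share fret_mean "
                    "(indistinguishable by FRET)"
                )

    @classmethod
    def default(cls, oligo_length: int = 9) -> "StateModel":
        """Default palette: open 0.40, closed 0.84, heteroduplex 0.20,
        oligo-bound 0.22 (9-nt) or 0.18 (15-nt)."""
        oligo_mean = 0.22 if oligo_length <= 9 else 0.18
        return cls({
            "heteroduplex": StateEmission(0.20),
            "open": StateEmission(0.40),
            "closed": StateEmission(0.84),
            "closed_liganded": StateEmission(0.84),
            "oligo_bound": StateEmission(oligo_mean, absorbing=True),
        })

    def mean(self, state: str) -> float:
        return self.states[state].fret_mean

    def sd(self, state: str) -> float:
        return self.states[state].fret_sd

    def scale(self, state: str) -> float:
        return self.states[state].intensity_scale


@dataclass
class KineticScheme:
    """First- and second-order rates of the conformational CTMC.

    ``base_rates`` holds first-order rates per ordered state pair (s⁻¹).
    Ligand binding (closed → closed_liganded by default) enters as
    ``ligand_kon`` (μM⁻¹s⁻¹) × concentration (μM); oligo binding
    (open → oligo_bound) as ``oligo_kon`` (nM⁻¹s⁻¹) × concentration (nM).
    ``heterogeneity_sigma`` is the log-normal sigma (natural log) of the
    shared per-molecule factor applied to folding/unfolding rates of
    dynamic molecules.
    """

    base_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    ligand_kon: float = 0.01     # μM⁻¹ s⁻¹
    ligand_koff: float = 0.1     # s⁻¹; 0 makes closed_liganded absorbing
    ligand_binds_from: str = "closed"
    oligo_kon: float = 2e-5      # nM⁻¹ s⁻¹ (slow: site exposure is gating)
    heterogeneity_sigma: float = 1.15
    archetype_weights: tuple[float, float, float] = LIGAND_FREE_WEIGHTS

    def __post_init__(self):
        for (a, b), r in self.base_rates.items():
            if a not in STATE_NAMES or b not in STATE_NAMES:
                raise ConfigError(f"unknown state in rate ({a}, {b})")
            if r < 0:
                raise ConfigError(f"negative rate for ({a}, {b})")
        if self.ligand_kon < 0 or self.ligand_koff < 0 or self.oligo_kon < 0:
            raise ConfigError("rate constants must be non-negative")
        if self.heterogeneity_sigma < 0:
            raise ConfigError("heterogeneity_sigma must be >= 0")
        w = np.asarray(self.archetype_weights, dtype=float)
        if w.min() < 0 or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("archetype_weights must be non-negative and sum to 1")

    @classmethod
    def default(cls, **kwargs) -> "KineticScheme":
        """Default dynamic-molecule rates: open dwell 3 s, closed dwell 1 s
        (the open conformation is longer-lived)."""
        base = {("open", "closed"): 1.0 / 3.0, ("closed", "open"): 1.0}
        base.update(kwargs.pop("extra_rates", {}))
        return cls(base_rates=base, **kwargs)


@dataclass
class PhotophysicsConfig:
    total_intensity: float = 500.0     # signal counts/frame at scale 1
    noise_sd: float = 30.0             # additive Gaussian sd per channel
    leakage_beta: float = 0.10         # donor signal fraction seen in acceptor
    direct_excitation_delta: float = 5.0   # constant acceptor counts/frame
    donor_bleach_rate: float = 0.002   # s⁻¹
    acceptor_bleach_rate: float = 0.002
    background_donor: float = 50.0
    background_acceptor: float = 40.0
    pife_amplitude: float = 1.5        # total-intensity multiplier during spike
    pife_duration: float = 0.3         # seconds

    def __post_init__(self):
        if self.total_intensity <= 0:
            raise ConfigError("total_intensity must be > 0")
        if not (0.0 <= self.leakage_beta < 1.0):
            raise ConfigError("leakage_beta must lie in [0, 1)")
        for r in (self.donor_bleach_rate, self.acceptor_bleach_rate):
            if r < 0:
                raise ConfigError("bleach rates must be >= 0")


@dataclass
class ScenarioConfig:
    mode: str = "prefolded"            # prefolded | flow_in | vectorial | competition
    duration: float = 60.0             # seconds
    frame_interval: float = 0.075      # 20 frames per 1.5 s
    short_movie_frames: int = 20
    ligand_concentration: float = 0.0  # μM
    oligo_length: int | None = None    # nt
    oligo_concentration: float = 0.0   # nM
    duplex_length: int = 66            # nt (48-nt riboswitch + 18-nt anchor)
    unwind_speed: float = 60.0         # nt/s, transcription-like
    helicase_init_rate: float = 0.5    # s⁻¹ exponential initiation wait
    event_time: float | None = None    # injection time; flow-in default 12 s
    lock_probability: float | None = None   # flow_in: P(absorbing high post-event)
    commit_probability: float | None = None  # vectorial: P(direct closed at release)
    oligo_reversible: bool = False     # 15-nt option: slow closed_liganded escape
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("prefolded", "flow_in", "vectorial", "competition"):
            raise ConfigError(f"unknown scenario mode {self.mode!r}")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ConfigError("duration and frame_interval must be > 0")
        if self.unwind_speed <= 0:
            raise ConfigError("unwind_speed must be > 0")
        if self.ligand_concentration < 0 or self.oligo_concentration < 0:
            raise ConfigError("concentrations must be >= 0")
        if self.mode == "flow_in" and self.event_time is None:
            self.event_time = 12.0
        if self.event_time is not None and not (0 <= self.event_time < self.duration):
            raise ConfigError("event_time must fall inside the movie")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


# ---------------------------------------------------------------------------
# molecule draws and exact CTMC simulation


@dataclass
class MoleculeParams:
    archetype: str
    rate_factor: float
    rates: dict[tuple[str, str], float]


def draw_molecule(scheme: KineticScheme, rng: np.random.Generator) -> MoleculeParams:
    """Sample a molecule's archetype and realized rates.

    Dynamic molecules get folding/unfolding rates multiplied by one shared
    log-normal factor (median 1, sigma = ``heterogeneity_sigma``); static
    archetypes are realized as zero-rate edges out of their home state.
    """
    idx = rng.choice(3, p=np.asarray(scheme.archetype_weights, dtype=float))
    archetype = ARCHETYPES[idx]
    rates = dict(scheme.base_rates)
    factor = 1.0
    if archetype == "dynamic":
        if scheme.heterogeneity_sigma > 0:
            factor = float(np.exp(rng.normal(0.0, scheme.heterogeneity_sigma)))
        for edge in (("open", "closed"), ("closed", "open")):
            if edge in rates:
                rates[edge] = rates[edge] * factor
    elif archetype == "static_mid":
        rates[("open", "closed")] = 0.0
    elif archetype == "static_high":
        rates[("closed", "open")] = 0.0
    return MoleculeParams(archetype, factor, rates)


def simulate_state_path(rates: dict[tuple[str, str], float], initial_state: str,
                        t_max: float, rng: np.random.Generator,
                        absorbing: Sequence[str] = ()) -> list[tuple[str, float]]:
    """Exact Gillespie realization of the CTMC on [0, t_max].

    Returns the jump sequence as (state, entry_time) pairs; the first entry
    is (initial_state, 0.0).  States listed in ``absorbing`` (or with zero
    total exit rate) terminate the jump process.
    """
    if t_max <= 0:
        raise ConfigError("t_max must be > 0")
    if initial_state not in STATE_NAMES:
        raise ConfigError(f"unknown initial state {initial_state!r}")
    for (a, b), r in rates.items():
        if r < 0:
            raise ConfigError(f"negative rate for ({a}, {b})")
    out: dict[str, list[tuple[str, float]]] = {}
    for (a, b), r in rates.items():
        if r > 0:
            out.setdefault(a, []).append((b, r))
    path = [(initial_state, 0.0)]
    state, t = initial_state, 0.0
    while True:
        if state in absorbing or state not in out:
            break
        targets = out[state]
        total = sum(r for _, r in targets)
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        probs = np.array([r for _, r in targets]) / total
        state = targets[rng.choice(len(targets), p=probs)][0]
        path.append((state, t))
    return path


def stationary_occupancy(rates: dict[tuple[str, str], float],
                         states: Sequence[str] = ("open", "closed")) -> dict[str, float]:
    """Stationary distribution of the CTMC restricted to ``states``.

    For the two-state folding chain this is detailed balance:
    p(closed) = k_oc / (k_oc + k_co).  Zero-rate edges give point masses.
    """
    states = list(states)
    n = len(states)
    Q = np.zeros((n, n))
    for i, a in enumerate(states):
        for j, b in enumerate(states):
            if i != j:
                Q[i, j] = rates.get((a, b), 0.0)
        Q[i, i] = -Q[i].sum()
    # solve pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return dict(zip(states, pi))


# ---------------------------------------------------------------------------
# rendering


def _frame_occupancy(path: list[tuple[str, float]], n_frames: int,
                     dt: float, values: dict[str, float],
                     t_end: float | None = None) -> np.ndarray:
    """Occupancy-weighted mean of a per-state value over each frame.

    The path is piecewise constant; the cumulative time-integral of the
    value is piecewise linear, so frame means come from interpolating the
    cumulative at frame edges (exact motion blur).
    """
    t_end = n_frames * dt if t_end is None else t_end
    knots = [t for _, t in path] + [max(t_end, n_frames * dt) + dt]
    vals = [values[s] for s, _ in path]
    knots_arr = np.asarray(knots)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(knots_arr) * np.asarray(vals))])
    edges = np.arange(n_frames + 1) * dt
    cum_at_edges = np.interp(edges, knots_arr, cum)
    return np.diff(cum_at_edges) / dt


def render_trace(path: list[tuple[str, float]], state_model: StateModel,
                 photo: PhotophysicsConfig, scenario: ScenarioConfig,
                 rng: np.random.Generator, molecule_id: str = "mol_0000",
                 pife_window: tuple[float, float] | None = None,
                 truth: dict | None = None,
                 event_frame: int | None = None) -> IntensityTrace:
    """Render a state path into a noisy two-channel intensity trace.

    Per frame the occupancy-weighted state FRET ``e`` and intensity scale
    are computed from the jump path; the background-free signal channels
    are donor = I(1-e), acceptor = I·e with I = total_intensity × scale.
    Crosstalk (donor leakage into the acceptor channel plus acceptor direct
    excitation), backgrounds and Gaussian noise are then applied.  After an
    acceptor bleach all signal appears in the donor channel; after a donor
    bleach both channels fall to background.
    """
    n = scenario.n_frames
    dt = scenario.frame_interval
    if path[-1][1] > n * dt:
        raise ConfigError("state path extends beyond the movie")
    means = {s: e.fret_mean for s, e in state_model.states.items()}
    scales = {s: e.intensity_scale for s, e in state_model.states.items()}
    e_bar = _frame_occupancy(path, n, dt, means)
    scale_bar = _frame_occupancy(path, n, dt, scales)
    # conformational spread of the emission, blurred like the mean
    sds = {s: e.fret_sd for s, e in state_model.states.items()}
    sd_bar = _frame_occupancy(path, n, dt, sds)
    e_frame = e_bar + rng.normal(0.0, 1.0, size=n) * sd_bar
    e_frame = np.clip(e_frame, 0.0, 1.0)

    if pife_window is not None:
        lo, hi = pife_window
        spike = {"on": photo.pife_amplitude, "off": 1.0}
        spike_path = [("off", 0.0)]
        if hi > lo and lo < n * dt:
            spike_path = [("off", 0.0), ("on", max(lo, 0.0)), ("off", min(hi, n * dt))]
            spike_path = [p for i, p in enumerate(spike_path)
                          if i == 0 or p[1] > spike_path[i - 1][1]]
        scale_bar = scale_bar * _frame_occupancy(spike_path, n, dt, spike)

    intensity = photo.total_intensity * scale_bar
    donor_sig = intensity * (1.0 - e_frame)
    acceptor_sig = intensity * e_frame

    # photobleaching: exponential times, frame containing the event onward
    t_d = rng.exponential(1.0 / photo.donor_bleach_rate) \
        if photo.donor_bleach_rate > 0 else np.inf
    t_a = rng.exponential(1.0 / photo.acceptor_bleach_rate) \
        if photo.acceptor_bleach_rate > 0 else np.inf
    frame_idx = np.arange(n)
    a_bleached = frame_idx >= int(t_a / dt) if np.isfinite(t_a) else np.zeros(n, bool)
    d_bleached = frame_idx >= int(t_d / dt) if np.isfinite(t_d) else np.zeros(n, bool)
    # acceptor bleach first: its signal transfers to the donor channel
    donor_sig = np.where(a_bleached & ~d_bleached, intensity, donor_sig)
    acceptor_sig = np.where(a_bleached & ~d_bleached, 0.0, acceptor_sig)
    donor_sig = np.where(d_bleached, 0.0, donor_sig)
    acceptor_sig = np.where(d_bleached, 0.0, acceptor_sig)
    direct = np.where(a_bleached | d_bleached, 0.0, photo.direct_excitation_delta)

    donor_obs = donor_sig + photo.background_donor
    acceptor_obs = (acceptor_sig + photo.leakage_beta * donor_sig + direct
                    + photo.background_acceptor)
    if photo.noise_sd > 0:
        donor_obs = donor_obs + rng.normal(0.0, photo.noise_sd, size=n)
        acceptor_obs = acceptor_obs + rng.normal(0.0, photo.noise_sd, size=n)

    truth = dict(truth or {})
    truth.setdefault("path", list(path))
    bleach_type = None
    bleach_time = None
    if min(t_d, t_a) < n * dt:
        bleach_type = "donor" if t_d <= t_a else "acceptor"
        bleach_time = min(t_d, t_a)
    truth["bleach"] = {
        "donor_time": None if not np.isfinite(t_d) else float(t_d),
        "acceptor_time": None if not np.isfinite(t_a) else float(t_a),
        "type": bleach_type,
        "frame": None if bleach_time is None else int(bleach_time / dt),
    }
    return IntensityTrace(molecule_id, donor_obs, acceptor_obs, dt,
                          event_frame=event_frame, truth=truth)


# ---------------------------------------------------------------------------
# scenario ensembles


def _molecule_rng(seed: int, index: int) -> np.random.Generator:
    # per-molecule substream keyed by (seed, index): reproducible and
    # independent of generation order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _initial_state(params: MoleculeParams, rng: np.random.Generator) -> str:
    if params.archetype == "static_mid":
        return "open"
    if params.archetype == "static_high":
        return "closed"
    occ = stationary_occupancy(params.rates)
    return "closed" if rng.random() < occ["closed"] else "open"


def _condition(scenario: ScenarioConfig, scheme: KineticScheme, n: int,
               seed: int) -> dict:
    return {
        "mode": scenario.mode,
        "ligand_concentration_uM": scenario.ligand_concentration,
        "oligo_length_nt": scenario.oligo_length,
        "oligo_concentration_nM": scenario.oligo_concentration,
        "n_molecules": n,
        "seed": seed,
        "archetype_weights": list(scheme.archetype_weights),
    }


def simulate_ensemble(scheme: KineticScheme, state_model: StateModel,
                      photo: PhotophysicsConfig, scenario: ScenarioConfig,
                      n: int, seed: int | None = None) -> TraceEnsemble:
    """Simulate n molecules under a prefolded or flow-in scenario.

    Prefolded molecules start in their archetype's stationary state.  In
    flow-in mode the ligand concentration switches from 0 to the scenario
    value at ``event_time``; with ``lock_probability`` set, a Bernoulli
    draw decides per molecule whether the post-event chain locks (the
    closed → open rate is zeroed, making the high state absorbing on next
    entry) — the phenomenological counterpart of strong ligand binding.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if scenario.mode not in ("prefolded", "flow_in"):
        raise ConfigError(f"simulate_ensemble handles prefolded/flow_in, "
                          f"not {scenario.mode!r}")
    seed = scenario.seed if seed is None else seed
    dt = scenario.frame_interval
    t_total = scenario.n_frames * dt
    traces = []
    for i in range(n):
        rng = _molecule_rng(seed, i)
        params = draw_molecule(scheme, rng)
        rates = dict(params.rates)
        if scenario.mode == "prefolded" and scenario.ligand_concentration > 0:
            rates[(scheme.ligand_binds_from, "closed_liganded")] = \
                scheme.ligand_kon * scenario.ligand_concentration
            if scheme.ligand_koff > 0:
                rates[("closed_liganded", scheme.ligand_binds_from)] = scheme.ligand_koff
        init = _initial_state(params, rng)
        truth = {"archetype": params.archetype, "rate_factor": params.rate_factor,
                 "rates": {f"{a}->{b}": r for (a, b), r in rates.items()}}
        event_frame = None
        if scenario.mode == "flow_in":
            t_ev = float(scenario.event_time)
            event_frame = int(round(t_ev / dt))
            pre = simulate_state_path(rates, init, t_ev, rng)
            state_at_event = pre[-1][0]
            post_rates = dict(rates)
            if scenario.lock_probability is not None:
                locker = bool(rng.random() < scenario.lock_probability)
                truth["locker"] = locker
                if locker:
                    post_rates[("closed", "open")] = 0.0
            elif scenario.ligand_concentration > 0:
                post_rates[(scheme.ligand_binds_from, "closed_liganded")] = \
                    scheme.ligand_kon * scenario.ligand_concentration
                if scheme.ligand_koff > 0:
                    post_rates[("closed_liganded", scheme.ligand_binds_from)] = \
                        scheme.ligand_koff
            post = simulate_state_path(post_rates, state_at_event,
                                       t_total - t_ev, rng)
            path = pre + [(s, t + t_ev) for s, t in post[1:]]
        else:
            path = simulate_state_path(rates, init, t_total, rng)
        traces.append(render_trace(path, state_model, photo, scenario, rng,
                                   molecule_id=f"mol_{i:04d}", truth=truth,
                                   event_frame=event_frame))
    return TraceEnsemble(traces, condition=_condition(scenario, scheme, n, seed))


def simulate_vectorial(scheme: KineticScheme, state_model: StateModel,
                       photo: PhotophysicsConfig, scenario: ScenarioConfig,
                       n: int, seed: int | None = None) -> TraceEnsemble:
    """Simulate helicase-driven vectorial (co-transcriptional mimic) folding.

    Each trace starts as the low-FRET heteroduplex.  Release occurs after
    an exponential helicase-initiation wait plus the deterministic unwinding
    time duplex_length / unwind_speed, preceded by a PIFE intensity spike.
    At release the molecule either commits directly to the liganded closed
    state (probability ``commit_probability``, the type-i channel) or enters
    the open conformation and evolves under the CTMC.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if scenario.mode not in ("vectorial", "competition"):
        raise ConfigError("scenario.mode must be vectorial (or competition)")
    if scenario.duplex_length is None:
        raise ConfigError("vectorial mode requires duplex_length")
    seed = scenario.seed if seed is None else seed
    dt = scenario.frame_interval
    t_total = scenario.n_frames * dt
    unwind_time = scenario.duplex_length / scenario.unwind_speed
    t0 = scenario.event_time or 0.0
    traces = []
    for i in range(n):
        rng = _molecule_rng(seed, i)
        params = draw_molecule(scheme, rng)
        rates = dict(params.rates)
        absorbing: list[str] = []
        if scenario.ligand_concentration > 0 and scenario.commit_probability is None:
            rates[(scheme.ligand_binds_from, "closed_liganded")] = \
                scheme.ligand_kon * scenario.ligand_concentration
            if scheme.ligand_koff > 0:
                rates[("closed_liganded", scheme.ligand_binds_from)] = scheme.ligand_koff
            else:
                absorbing.append("closed_liganded")
        if scenario.mode == "competition" and scenario.oligo_concentration > 0:
            rates[("open", "oligo_bound")] = \
                scheme.oligo_kon * scenario.oligo_concentration
            absorbing.append("oligo_bound")
            if not scenario.oligo_reversible:
                absorbing.append("closed_liganded")
        t_release = t0 + rng.exponential(1.0 / scenario.helicase_init_rate) \
            + unwind_time
        committed = False
        if scenario.commit_probability is not None:
            committed = bool(rng.random() < scenario.commit_probability)
        truth = {"archetype": params.archetype, "rate_factor": params.rate_factor,
                 "release_time": float(t_release), "committed": committed}
        if t_release >= t_total:
            path = [("heteroduplex", 0.0)]
            pife = None
        else:
            if committed:
                post = [("closed_liganded", 0.0)]
            else:
                post = simulate_state_path(rates, "open", t_total - t_release,
                                           rng, absorbing=tuple(absorbing))
            path = [("heteroduplex", 0.0)] + [(s, t + t_release) for s, t in post]
            pife = (t_release - photo.pife_duration, t_release)
        if scenario.mode == "competition":
            final = path[-1][0]
            truth["on_off"] = ("ON" if final == "oligo_bound" else
                               "OFF" if final == "closed_liganded" else "undecided")
        traces.append(render_trace(path, state_model, photo, scenario, rng,
                                   molecule_id=f"mol_{i:04d}", pife_window=pife,
                                   truth=truth,
                                   event_frame=int(round(t0 / dt)) if t0 else None))
    return TraceEnsemble(traces, condition=_condition(scenario, scheme, n, seed))


def simulate_competition(scheme: KineticScheme, state_model: StateModel,
                         photo: PhotophysicsConfig, scenario: ScenarioConfig,
                         n: int, seed: int | None = None,
                         prefolded_start: bool = True) -> TraceEnsemble:
    """Simulate the ribosome-mimic competition assay.

    The oligo-bound state is absorbing and reachable only from the open
    conformation at pseudo-first-order rate oligo_kon × [oligo]; with
    ligand present the liganded closed state is absorbing for the 9-nt
    mimic (k_off ≈ 0) and slowly reversible for the 15-nt option
    (``oligo_reversible``).  Truth labels record the translation readout:
    ON = oligo_bound (site accessible), OFF = closed_liganded.
    """
    if scenario.oligo_length is None or scenario.oligo_concentration <= 0:
        raise ConfigError("competition mode requires an oligo")
    if scenario.mode != "competition":
        raise ConfigError("scenario.mode must be competition")
    if not prefolded_start:
        return simulate_vectorial(scheme, state_model, photo, scenario, n, seed)
    seed = scenario.seed if seed is None else seed
    dt = scenario.frame_interval
    t_total = scenario.n_frames * dt
    traces = []
    for i in range(n):
        rng = _molecule_rng(seed, i)
        params = draw_molecule(scheme, rng)
        rates = dict(params.rates)
        absorbing = ["oligo_bound"]
        rates[("open", "oligo_bound")] = scheme.oligo_kon * scenario.oligo_concentration
        if scenario.ligand_concentration > 0:
            rates[(scheme.ligand_binds_from, "closed_liganded")] = \
                scheme.ligand_kon * scenario.ligand_concentration
            if scenario.oligo_reversible and scheme.ligand_koff > 0:
                rates[("closed_liganded", scheme.ligand_binds_from)] = scheme.ligand_koff
            else:
                absorbing.append("closed_liganded")
        init = _initial_state(params, rng)
        path = simulate_state_path(rates, init, t_total, rng,
                                   absorbing=tuple(absorbing))
        final = path[-1][0]
        truth = {"archetype": params.archetype, "rate_factor": params.rate_factor,
                 "on_off": ("ON" if final == "oligo_bound" else
                            "OFF" if final == "closed_liganded" else "undecided")}
        traces.append(render_trace(path, state_model, photo, scenario, rng,
                                   molecule_id=f"mol_{i:04d}", truth=truth))
    return TraceEnsemble(traces, condition=_condition(scenario, scheme, n, seed))


# ---------------------------------------------------------------------------
# phenomenological equilibrium generator


def bound_fraction_isotherm(c, Kd: float, f0: float, fmax: float):
    """Two-state binding isotherm f(c) = f0 + (fmax - f0) * c / (Kd + c).

    Serves both as the generator of high-FRET weights at each ligand
    concentration and as the model function for titration fitting.
    """
    if Kd <= 0:
        raise ConfigError("Kd must be > 0")
    c = np.asarray(c, dtype=float)
    out = f0 + (fmax - f0) * c / (Kd + c)
    return float(out) if out.ndim == 0 else out


def simulate_static_population(high_weight: float, n: int, seed: int,
                               state_model: StateModel | None = None,
                               photo: PhotophysicsConfig | None = None,
                               scenario: ScenarioConfig | None = None) -> TraceEnsemble:
    """Equilibrium short-movie generator: each molecule is statically high
    with probability ``high_weight``, else statically mid.

    This is the phenomenological mode used for titrations, where the
    short 1.5-s movies report state weights, not kinetics.
    """
    if not (0.0 <= high_weight <= 1.0):
        raise ConfigError("high_weight must lie in [0, 1]")
    state_model = state_model or StateModel.default()
    photo = photo or PhotophysicsConfig()
    scenario = scenario or ScenarioConfig(
        mode="prefolded", duration=1.5, short_movie_frames=20)
    scheme = KineticScheme.default(
        archetype_weights=(1.0 - high_weight, high_weight, 0.0))
    ens = simulate_ensemble(scheme, state_model, photo, scenario, n, seed)
    ens.condition["high_weight"] = high_weight
    return ens


def simulate_titration(concentrations: Sequence[float], Kd: float,
                       f0: float, fmax: float, n_per_point: int, seed: int,
                       **kwargs) -> dict[float, TraceEnsemble]:
    """Phenomenological titration: per concentration, the static high-state
    weight follows the binding isotherm with the given ground truth."""
    out = {}
    for k, c in enumerate(concentrations):
        w = bound_fraction_isotherm(c, Kd, f0, fmax)
        sub_seed = int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0]
                       % (2**31 - 1))
        ens = simulate_static_population(w, n_per_point, sub_seed, **kwargs)
        ens.condition["ligand_concentration_uM"] = float(c)
        ens.condition["true_high_weight"] = float(w)
        out[float(c)] = ens
    return out
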