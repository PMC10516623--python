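"""End-to-end study recipes: simulate an assay at its reported operating
point, run the analysis pipeline, and return the headline quantity.

Each function is a self-contained in-silico version of one experiment on
the SAM/SAH riboswitch — the ligand-free landscape, the SAM titrations of
wild type and pseudoknot mutants, ligand flow-in locking, vectorial
(co-transcriptional mimic) folding, and the ribosome-mimic competition —
with ground truth set at the reported values so that pipeline recovery can
be checked quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classify as cl
from . import hmm as hm
from . import population as pop
from .preprocess import preprocess_ensemble
from .simulate import (
    LIGAND_FREE_WEIGHTS,
    SAM_1MM_WEIGHTS,
    KineticScheme,
    PhotophysicsConfig,
    ScenarioConfig,
    StateModel,
    bound_fraction_isotherm,
    simulate_competition,
    simulate_ensemble,
    simulate_static_population,
    simulate_titration,
    simulate_vectorial,
)

# Reported operating points used as simulation ground truth -----------------

KD_WILD_TYPE_UM = 10.0        # prefolded SAM titration, wild type
KD_T_G16P_UM = 607.0          # base-triple mutant
KD_VECTORIAL_UM = 108.0       # apparent Kd during vectorial folding
LOCK_PROBABILITY = 37 / 86    # ~43% of dynamic molecules lock after 1 mM SAM
MG_FREE_HIGH_WEIGHT = 0.35    # high-FRET weight without Mg2+ (> 30% persists)
TITRATION_F0 = 0.30           # ligand-free high-FRET fraction (frame-weighted)
TITRATION_FMAX = 0.85         # saturating high-FRET fraction

WT_CONCENTRATIONS_UM = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
T_G16P_CONCENTRATIONS_UM = (0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)
VECTORIAL_CONCENTRATIONS_UM = (0.0, 10.0, 30.0, 100.0, 300.0, 1000.0)

MUTANT_KD_TABLE_UM = {
    "wild_type": 11.0,
    "P1x_C26Z": 42.0,
    "P1x_A14P": 61.0,
    "T_G16P": 607.0,
    "PK_C18A_G49U_C50U": 1000.0,   # lower bound: reported as > 1 mM
    "P1x_A14C_C26U": 593.0,
}


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0]
               % (2**31 - 1))


# ---------------------------------------------------------------------------
# ligand-free landscape


def emission_peak_recovery(seed: int = 1, n: int = 300) -> pop.MixtureFit:
    """Short-movie histogram of a ligand-free pre-folded ensemble,
    decomposed into two Gaussians (open/closed recovery)."""
    scheme = KineticScheme.default(archetype_weights=LIGAND_FREE_WEIGHTS)
    scenario = ScenarioConfig(mode="prefolded", duration=60.0)
    ens = simulate_ensemble(scheme, StateModel.default(), PhotophysicsConfig(),
                            scenario, n=n, seed=seed)
    fret = preprocess_ensemble(ens, PhotophysicsConfig())
    sample = pop.pool_efficiencies(fret, n_frames=20)
    return pop.fit_mixture(sample, K=2)


@dataclass
class PrefoldedClassification:
    fractions: dict[str, float]
    table: list[dict]
    dwells: list[hm.DwellSummary]
    n_classified: int


def prefolded_classification(weights=LIGAND_FREE_WEIGHTS, seed: int = 4,
                             n: int = 500, duration: float = 60.0
                             ) -> PrefoldedClassification:
    """Simulate, preprocess, HMM-fit and classify a pre-folded ensemble;
    returns behavioral fractions and the per-molecule dwell table."""
    scheme = KineticScheme.default(archetype_weights=tuple(weights))
    scenario = ScenarioConfig(mode="prefolded", duration=duration)
    photo = PhotophysicsConfig()
    ens = simulate_ensemble(scheme, StateModel.default(), photo, scenario,
                            n=n, seed=seed)
    fret = preprocess_ensemble(ens, photo)
    fits = hm.fit_hmm(fret, shared_emissions=True)
    by_id = {f.molecule_id: f for f in fits}
    classes = [cl.classify_prefolded(tr, by_id.get(tr.molecule_id))
               for tr in fret]
    table = cl.population_table(classes, labels=("static_mid", "static_high",
                                                 "dynamic"))
    fractions = {row["label"]: row["fraction"] for row in table
                 if row["label"] in ("static_mid", "static_high", "dynamic")}
    dynamic_ids = {c.molecule_id for c in classes if c.label == "dynamic"}
    dwells = hm.dwell_summary([t for t in fret if t.molecule_id in dynamic_ids],
                              fits)
    n_classified = sum(1 for c in classes
                      if c.label in ("static_mid", "static_high", "dynamic"))
    return PrefoldedClassification(fractions, table, dwells, n_classified)


# ---------------------------------------------------------------------------
# titrations


def titration_recovery(kd_true: float, concentrations, seed: int,
                       n_per_point: int = 2000, f0: float = TITRATION_F0,
                       fmax: float = TITRATION_FMAX,
                       n_bootstrap: int = 50) -> pop.TitrationResult:
    """Phenomenological SAM titration: high-state weights follow the
    isotherm at ``kd_true``; the pipeline (mixture fits + isotherm fit)
    must hand back the Kd."""
    photo = PhotophysicsConfig()
    ensembles = simulate_titration(concentrations, kd_true, f0, fmax,
                                   n_per_point, seed, photo=photo)
    samples = {}
    for c, ens in ensembles.items():
        fret = preprocess_ensemble(ens, photo)
        samples[c] = pop.pool_efficiencies(fret, n_frames=20)
    return pop.titrate(samples, K=2, n_bootstrap=n_bootstrap, seed=seed)


# ---------------------------------------------------------------------------
# flow-in locking


@dataclass
class LockingResult:
    percent_locked: float
    n_locked: int
    n_applicable: int
    n_total: int


def flow_in_locking(seed: int = 6, n: int = 200,
                    p_lock: float = LOCK_PROBABILITY,
                    event_time: float = 20.0,
                    duration: float = 140.0) -> LockingResult:
    """Ligand flow-in on an all-dynamic ensemble: score the percentage of
    applicable (pre-event dynamic, observable post-event) molecules that
    lock into the closed conformation."""
    scheme = KineticScheme.default(archetype_weights=(0.0, 0.0, 1.0))
    scenario = ScenarioConfig(mode="flow_in", duration=duration,
                              event_time=event_time,
                              ligand_concentration=1000.0,
                              lock_probability=p_lock)
    photo = PhotophysicsConfig()
    ens = simulate_ensemble(scheme, StateModel.default(), photo, scenario,
                            n=n, seed=seed)
    fret = preprocess_ensemble(ens, photo)
    fits = hm.fit_hmm(fret, shared_emissions=True)
    by_id = {f.molecule_id: f for f in fits}
    calls = [cl.detect_locking(tr, by_id.get(tr.molecule_id), tr.event_frame)
             for tr in fret]
    n_locked = sum(c.label == "locked" for c in calls)
    n_applicable = sum(c.label in ("locked", "not_locked") for c in calls)
    pct = 100.0 * n_locked / n_applicable if n_applicable else float("nan")
    return LockingResult(pct, n_locked, n_applicable, len(calls))


# ---------------------------------------------------------------------------
# vectorial folding


@dataclass
class VectorialTitration:
    result: pop.TitrationResult
    type_fractions: dict[float, dict[str, float]]


def vectorial_titration(seed: int = 7, kd_true: float = KD_VECTORIAL_UM,
                        concentrations=VECTORIAL_CONCENTRATIONS_UM,
                        n_per_point: int = 400, f0: float = 0.05,
                        fmax: float = 0.85,
                        duration: float = 40.0) -> VectorialTitration:
    """Vectorial-folding titration: the probability of direct commitment to
    the closed state at release (type-i behavior) follows an isotherm at
    the apparent Kd; classify the four behaviors and fit the type-i
    fraction against concentration."""
    photo = PhotophysicsConfig()
    fracs, type_fracs = [], {}
    for k, c in enumerate(concentrations):
        p_commit = bound_fraction_isotherm(c, kd_true, f0, fmax)
        scenario = ScenarioConfig(mode="vectorial", duration=duration,
                                  ligand_concentration=c,
                                  commit_probability=p_commit,
                                  seed=_sub_seed(seed, k))
        scheme = KineticScheme.default()
        ens = simulate_vectorial(scheme, StateModel.default(), photo, scenario,
                                 n=n_per_point, seed=_sub_seed(seed, k))
        fret = preprocess_ensemble(ens, photo)
        classes = [cl.classify_vectorial(tr) for tr in fret]
        table = cl.population_table(
            classes, labels=("type_i", "type_ii", "type_iii", "type_iv"))
        tf = {row["label"]: row["fraction"] for row in table
              if row["label"].startswith("type")}
        type_fracs[float(c)] = tf
        n_typed = sum(1 for cc in classes if cc.label.startswith("type"))
        f_i = tf.get("type_i", 0.0)
        # per-point binomial standard error with a continuity floor
        se = float(np.sqrt((f_i * (1 - f_i) + 1.0 / max(n_typed, 2))
                           / max(n_typed, 2)))
        fracs.append((f_i, se))
    result = pop.fit_isotherm([float(c) for c in concentrations],
                              [f for f, _ in fracs], [s for _, s in fracs])
    return VectorialTitration(result, type_fracs)


# ---------------------------------------------------------------------------
# ribosome-mimic competition


def competition_mixture(seed: int = 8, n: int = 300, duration: float = 400.0,
                        oligo_length: int = 9,
                        oligo_concentration: float = 500.0) -> pop.MixtureFit:
    """Ligand-free competition with a saturating 9-nt ribosome mimic: a
    long movie lets open-state molecules absorb into the low-FRET
    oligo-bound state; a three-component mixture should place its lowest
    component at the oligo-bound efficiency."""
    scheme = KineticScheme.default()
    scenario = ScenarioConfig(mode="competition", duration=duration,
                              oligo_length=oligo_length,
                              oligo_concentration=oligo_concentration)
    photo = PhotophysicsConfig()
    ens = simulate_competition(scheme, StateModel.default(oligo_length), photo,
                               scenario, n=n, seed=seed)
    fret = preprocess_ensemble(ens, photo)
    sample = pop.pool_efficiencies(fret, n_frames=None)
    return pop.fit_mixture(sample, K=3,
                           init_means=np.array([0.22, 0.40, 0.84]))


def mg_free_high_fraction(seed: int = 9, n: int = 500,
                          high_weight: float = MG_FREE_HIGH_WEIGHT) -> float:
    """Short movies of the Mg2+-free equilibrium: percentage of the
    population in the high-FRET closed state from a two-Gaussian fit."""
    photo = PhotophysicsConfig()
    ens = simulate_static_population(high_weight, n, seed, photo=photo)
    fret = preprocess_ensemble(ens, photo)
    sample = pop.pool_efficiencies(fret, n_frames=20)
    fit = pop.fit_mixture(sample, K=2)
    frac, _ = pop.high_fret_fraction(fit, allow_degenerate=True)
    return 100.0 * frac
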