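# rsfret

Single-molecule FRET analysis of SAM/SAH riboswitch folding, paired with a
two-color trace simulator so every stage of the analysis can be exercised
and validated without raw microscope data.

## The scientific problem

The SAM/SAH riboswitch is a small translational riboswitch that sequesters
its Shine–Dalgarno (S–D) sequence inside an H-type pseudoknot when it binds
S-adenosylmethionine (or S-adenosylhomocysteine), switching translation
off.  In smFRET experiments a donor dye in the pseudoknot loop and an
acceptor on the tethering duplex report conformation through the FRET
efficiency E: the open stem-loop sits at E ≈ 0.4, the closed pseudoknot at
E ≈ 0.84, the pre-release RNA:DNA heteroduplex at E ≈ 0.2, and the
ribosome-mimic (anti-S–D oligo) bound state at E ≈ 0.22 (9-nt) or ≈ 0.18
(15-nt).

This package implements the complete trace-analysis chain for such
experiments:

* **trace_io** — the community binary ``.traces`` dialect and a lossless
  long-form CSV, with metadata sidecars;
* **simulate** — exact Gillespie simulation of the conformational CTMC
  with molecule archetypes (constant-mid, constant-high, dynamic),
  per-molecule log-normal rate heterogeneity, ligand- and oligo-binding,
  vectorial (helicase-driven) release with a PIFE intensity spike, camera
  frame integration (motion blur), crosstalk, noise and photobleaching;
* **preprocess** — background/leakage/direct-excitation correction,
  ``E = A'/(D'+A')``, intensity masking, and bleach truncation;
* **hmm** — a two-state Gaussian-emission hidden Markov model
  (Baum–Welch/Viterbi, missing-frame aware, optional ensemble-shared
  emissions) and per-molecule dwell-time summaries;
* **classify** — the three-type pre-folded taxonomy, the four-type
  vectorial taxonomy, and ligand-induced locking detection;
* **population** — pooled-histogram Gaussian-mixture decomposition, the
  two-state binding isotherm ``f(c) = f0 + (fmax − f0)·c/(Kd + c)``, and
  cluster-bootstrap titration fits;
* **pipeline / cli** — configured end-to-end runs (``rsfret run``,
  ``rsfret classify`` …) with deterministic, diffable outputs.

The numbered scripts under `analysis/` retrace the main riboswitch analyses
on synthetic data generated at the reported operating points and write
their tables under `results/`.

## Worked example

```python
from rsfret import (KineticScheme, PhotophysicsConfig, ScenarioConfig,
                    StateModel, simulate_ensemble, preprocess_ensemble,
                    fit_hmm, classify_prefolded, population_table)

scheme = KineticScheme.default(archetype_weights=(0.29, 0.16, 0.55))
photo = PhotophysicsConfig()
scenario = ScenarioConfig(mode="prefolded", duration=60.0)
ens = simulate_ensemble(scheme, StateModel.default(), photo, scenario,
                        n=200, seed=4)
fret = preprocess_ensemble(ens, photo)
fits = {f.molecule_id: f for f in fit_hmm(fret, shared_emissions=True)}
classes = [classify_prefolded(t, fits.get(t.molecule_id)) for t in fret]
for row in population_table(classes, labels=("static_mid", "static_high",
                                             "dynamic")):
    print(row["label"], row["count"], round(row["fraction"], 3))
```

prints (seed 4, n = 200; three traces bleach too early to classify and
are reported as a `rejected` row):

```
static_mid 51 0.259
static_high 39 0.198
dynamic 107 0.543
rejected 3 nan
```

i.e. the classifier recovers the generating archetype weights — a majority
of ligand-free molecules transition dynamically between the open and
closed conformations, with the rest split between molecules statically
trapped in either state.

Or from the shell:

```bash
rsfret classify analysis/configs/prefolded_demo.yaml -o scratch/demo --seed 4
rsfret report scratch/demo
```

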