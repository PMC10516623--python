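#!/usr/bin/env python
"""Ribosome-mimic accessibility: the oligo-bound low-FRET state, and the
Mg2+-free closed-state population.

Two short analyses.  First, a ligand-free competition with a saturating
9-nt oligonucleotide complementary to the Shine–Dalgarno site: open-state
molecules absorb into the stable oligo-bound duplex, and the pooled
histogram gains a low-FRET component whose fitted position should sit at
the 9-nt palette value (E ≈ 0.22).  Second, the Mg2+-free equilibrium,
where a two-Gaussian fit measures how much of the population still
reaches the closed conformation without divalent ions (reported: > 30%).

Writes: results/competition_mixture.json, results/mg_free.json
"""

import json
from pathlib import Path

from rsfret import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    fit = ex.competition_mixture(seed=8, n=300)
    print("Three-Gaussian decomposition of the 9-nt competition histogram:")
    for w, m in zip(fit.weights, fit.means):
        print(f"  mean E = {m:.3f}  weight = {w:.3f}")
    print(f"Oligo-bound (lowest) peak at E = {fit.means[0]:.3f} "
          "(palette value 0.22)")
    (OUT / "competition_mixture.json").write_text(json.dumps({
        "means": fit.means.tolist(), "weights": fit.weights.tolist(),
        "sds": fit.sds.tolist()}, indent=1))

    pct = ex.mg_free_high_fraction(seed=9, n=500)
    print(f"\nMg2+-free high-FRET population: {pct:.1f}% "
          "(configured weight 35%; reported persistence > 30%)")
    (OUT / "mg_free.json").write_text(json.dumps({
        "high_fret_percent": pct}, indent=1))


if __name__ == "__main__":
    main()
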