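#!/usr/bin/env python
"""Ligand flow-in: locking of dynamic molecules into the closed state.

Simulates an all-dynamic ensemble imaged through a 1 mM SAM injection at
20 s, with each molecule locking (the closed state becoming absorbing)
with the reported probability 37/86 ≈ 43%.  The detector then scores
locking blind — a pre-event dynamic molecule whose post-event path ends in
an uninterrupted ≥30-s high-FRET run — and the recovered percentage is
compared with the generating probability.

Writes: results/flow_in_locking.json
"""

import json
from pathlib import Path

from rsfret import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    r = ex.flow_in_locking(seed=6, n=200)
    print(f"Locking probability used by the generator: "
          f"{100 * ex.LOCK_PROBABILITY:.1f}%")
    print(f"Detected: {r.n_locked} locked of {r.n_applicable} applicable "
          f"molecules ({r.percent_locked:.1f}%); "
          f"{r.n_total - r.n_applicable} of {r.n_total} traces were not "
          f"scoreable (static pre-event or too little post-event observation)")
    (OUT / "flow_in_locking.json").write_text(json.dumps({
        "p_lock_true": ex.LOCK_PROBABILITY,
        "percent_locked": r.percent_locked,
        "n_locked": r.n_locked, "n_applicable": r.n_applicable,
        "n_total": r.n_total}, indent=1))


if __name__ == "__main__":
    main()
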