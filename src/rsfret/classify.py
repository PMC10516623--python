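"""Behavioral classification of riboswitch traces.

Pre-folded molecules fall into three behaviors over the observation
window: constant mid-FRET (open, possibly misfolded-trapped), constant
high-FRET (closed), and dynamic molecules transitioning between the two.
Vectorially released molecules fall into four: (i) direct, stable closed;
(ii) stable open; (iii) persistent open/closed fluctuation; (iv)
fluctuation followed by terminal locking in the closed state.  Ligand
flow-in experiments are scored for locking — a pre-event dynamic molecule
whose post-event path ends in a long uninterrupted high-FRET run.

Thresholds (two merged transitions to call "dynamic", a 30-s terminal run
to call "locked") are declared conventions; the state boundary derives
from the fitted emission means rather than a fixed value so mutants with a
shifted palette classify identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .hmm import HIGH, MID, HmmFit, merge_short_runs, _runs
from .preprocess import FretTrace

log = logging.getLogger(__name__)

PREFOLDED_LABELS = ("static_mid", "static_high", "dynamic", "rejected")
VECTORIAL_LABELS = ("type_i", "type_ii", "type_iii", "type_iv", "unresolved")


@dataclass
class ClassPolicy:
    min_transitions_dynamic: int = 2
    min_analysis_frames: int = 40
    lock_dwell_seconds: float = 30.0
    min_dwell_frames: int = 2
    # vectorial release detection
    release_threshold: float = 0.31      # low/mid boundary in E
    mid_high_boundary: float = 0.62      # fallback when no fitted means
    release_confirm_frames: int = 5
    post_release_skip_frames: int = 3    # blur/PIFE grace after release

    def __post_init__(self):
        if self.min_transitions_dynamic < 1 or self.min_analysis_frames < 1:
            raise ValueError("thresholds must be positive")
        if self.lock_dwell_seconds <= 0:
            raise ValueError("lock_dwell_seconds must be positive")


@dataclass
class TraceClass:
    molecule_id: str
    label: str
    n_transitions: int = 0
    reason: str = ""
    evidence: dict = field(default_factory=dict)


def _merged_path(fit: HmmFit, trace: FretTrace, policy: ClassPolicy,
                 frames: slice | None = None) -> np.ndarray:
    """Viterbi path restricted to the valid region (optionally within a
    frame window), with sub-threshold runs merged."""
    sel = np.flatnonzero(trace.valid_mask)
    if frames is not None:
        sel = sel[(sel >= (frames.start or 0))
                  & (sel < (frames.stop if frames.stop is not None
                            else len(trace)))]
    if sel.size == 0:
        return np.empty(0, dtype=int)
    region = fit.viterbi_path[sel[0]:sel[-1] + 1]
    return merge_short_runs(region, policy.min_dwell_frames)


def classify_prefolded(trace: FretTrace, fit: HmmFit | None,
                       policy: ClassPolicy | None = None,
                       frames: slice | None = None) -> TraceClass:
    """Three-way behavioral call for a pre-folded molecule.

    Dynamic requires at least ``min_transitions_dynamic`` transitions in
    the merged decoded path (one spurious transition never flips a static
    label); otherwise the majority state decides static_high vs
    static_mid.  Too few valid frames → rejected (a label, not an error).
    """
    policy = policy or ClassPolicy()
    if fit is None:
        return TraceClass(trace.molecule_id, "rejected", reason="no HMM fit")
    path = _merged_path(fit, trace, policy, frames)
    if len(path) < policy.min_analysis_frames:
        return TraceClass(trace.molecule_id, "rejected",
                          reason=f"only {len(path)} analyzable frames")
    n_trans = len(_runs(path)) - 1
    if n_trans >= policy.min_transitions_dynamic:
        label = "dynamic"
    else:
        label = "static_high" if np.mean(path == HIGH) >= 0.5 else "static_mid"
    return TraceClass(trace.molecule_id, label, n_transitions=n_trans,
                      evidence={"occupancy_high": float(np.mean(path == HIGH))})


def detect_locking(trace: FretTrace, fit: HmmFit | None, event_frame: int | None,
                   policy: ClassPolicy | None = None) -> TraceClass:
    """Score ligand-induced locking in a flow-in trace.

    Applicable only when the pre-event segment is dynamic and at least
    ``lock_dwell_seconds`` of pre-bleach observation follows the event
    (a shorter window cannot support a locking call).  Locked means the
    post-event path ends in an uninterrupted high-state run of at least
    ``lock_dwell_seconds`` (running to bleach or trace end).
    """
    policy = policy or ClassPolicy()
    if event_frame is None:
        raise ValueError("flow-in trace without event_frame")
    if fit is None:
        return TraceClass(trace.molecule_id, "not_applicable", reason="no HMM fit")
    pre = classify_prefolded(trace, fit, policy, frames=slice(0, event_frame))
    if pre.label != "dynamic":
        return TraceClass(trace.molecule_id, "not_applicable",
                          reason=f"pre-event {pre.label}")
    post = _merged_path(fit, trace, policy, frames=slice(event_frame, None))
    post_seconds = len(post) * trace.frame_interval
    if post_seconds < policy.lock_dwell_seconds:
        return TraceClass(trace.molecule_id, "not_applicable",
                          reason=f"only {post_seconds:.1f} s observable post-event")
    runs = _runs(post)
    last_state, last_len = runs[-1]
    terminal_seconds = last_len * trace.frame_interval
    locked = last_state == HIGH and terminal_seconds >= policy.lock_dwell_seconds
    return TraceClass(trace.molecule_id, "locked" if locked else "not_locked",
                      n_transitions=len(runs) - 1,
                      evidence={"terminal_high_seconds":
                                terminal_seconds if last_state == HIGH else 0.0})


def classify_vectorial(trace: FretTrace, policy: ClassPolicy | None = None
                       ) -> TraceClass:
    """Four-way behavioral call for a vectorially released molecule.

    The release event is located as the departure from the initial
    low-FRET heteroduplex segment (sustained efficiency above the release
    threshold); the post-release segment is thresholded into mid/high
    states, short runs merged, and scored:

    * type_i  — straight to a stable high state, no mid dwell;
    * type_ii — stable mid, no high dwell;
    * type_iii — persistent fluctuation between the two;
    * type_iv — fluctuation ending in a terminal high run of at least
      ``lock_dwell_seconds``.
    """
    policy = policy or ClassPolicy()
    eff, valid = trace.efficiency, trace.valid_mask
    idx = np.flatnonzero(valid)
    if idx.size < policy.min_analysis_frames:
        return TraceClass(trace.molecule_id, "unresolved",
                          reason="too few valid frames")
    e = eff[idx]
    above = e > policy.release_threshold
    w = policy.release_confirm_frames
    release = None
    if len(above) >= w:
        run = np.convolve(above.astype(int), np.ones(w, dtype=int), "valid")
        hits = np.flatnonzero(run == w)
        if hits.size:
            release = int(hits[0])
    if release is None:
        return TraceClass(trace.molecule_id, "unresolved",
                          reason="no release from heteroduplex detected")
    if release == 0 and not (~above[:1]).any():
        # never saw a heteroduplex segment; still score from the start
        log.debug("%s: no low-FRET segment before release", trace.molecule_id)
    post = e[release + policy.post_release_skip_frames:]
    if len(post) < policy.min_analysis_frames:
        return TraceClass(trace.molecule_id, "unresolved",
                          reason="post-release segment too short")
    states = (post > policy.mid_high_boundary).astype(int)
    states = merge_short_runs(states, policy.min_dwell_frames)
    runs = _runs(states)
    has_mid = any(s == MID for s, _ in runs)
    has_high = any(s == HIGH for s, _ in runs)
    n_trans = len(runs) - 1
    if has_high and not has_mid:
        label = "type_i"
    elif has_mid and not has_high:
        label = "type_ii"
    else:
        last_state, last_len = runs[-1]
        terminal_seconds = last_len * trace.frame_interval
        if last_state == HIGH and terminal_seconds >= policy.lock_dwell_seconds:
            label = "type_iv"
        else:
            label = "type_iii"
    return TraceClass(trace.molecule_id, label, n_transitions=n_trans,
                      evidence={"release_frame": int(idx[release])})


# ---------------------------------------------------------------------------
# population fractions


def goodman_intervals(counts: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Simultaneous 95% multinomial confidence intervals (Goodman 1965)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = len(counts)
    if n == 0:
        return np.zeros((k, 2))
    b = chi2.ppf(1 - alpha / k, 1)
    lo = (b + 2 * counts - np.sqrt(b * (b + 4 * counts * (n - counts) / n))) \
        / (2 * (n + b))
    hi = (b + 2 * counts + np.sqrt(b * (b + 4 * counts * (n - counts) / n))) \
        / (2 * (n + b))
    return np.clip(np.column_stack([lo, hi]), 0.0, 1.0)


def population_table(classes: list[TraceClass],
                     labels: tuple[str, ...] | None = None) -> list[dict]:
    """Counts, fractions and simultaneous 95% CIs per behavioral label.

    Rejected/unresolved/not_applicable traces are excluded from the
    denominator and reported as separate rows with NaN fractions.
    """
    if not classes:
        raise ValueError("no classified traces")
    excluded_labels = {"rejected", "unresolved", "not_applicable"}
    observed = [c for c in classes if c.label not in excluded_labels]
    if labels is None:
        labels = tuple(dict.fromkeys(c.label for c in observed))
    counts = np.array([sum(c.label == lab for c in observed) for lab in labels])
    n = counts.sum()
    cis = goodman_intervals(counts)
    rows = []
    for lab, cnt, (lo, hi) in zip(labels, counts, cis):
        rows.append({"label": lab, "count": int(cnt),
                     "fraction": cnt / n if n else float("nan"),
                     "ci_low": float(lo), "ci_high": float(hi)})
    for lab in sorted({c.label for c in classes} & excluded_labels):
        cnt = sum(c.label == lab for c in classes)
        rows.append({"label": lab, "count": int(cnt),
                     "fraction": float("nan"), "ci_low": float("nan"),
                     "ci_high": float("nan")})
    return rows
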