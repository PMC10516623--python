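"""Convert raw two-channel intensities into corrected FRET traces.

Correction is the fixed-protocol kind: background subtraction, donor
leakage into the acceptor channel, and acceptor direct excitation, with
constants supplied by configuration (they are instrument properties, not
per-trace estimates).  No gamma (detection-efficiency) correction is
applied; the efficiency reported is the proximity ratio after crosstalk
correction,

    E = A' / (D' + A'),   D' = D - bg_D,
                          A' = A - bg_A - beta * D' - delta.

Frames with total corrected intensity below a threshold are masked, and
traces are truncated at photobleaching: a donor bleach shows as a sustained
drop of total intensity to background; an acceptor bleach as a sustained
anti-correlated step (acceptor to background while the donor rises, since
energy transfer stops).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import PhotophysicsConfig
from .trace_io import IntensityTrace

log = logging.getLogger(__name__)

CLIP_RANGE = (-0.2, 1.2)
DEFAULT_BLEACH_WINDOW = 5  # frames


@dataclass
class FretTrace:
    """Corrected FRET-efficiency series with validity mask.

    ``efficiency`` is NaN wherever ``valid_mask`` is False; frames at or
    after ``bleach_frame`` are never valid.
    """

    molecule_id: str
    efficiency: np.ndarray
    valid_mask: np.ndarray
    frame_interval: float
    bleach_frame: int | None = None
    bleach_type: str = "none"
    event_frame: int | None = None
    source: IntensityTrace | None = None

    def __post_init__(self):
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.efficiency.shape != self.valid_mask.shape:
            raise ValueError("efficiency and valid_mask shapes differ")
        if self.bleach_frame is not None and self.bleach_frame > len(self.efficiency):
            raise ValueError("bleach_frame beyond trace end")

    def __len__(self) -> int:
        return len(self.efficiency)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_efficiencies(self) -> np.ndarray:
        return self.efficiency[self.valid_mask]


def correct_crosstalk(trace: IntensityTrace, leakage_beta: float,
                      direct_excitation_delta: float,
                      background_donor: float,
                      background_acceptor: float) -> IntensityTrace:
    """Apply background/leakage/direct-excitation correction.

    Exact inverse of the simulator's crosstalk application at zero noise.
    Negative corrected counts are permitted; downstream masking handles
    them.
    """
    if not (0.0 <= leakage_beta < 1.0):
        raise ValueError("leakage_beta must lie in [0, 1)")
    donor_c = trace.donor - background_donor
    acceptor_c = (trace.acceptor - background_acceptor
                  - leakage_beta * donor_c - direct_excitation_delta)
    return IntensityTrace(trace.molecule_id, donor_c, acceptor_c,
                          trace.frame_interval, event_frame=trace.event_frame,
                          truth=trace.truth)


def compute_fret(corrected: IntensityTrace, min_total_intensity: float,
                 bleach_frame: int | None = None,
                 bleach_type: str = "none") -> FretTrace:
    """Per-frame proximity ratio with intensity masking.

    Frames with corrected total below ``min_total_intensity`` (and frames
    at/after ``bleach_frame``) are masked.  Values are clipped to
    [-0.2, 1.2]; clip events are logged, and slightly out-of-range values
    are retained for histogram fidelity.
    """
    total = corrected.donor + corrected.acceptor
    valid = total >= min_total_intensity
    if bleach_frame is not None:
        valid &= np.arange(len(corrected)) < bleach_frame
    eff = np.full(len(corrected), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = corrected.acceptor[valid] / total[valid]
    n_clip = int(((raw < CLIP_RANGE[0]) | (raw > CLIP_RANGE[1])).sum())
    if n_clip:
        log.info("clipped %d efficiency values in %s", n_clip, corrected.molecule_id)
    eff[valid] = np.clip(raw, *CLIP_RANGE)
    if not valid.any():
        log.warning("all frames masked in %s", corrected.molecule_id)
    return FretTrace(corrected.molecule_id, eff, valid, corrected.frame_interval,
                     bleach_frame=bleach_frame, bleach_type=bleach_type,
                     event_frame=corrected.event_frame, source=corrected)


def _first_sustained(condition: np.ndarray, window: int) -> int | None:
    """First index where ``condition`` holds for ``window`` consecutive
    frames (or holds through the end of the trace for >= window frames)."""
    if len(condition) < window:
        return None
    run = np.convolve(condition.astype(int), np.ones(window, dtype=int), "valid")
    hits = np.flatnonzero(run == window)
    return int(hits[0]) if hits.size else None


def detect_bleach(corrected: IntensityTrace, total_threshold: float,
                  window: int = DEFAULT_BLEACH_WINDOW,
                  acceptor_threshold: float | None = None,
                  donor_threshold: float | None = None,
                  ) -> tuple[int | None, str]:
    """Locate single-step photobleaching in a corrected trace.

    Donor bleach: total corrected intensity stays below ``total_threshold``
    for >= ``window`` frames.  Acceptor bleach: corrected acceptor stays
    below ``acceptor_threshold`` while the corrected donor stays above
    ``donor_threshold`` (the anti-correlated signature of lost energy
    transfer) for >= ``window`` frames.  The earliest event wins.
    """
    if len(corrected) < window:
        raise ValueError("trace shorter than the bleach detection window")
    acceptor_threshold = (total_threshold * 0.5 if acceptor_threshold is None
                          else acceptor_threshold)
    donor_threshold = total_threshold if donor_threshold is None else donor_threshold
    total = corrected.donor + corrected.acceptor
    donor_event = _first_sustained(total < total_threshold, window)
    acceptor_event = _first_sustained(
        (corrected.acceptor < acceptor_threshold)
        & (corrected.donor > donor_threshold), window)
    candidates = [(f, t) for f, t in
                  ((donor_event, "donor"), (acceptor_event, "acceptor"))
                  if f is not None]
    if not candidates:
        return None, "none"
    frame, kind = min(candidates, key=lambda ft: ft[0])
    return frame, kind


def preprocess_trace(trace: IntensityTrace, photo: PhotophysicsConfig,
                     min_total_fraction: float = 0.2,
                     bleach_window: int = DEFAULT_BLEACH_WINDOW) -> FretTrace:
    """Full correction pipeline with constants taken from a photophysics
    configuration: crosstalk correction, bleach truncation, masking.

    ``min_total_fraction`` sets the intensity mask threshold as a fraction
    of the configured total intensity (default 20%).
    """
    corrected = correct_crosstalk(trace, photo.leakage_beta,
                                  photo.direct_excitation_delta,
                                  photo.background_donor,
                                  photo.background_acceptor)
    threshold = min_total_fraction * photo.total_intensity
    bleach_frame, bleach_type = detect_bleach(corrected, threshold,
                                              window=bleach_window)
    return compute_fret(corrected, threshold, bleach_frame=bleach_frame,
                        bleach_type=bleach_type)


def preprocess_ensemble(ensemble, photo: PhotophysicsConfig,
                        min_total_fraction: float = 0.2,
                        bleach_window: int = DEFAULT_BLEACH_WINDOW) -> list[FretTrace]:
    return [preprocess_trace(t, photo, min_total_fraction, bleach_window)
            for t in ensemble]
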