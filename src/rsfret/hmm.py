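"""Two-state Gaussian-emission hidden Markov model for FRET traces.

This fills the dwell-kinetics role that ebFRET-style analysis plays for
experimental data: fit per-frame transition probabilities and Gaussian
emissions for the mid-FRET (open) and high-FRET (closed) states, decode
the state path, and extract per-molecule dwell-time statistics.

The implementation is maximum-likelihood Baum–Welch per trace, with an
optional ensemble-shared emission mode (a two-pass scheme: a global
Gaussian-mixture fit pins the emission means/sds, then per-trace EM
re-estimates only the transition matrix and initial distribution).  Masked
frames are treated as missing observations: their emission terms are
skipped and the transition structure bridges across them.

State index 0 is the mid-FRET state and index 1 the high-FRET state
(means are relabeled to ascending order after fitting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .preprocess import FretTrace

log = logging.getLogger(__name__)

MIN_VALID_FRAMES = 10
SD_FLOOR = 0.01
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
MIN_DWELL_FRAMES = 2

MID, HIGH = 0, 1


class HmmNumericalError(RuntimeError):
    pass


@dataclass
class HmmModel:
    means: np.ndarray          # (2,) ascending: [mid, high]
    sds: np.ndarray            # (2,)
    transmat: np.ndarray       # (2, 2) row-stochastic, per frame
    startprob: np.ndarray      # (2,)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if (self.sds <= 0).any():
            raise ValueError("emission sds must be positive")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if ((self.transmat < 0) | (self.transmat > 1)).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.means[1] <= self.means[0]:
            raise ValueError("canonical ordering requires mean_high > mean_mid")

    @classmethod
    def default_init(cls, eff: np.ndarray | None = None) -> "HmmModel":
        """Quantile-based initialization (fallback when no mixture fit is
        available): means at the 25th/75th percentiles of the data."""
        if eff is not None and len(eff) >= 4:
            lo, hi = np.quantile(eff, [0.25, 0.75])
            if hi - lo < 0.05:
                lo, hi = lo - 0.05, hi + 0.05
        else:
            lo, hi = 0.4, 0.84
        return cls(np.array([lo, hi]), np.array([0.05, 0.05]),
                   np.array([[0.97, 0.03], [0.03, 0.97]]),
                   np.array([0.5, 0.5]))


@dataclass
class HmmFit:
    molecule_id: str
    model: HmmModel
    log_likelihood: float
    ll_trajectory: list[float]
    viterbi_path: np.ndarray
    posterior: np.ndarray
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# core recursions


def _emission_matrix(model: HmmModel, eff: np.ndarray,
                     valid: np.ndarray) -> np.ndarray:
    """Per-frame emission likelihoods, shape (L, 2); masked frames get 1
    for every state (missing observation)."""
    L = len(eff)
    b = np.ones((L, 2))
    x = eff[valid]
    for k in range(2):
        b[valid, k] = (np.exp(-0.5 * ((x - model.means[k]) / model.sds[k]) ** 2)
                       / (model.sds[k] * math.sqrt(2 * math.pi)))
    return b


def forward_backward(model: HmmModel, eff: np.ndarray, valid: np.ndarray):
    """Scaled forward-backward pass.

    Returns (log_likelihood, gamma, xi_sum, b) where gamma is the (L, 2)
    posterior and xi_sum the (2, 2) expected transition counts.
    """
    b = _emission_matrix(model, eff, valid)
    L = len(eff)
    alpha = np.empty((L, 2))
    c = np.empty(L)
    alpha[0] = model.startprob * b[0]
    c[0] = alpha[0].sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise HmmNumericalError("zero forward probability at frame 0")
    alpha[0] /= c[0]
    A = model.transmat
    for t in range(1, L):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise HmmNumericalError(f"zero forward probability at frame {t}")
        alpha[t] = a / c[t]
    ll = float(np.log(c).sum())
    beta = np.empty((L, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(L - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb) * A / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ll, gamma, xi_sum, b


def log_likelihood(model: HmmModel, trace: FretTrace) -> float:
    """Forward-algorithm log-likelihood of a trace under the model."""
    ll, *_ = forward_backward(model, trace.efficiency, trace.valid_mask)
    return ll


def viterbi(model: HmmModel, trace: FretTrace) -> np.ndarray:
    """Maximum-probability state path (0 = mid, 1 = high).

    Masked frames carry no emission term and are bridged by the transition
    structure.  Ties are broken with hysteresis — toward remaining in the
    previous state — and a first-frame tie goes to the argmax of the
    initial distribution.
    """
    eff, valid = trace.efficiency, trace.valid_mask
    b = _emission_matrix(model, eff, valid)
    with np.errstate(divide="ignore"):
        logb = np.log(b)
        logA = np.log(model.transmat)
        logpi = np.log(model.startprob)
    L = len(eff)
    delta = np.empty((L, 2))
    psi = np.zeros((L, 2), dtype=int)
    delta[0] = logpi + logb[0]
    for t in range(1, L):
        for k in range(2):
            scores = delta[t - 1] + logA[:, k]
            # hysteresis: on a tie prefer predecessor == k (stay)
            best = int(np.argmax(scores))
            if scores[k] >= scores[best]:
                best = k
            psi[t, k] = best
            delta[t, k] = scores[best] + logb[t, k]
    path = np.empty(L, dtype=int)
    end_scores = delta[-1]
    path[-1] = int(np.argmax(end_scores))
    if end_scores[0] == end_scores[1]:
        path[-1] = int(np.argmax(model.startprob))
    for t in range(L - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# EM fitting


def _em_single(eff: np.ndarray, valid: np.ndarray, init: HmmModel, tol: float,
               max_iter: int, update_emissions: bool
               ) -> tuple[HmmModel, list[float], bool]:
    model = init
    trajectory: list[float] = []
    converged = False
    for _ in range(max_iter):
        ll, gamma, xi_sum, _ = forward_backward(model, eff, valid)
        if trajectory and ll < trajectory[-1] - 1e-8:
            log.warning("EM log-likelihood decreased by %g", trajectory[-1] - ll)
        trajectory.append(ll)
        if len(trajectory) > 1 and abs(trajectory[-1] - trajectory[-2]) < tol:
            converged = True
            break
        denom = gamma[:-1].sum(axis=0)
        transmat = xi_sum / np.where(denom > 0, denom, 1.0)[:, None]
        # guard rows that received no mass
        rowsum = transmat.sum(axis=1, keepdims=True)
        transmat = np.where(rowsum > 0, transmat / rowsum,
                            model.transmat)
        startprob = gamma[0] / gamma[0].sum()
        means, sds = model.means, model.sds
        if update_emissions:
            g = gamma[valid]
            x = eff[valid]
            w = g.sum(axis=0)
            w = np.where(w > 0, w, 1.0)
            means = (g * x[:, None]).sum(axis=0) / w
            var = (g * (x[:, None] - means) ** 2).sum(axis=0) / w
            sds = np.maximum(np.sqrt(var), SD_FLOOR)
            if means[1] < means[0]:
                means, sds = means[::-1].copy(), sds[::-1].copy()
                transmat = transmat[::-1, ::-1].copy()
                startprob = startprob[::-1].copy()
            if means[1] - means[0] < 1e-6:
                means = np.array([means[0] - 5e-7, means[1] + 5e-7])
        model = HmmModel(means, sds, transmat, startprob)
    return model, trajectory, converged


def fit_hmm(traces: list[FretTrace], init: HmmModel | None = None,
            tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
            shared_emissions: bool = False) -> list[HmmFit]:
    """Baum–Welch EM over an ensemble of FRET traces.

    With ``shared_emissions`` the emission parameters are estimated once
    from the pooled efficiencies (global two-component mixture) and frozen,
    and per-trace EM re-estimates only transition/initial probabilities —
    the stable choice when many traces occupy a single state.  Traces with
    fewer than 10 valid frames are skipped with a warning.
    """
    usable = []
    for tr in traces:
        if tr.n_valid < MIN_VALID_FRAMES:
            log.warning("skipping %s: only %d valid frames",
                        tr.molecule_id, tr.n_valid)
        else:
            usable.append(tr)
    if not usable:
        return []
    if init is None:
        pooled = np.concatenate([t.valid_efficiencies for t in usable])
        if shared_emissions:
            from .population import fit_mixture
            mix = fit_mixture(pooled, K=2)
            init = HmmModel(mix.means.copy(),
                            np.maximum(mix.sds, SD_FLOOR),
                            np.array([[0.97, 0.03], [0.03, 0.97]]),
                            np.array([0.5, 0.5]))
        else:
            init = HmmModel.default_init(pooled)
    fits = []
    for tr in usable:
        try:
            model, traj, conv = _em_single(tr.efficiency, tr.valid_mask, init,
                                           tol, max_iter,
                                           update_emissions=not shared_emissions)
        except HmmNumericalError as exc:
            raise HmmNumericalError(f"{tr.molecule_id}: {exc}") from exc
        ll, gamma, _, _ = forward_backward(model, tr.efficiency, tr.valid_mask)
        path = viterbi(model, tr)
        fits.append(HmmFit(tr.molecule_id, model, ll, traj, path, gamma,
                           n_iterations=len(traj), converged=conv))
    return fits


# ---------------------------------------------------------------------------
# dwell extraction


@dataclass
class Dwell:
    state: int
    n_frames: int
    duration: float
    censored: bool


@dataclass
class DwellSummary:
    molecule_id: str
    mean_dwell_high: float | None
    mean_dwell_mid: float | None
    n_transitions: int
    occupancy_high: float
    censored_edge_dwells: int


def _runs(path: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs as (state, length)."""
    runs = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            runs.append((int(path[start]), i - start))
            start = i
    return runs


def merge_short_runs(path: np.ndarray, min_frames: int = MIN_DWELL_FRAMES
                     ) -> np.ndarray:
    """Relabel interior runs shorter than ``min_frames`` into the flanking
    state.

    The shortest offending run is merged first, then the path is
    re-scanned, so cascades of blur-frame flicker collapse cleanly.  Edge
    runs are left alone: they are censored anyway, and merging them would
    silently change the censoring of their neighbors.
    """
    path = np.asarray(path).copy()
    while True:
        runs = _runs(path)
        if len(runs) <= 2:
            return path
        short = [(length, i) for i, (_, length) in enumerate(runs)
                 if length < min_frames and 0 < i < len(runs) - 1]
        if not short:
            return path
        _, idx = min(short)
        # rebuild with run idx relabeled to its neighbor's state
        neighbor = runs[idx - 1][0] if idx > 0 else runs[idx + 1][0]
        offset = sum(length for _, length in runs[:idx])
        path[offset:offset + runs[idx][1]] = neighbor


def extract_dwells(path: np.ndarray, frame_interval: float,
                   min_dwell_frames: int = MIN_DWELL_FRAMES) -> list[Dwell]:
    """Convert a decoded path into dwell durations.

    Runs shorter than ``min_dwell_frames`` are first merged into their
    flanking state; the first and last runs are flagged censored (their
    true duration extends beyond the observation window).
    """
    merged = merge_short_runs(path, min_dwell_frames)
    runs = _runs(merged)
    dwells = []
    for i, (state, length) in enumerate(runs):
        censored = i == 0 or i == len(runs) - 1
        dwells.append(Dwell(state, length, length * frame_interval, censored))
    return dwells


def dwell_summary(traces: list[FretTrace], fits: list[HmmFit],
                  min_dwell_frames: int = MIN_DWELL_FRAMES) -> list[DwellSummary]:
    """Per-molecule dwell statistics behind the log-scale dwell scatter.

    Mean dwells use uncensored dwells only; molecules lacking an uncensored
    dwell in a state report None there, and molecules with no uncensored
    dwell at all are excluded (logged).
    """
    by_id = {f.molecule_id: f for f in fits}
    out = []
    for tr in traces:
        fit = by_id.get(tr.molecule_id)
        if fit is None:
            continue
        vi = np.flatnonzero(tr.valid_mask)
        if vi.size == 0:
            continue
        region = fit.viterbi_path[vi[0]:vi[-1] + 1]
        dwells = extract_dwells(region, tr.frame_interval, min_dwell_frames)
        unc = [d for d in dwells if not d.censored]
        if not unc:
            log.info("%s: no uncensored dwells; excluded from dwell summary",
                     tr.molecule_id)
            continue
        high = [d.duration for d in unc if d.state == HIGH]
        mid = [d.duration for d in unc if d.state == MID]
        occupancy_high = float(np.mean(region == HIGH))
        out.append(DwellSummary(
            molecule_id=tr.molecule_id,
            mean_dwell_high=float(np.mean(high)) if high else None,
            mean_dwell_mid=float(np.mean(mid)) if mid else None,
            n_transitions=len(dwells) - 1,
            occupancy_high=occupancy_high,
            censored_edge_dwells=sum(d.censored for d in dwells),
        ))
    return out
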