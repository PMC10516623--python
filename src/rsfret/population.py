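"""FRET-efficiency distributions, Gaussian-mixture decomposition, and
ligand-titration isotherm fitting.

Short movies (20 frames at 75 ms) sample the equilibrium conformational
distribution; pooled per-frame efficiencies are decomposed into Gaussian
components (two by default — open and closed; three when a ribosome-mimic
oligo adds a low-FRET bound state).  The weight of the high-FRET component
versus ligand concentration is fitted with the two-state binding isotherm

    f(c) = f0 + (fmax - f0) * c / (Kd + c)

with Kd parameterized on a log scale for positivity.  Uncertainties come
from a cluster bootstrap that resamples molecules, not frames, because
frames within a molecule are strongly correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .preprocess import FretTrace
from .simulate import bound_fraction_isotherm

log = logging.getLogger(__name__)

SD_FLOOR = 0.01
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


class DegenerateFitError(RuntimeError):
    pass


class UnidentifiableKdError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pooling


@dataclass
class PooledSample:
    """Pooled per-frame efficiencies, retaining per-molecule grouping so a
    cluster bootstrap can resample molecules."""

    values: np.ndarray
    by_molecule: list[np.ndarray]
    molecule_ids: list[str]

    def __len__(self) -> int:
        return len(self.values)


def pool_efficiencies(traces: list[FretTrace], n_frames: int | None = 20
                      ) -> PooledSample:
    """Pool valid per-frame E values from the first ``n_frames`` of each
    molecule (``None`` pools every valid frame).

    Pooling is per frame, not per molecule mean: the short movies are brief
    relative to dwell times, so frames are the natural histogram unit.
    """
    if n_frames is not None and n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    per_mol, ids = [], []
    for tr in traces:
        eff = tr.efficiency if n_frames is None else tr.efficiency[:n_frames]
        mask = tr.valid_mask if n_frames is None else tr.valid_mask[:n_frames]
        vals = eff[mask]
        if vals.size:
            per_mol.append(vals)
            ids.append(tr.molecule_id)
    if not per_mol:
        raise ValueError("no valid efficiencies to pool")
    return PooledSample(np.concatenate(per_mol), per_mol, ids)


# ---------------------------------------------------------------------------
# Gaussian mixture EM


@dataclass
class MixtureFit:
    weights: np.ndarray
    means: np.ndarray      # ascending
    sds: np.ndarray
    log_likelihood: float
    ll_trajectory: list[float] = field(default_factory=list)
    converged: bool = True
    n_samples: int = 0
    degenerate: bool = False

    @property
    def K(self) -> int:
        return len(self.weights)


def _mixture_loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                    sd: np.ndarray) -> tuple[float, np.ndarray]:
    comp = (w / (sd * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((x[:, None] - mu) / sd) ** 2))
    tot = comp.sum(axis=1)
    tot = np.maximum(tot, 1e-300)
    return float(np.log(tot).sum()), comp / tot[:, None]


def fit_mixture(samples: np.ndarray | PooledSample, K: int = 2,
                init_means: np.ndarray | None = None, tol: float = DEFAULT_TOL,
                max_iter: int = DEFAULT_MAX_ITER) -> MixtureFit:
    """Deterministic EM for a K-component Gaussian mixture on pooled E.

    Initialization is from evenly spaced quantiles (or user-supplied means,
    e.g. the 0.4/0.84 open/closed palette); no random restarts, so the fit
    is reproducible.  Emission sds are floored at 0.01.  Components are
    reported sorted by mean.  Fits with a vanishing component or
    unseparated means are flagged degenerate rather than raised.
    """
    x = samples.values if isinstance(samples, PooledSample) else \
        np.asarray(samples, dtype=float)
    if len(x) < 10 * K:
        raise ValueError(f"need at least {10 * K} samples for K={K}")
    if init_means is None:
        mu = np.quantile(x, (np.arange(K) + 0.5) / K)
        mu = mu + np.arange(K) * 1e-6  # break exact ties
    else:
        mu = np.sort(np.asarray(init_means, dtype=float))
        if len(mu) != K:
            raise ValueError("init_means length must equal K")
    sd = np.full(K, max(np.std(x), SD_FLOOR))
    w = np.full(K, 1.0 / K)
    trajectory: list[float] = []
    converged = False
    for _ in range(max_iter):
        ll, resp = _mixture_loglik(x, w, mu, sd)
        trajectory.append(ll)
        if len(trajectory) > 1 and abs(trajectory[-1] - trajectory[-2]) < tol:
            converged = True
            break
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), SD_FLOOR)
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    degenerate = bool((w < 0.05).any())
    for i in range(K - 1):
        if mu[i + 1] - mu[i] < max(sd[i], sd[i + 1]):
            degenerate = True
    if (w < 1e-3).any():
        log.warning("mixture component weight < 1e-3 (degenerate)")
    if not converged:
        log.warning("mixture EM did not converge in %d iterations", max_iter)
    return MixtureFit(w, mu, sd, trajectory[-1], trajectory, converged,
                      n_samples=len(x), degenerate=degenerate)


def high_fret_fraction(fit: MixtureFit, sample: PooledSample | None = None,
                       n_bootstrap: int = 0,
                       rng: np.random.Generator | None = None,
                       allow_degenerate: bool = False
                       ) -> tuple[float, float | None]:
    """Weight of the highest-mean component among the mid+high components.

    For K = 3 the lowest (oligo-bound/heteroduplex) component is excluded
    from the denominator, matching how competition histograms are scored.
    Returns (fraction, standard_error); the SE comes from a nonparametric
    cluster bootstrap over molecules when a pooled sample is supplied.
    """
    if fit.K < 2:
        raise ValueError("need at least two components")
    if fit.degenerate and not allow_degenerate:
        raise DegenerateFitError(
            "degenerate mixture fit; consider a different K")
    start = fit.K - 2  # mid + high are the two highest-mean components
    denom = fit.weights[start:].sum()
    frac = float(fit.weights[-1] / denom)
    se = None
    if n_bootstrap and sample is not None:
        rng = rng or np.random.default_rng(0)
        reps = _bootstrap_fractions(sample, fit, n_bootstrap, rng)
        se = float(np.std(reps, ddof=1))
    return frac, se


def _bootstrap_fractions(sample: PooledSample, fit: MixtureFit, n_boot: int,
                         rng: np.random.Generator) -> np.ndarray:
    n_mol = len(sample.by_molecule)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_mol, size=n_mol)
        x = np.concatenate([sample.by_molecule[i] for i in pick])
        try:
            refit = fit_mixture(x, K=fit.K, init_means=fit.means, max_iter=200)
            reps[b], _ = high_fret_fraction(refit, allow_degenerate=True)
        except ValueError:
            reps[b] = np.nan
    return reps[np.isfinite(reps)]


# ---------------------------------------------------------------------------
# isotherm fitting


@dataclass
class TitrationResult:
    concentrations: np.ndarray   # μM
    fractions: np.ndarray
    uncertainties: np.ndarray | None
    kd: float                    # μM
    f0: float
    fmax: float
    covariance: np.ndarray
    kd_ci: tuple[float, float] | None = None
    n_bootstrap: int = 0
    converged: bool = True
    extrapolated: bool = False


def fit_isotherm(concentrations, fractions, uncertainties=None,
                 fix_f0: float | None = None, fix_fmax: float | None = None
                 ) -> TitrationResult:
    """Weighted least-squares fit of the two-state binding isotherm.

    Kd is parameterized as exp(log Kd) to enforce positivity; f0 and fmax
    are free unless fixed.  A response flatter than twice the median
    uncertainty is rejected as unidentifiable.  Results marked
    ``extrapolated`` when the grid tops out below 5 × fitted Kd (relevant
    to very weak binders).
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if ((f < 0) | (f > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    order = np.argsort(c)
    c, f = c[order], f[order]
    if uncertainties is not None:
        u = np.asarray(uncertainties, dtype=float)[order]
        med_u = float(np.median(u))
    else:
        u = None
        med_u = 0.01
    if f.max() - f.min() < 2 * med_u:
        raise UnidentifiableKdError(
            f"response range {f.max() - f.min():.4f} below twice the median "
            f"uncertainty {med_u:.4f}")

    def model(cc, log_kd, *rest):
        i = 0
        if fix_f0 is None:
            f0 = rest[i]; i += 1
        else:
            f0 = fix_f0
        fmax = rest[i] if fix_fmax is None else fix_fmax
        return bound_fraction_isotherm(cc, np.exp(log_kd), f0, fmax)

    # initial guesses: Kd at the half-rise concentration
    half = f.min() + 0.5 * (f.max() - f.min())
    nz = c[c > 0]
    kd0 = float(np.interp(half, f, c)) if f[-1] > f[0] else float(np.median(nz))
    kd0 = max(kd0, nz.min() / 10 if nz.size else 1e-3)
    p0 = [np.log(kd0)]
    if fix_f0 is None:
        p0.append(float(f.min()))
    if fix_fmax is None:
        p0.append(float(f.max()))
    converged = True
    try:
        popt, pcov = curve_fit(model, c, f, p0=p0, sigma=u,
                               absolute_sigma=False, maxfev=20000)
    except RuntimeError:
        converged = False
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        log.warning("isotherm fit did not converge")
    kd = float(np.exp(popt[0]))
    i = 1
    f0 = fix_f0 if fix_f0 is not None else float(popt[i]); i += (fix_f0 is None)
    fmax = fix_fmax if fix_fmax is not None else float(popt[i])
    return TitrationResult(c, f, u, kd, f0, fmax, pcov,
                           converged=converged,
                           extrapolated=bool(c.max() < 5 * kd))


def titrate(samples_by_concentration: dict[float, PooledSample], K: int = 2,
            n_bootstrap: int = 100, seed: int = 0,
            fix_f0: float | None = None, fix_fmax: float | None = None
            ) -> TitrationResult:
    """Full titration analysis: mixture fit per concentration, isotherm fit
    across concentrations, cluster-bootstrap confidence interval on Kd.

    The bootstrap resamples molecules within every concentration, refits
    the mixture (warm-started at the full-data parameters) and the
    isotherm, and reports the 2.5/97.5 percentile interval.
    """
    concs = sorted(samples_by_concentration)
    fits, fracs, ses = [], [], []
    rng = np.random.default_rng(seed)
    for c in concs:
        sample = samples_by_concentration[c]
        mfit = fit_mixture(sample, K=K)
        frac, se = high_fret_fraction(mfit, sample, n_bootstrap=0,
                                      allow_degenerate=True)
        # binomial-scale uncertainty on a weight from n_mol molecules
        n_mol = max(len(sample.by_molecule), 2)
        se = max(np.sqrt(max(frac * (1 - frac), 1e-4) / n_mol), 1e-4)
        fits.append(mfit)
        fracs.append(frac)
        ses.append(se)
    result = fit_isotherm(concs, fracs, ses, fix_f0=fix_f0, fix_fmax=fix_fmax)
    if n_bootstrap:
        kds = []
        for _ in range(n_bootstrap):
            bf = []
            for c, mfit in zip(concs, fits):
                sample = samples_by_concentration[c]
                n_mol = len(sample.by_molecule)
                pick = rng.integers(0, n_mol, size=n_mol)
                x = np.concatenate([sample.by_molecule[i] for i in pick])
                refit = fit_mixture(x, K=K, init_means=mfit.means, max_iter=100)
                frac, _ = high_fret_fraction(refit, allow_degenerate=True)
                bf.append(min(max(frac, 0.0), 1.0))
            try:
                kds.append(fit_isotherm(concs, bf, ses, fix_f0=fix_f0,
                                        fix_fmax=fix_fmax).kd)
            except (UnidentifiableKdError, ValueError):
                continue
        if len(kds) >= 10:
            lo, hi = np.percentile(kds, [2.5, 97.5])
            result.kd_ci = (float(lo), float(hi))
            result.n_bootstrap = len(kds)
    return result
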