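"""Gumbel psychometric function: evaluation, likelihood, and Bayesian fitting.

The detection model is the four-parameter Gumbel (log-Weibull) sigmoid

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-10 ** (beta * (x - alpha))))

with threshold ``alpha`` (dB SPL), slope parameter ``beta`` (per dB, inside the
log10 exponent), false-alarm rate ``gamma`` (lower asymptote) and lapse rate
``lambda`` (``1 - lambda`` is the upper asymptote).  At ``x = alpha`` a fraction
``gamma + (1 - gamma - lambda) * (1 - 1/e)`` of stimuli is detected.

Fitting is grid-Bayesian: the posterior over (alpha, beta) is evaluated on a
dense grid with the nuisance rates (gamma, lambda) profiled at their
penalized-likelihood optima per cell, followed by a Nelder-Mead (Simplex)
refinement of the MAP.  Priors follow the study conventions: alpha ~
Normal(45 dB, 30 dB), beta ~ Beta(0.1, 1) on (0, 1], gamma and lambda uniform
on small intervals.  Silence ("catch") trials enter the likelihood only through
gamma; they are encoded with the :data:`SILENCE` sentinel (negative infinity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SILENCE",
    "PsychometricParams",
    "FitConfig",
    "Trial",
    "RunData",
    "FitResult",
    "DegenerateFitError",
    "gumbel_psi",
    "slope_to_max_rate",
    "log_likelihood",
    "fit_psychometric",
    "posterior_hdi",
    "hdi_of_samples",
    "threshold_difference_test",
    "select_or_pool_runs",
    "BatchFitter",
    "DifferenceTestResult",
    "PoolingDecision",
]

#: Sentinel stimulus level for catch ("no sound") trials.  Distinct from every
#: finite level; psi(SILENCE) is exactly the false-alarm rate.
SILENCE = float("-inf")

_LN10 = math.log(10.0)


class DegenerateFitError(ValueError):
    """Raised when run data cannot constrain the psychometric function."""

    def __init__(self, message: str, diagnostic: dict | None = None):
        super().__init__(message)
        self.diagnostic = diagnostic or {}


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of a Gumbel detection curve.

    ``lam`` is the lapse rate (the field's lambda; renamed because ``lambda``
    is reserved in Python).
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lam: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.alpha):
            raise ValueError(f"threshold alpha must be finite, got {self.alpha}")
        if not self.beta >= 0:
            raise ValueError(f"slope beta must be >= 0, got {self.beta}")
        if not (0 <= self.gamma < 1):
            raise ValueError(f"false-alarm rate gamma must be in [0, 1), got {self.gamma}")
        if not (0 <= self.lam < 1):
            raise ValueError(f"lapse rate lambda must be in [0, 1), got {self.lam}")
        if not self.gamma + self.lam < 1:
            raise ValueError(
                f"gamma + lambda must be < 1, got {self.gamma} + {self.lam}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.lam)


def gumbel_psi(x, p: PsychometricParams):
    """Detection probability of the Gumbel psychometric function at level ``x``.

    ``x`` may be a scalar (possibly :data:`SILENCE`) or an array of levels.
    Returns values in ``[gamma, 1 - lambda]``; silence maps exactly to the
    lower asymptote ``gamma``.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        t = np.power(10.0, p.beta * (x - p.alpha))
    f = -np.expm1(-t)  # 1 - exp(-t), stable near t = 0
    out = p.gamma + (1.0 - p.gamma - p.lam) * f
    if out.ndim == 0:
        return float(out)
    return out


def slope_to_max_rate(p: PsychometricParams) -> float:
    """Maximum rate of rise beta' of psi, in psi units per dB.

    ``beta' = (1 - gamma - lambda) * beta * ln(10) / e`` — the slope of the
    curve at its steepest point.
    """
    return (1.0 - p.gamma - p.lam) * p.beta * _LN10 / math.e


@dataclass(frozen=True)
class Trial:
    """A single yes/no detection trial."""

    level: float  # dB SPL, or SILENCE
    response: bool
    block: int = 0

    def __post_init__(self):
        if not (self.level == SILENCE or np.isfinite(self.level)):
            raise ValueError(f"trial level must be finite or SILENCE, got {self.level}")
        if not isinstance(self.response, (bool, np.bool_)):
            raise TypeError(f"response must be boolean, got {type(self.response)}")


@dataclass(frozen=True)
class RunData:
    """One constant-stimuli run: a frequency and its trial records."""

    frequency_khz: float
    trials: tuple[Trial, ...]

    def __init__(self, frequency_khz: float, trials: Iterable[Trial]):
        object.__setattr__(self, "frequency_khz", float(frequency_khz))
        object.__setattr__(self, "trials", tuple(trials))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def levels(self) -> np.ndarray:
        """Sorted distinct finite levels."""
        finite = sorted({t.level for t in self.trials if t.level != SILENCE})
        return np.asarray(finite, dtype=float)

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
        """Aggregate to (levels, n per level, hits per level, n silence, silence hits)."""
        levels = self.levels
        idx = {lv: i for i, lv in enumerate(levels)}
        n = np.zeros(len(levels), dtype=float)
        k = np.zeros(len(levels), dtype=float)
        n0 = 0
        k0 = 0
        for t in self.trials:
            if t.level == SILENCE:
                n0 += 1
                k0 += int(t.response)
            else:
                i = idx[t.level]
                n[i] += 1
                k[i] += int(t.response)
        return levels, n, k, n0, k0

    def pooled_with(self, other: "RunData") -> "RunData":
        if self.frequency_khz != other.frequency_khz:
            raise ValueError(
                f"cannot pool runs at different frequencies "
                f"({self.frequency_khz} vs {other.frequency_khz} kHz)"
            )
        return RunData(self.frequency_khz, self.trials + other.trials)


def log_likelihood(run: RunData, p: PsychometricParams) -> float:
    """Bernoulli log-likelihood of a run under parameters ``p``.

    Returns ``-inf`` (with a warning) when a trial outcome has probability
    exactly zero under ``p`` — e.g. a silence detection with ``gamma = 0``.
    """
    levels, n, k, n0, k0 = run.counts()
    ll = 0.0
    if n0:
        for count, prob in ((k0, p.gamma), (n0 - k0, 1.0 - p.gamma)):
            if count:
                if prob <= 0.0:
                    warnings.warn(
                        "observed response has zero probability under the "
                        "supplied parameters; log-likelihood is -inf",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    return float("-inf")
                ll += count * math.log(prob)
    if len(levels):
        psi = np.atleast_1d(gumbel_psi(levels, p))
        for ki, ni, prob in zip(k, n, psi):
            for count, pr in ((ki, prob), (ni - ki, 1.0 - prob)):
                if count:
                    if pr <= 0.0:
                        warnings.warn(
                            "observed response has zero probability under the "
                            "supplied parameters; log-likelihood is -inf",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                        return float("-inf")
                    ll += count * math.log(pr)
    return float(ll)


@dataclass(frozen=True)
class FitConfig:
    """Grids, priors and Monte-Carlo settings of the Bayesian fit.

    Defaults implement the study conventions: threshold prior Normal(45, 30)
    dB, slope prior Beta(0.1, 1) on (0, 1], nuisance rates uniform on
    [0, 0.25] (gamma) and [0, 0.10] (lambda), 95% HDIs, 10,000 posterior draws
    for difference tests.
    """

    alpha_prior_mean: float = 45.0
    alpha_prior_sd: float = 30.0
    beta_prior_a: float = 0.1
    beta_prior_b: float = 1.0
    alpha_lo: float = 0.0
    alpha_hi: float = 90.0
    alpha_step: float = 0.25
    beta_lo: float = 0.01
    beta_hi: float = 1.0
    n_beta: int = 120
    gamma_max: float = 0.25
    n_gamma: int = 11
    lambda_max: float = 0.10
    n_lambda: int = 5
    hdi_mass: float = 0.95
    n_draws: int = 10_000
    seed: int = 0
    refine: bool = True

    def __post_init__(self):
        if not (0.0 < self.hdi_mass < 1.0):
            raise ValueError(f"hdi_mass must be in (0, 1), got {self.hdi_mass}")
        if self.alpha_hi <= self.alpha_lo or self.alpha_step <= 0:
            raise ValueError("alpha grid must be non-empty and increasing")
        if self.beta_hi <= self.beta_lo or self.beta_lo <= 0 or self.n_beta < 2:
            raise ValueError("beta grid must be non-empty, positive and increasing")

    @cached_property
    def alpha_grid(self) -> np.ndarray:
        n = int(round((self.alpha_hi - self.alpha_lo) / self.alpha_step)) + 1
        return self.alpha_lo + self.alpha_step * np.arange(n)

    @cached_property
    def beta_grid(self) -> np.ndarray:
        return np.geomspace(self.beta_lo, self.beta_hi, self.n_beta)

    @cached_property
    def gamma_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.gamma_max, self.n_gamma)

    @cached_property
    def lambda_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.lambda_max, self.n_lambda)

    @cached_property
    def log_prior_alpha(self) -> np.ndarray:
        a = self.alpha_grid
        return -0.5 * ((a - self.alpha_prior_mean) / self.alpha_prior_sd) ** 2

    @cached_property
    def log_prior_beta(self) -> np.ndarray:
        # Beta(a, b) density on (0, 1]; improper spillover outside is excluded
        # by the grid itself.
        b = self.beta_grid
        return (self.beta_prior_a - 1.0) * np.log(b) + (self.beta_prior_b - 1.0) * np.log1p(-np.minimum(b, 1 - 1e-12))

    @cached_property
    def beta_cell_widths(self) -> np.ndarray:
        """Integration weights of the log-spaced beta grid (trapezoid cells)."""
        b = self.beta_grid
        w = np.empty_like(b)
        w[1:-1] = 0.5 * (b[2:] - b[:-2])
        w[0] = b[1] - b[0]
        w[-1] = b[-1] - b[-2]
        return w

    def log_prior_density(self, params: PsychometricParams) -> float:
        """Joint log prior density at arbitrary parameter values (for refinement)."""
        if not (self.beta_lo <= params.beta <= self.beta_hi):
            return float("-inf")
        if params.gamma > self.gamma_max or params.lam > self.lambda_max:
            return float("-inf")
        lp = -0.5 * ((params.alpha - self.alpha_prior_mean) / self.alpha_prior_sd) ** 2
        lp += (self.beta_prior_a - 1.0) * math.log(params.beta)
        if params.beta < 1.0:
            lp += (self.beta_prior_b - 1.0) * math.log1p(-params.beta)
        return lp


@dataclass(frozen=True)
class FitResult:
    """MAP estimates plus discretized marginal posteriors of a fitted run."""

    map_params: PsychometricParams
    alpha_grid: np.ndarray
    alpha_posterior: np.ndarray  # probability mass per grid point, sums to 1
    beta_grid: np.ndarray
    beta_posterior: np.ndarray
    alpha_hdi: tuple[float, float]
    beta_hdi: tuple[float, float]
    alpha_sd: float
    log_likelihood_map: float
    n_trials: int
    at_boundary: bool = False
    hdi_flags: tuple[str, ...] = ()

    @property
    def alpha_mean(self) -> float:
        return float(np.dot(self.alpha_grid, self.alpha_posterior))

    @property
    def beta_mean(self) -> float:
        return float(np.dot(self.beta_grid, self.beta_posterior))

    @property
    def beta_sd(self) -> float:
        m = self.beta_mean
        return float(np.sqrt(np.dot((self.beta_grid - m) ** 2, self.beta_posterior)))

    def draw_alphas(self, n: int, rng: np.random.Generator, jitter: float | None = None) -> np.ndarray:
        """Posterior draws of alpha from the discretized marginal.

        A uniform within-cell jitter (half the grid step by default) smooths
        the discretization.
        """
        step = float(self.alpha_grid[1] - self.alpha_grid[0]) if len(self.alpha_grid) > 1 else 0.0
        if jitter is None:
            jitter = 0.5 * step
        draws = rng.choice(self.alpha_grid, size=n, p=self.alpha_posterior)
        if jitter > 0:
            draws = draws + rng.uniform(-jitter, jitter, size=n)
        return draws

    def draw_betas(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.beta_grid), size=n, p=self.beta_posterior)
        draws = self.beta_grid[idx]
        # multiplicative within-cell jitter on the log-spaced grid
        if len(self.beta_grid) > 1:
            ratio = self.beta_grid[1] / self.beta_grid[0]
            draws = draws * ratio ** rng.uniform(-0.5, 0.5, size=n)
        return draws


def posterior_hdi(
    grid: np.ndarray, density: np.ndarray, mass: float
) -> tuple[tuple[float, float], list[tuple[float, float]], bool]:
    """Highest-density region of a discretized marginal.

    Returns ``(interval, segments, disjoint)`` where ``interval`` is the
    bounding interval of the smallest set of grid cells whose probability mass
    reaches ``mass``, ``segments`` are its contiguous pieces, and ``disjoint``
    flags a multimodal density whose HDI is a union of intervals.  Ties in
    density (e.g. a uniform) are broken toward the distribution's center, so a
    uniform on [0, 1] at mass 0.95 yields the central interval of width 0.95.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    grid = np.asarray(grid, dtype=float)
    p = np.asarray(density, dtype=float)
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("density must have positive finite total mass")
    p = p / total
    center = float(np.dot(grid, p))
    # Sort by density (descending); break ties toward the center of mass.
    order = np.lexsort((np.abs(grid - center), -p))
    csum = np.cumsum(p[order])
    m = int(np.searchsorted(csum, mass - 1e-12)) + 1
    chosen = np.sort(order[:m])
    # contiguous segments of selected indices
    segments: list[tuple[float, float]] = []
    start = chosen[0]
    prev = chosen[0]
    for i in chosen[1:]:
        if i != prev + 1:
            segments.append((float(grid[start]), float(grid[prev])))
            start = i
        prev = i
    segments.append((float(grid[start]), float(grid[prev])))
    disjoint = len(segments) > 1
    interval = (segments[0][0], segments[-1][1])
    return interval, segments, disjoint


def hdi_of_samples(samples: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples (via arviz)."""
    import arviz  # deferred: heavy import

    lo, hi = arviz.hdi(np.asarray(samples, dtype=float), hdi_prob=mass)
    return float(lo), float(hi)


class BatchFitter:
    """Grid-Bayesian fitter specialized to one level set and one config.

    Precomputes, once per (config, level-set) pair, the per-cell log detection
    probabilities for every (alpha, beta, gamma, lambda) combination so that
    fitting a run reduces to two tensor contractions over the observed counts.
    Used directly by Monte-Carlo studies; :func:`fit_psychometric` delegates
    here, so both paths share the same arithmetic.
    """

    def __init__(self, cfg: FitConfig, levels: Sequence[float]):
        self.cfg = cfg
        self.levels = np.asarray(sorted(levels), dtype=float)
        if len(self.levels) == 0:
            raise ValueError("BatchFitter requires at least one finite level")
        A = cfg.alpha_grid[:, None, None]
        B = cfg.beta_grid[None, :, None]
        X = self.levels[None, None, :]
        with np.errstate(over="ignore"):
            t = np.power(10.0, B * (X - A))
        F = -np.expm1(-t)  # (nA, nB, L)
        G = cfg.gamma_grid
        L = cfg.lambda_grid
        # pairs with gamma + lambda < 1 (always true for the default bounds)
        gg, ll = np.meshgrid(G, L, indexing="ij")
        keep = (gg + ll) < 1.0
        self.pair_gamma = gg[keep]  # (P,)
        self.pair_lambda = ll[keep]
        P = len(self.pair_gamma)
        scale = (1.0 - self.pair_gamma - self.pair_lambda).astype(np.float64)
        # psi per (nA, nB, P, L); float32 keeps the cache compact
        psi = (
            self.pair_gamma[None, None, :, None]
            + scale[None, None, :, None] * F[:, :, None, :]
        )
        eps = 1e-12
        np.clip(psi, eps, 1.0 - eps, out=psi)
        self.log_psi = np.log(psi, dtype=np.float32)
        self.log_1m_psi = np.log1p(-psi).astype(np.float32)
        with np.errstate(divide="ignore"):
            self.log_pair_gamma = np.log(np.maximum(self.pair_gamma, eps))
            self.log_pair_1m_gamma = np.log1p(-self.pair_gamma)
        self.log_prior_2d = cfg.log_prior_alpha[:, None] + cfg.log_prior_beta[None, :]

    def _check_degenerate(self, run: RunData):
        responses = [bool(t.response) for t in run.trials]
        if all(responses):
            raise DegenerateFitError(
                "all trials detected: psychometric function unconstrained",
                {"n_trials": len(responses), "all_response": True},
            )
        if not any(responses):
            raise DegenerateFitError(
                "no trial detected: psychometric function unconstrained",
                {"n_trials": len(responses), "all_response": False},
            )

    def fit_counts(
        self, n: np.ndarray, k: np.ndarray, n0: int, k0: int, n_trials: int
    ) -> FitResult:
        cfg = self.cfg
        k = np.asarray(k, dtype=np.float32)
        miss = np.asarray(n, dtype=np.float32) - k
        # (nA, nB, P): likelihood profiled over the nuisance pairs
        ll = self.log_psi @ k + self.log_1m_psi @ miss
        if n0:
            ll = ll + (
                k0 * self.log_pair_gamma + (n0 - k0) * self.log_pair_1m_gamma
            )[None, None, :].astype(np.float32)
        pair_idx = np.argmax(ll, axis=2)
        prof = np.take_along_axis(ll, pair_idx[:, :, None], axis=2)[:, :, 0].astype(np.float64)
        log_post = prof + self.log_prior_2d
        # posterior mass per cell (alpha cells uniform, beta cells log-spaced)
        log_post_mass = log_post + np.log(cfg.beta_cell_widths)[None, :]
        log_post_mass -= log_post_mass.max()
        post = np.exp(log_post_mass)
        post /= post.sum()
        alpha_marg = post.sum(axis=1)
        beta_marg = post.sum(axis=0)
        ia, ib = np.unravel_index(np.argmax(log_post), log_post.shape)
        at_boundary = ia in (0, len(cfg.alpha_grid) - 1)
        ip = pair_idx[ia, ib]
        map_params = PsychometricParams(
            float(cfg.alpha_grid[ia]),
            float(cfg.beta_grid[ib]),
            float(self.pair_gamma[ip]),
            float(self.pair_lambda[ip]),
        )
        if cfg.refine and n_trials:
            map_params = self._refine(map_params, n, k, n0, k0)
        a_hdi, _, a_disjoint = posterior_hdi(cfg.alpha_grid, alpha_marg, cfg.hdi_mass)
        b_hdi, _, b_disjoint = posterior_hdi(cfg.beta_grid, beta_marg, cfg.hdi_mass)
        flags = tuple(
            name for name, flag in
            [("alpha_hdi_disjoint", a_disjoint), ("beta_hdi_disjoint", b_disjoint)]
            if flag
        )
        a_mean = float(np.dot(cfg.alpha_grid, alpha_marg))
        a_sd = float(np.sqrt(np.dot((cfg.alpha_grid - a_mean) ** 2, alpha_marg)))
        ll_map = self._loglik_exact(map_params, n, k, n0, k0)
        return FitResult(
            map_params=map_params,
            alpha_grid=cfg.alpha_grid,
            alpha_posterior=alpha_marg,
            beta_grid=cfg.beta_grid,
            beta_posterior=beta_marg,
            alpha_hdi=a_hdi,
            beta_hdi=b_hdi,
            alpha_sd=a_sd,
            log_likelihood_map=ll_map,
            n_trials=n_trials,
            at_boundary=at_boundary,
            hdi_flags=flags,
        )

    def _loglik_exact(
        self, p: PsychometricParams, n, k, n0: int, k0: int
    ) -> float:
        eps = 1e-12
        psi = np.clip(np.atleast_1d(gumbel_psi(self.levels, p)), eps, 1 - eps)
        ll = float(np.dot(k, np.log(psi)) + np.dot(np.asarray(n) - k, np.log1p(-psi)))
        if n0:
            g = min(max(p.gamma, eps), 1 - eps)
            ll += k0 * math.log(g) + (n0 - k0) * math.log1p(-g)
        return ll

    def _refine(self, start: PsychometricParams, n, k, n0, k0) -> PsychometricParams:
        cfg = self.cfg

        def neg_log_post(v):
            a, b, g, l = v
            if not (cfg.beta_lo <= b <= cfg.beta_hi):
                return 1e12
            if not (0 <= g <= cfg.gamma_max and 0 <= l <= cfg.lambda_max and g + l < 1):
                return 1e12
            p = PsychometricParams(a, b, g, l)
            return -(self._loglik_exact(p, n, k, n0, k0) + cfg.log_prior_density(p))

        x0 = np.array(start.as_tuple())
        res = minimize(
            neg_log_post,
            x0,
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-7},
        )
        if res.fun <= neg_log_post(x0):
            a, b, g, l = res.x
            return PsychometricParams(float(a), float(b), float(g), float(l))
        return start

    def fit(self, run: RunData) -> FitResult:
        levels, n, k, n0, k0 = run.counts()
        if len(levels) and (len(levels) != len(self.levels) or not np.allclose(levels, self.levels)):
            raise ValueError("run level set does not match this fitter's level set")
        if run.n_trials:
            self._check_degenerate(run)
        if len(levels) == 0:
            n = np.zeros(len(self.levels))
            k = np.zeros(len(self.levels))
        return self.fit_counts(n, k, n0, k0, run.n_trials)


_FITTER_CACHE: dict[tuple, BatchFitter] = {}
_FITTER_CACHE_MAX = 6


def _fitter_for(cfg: FitConfig, levels: tuple[float, ...]) -> BatchFitter:
    key = (cfg, levels)
    fitter = _FITTER_CACHE.get(key)
    if fitter is None:
        if len(_FITTER_CACHE) >= _FITTER_CACHE_MAX:
            _FITTER_CACHE.pop(next(iter(_FITTER_CACHE)))
        fitter = BatchFitter(cfg, levels)
        _FITTER_CACHE[key] = fitter
    return fitter


def fit_psychometric(run: RunData, cfg: FitConfig) -> FitResult:
    """Fit the Gumbel psychometric function to a run.

    MAP maximizes the prior-weighted likelihood on the configured grids with
    Simplex refinement; marginal posteriors and 95% HDIs are computed over the
    (alpha, beta) grid with gamma and lambda profiled per cell.  An empty run
    returns the prior (alpha MAP at the prior mean); single-response-type data
    raise :class:`DegenerateFitError`.
    """
    levels = tuple(run.levels)
    if run.n_trials == 0:
        # no-data posterior = prior; use a nominal level so the fitter builds
        fitter = _fitter_for(replace(cfg, refine=False), (cfg.alpha_prior_mean,))
        n = np.zeros(1)
        k = np.zeros(1)
        return fitter.fit_counts(n, k, 0, 0, 0)
    responses = {bool(t.response) for t in run.trials}
    if len(responses) < 2:
        raise DegenerateFitError(
            "run has only one response type; cannot constrain the fit",
            {"n_trials": run.n_trials, "all_response": responses.pop()},
        )
    if len(levels) < 2:
        raise DegenerateFitError(
            "run needs at least two distinct finite levels",
            {"n_levels": len(levels)},
        )
    return _fitter_for(cfg, levels).fit(run)


@dataclass(frozen=True)
class DifferenceTestResult:
    """Posterior of a threshold difference (run B minus run A)."""

    hdi: tuple[float, float]
    significant: bool
    delta_mean: float
    delta_sd: float


def threshold_difference_test(
    fitA: FitResult, fitB: FitResult, cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> DifferenceTestResult:
    """HDI test of the threshold difference between two fitted runs.

    Forms the posterior of ``alphaB - alphaA`` from independent draws of the
    two marginal posteriors; the difference is significant when 0 falls
    outside its HDI (mass ``cfg.hdi_mass``).  Deterministic given ``cfg.seed``
    unless an explicit ``rng`` is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    a = fitA.draw_alphas(cfg.n_draws, rng)
    b = fitB.draw_alphas(cfg.n_draws, rng)
    delta = b - a
    lo, hi = hdi_of_samples(delta, cfg.hdi_mass)
    significant = not (lo <= 0.0 <= hi)
    return DifferenceTestResult(
        hdi=(lo, hi),
        significant=significant,
        delta_mean=float(delta.mean()),
        delta_sd=float(delta.std()),
    )


@dataclass(frozen=True)
class PoolingDecision:
    """Which branch the pool-or-select rule fired, and why."""

    pooled: bool
    chosen: str  # "pooled", "A" or "B"
    test: DifferenceTestResult
    alpha_sd_a: float
    alpha_sd_b: float


def select_or_pool_runs(
    runA: RunData, runB: RunData, cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> tuple[RunData, PoolingDecision]:
    """Pool two runs at the same frequency, or pick the more precise one.

    Trials are concatenated when the threshold-difference HDI test is not
    significant; otherwise the run whose threshold posterior has the smaller
    standard deviation is returned.
    """
    if runA.frequency_khz != runB.frequency_khz:
        raise ValueError(
            f"runs are at different frequencies "
            f"({runA.frequency_khz} vs {runB.frequency_khz} kHz)"
        )
    fitA = fit_psychometric(runA, cfg)
    fitB = fit_psychometric(runB, cfg)
    test = threshold_difference_test(fitA, fitB, cfg, rng=rng)
    if not test.significant:
        decision = PoolingDecision(True, "pooled", test, fitA.alpha_sd, fitB.alpha_sd)
        return runA.pooled_with(runB), decision
    if fitA.alpha_sd <= fitB.alpha_sd:
        return runA, PoolingDecision(False, "A", test, fitA.alpha_sd, fitB.alpha_sd)
    return runB, PoolingDecision(False, "B", test, fitA.alpha_sd, fitB.alpha_sd)
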