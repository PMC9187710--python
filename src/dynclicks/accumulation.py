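"""Behavioral accumulation model for the dynamic clicks task.

The model describes the evolution of a latent decision variable ``a``
driven by left/right click trains:

    da = (dR(t) * C - dL(t) * C) dt - lam * a dt + sigma_a dW

where each click's magnitude is scaled by a sensory adaptation state ``C``
(depression for phi < 1, facilitation for phi > 1, recovery time constant
tau_phi) and carries per-click noise.  Because the dynamics are affine in
``a``, the distribution of ``a`` at any time, starting from a Gaussian
initial condition a0 ~ N(0, sigma_i^2), is Gaussian with closed-form
moments.  The probability of a rightward choice is the Gaussian tail mass
above the decision boundary ``B``, mixed with a lapse rate ``l``.

Two conventions for the per-click noise variance are supported:
``"linear"`` (variance sigma_s^2 * C, the default) and ``"quadratic"``
(variance sigma_s^2 * C^2, i.e. multiplicative noise eta ~ N(1, sigma_s^2)
on the adapted magnitude).  The SDE simulator in :mod:`dynclicks.synth`
follows the same flag so analytic moments and Monte-Carlo paths agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import ndtr

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "ModelParams",
    "AdaptedClicks",
    "GaussianTrace",
    "FitResult",
    "PriorConfig",
    "adapt_clicks",
    "forward_moments",
    "moments_at_end",
    "choice_prob",
    "negative_log_likelihood",
    "fit_parameters",
    "pack_trials",
    "DEFAULT_BOUNDS",
]

PARAM_NAMES = ("sigma_i2", "sigma_a2", "sigma_s2", "lam", "phi", "tau_phi", "B", "lapse")

DEFAULT_BOUNDS = {
    "sigma_i2": (0.0, 40.0),
    "sigma_a2": (0.0, 200.0),
    "sigma_s2": (0.0, 200.0),
    "lam": (-10.0, 10.0),
    "phi": (0.01, 5.0),
    "tau_phi": (0.005, 2.0),
    "B": (-5.0, 5.0),
    "lapse": (0.0, 1.0),
}

_PROB_FLOOR = 1e-10


@dataclass
class ModelParams:
    """The eight accumulation-model parameters.

    sigma_i2 : initial variance of a0 (a^2 units)
    sigma_a2 : memory (diffusion) noise variance per second
    sigma_s2 : per-click noise variance (per unit adapted magnitude)
    lam      : evidence discounting rate, 1/s (negative = leaky)
    phi      : adaptation strength (phi < 1 depresses, phi > 1 facilitates)
    tau_phi  : adaptation recovery time constant, s
    B        : decision boundary / side bias (a units)
    lapse    : probability of a stimulus-independent random choice
    """

    sigma_i2: float = 0.5
    sigma_a2: float = 1.0
    sigma_s2: float = 1.0
    lam: float = -2.0
    phi: float = 0.5
    tau_phi: float = 0.2
    B: float = 0.0
    lapse: float = 0.05
    click_noise: str = "linear"  # "linear": var = ss2*C; "quadratic": var = ss2*C^2

    def __post_init__(self) -> None:
        if self.sigma_i2 < 0 or self.sigma_a2 < 0 or self.sigma_s2 < 0:
            raise ValueError("noise variances must be non-negative")
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if self.click_noise not in ("linear", "quadratic"):
            raise ValueError("click_noise must be 'linear' or 'quadratic'")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec, click_noise: str = "linear") -> "ModelParams":
        kw = {n: float(v) for n, v in zip(PARAM_NAMES, vec)}
        return cls(click_noise=click_noise, **kw)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class AdaptedClicks:
    """Merged click train with per-click adapted magnitudes."""

    times: np.ndarray   # ascending, s
    signs: np.ndarray   # +1 right, -1 left
    magnitudes: np.ndarray  # effective C at each click (pre-jump)


@dataclass
class GaussianTrace:
    """Forward-model Gaussian moments on a time grid."""

    times: np.ndarray
    mu: np.ndarray
    var: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.var, 0.0))


@dataclass
class PriorConfig:
    """Half-Gaussian priors (scale = SD) on the two noise variances."""

    sigma_i2_scale: float = 30.0
    sigma_a2_scale: float = 30.0

    def penalty(self, sigma_i2: float, sigma_a2: float) -> float:
        return 0.5 * (sigma_i2 / self.sigma_i2_scale) ** 2 + 0.5 * (
            sigma_a2 / self.sigma_a2_scale
        ) ** 2


@dataclass
class FitResult:
    theta_hat: ModelParams
    nll: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    n_trials: int = 0
    message: str = ""
    hessian: np.ndarray | None = None


def _expm1_over_x(x: np.ndarray | float) -> np.ndarray | float:
    """(exp(x) - 1) / x with the series limit at x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-8, 1.0 + x / 2.0, np.expm1(np.where(np.abs(x) < 1e-8, 0.0, x)) / np.where(x == 0, 1.0, x))
    return out


def merge_clicks(left_clicks, right_clicks) -> tuple[np.ndarray, np.ndarray]:
    """Merge left/right click times into one ascending train with signs.

    Exact ties are ordered left before right (stable sort on the
    concatenation), so coincident clicks contribute both updates
    sequentially.
    """
    left = np.asarray(left_clicks, dtype=float)
    right = np.asarray(right_clicks, dtype=float)
    if left.size and np.any(np.diff(left) < 0):
        raise ValueError("left click times must be ascending")
    if right.size and np.any(np.diff(right) < 0):
        raise ValueError("right click times must be ascending")
    times = np.concatenate([left, right])
    signs = np.concatenate([-np.ones(left.size), np.ones(right.size)])
    order = np.argsort(times, kind="stable")
    return times[order], signs[order]


def adapt_clicks(trial_or_left, right_clicks=None, *, phi: float, tau_phi: float) -> AdaptedClicks:
    """Compute per-click effective magnitudes under sensory adaptation.

    The adaptation state C starts at 1.  A click's effective magnitude is
    C evaluated immediately before the click; C then jumps to phi*C and
    relaxes exponentially back toward 1 with time constant tau_phi.
    """
    if phi <= 0 or tau_phi <= 0:
        raise ValueError("phi and tau_phi must be positive")
    if right_clicks is None:
        times, signs = merge_clicks(trial_or_left.left_clicks, trial_or_left.right_clicks)
    else:
        times, signs = merge_clicks(trial_or_left, right_clicks)
    n = times.size
    mags = np.empty(n)
    c = 1.0
    t_prev = 0.0
    for k in range(n):
        c = 1.0 + (c - 1.0) * math.exp(-(times[k] - t_prev) / tau_phi)
        mags[k] = c
        c = phi * c
        t_prev = times[k]
    return AdaptedClicks(times=times, signs=signs, magnitudes=mags)


def _click_var_weights(mags: np.ndarray, click_noise: str) -> np.ndarray:
    return mags * mags if click_noise == "quadratic" else mags


def forward_moments(trial, theta: ModelParams, dt: float = 1e-3, t_grid=None) -> GaussianTrace:
    """Closed-form Gaussian moments of the accumulator on a time grid.

    mu(t)  = sum_clicks sign * C * exp(lam (t - s))
    var(t) = sigma_i2 e^{2 lam t} + sigma_a2 t g(2 lam t)
             + sigma_s2 sum_clicks w(C) e^{2 lam (t - s)}
    with g(x) = (e^x - 1)/x and w(C) the click-noise convention weight.
    """
    if t_grid is None:
        n_steps = int(round(trial.duration / dt))
        t_grid = np.linspace(0.0, n_steps * dt, n_steps + 1)
    t_grid = np.asarray(t_grid, dtype=float)
    ac = adapt_clicks(trial, phi=theta.phi, tau_phi=theta.tau_phi)
    lam = theta.lam
    mu = np.zeros_like(t_grid)
    cvar = np.zeros_like(t_grid)
    if ac.times.size:
        dtm = t_grid[:, None] - ac.times[None, :]
        mask = dtm >= 0
        e1 = np.where(mask, np.exp(np.where(mask, lam * dtm, 0.0)), 0.0)
        w = _click_var_weights(ac.magnitudes, theta.click_noise)
        mu = e1 @ (ac.signs * ac.magnitudes)
        cvar = (e1 * e1) @ w * theta.sigma_s2
    x = 2.0 * lam * t_grid
    var = theta.sigma_i2 * np.exp(x) + theta.sigma_a2 * t_grid * _expm1_over_x(x) + cvar
    return GaussianTrace(times=t_grid, mu=mu, var=np.maximum(var, 0.0))


def moments_at_end(trial, theta: ModelParams) -> tuple[float, float]:
    """(mu, var) of the accumulator at the trial's final time."""
    tr = forward_moments(trial, theta, t_grid=np.array([trial.duration]))
    return float(tr.mu[0]), float(tr.var[0])


def choice_prob(trial, theta: ModelParams) -> float:
    """P(choice = right) = (1 - l) P(a_N > B) + l/2."""
    mu, var = moments_at_end(trial, theta)
    sd = math.sqrt(max(var, 0.0))
    if sd == 0.0:
        p_tail = 0.5 if mu == theta.B else float(mu > theta.B)
    else:
        p_tail = float(ndtr((mu - theta.B) / sd))
    return (1.0 - theta.lapse) * p_tail + theta.lapse / 2.0


# ---------------------------------------------------------------------------
# Likelihood machinery (flattened arrays for speed)
# ---------------------------------------------------------------------------


@dataclass
class PackedTrials:
    times: np.ndarray     # all clicks, trial-major
    signs: np.ndarray
    offsets: np.ndarray   # int64, len n_trials + 1
    t_end: np.ndarray
    choices: np.ndarray   # +1 / -1

    @property
    def n_trials(self) -> int:
        return self.t_end.size


def pack_trials(trials, choices=None) -> PackedTrials:
    """Flatten trials (and their choices) for the likelihood kernel."""
    times_l, signs_l, offs = [], [], [0]
    t_end = np.empty(len(trials))
    ch = np.empty(len(trials))
    for i, tr in enumerate(trials):
        t, s = merge_clicks(tr.left_clicks, tr.right_clicks)
        times_l.append(t)
        signs_l.append(s)
        offs.append(offs[-1] + t.size)
        t_end[i] = tr.duration
        c = choices[i] if choices is not None else tr.choice
        if c is None or c == 0:
            raise ValueError(f"trial {i} has no choice; cannot enter the likelihood")
        ch[i] = c
    return PackedTrials(
        times=np.concatenate(times_l) if times_l else np.empty(0),
        signs=np.concatenate(signs_l) if signs_l else np.empty(0),
        offsets=np.asarray(offs, dtype=np.int64),
        t_end=t_end,
        choices=ch,
    )


@njit(cache=True)
def _nll_kernel(times, signs, offsets, t_end, choices,
                si2, sa2, ss2, lam, phi, tau, B, lapse, quad):  # pragma: no cover
    sqrt2 = math.sqrt(2.0)
    total = 0.0
    n = t_end.size
    for i in range(n):
        tN = t_end[i]
        c = 1.0
        t_prev = 0.0
        mu = 0.0
        cvar = 0.0
        for k in range(offsets[i], offsets[i + 1]):
            s = times[k]
            c = 1.0 + (c - 1.0) * math.exp(-(s - t_prev) / tau)
            mag = c
            c = phi * c
            t_prev = s
            e = math.exp(lam * (tN - s))
            mu += signs[k] * mag * e
            w = mag * mag if quad else mag
            cvar += ss2 * w * e * e
        x = 2.0 * lam * tN
        if abs(x) < 1e-8:
            g = tN * (1.0 + 0.5 * x)
        else:
            g = math.expm1(x) / (2.0 * lam)
        var = si2 * math.exp(x) + sa2 * g + cvar
        if var < 1e-30:
            var = 1e-30
        sd = math.sqrt(var)
        p_right = 0.5 * math.erfc((B - mu) / (sd * sqrt2))
        p = (1.0 - lapse) * p_right + 0.5 * lapse
        if choices[i] < 0:
            p = 1.0 - p
        if p < 1e-10:
            p = 1e-10
        elif p > 1.0 - 1e-10:
            p = 1.0 - 1e-10
        total -= math.log(p)
    return total


def _nll_from_packed(packed: PackedTrials, vec: np.ndarray, click_noise: str,
                     priors: PriorConfig | None) -> float:
    si2, sa2, ss2, lam, phi, tau, B, lapse = [float(v) for v in vec]
    val = _nll_kernel(
        packed.times, packed.signs, packed.offsets, packed.t_end, packed.choices,
        si2, sa2, ss2, lam, phi, tau, B, lapse, click_noise == "quadratic",
    )
    if priors is not None:
        val += priors.penalty(si2, sa2)
    return float(val)


def negative_log_likelihood(trials, theta: ModelParams, choices=None,
                            priors: PriorConfig | None = None) -> float:
    """-sum_i log P(y_i | theta), plus half-Gaussian prior penalties.

    ``trials`` may be a list of Trial objects (choices taken from the
    trials unless given separately) or a :class:`PackedTrials`.
    """
    packed = trials if isinstance(trials, PackedTrials) else pack_trials(trials, choices)
    return _nll_from_packed(packed, theta.to_vector(), theta.click_noise, priors)


def _numeric_hessian(f, x0, rel_step=1e-3, abs_step=1e-5):
    n = x0.size
    h = np.maximum(np.abs(x0) * rel_step, abs_step)
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_parameters(trials, choices=None, theta0: ModelParams | None = None,
                   bounds: dict | None = None, priors: PriorConfig | None = None,
                   n_starts: int = 3, seed: int = 0,
                   click_noise: str = "linear",
                   fixed: dict | None = None) -> FitResult:
    """Maximum-likelihood fit of the eight model parameters.

    Bounded L-BFGS-B with ``n_starts`` random restarts; standard errors
    from the inverse numeric Hessian at the optimum (unavailable entries
    are NaN when the Hessian is not positive definite).  ``fixed`` maps
    parameter names to frozen values.
    """
    packed = trials if isinstance(trials, PackedTrials) else pack_trials(trials, choices)
    if packed.n_trials == 0:
        raise ValueError("cannot fit with zero trials")
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    fixed = dict(fixed or {})
    if priors is None:
        priors = PriorConfig()
    theta0 = theta0 or ModelParams(click_noise=click_noise)
    x_full0 = theta0.to_vector()
    free_idx = [i for i, n in enumerate(PARAM_NAMES) if n not in fixed]
    for name, v in fixed.items():
        x_full0[PARAM_NAMES.index(name)] = v

    def expand(xf):
        x = x_full0.copy()
        x[free_idx] = xf
        return x

    def obj(xf):
        return _nll_from_packed(packed, expand(xf), click_noise, priors)

    rng = np.random.default_rng(seed)
    bnds = [bounds[PARAM_NAMES[i]] for i in free_idx]
    best = None
    start = x_full0[free_idx].copy()
    for s in range(max(1, n_starts)):
        x_init = start if s == 0 else np.array(
            [np.clip(v + rng.normal(0, 0.25 * (hi - lo)), lo, hi)
             for v, (lo, hi) in zip(start, bnds)]
        )
        res = optimize.minimize(obj, x_init, method="L-BFGS-B", bounds=bnds,
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    x_hat = expand(best.x)
    theta_hat = ModelParams.from_vector(x_hat, click_noise=click_noise)

    se = {n: math.nan for n in PARAM_NAMES}
    H = None
    try:
        H = _numeric_hessian(obj, np.asarray(best.x, dtype=float))
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        for k, i in enumerate(free_idx):
            se[PARAM_NAMES[i]] = math.sqrt(d[k]) if d[k] > 0 else math.nan
    except np.linalg.LinAlgError:
        pass
    return FitResult(theta_hat=theta_hat, nll=float(best.fun), se=se,
                     converged=bool(best.success), n_trials=packed.n_trials,
                     message=str(best.message), hessian=H)
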