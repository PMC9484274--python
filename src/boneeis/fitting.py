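"""Complex nonlinear least-squares circuit fitting via Nelder-Mead.

The objective is the weighted sum of squared complex residuals

    S = sum_i w_i * |Z_model(f_i) - Z_obs(f_i)|^2

with modulus weighting ``w_i = 1/|Z_obs(f_i)|^2`` by default (|Z| spans
about two decades across the grid, so unweighted fits would ignore the
high-frequency structure). Optimization runs over
``[log10 R_b, log10 R_Ct, log10 Q, alpha]`` to enforce positivity, with
alpha clamped to (0, 1]. Nelder-Mead is local, so a seeded multistart
(first start from a heuristic initial guess, the rest jittered) keeps
results reproducible yet robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .circuit import CircuitParams, ImpedanceSpectrum, circuit_impedance
from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = ["FitOptions", "FitResult", "initial_guess", "fit_spectrum", "r_squared",
           "objective"]

_ALPHA_MIN = 1e-3


@dataclass(frozen=True)
class FitOptions:
    """Multistart Nelder-Mead settings.

    ``tol`` is the relative convergence tolerance on the objective;
    ``weighting`` is ``"modulus"`` (1/|Z_obs|^2) or ``"unit"``.
    """

    n_restarts: int = 8
    max_iterations: int = 2000
    tol: float = 1e-10
    weighting: str = "modulus"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise InvalidArgumentError("n_restarts must be >= 1")
        if self.tol <= 0:
            raise InvalidArgumentError("tol must be > 0")
        if self.weighting not in ("modulus", "unit"):
            raise InvalidArgumentError(
                f"weighting must be 'modulus' or 'unit', got {self.weighting!r}"
            )


@dataclass(frozen=True)
class FitResult:
    params: CircuitParams
    r_squared: float
    objective: float
    converged: bool
    restarts_used: int


def _weights(spectrum: ImpedanceSpectrum, weighting: str) -> np.ndarray:
    if weighting == "unit":
        return np.ones(len(spectrum))
    mod2 = spectrum.z_real**2 + spectrum.z_imag**2
    if np.any(mod2 == 0):
        raise InvalidArgumentError("modulus weighting undefined for |Z_obs| = 0")
    return 1.0 / mod2


def objective(spectrum: ImpedanceSpectrum, params: CircuitParams,
              weighting: str = "modulus") -> float:
    """Weighted residual sum S evaluated at given parameters."""
    w = _weights(spectrum, weighting)
    model = circuit_impedance(params, spectrum.grid)
    r = model.z - spectrum.z
    return float(np.sum(w * (r.real**2 + r.imag**2)))


def initial_guess(spectrum: ImpedanceSpectrum) -> CircuitParams:
    """Heuristic starting point from spectrum asymptotics.

    R_b from the high-frequency modulus plateau; alpha from the
    low-frequency phase magnitude (|theta|/90); Q from the low-frequency CPE
    modulus after subtracting R_b; R_Ct set large (100x the low-frequency
    modulus) since no sub-grid plateau is visible in general.
    """
    if len(spectrum) < 4:
        raise InsufficientDataError("initial guess needs at least 4 frequencies")
    mod = spectrum.modulus
    phase = spectrum.phase_deg
    f = spectrum.grid.frequencies
    r_b = max(mod[-1], 1e-12)
    alpha = float(np.clip(abs(phase[0]) / 90.0, 0.05, 1.0))
    z_low = max(mod[0] - r_b, 0.1 * mod[0])
    q = 1.0 / (z_low * (2.0 * np.pi * f[0]) ** alpha)
    return CircuitParams(r_b=r_b, r_ct=100.0 * mod[0], q=q, alpha=alpha)


def _clipped_params(x: np.ndarray) -> CircuitParams:
    x = np.asarray(x, dtype=float)
    return CircuitParams(
        r_b=10.0 ** np.clip(x[0], -12, 15),
        r_ct=10.0 ** np.clip(x[1], -12, 15),
        q=10.0 ** np.clip(x[2], -15, 3),
        alpha=float(np.clip(x[3], _ALPHA_MIN, 1.0)),
    )


def fit_spectrum(
    spectrum: ImpedanceSpectrum, options: FitOptions | None = None
) -> FitResult:
    """Fit the equivalent circuit to a spectrum; returns the best of
    ``n_restarts`` Nelder-Mead runs.

    Restart 0 starts from :func:`initial_guess`; the others jitter it by
    +-0.5 in log10 space (alpha +-0.1) using the seeded restart RNG.
    Non-convergence of every restart is reported via ``converged=False``,
    never as an exception.
    """
    opts = options or FitOptions()
    if not (
        np.all(np.isfinite(spectrum.z_real)) and np.all(np.isfinite(spectrum.z_imag))
    ):
        raise InvalidArgumentError("spectrum contains non-finite values")
    w = _weights(spectrum, opts.weighting)
    z_obs = spectrum.z
    grid = spectrum.grid
    omega = grid.omega

    def fun(x: np.ndarray) -> float:
        p = _clipped_params(x)
        y = 1.0 / p.r_ct + p.q * (1j * omega) ** p.alpha
        r = p.r_b + 1.0 / y - z_obs
        return float(np.sum(w * (r.real**2 + r.imag**2)))

    x0 = initial_guess(spectrum).as_array()
    rng = np.random.default_rng(opts.seed)
    best_x, best_fun, any_converged = None, np.inf, False
    for k in range(opts.n_restarts):
        start = x0.copy()
        if k > 0:
            start[:3] += rng.uniform(-0.5, 0.5, 3)
            start[3] = np.clip(start[3] + rng.uniform(-0.1, 0.1), _ALPHA_MIN, 1.0)
        res = optimize.minimize(
            fun,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": opts.max_iterations,
                "xatol": 1e-10,
                "fatol": opts.tol * max(1.0, fun(start)),
                "adaptive": True,
            },
        )
        if res.fun < best_fun:
            best_x, best_fun = res.x, res.fun
            any_converged = bool(res.success)
    # polish the winner from its own optimum
    res = optimize.minimize(
        fun,
        best_x,
        method="Nelder-Mead",
        options={"maxiter": opts.max_iterations, "xatol": 1e-12, "fatol": 1e-16,
                 "adaptive": True},
    )
    if res.fun <= best_fun:
        best_x, best_fun = res.x, res.fun
        any_converged = any_converged or bool(res.success)
    params = _clipped_params(best_x)
    return FitResult(
        params=params,
        r_squared=r_squared(spectrum, params),
        objective=best_fun,
        converged=any_converged,
        restarts_used=opts.n_restarts,
    )


def _r2_concat(z_obs: np.ndarray, z_pred: np.ndarray) -> float:
    obs = np.concatenate([z_obs.real, z_obs.imag])
    pred = np.concatenate([z_pred.real, z_pred.imag])
    ss_tot = float(
        np.sum((z_obs.real - z_obs.real.mean()) ** 2)
        + np.sum((z_obs.imag - z_obs.imag.mean()) ** 2)
    )
    if ss_tot == 0:
        raise DegenerateDataError("observed spectrum is constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared(spectrum: ImpedanceSpectrum, params: CircuitParams) -> float:
    """Goodness of fit over the concatenated real and imaginary components,
    with the total sum of squares centred on the per-component means."""
    model = circuit_impedance(params, spectrum.grid)
    return _r2_concat(spectrum.z, model.z)
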