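"""Constitutive models for the pre-stressed viscoelastic cell capsule.

The cell surface is modelled as a tensed shell whose resistance to areal
strain ``alpha = dA/A0`` is a power-law viscoelastic area-compressibility
modulus ``K_A(t) = K_A^0 (t/t0)^(-beta)``.  The total tension follows the
elastic-viscoelastic correspondence principle as a hereditary integral of
the strain-rate history.  Two refinements are provided: the excess-area
("surface reservoir") bookkeeping that softens the apparent modulus by the
projected-area fraction ``xi``, and a membrane+cortex composite in which a
purely elastic bilayer acts in parallel with the power-law cortex.

All quantities are SI: tensions and moduli in N/m, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "RheologyParams",
    "MembraneCortexParams",
    "AreaBudget",
    "StrainHistory",
    "powerlaw_kernel",
    "hereditary_tension",
    "membrane_cortex_tension",
    "apparent_modulus",
    "apparent_fluidity_laplace",
]


@dataclass(frozen=True)
class RheologyParams:
    """Capsule triple (sigma0, KA0, beta) plus the reference time t0.

    sigma0 : prestress of the membrane/cortex shell, N/m
    KA0    : area-compressibility scaling factor at t = t0, N/m
    beta   : fluidity exponent; 0 = solid, 1 = fluid
    t0     : reference time, s (conventionally 1 s)
    """

    sigma0: float
    KA0: float
    beta: float
    t0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.KA0 < 0:
            raise ValueError("sigma0 and KA0 must be non-negative")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")


@dataclass(frozen=True)
class MembraneCortexParams:
    """Composite shell: power-law cortex in parallel with an elastic bilayer.

    KAcort0 is the cortex scaling factor, KAmem the (time-independent)
    membrane area modulus; both in N/m.
    """

    sigma0: float
    KAcort0: float
    beta: float
    KAmem: float
    t0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma0, self.KAcort0, self.KAmem) < 0:
            raise ValueError("moduli and prestress must be non-negative")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")

    @property
    def cortex(self) -> RheologyParams:
        """The cortex-only capsule triple (membrane contribution dropped)."""
        return RheologyParams(self.sigma0, self.KAcort0, self.beta, self.t0)


@dataclass(frozen=True)
class AreaBudget:
    """Area bookkeeping for surface reservoirs.

    The measured modulus refers to the projected area A0 while the shell
    carries the full area A = A0 + Ares.  Cortex extensibility (KAtrue) and
    reservoir recruitment (KAres) act as two 2D springs in series, and the
    projection contributes the factor xi = A0/(A0 + Ares).

    ``KAres=None`` encodes the no-reservoir limit (a rigid reservoir spring);
    it avoids representing an infinite modulus.
    """

    A0: float
    Ares: float
    KAtrue: float
    KAres: float | None = None

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if self.Ares < 0:
            raise ValueError("Ares must be non-negative")
        if self.KAtrue < 0 or (self.KAres is not None and self.KAres < 0):
            raise ValueError("moduli must be non-negative")

    @property
    def xi(self) -> float:
        return self.A0 / (self.A0 + self.Ares)


@dataclass
class StrainHistory:
    """Sampled area-dilation history alpha(t), piecewise linear in between.

    ``t`` must be strictly increasing and the history starts unstrained
    (alpha at the first sample is 0).
    """

    t: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.alpha.shape:
            raise ValueError("t and alpha must be 1-D arrays of equal length")
        if self.t.size < 1:
            raise ValueError("history must contain at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.alpha[0] != 0.0:
            raise ValueError("history must start at alpha = 0")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """alpha at time t (piecewise-linear; constant after the last sample)."""
        return np.interp(t, self.t, self.alpha)


def powerlaw_kernel(params: RheologyParams, t: float | np.ndarray) -> np.ndarray:
    """Relaxation modulus K_A(t) = KA0 (t/t0)^(-beta).

    The kernel is singular at t = 0 for beta > 0; it is only ever evaluated
    at strictly positive lag.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("powerlaw_kernel requires t > 0")
    return params.KA0 * (t / params.t0) ** (-params.beta)


def hereditary_tension(
    params: RheologyParams,
    alpha: StrainHistory,
    t: float | np.ndarray,
) -> np.ndarray:
    """Total tension sigma(t) = sigma0 + int_0^t K_A(t-tau) dalpha/dtau dtau.

    The convolution is evaluated by product integration: on each
    piecewise-linear segment of the history the strain rate is constant and
    the singular kernel integrates in closed form,

        int_{tau1}^{tau2} ((t-tau)/t0)^(-beta) c dtau
            = c t0^beta [(t-tau1)^(1-beta) - (t-tau2)^(1-beta)] / (1-beta),

    which handles the (t-tau)^(-beta) endpoint singularity exactly.
    Segments beyond t contribute nothing; partially covered segments are
    clipped at t.
    """
    if params.beta >= 1.0:
        raise ValueError("hereditary integral requires beta < 1 (integrable kernel)")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = np.isscalar(t) or np.ndim(t) == 0

    tau = alpha.t
    if tau.size < 2:
        out = np.full(t_arr.shape, params.sigma0)
        return out[0] if scalar else out

    slopes = np.diff(alpha.alpha) / np.diff(tau)  # (n-1,)
    tau1 = tau[:-1]
    tau2 = tau[1:]
    one_m_b = 1.0 - params.beta

    # lags clipped at zero: segments after t drop out automatically
    d1 = np.clip(t_arr[:, None] - tau1[None, :], 0.0, None)
    d2 = np.clip(t_arr[:, None] - tau2[None, :], 0.0, None)
    seg = slopes[None, :] * (d1**one_m_b - d2**one_m_b)
    integral = params.KA0 * params.t0**params.beta / one_m_b * seg.sum(axis=1)
    out = params.sigma0 + integral
    return out[0] if scalar else out


def membrane_cortex_tension(
    params: MembraneCortexParams,
    alpha: StrainHistory,
    t: float | np.ndarray,
) -> np.ndarray:
    """Composite tension: hereditary cortex term plus elastic KAmem * alpha(t)."""
    cortex = hereditary_tension(params.cortex, alpha, t)
    return cortex + params.KAmem * alpha(t)


def apparent_modulus(budget: AreaBudget) -> float:
    """Apparent area-compressibility modulus K_A = xi * KAeff.

    KAeff is the series combination of the cortex in-plane modulus and the
    reservoir recruitment modulus; the projection of the full area A onto the
    substrate plane contributes the factor xi = A0/(A0 + Ares).
    """
    if budget.KAres is None:
        # rigid reservoir spring: series combination returns KAtrue
        return budget.xi * budget.KAtrue
    if budget.KAtrue == 0.0 and budget.KAres == 0.0:
        raise ValueError("at least one of KAtrue, KAres must be positive")
    k_eff = budget.KAtrue * budget.KAres / (budget.KAtrue + budget.KAres)
    return budget.xi * k_eff


def _log_laplace_composite(p: MembraneCortexParams, s: np.ndarray) -> np.ndarray:
    """log of s * L{K(t)}(s) for the composite kernel (dimension N/m).

    L{KAcort0 ((t)/t0)^-beta} = KAcort0 t0^beta Gamma(1-beta) s^(beta-1) and
    L{KAmem * delta-response} contributes KAmem / s; both multiplied by s so
    the quantity stays O(modulus) over the window.
    """
    cort = p.KAcort0 * p.t0**p.beta * np.exp(gammaln(1.0 - p.beta)) * s**p.beta
    return np.log(cort + p.KAmem)


def apparent_fluidity_laplace(
    params: MembraneCortexParams,
    s_range: tuple[float, float],
    n_points: int = 50,
) -> tuple[float, float]:
    """Best single power law matching the composite kernel in Laplace space.

    Equating transforms, a single power law (beta_t, KA0_t) satisfies

        KA0_t Gamma(1-beta_t) / s^(1-beta_t)
            = KAcort0 Gamma(1-beta) / s^(1-beta) + KAmem / s

    exactly only in degenerate limits; otherwise the apparent pair is the
    least-squares match of the log-transforms on ``n_points`` log-spaced
    Laplace frequencies over ``s_range``.  The apparent fluidity lies in
    [0, beta] and decreases as the elastic membrane share grows.

    Returns (beta_tilde, KA0_tilde).
    """
    lo, hi = s_range
    if not (0.0 < lo < hi and np.isfinite(hi)):
        raise ValueError("s_range must be a positive, finite, increasing interval")
    if params.beta >= 1.0:
        raise ValueError("requires beta < 1")
    # degenerate limits are exact, not asymptotic
    if params.KAmem == 0.0:
        return params.beta, params.KAcort0
    if params.KAcort0 == 0.0:
        return 0.0, params.KAmem

    s = np.logspace(np.log10(lo), np.log10(hi), n_points)
    log_s = np.log(s)
    target = _log_laplace_composite(params, s)

    def amplitude(beta_t: float) -> float:
        # optimal log-amplitude for given exponent is the mean offset
        return float(np.mean(target - beta_t * log_s))

    def objective(beta_t: float) -> float:
        resid = target - (amplitude(beta_t) + beta_t * log_s)
        return float(resid @ resid)

    res = minimize_scalar(objective, bounds=(0.0, params.beta), method="bounded",
                          options={"xatol": 1e-12})
    beta_t = float(res.x)
    # the bounded minimizer cannot land exactly on an endpoint; snap if better
    for edge in (0.0, params.beta):
        if objective(edge) <= objective(beta_t):
            beta_t = edge
    log_amp = amplitude(beta_t)
    ka0_t = float(
        np.exp(log_amp - gammaln(1.0 - beta_t)) / params.t0**beta_t
    )
    return beta_t, ka0_t
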