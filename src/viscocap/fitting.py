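"""Preprocessing and capsule-model fitting of AFM force curves.

The pipeline mirrors standard force-spectroscopy practice: baseline
correction from the pre-contact approach, contact-point detection by a
noise-threshold crossing refined with back-extrapolation, conversion of
piezo position and deflection into an indentation history, and bounded
nonlinear least squares of the tensed-capsule force

    f(t) = 2 pi g_cap(delta(t)/R1) R1 sigma(t)

with sigma(t) from the hereditary power-law tension.  Three parameters are
recovered per curve: prestress sigma0, scaling factor KA0 and fluidity
beta.  Only the initial part of the retraction segment enters the fit by
default, to stay clear of adhesion-contaminated data; for relaxation
curves (dwell at constant piezo position) the approach and dwell are fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .curves import ForceCurve
from .geometry import ShapeFunctionTable, evaluate
from .rheology import RheologyParams, StrainHistory, hereditary_tension

__all__ = [
    "FitOptions",
    "FitResult",
    "baseline_correct",
    "find_contact_point",
    "refine_contact_z",
    "build_indentation_history",
    "fit_capsule_model",
]


@dataclass
class FitOptions:
    """Knobs for preprocessing and the capsule-model fit."""

    retract_fraction: float = 0.10  # initial share of retraction included
    fit_dwell: bool = True  # relaxation curves: fit approach + dwell
    baseline_fraction: float = 0.5
    remove_oscillation: bool = False
    threshold_sigmas: float = 5.0
    run_length: int = 10
    rigid_cantilever: bool = False  # delta = z - z_contact (no deflection term)
    rigid_dwell: bool = True  # hold delta constant during the dwell
    setpoint_guard: float = 1.05  # trim samples above setpoint * guard
    n_starts: int = 8
    ka0_start_range: tuple[float, float] = (0.005, 0.5)
    beta_starts: tuple[float, ...] = (0.2, 0.5, 0.8)
    tie_break_rtol: float = 1e-3  # residual ties broken toward smaller beta
    seed: int = 0
    max_nfev: int = 400


@dataclass
class FitResult:
    """Recovered capsule parameters and fit diagnostics for one curve."""

    params: RheologyParams
    window: np.ndarray  # sample indices entering the residual
    residual_rms: float  # N
    n_starts: int
    converged: bool
    contact_index: int
    contact_z: float  # m


def baseline_correct(
    curve: ForceCurve,
    fraction: float = 0.5,
    remove_oscillation: bool = False,
) -> ForceCurve:
    """Subtract a line fitted to the pre-contact part of the approach.

    The first ``fraction`` of the approach samples is taken as pre-contact;
    with ``remove_oscillation`` a single sinusoid (frequency seeded by the
    FFT peak of the de-trended segment, then refined) is additionally
    fitted there and subtracted from the whole curve.  This targets the
    periodic artifact that thin elastomer substrates imprint on force
    curves.
    """
    approach = curve.indices("approach")
    n_pre = int(len(approach) * fraction)
    if n_pre < max(10, int(0.2 * len(approach))):
        raise ValueError("too few pre-contact samples for baseline estimation")
    pre = approach[:n_pre]
    t_pre, f_pre = curve.t[pre], curve.force[pre]
    coef = np.polyfit(t_pre, f_pre, 1)
    corrected = curve.force - np.polyval(coef, curve.t)

    if remove_oscillation:
        resid = corrected[pre]
        dt = np.median(np.diff(t_pre))
        freqs = np.fft.rfftfreq(resid.size, dt)
        spec = np.abs(np.fft.rfft(resid - resid.mean()))
        k_peak = int(np.argmax(spec[1:]) + 1)
        f0 = freqs[k_peak]
        df = freqs[1]

        def rms_after(freq: float) -> float:
            w = 2 * np.pi * freq * t_pre
            design = np.column_stack([np.sin(w), np.cos(w), np.ones_like(w)])
            beta, *_ = np.linalg.lstsq(design, resid, rcond=None)
            return float(np.sqrt(np.mean((resid - design @ beta) ** 2)))

        res = minimize_scalar(
            rms_after, bounds=(max(f0 - 2 * df, df / 4), f0 + 2 * df), method="bounded"
        )
        freq = float(res.x)
        w = 2 * np.pi * freq * t_pre
        design = np.column_stack([np.sin(w), np.cos(w), np.ones_like(w)])
        beta, *_ = np.linalg.lstsq(design, resid, rcond=None)
        w_all = 2 * np.pi * freq * curve.t
        corrected = corrected - (beta[0] * np.sin(w_all) + beta[1] * np.cos(w_all) + beta[2])

    return curve.with_force(corrected)


def find_contact_point(
    curve: ForceCurve,
    threshold_sigmas: float = 5.0,
    run_length: int = 10,
) -> int:
    """Index of the tip-sample contact on the (baseline-corrected) approach.

    First crossing of ``threshold_sigmas`` times the robust (MAD) baseline
    noise that persists for ``run_length`` samples, refined by linearly
    back-extrapolating the first 10% of the post-contact force to zero.
    """
    approach = curve.indices("approach")
    f = curve.force[approach]
    n_noise = max(10, len(approach) // 2)
    mad = np.median(np.abs(f[:n_noise] - np.median(f[:n_noise])))
    noise_sd = 1.4826 * mad
    thr = max(threshold_sigmas * noise_sd, 1e-15)

    above = f > thr
    crossing = None
    run = min(run_length, len(f))
    for i in range(len(f) - run + 1):
        if above[i : i + run].all():
            crossing = i
            break
    if crossing is None:
        raise ValueError("no contact detected: threshold never crossed")

    # back-extrapolate early post-contact force to zero force
    post = np.arange(crossing, len(f))
    n_fit = max(3, len(post) // 10)
    seg = post[:n_fit]
    z_seg, f_seg = curve.z[approach[seg]], f[seg]
    if np.ptp(z_seg) > 0:
        slope, intercept = np.polyfit(z_seg, f_seg, 1)
        if slope > 0:
            z0 = -intercept / slope
            z_app = curve.z[approach]
            candidates = np.flatnonzero(z_app[: crossing + 1] >= z0)
            refined = int(candidates[0]) if candidates.size else crossing
            # never move forward of the threshold crossing
            crossing = min(crossing, refined) if candidates.size else crossing
    return int(approach[crossing])


def refine_contact_z(curve: ForceCurve, contact: int) -> float:
    """Sub-sample contact height from the early post-contact force.

    The true contact height falls between piezo samples, at most one
    sample step before the detected crossing.  Near contact the capsule
    force follows f ~ C (z - z0)^p (p near 1, steeper early transients for
    fluid-like cells), so z0 is chosen on a fine grid over that one-step
    interval to maximise the linearity of log f versus log(z - z0) on the
    first post-contact samples.  Falls back to the sample height for
    degenerate segments.
    """
    approach = curve.indices("approach")
    post = approach[approach >= contact]
    n_fit = min(max(5, post.size // 20), 25, post.size)
    z_seg = curve.z[post[:n_fit]]
    f_seg = curve.force[post[:n_fit]]
    z_c = float(curve.z[contact])
    keep = f_seg > 0
    if np.ptp(z_seg) <= 0 or keep.sum() < 4:
        return z_c
    z_seg, f_seg = z_seg[keep], f_seg[keep]
    dz = float(np.median(np.diff(curve.z[approach]))) if approach.size > 1 else 0.0
    if dz <= 0:
        return z_c
    log_f = np.log(f_seg)
    best_z0, best_sse = z_c, np.inf
    for z0 in np.linspace(z_c - dz, z_c - 1e-4 * dz, 41):
        x = np.log(z_seg - z0)
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, log_f, rcond=None)
        sse = float(np.sum((log_f - design @ coef) ** 2))
        if sse < best_sse:
            best_sse, best_z0 = sse, float(z0)
    return best_z0


def _indentation(
    curve: ForceCurve,
    contact: int,
    k: float | None,
    rigid: bool,
    rigid_dwell: bool = True,
    z_contact: float | None = None,
) -> np.ndarray:
    """Per-sample indentation depth delta(t), m (zero before contact)."""
    z_c = curve.z[contact] if z_contact is None else z_contact
    delta = curve.z - z_c
    if not rigid:
        if k is None or k <= 0:
            raise ValueError("spring constant k required unless rigid=True")
        delta = delta - curve.force / k
    delta = np.clip(delta, 0.0, None)
    delta[:contact] = 0.0
    dwell = curve.indices("dwell")
    if dwell.size and rigid_dwell:
        delta[dwell] = delta[dwell[0]]
    return delta


def build_indentation_history(
    curve: ForceCurve,
    contact: int,
    k: float | None,
    geom_table: ShapeFunctionTable,
    rigid: bool = False,
    rigid_dwell: bool = True,
    z_contact: float | None = None,
) -> StrainHistory:
    """Area-dilation history alpha(t) from piezo position and deflection.

    Indentation delta(t) = (z - z_contact) - force/k; with ``rigid`` the
    deflection term is dropped (infinitely stiff cantilever).  During a
    dwell the piezo is stationary, so under the rigid-dwell approximation
    delta is held at its dwell-entry value; otherwise it varies through the
    measured deflection.  Times are referenced to the contact sample and
    alpha is zero before contact.  ``z_contact`` overrides the sample
    height with a sub-sample refined estimate.
    """
    delta = _indentation(curve, contact, k, rigid, rigid_dwell, z_contact)
    if delta.max() > geom_table.z_max * (1 + 1e-9):
        raise ValueError(
            f"indentation {delta.max():.3e} m exceeds the shape-table range "
            f"{geom_table.z_max:.3e} m; rebuild the table deeper"
        )
    _, alpha = evaluate(geom_table, np.minimum(delta, geom_table.z_max))
    # start one sample before contact so the history opens at alpha = 0
    # even when a sub-sample z_contact puts strain on the contact sample
    start = max(contact - 1, 0)
    t = curve.t - curve.t[contact]
    return StrainHistory(t=t[start:], alpha=alpha[start:])


def _fit_window(curve: ForceCurve, contact: int, options: FitOptions) -> np.ndarray:
    approach = curve.indices("approach")
    window = approach[approach >= contact]
    dwell = curve.indices("dwell")
    retract = curve.indices("retract")
    if dwell.size and options.fit_dwell:
        window = np.concatenate([window, dwell])
    elif retract.size:
        n_ret = max(1, int(round(options.retract_fraction * retract.size)))
        window = np.concatenate([window, retract[:n_ret]])
    setpoint = curve.metadata.get("setpoint")
    if setpoint is not None and np.isfinite(setpoint) and setpoint > 0:
        window = window[curve.force[window] <= setpoint * options.setpoint_guard]
    return window


def fit_capsule_model(
    curve: ForceCurve,
    geom_table: ShapeFunctionTable,
    options: FitOptions | None = None,
    contact: int | None = None,
    preprocess: bool = True,
) -> FitResult:
    """Fit (sigma0, KA0, beta) to one curve by multi-start least squares.

    The indentation history is built once from the measured curve; the
    optimizer varies only the three rheological parameters inside bounds
    (moduli non-negative, beta in [0, 1)).  Starting points cycle beta
    through ``beta_starts`` with KA0 log-spaced and sigma0 seeded from the
    low-indentation force; the best residual wins, with near-ties (relative
    difference below ``tie_break_rtol``) resolved toward smaller beta.
    """
    options = options or FitOptions()
    if preprocess:
        curve = baseline_correct(
            curve, options.baseline_fraction, options.remove_oscillation
        )
    if contact is None:
        contact = find_contact_point(curve, options.threshold_sigmas, options.run_length)

    k = curve.metadata.get("k")
    rigid = options.rigid_cantilever or k is None or not np.isfinite(k)
    z_c = refine_contact_z(curve, contact)
    history = build_indentation_history(
        curve, contact, k, geom_table, rigid=rigid,
        rigid_dwell=options.rigid_dwell, z_contact=z_c,
    )
    delta = _indentation(curve, contact, k, rigid, options.rigid_dwell, z_contact=z_c)

    window = _fit_window(curve, contact, options)
    R1 = geom_table.geometry.R1
    g_win, _ = evaluate(geom_table, delta[window])
    t_win = curve.t[window] - curve.t[contact]
    f_meas = curve.force[window]

    # nondimensionalize so the optimizer's tolerances see O(1) numbers
    f_scale = max(float(np.max(np.abs(f_meas))), 1e-12)

    def model(theta: np.ndarray) -> np.ndarray:
        params = RheologyParams(sigma0=theta[0], KA0=theta[1], beta=theta[2])
        sigma = hereditary_tension(params, history, t_win)
        return 2.0 * np.pi * g_win * R1 * sigma

    def residual(theta: np.ndarray) -> np.ndarray:
        return (model(theta) - f_meas) / f_scale

    # sigma0 seed from the low-indentation force, where K_A barely acts
    early = window[: max(5, window.size // 20)]
    g_early, _ = evaluate(geom_table, delta[early])
    ok = g_early > 1e-6
    sigma0_seed = (
        float(np.median(curve.force[early][ok] / (2 * np.pi * g_early[ok] * R1)))
        if ok.any() else 1e-3
    )
    sigma0_seed = min(max(sigma0_seed, 1e-5), 0.1)

    lo, hi = options.ka0_start_range
    ka_starts = np.logspace(np.log10(lo), np.log10(hi), options.n_starts)
    beta_cycle = [options.beta_starts[i % len(options.beta_starts)]
                  for i in range(options.n_starts)]
    bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, 0.999])

    candidates = []
    for ka0, b0 in zip(ka_starts, beta_cycle):
        x0 = np.array([sigma0_seed, ka0, b0])
        try:
            sol = least_squares(
                residual, x0, bounds=bounds, method="trf",
                x_scale=[1e-3, 0.05, 0.3], max_nfev=options.max_nfev,
                ftol=1e-12, xtol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if sol.success and np.all(np.isfinite(sol.x)):
            rms = float(np.sqrt(np.mean(sol.fun**2))) * f_scale
            candidates.append((rms, sol.x))

    if not candidates:
        return FitResult(
            params=RheologyParams(sigma0_seed, lo, 0.5),
            window=window, residual_rms=np.inf, n_starts=options.n_starts,
            converged=False, contact_index=contact, contact_z=float(curve.z[contact]),
        )

    best_rms = min(c[0] for c in candidates)
    tol = best_rms * (1 + options.tie_break_rtol) + 1e-30
    tied = [c for c in candidates if c[0] <= tol]
    rms, x = min(tied, key=lambda c: c[1][2])  # smaller beta wins ties
    params = RheologyParams(sigma0=float(x[0]), KA0=float(x[1]), beta=float(min(x[2], 0.999)))
    return FitResult(
        params=params, window=window, residual_rms=rms,
        n_starts=options.n_starts, converged=True,
        contact_index=contact, contact_z=z_c,
    )
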