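"""Synthetic AFM experiments with the statistical structure the analysis assumes.

Force curves are generated forward from the capsule models (hereditary
power-law tension, optionally with an elastic membrane term in parallel)
under a trapezoidal piezo protocol, with Gaussian sensor noise, an optional
periodic baseline artifact (as imprinted by thin elastomer substrates) and
an optional adhesion dip on retraction.  Cell populations are drawn so that
(beta, KA0) pairs scatter around a line beta = a - m * log10(KA0), with a
condition arm whose KA0 is multiplied by an excess-area exhaustion factor
xi^-1 at unchanged beta — the structure the scaling analyses are designed
to detect.

Every generator is deterministic under a fixed seed, which is recorded in
the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import ForceCurve
from .geometry import CapsuleGeometry, Probe, ShapeFunctionTable, build_shape_table, evaluate
from .rheology import (
    MembraneCortexParams,
    RheologyParams,
    StrainHistory,
    hereditary_tension,
    membrane_cortex_tension,
)

__all__ = [
    "Protocol",
    "NoiseModel",
    "PopulationModel",
    "SyntheticConfig",
    "default_geometry",
    "simulate_force_curve",
    "simulate_population",
    "simulate_bead_field",
]

#: colloidal probe radius, m ("6.62 um-sized" spheres read as diameter)
DEFAULT_PROBE_RADIUS = 3.31e-6


@dataclass(frozen=True)
class Protocol:
    """Piezo protocol: approach at v_approach to depth delta_max, optional
    dwell at constant piezo position, retract at v_retract."""

    v_approach: float = 2e-6  # m/s (monolayer-stretcher default)
    v_retract: float = 2e-6  # m/s
    delta_max: float = 2e-6  # m, piezo travel past contact
    dwell_s: float = 0.0
    sample_hz: float = 200.0
    setpoint: float | None = 5e-9  # N, recorded in metadata
    k: float | None = None  # cantilever spring constant, N/m; None = rigid
    #: approach travel before contact, m; None = 1.2 * delta_max so the
    #: pre-contact segment dominates the approach for baseline estimation
    pre_contact: float | None = None

    @property
    def pre_travel(self) -> float:
        return self.pre_contact if self.pre_contact is not None else 1.2 * self.delta_max


@dataclass(frozen=True)
class NoiseModel:
    force_sd: float = 0.0  # N, Gaussian sensor noise
    baseline_amp: float = 0.0  # N, sinusoidal baseline artifact
    baseline_hz: float = 30.0
    adhesion_depth: float = 0.0  # N, retraction dip depth
    adhesion_width: float = 0.2e-6  # m, dip width in z


@dataclass(frozen=True)
class PopulationModel:
    """Noisy line beta = a - m log10(KA0) with a condition-arm KA0 shift."""

    a: float = 0.21
    m: float = 0.30
    scatter_sd: float = 0.05
    log10_ka0_range: tuple[float, float] = (-2.3, -0.7)  # 0.005 .. 0.2 N/m
    n_cells: int = 100
    xi_inv: float = 1.0
    sigma0_median: float = 1e-3  # N/m
    sigma0_log_sd: float = 0.3  # lognormal width


@dataclass
class SyntheticConfig:
    rheology: RheologyParams | MembraneCortexParams = field(
        default_factory=lambda: RheologyParams(sigma0=5e-4, KA0=0.05, beta=0.6)
    )
    geometry: CapsuleGeometry | None = None
    protocol: Protocol = field(default_factory=Protocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    population: PopulationModel = field(default_factory=PopulationModel)
    seed: int = 0


def default_geometry(R1: float = 12e-6) -> CapsuleGeometry:
    """Hemispherical cap indented by the default colloidal sphere."""
    return CapsuleGeometry(R1=R1, probe=Probe("sphere", R_p=DEFAULT_PROBE_RADIUS))


def _tension(rheo, history: StrainHistory, t: np.ndarray) -> np.ndarray:
    if isinstance(rheo, MembraneCortexParams):
        return membrane_cortex_tension(rheo, history, t)
    return hereditary_tension(rheo, history, t)


def _solve_compliant(
    t: np.ndarray,
    z: np.ndarray,
    k: float,
    table: ShapeFunctionTable,
    R1: float,
    rheo,
) -> np.ndarray:
    """Force with cantilever compliance: delta = z - f/k solved causally.

    At each sample the strain history before it is already fixed, so the
    hereditary tension splits into a frozen part plus the last-segment
    contribution, and delta_i solves the monotone scalar equation
    delta + f(delta)/k = z by Brent's method.  This avoids the whole-curve
    fixed point, which loses contractivity when the cell's force gradient
    approaches the spring constant.
    """
    from scipy.optimize import brentq

    if isinstance(rheo, MembraneCortexParams):
        sigma0, K0, beta, t0, kmem = rheo.sigma0, rheo.KAcort0, rheo.beta, rheo.t0, rheo.KAmem
    else:
        sigma0, K0, beta, t0, kmem = rheo.sigma0, rheo.KA0, rheo.beta, rheo.t0, 0.0
    one_m_b = 1.0 - beta
    C = K0 * t0**beta / one_m_b

    n = t.size
    alpha = np.zeros(n)
    force = np.zeros(n)
    slopes = np.zeros(n)  # slopes[j] covers segment (t[j-1], t[j])

    for i in range(1, n):
        ti = t[i]
        if i > 1:
            d1 = (ti - t[: i - 1]) ** one_m_b
            d2 = (ti - t[1:i]) ** one_m_b
            frozen = C * float(np.sum(slopes[1:i] * (d1 - d2)))
        else:
            frozen = 0.0
        dt_last = ti - t[i - 1]
        w_last = C * dt_last ** (-beta)  # multiplies (alpha_i - alpha_{i-1})

        def net_force(delta_i: float) -> float:
            g, a = evaluate(table, min(max(delta_i, 0.0), table.z_max))
            sigma = sigma0 + frozen + w_last * (a - alpha[i - 1]) + kmem * a
            return 2.0 * np.pi * g * R1 * sigma

        zi = z[i]
        if zi <= 0.0:
            delta_i = 0.0
        else:
            hi = min(zi, table.z_max)

            def residual(delta_i: float) -> float:
                return delta_i + net_force(delta_i) / k - zi

            if residual(hi) <= 0.0:
                delta_i = hi  # tension non-positive: cantilever not loaded
            else:
                delta_i = brentq(residual, 0.0, hi, xtol=1e-16, rtol=8.9e-16)
        _, alpha[i] = evaluate(table, min(delta_i, table.z_max))
        force[i] = net_force(delta_i)
        slopes[i] = (alpha[i] - alpha[i - 1]) / dt_last
    return force


def simulate_force_curve(
    config: SyntheticConfig,
    table: ShapeFunctionTable | None = None,
    rng: np.random.Generator | None = None,
) -> ForceCurve:
    """One synthetic indentation / relaxation / retraction curve.

    The piezo trajectory is a trapezoid; the indentation follows
    delta = z - f/k (solved by fixed-point iteration when the cantilever is
    compliant, exact for a rigid one), the tension from the configured
    constitutive model and the force from f = 2 pi g_cap R1 sigma.
    Noise and artifacts are added last, so the noiseless force is exactly
    the forward model.
    """
    rng = rng or np.random.default_rng(config.seed)
    geom = config.geometry or default_geometry()
    p = config.protocol
    if table is None:
        table = build_shape_table(geom, p.delta_max * 1.05, n=200)
    if p.delta_max > table.z_max:
        raise ValueError("delta_max outside the shape-table range")

    dt = 1.0 / p.sample_hz
    t_app = (p.pre_travel + p.delta_max) / p.v_approach
    t_ret = (p.pre_travel + p.delta_max) / p.v_retract
    n_app = int(round(t_app / dt))
    n_dwell = int(round(p.dwell_s / dt))
    n_ret = int(round(t_ret / dt))
    t = np.arange(n_app + n_dwell + n_ret) * dt

    z = np.empty_like(t)
    z[:n_app] = -p.pre_travel + p.v_approach * t[:n_app]
    z_top = -p.pre_travel + p.v_approach * n_app * dt
    z[n_app : n_app + n_dwell] = z_top
    t_ret0 = t[n_app + n_dwell] if n_ret else 0.0
    z[n_app + n_dwell :] = z_top - p.v_retract * (t[n_app + n_dwell :] - t_ret0)

    phase = np.empty(t.size, dtype=object)
    phase[:n_app] = "approach"
    phase[n_app : n_app + n_dwell] = "dwell"
    phase[n_app + n_dwell :] = "retract"

    def forward(delta: np.ndarray) -> np.ndarray:
        delta = np.clip(delta, 0.0, table.z_max)
        g, alpha = evaluate(table, delta)
        history = StrainHistory(t=t, alpha=alpha)
        sigma = _tension(config.rheology, history, t)
        return 2.0 * np.pi * g * geom.R1 * sigma

    if p.k is None:
        force = forward(np.clip(z, 0.0, None))
    else:
        force = _solve_compliant(t, z, p.k, table, geom.R1, config.rheology)

    noise = config.noise
    if noise.baseline_amp:
        force = force + noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_hz * t)
    if noise.adhesion_depth:
        ret = phase == "retract"
        dip = noise.adhesion_depth * np.exp(-0.5 * (z[ret] / noise.adhesion_width) ** 2)
        force[ret] = force[ret] - dip
    if noise.force_sd:
        force = force + rng.normal(0.0, noise.force_sd, size=t.size)

    rheo = config.rheology
    meta = {
        "k": p.k if p.k is not None else np.inf,
        "v_approach": p.v_approach,
        "v_retract": p.v_retract,
        "setpoint": p.setpoint if p.setpoint is not None else np.nan,
        "seed": config.seed,
        "R1": geom.R1,
        "true_sigma0": rheo.sigma0,
        "true_beta": rheo.beta,
        "true_KA0": rheo.KA0 if isinstance(rheo, RheologyParams) else rheo.KAcort0,
    }
    return ForceCurve(t=t, z=z, force=force, phase=phase, metadata=meta)


def simulate_population(
    config: SyntheticConfig,
    table: ShapeFunctionTable | None = None,
    emit_curves: bool = False,
) -> tuple[pd.DataFrame, list[ForceCurve] | None]:
    """Paired reference/condition cell populations on the beta-log(KA0) line.

    Returns a DataFrame with one row per cell and condition
    (columns: cell, condition, sigma0, KA0, beta) and, with
    ``emit_curves``, the per-cell reference-arm force curves.
    """
    pop = config.population
    if pop.n_cells < 10:
        raise ValueError("population needs at least 10 cells")
    rng = np.random.default_rng(config.seed)

    log_k = rng.uniform(*pop.log10_ka0_range, size=pop.n_cells)
    beta_raw = pop.a - pop.m * log_k + rng.normal(0.0, pop.scatter_sd, pop.n_cells)
    beta = np.clip(beta_raw, 0.05, 0.95)
    n_clipped = int(np.sum(beta != beta_raw))
    if n_clipped > 0.2 * pop.n_cells:
        warnings.warn(
            f"{n_clipped}/{pop.n_cells} beta values clipped to [0.05, 0.95]; "
            "scatter or line parameters push outside the physical range"
        )
    sigma0 = pop.sigma0_median * np.exp(rng.normal(0.0, pop.sigma0_log_sd, pop.n_cells))

    ref = pd.DataFrame(
        {
            "cell": np.arange(pop.n_cells),
            "condition": "reference",
            "sigma0": sigma0,
            "KA0": 10.0**log_k,
            "beta": beta,
        }
    )
    cond = ref.assign(condition="condition", KA0=ref["KA0"] * pop.xi_inv)
    records = pd.concat([ref, cond], ignore_index=True)

    curves = None
    if emit_curves:
        curves = []
        for _, row in ref.iterrows():
            cell_cfg = replace(
                config,
                rheology=RheologyParams(
                    sigma0=float(row.sigma0), KA0=float(row.KA0), beta=float(row.beta)
                ),
                seed=int((config.seed + 1) * 100003 + row.cell) % (2**31),
            )
            curves.append(simulate_force_curve(cell_cfg, table=table))
    return records, curves


def simulate_bead_field(
    strain_long: float,
    strain_lat: float,
    n: int = 50,
    jitter: float = 0.0,
    seed: int = 0,
    box: float = 100e-6,
    min_spacing: float = 5e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fiducial bead positions before and during substrate stretch.

    Beads are placed uniformly in a square of side ``box`` with a minimum
    pairwise spacing (distinct bead clusters resolve only when separated by
    roughly a bead diameter); the stretched positions are an affine scaling
    (1+strain_long in x, 1+strain_lat in y) plus Gaussian jitter of scale
    ``jitter`` (m).  Returns (pre, during) as (n, 2) arrays in meters.
    """
    if n < 4:
        raise ValueError("need at least 4 beads")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise ValueError("cannot place beads: box too small for min_spacing")
        cand = rng.uniform(0.0, box, size=2)
        if all(np.hypot(*(cand - q)) >= min_spacing for q in placed):
            placed.append(cand)
    pre = np.asarray(placed)
    scale = np.array([1.0 + strain_long, 1.0 + strain_lat])
    during = pre * scale + rng.normal(0.0, jitter, size=(n, 2))
    return pre, during
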