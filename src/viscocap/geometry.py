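"""Capsule shape function for tension-dominated indentation.

The cell is idealised as a liquid-filled spherical cap of apical radius R1,
pinned at its base circle (focal adhesions) and held at constant volume.
A rigid probe (colloidal sphere, cone, or flat punch) indents the apex; the
surface splits into a probe-conforming contact zone and a free zone that is
approximated as a spherical segment meeting the pinned base.  For each
indentation depth the free-surface radius follows from root-finding on the
enclosed-volume constraint.

At fixed tension the force follows from virtual work at constant volume,
f = sigma * dA/dz, written in the dimensionless form

    f = 2 pi g_cap(z~) R1 sigma,      z~ = z / R1,

so the shape function is g_cap = (dA/dz) / (2 pi R1) and the area dilation
alpha(z~) = (A - A0)/A0 feeds the viscoelastic tension model.  Both are
dimensionless functions of z~ and the shape ratios only; they are tabulated
once per geometry and interpolated monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "Probe",
    "CapsuleGeometry",
    "CapsuleConfiguration",
    "ShapeFunctionTable",
    "solve_configuration",
    "build_shape_table",
    "evaluate",
    "write_shape_table",
    "read_shape_table",
]

_BRENT_XTOL = 1e-14


@dataclass(frozen=True)
class Probe:
    """Indenter geometry: sphere (radius m), cone (half-angle rad) or flat punch."""

    kind: str  # "sphere" | "cone" | "flat"
    R_p: float | None = None
    half_angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "sphere":
            if self.R_p is None or self.R_p <= 0:
                raise ValueError("sphere probe requires positive R_p")
        elif self.kind == "cone":
            if self.half_angle is None or not 0 < self.half_angle < np.pi / 2:
                raise ValueError("cone probe requires half_angle in (0, pi/2)")
        elif self.kind != "flat":
            raise ValueError(f"unknown probe kind {self.kind!r}")


@dataclass(frozen=True)
class CapsuleGeometry:
    """Spherical-cap cell of apical radius R1 (m) pinned at contact angle theta_c."""

    R1: float
    probe: Probe
    theta_c: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.R1 <= 0:
            raise ValueError("R1 must be positive")
        if not 0 < self.theta_c <= np.pi / 2:
            raise ValueError("theta_c must lie in (0, pi/2]")

    # reduced (units of R1) quantities ------------------------------------
    @property
    def base_radius(self) -> float:
        return float(np.sin(self.theta_c))

    @property
    def cap_height(self) -> float:
        """Apex height above the base plane, units of R1."""
        return float(1.0 - np.cos(self.theta_c))

    @property
    def cap_volume(self) -> float:
        h = self.cap_height
        return np.pi * h * h * (3.0 - h) / 3.0

    @property
    def cap_area(self) -> float:
        return 2.0 * np.pi * self.cap_height

    @property
    def V0(self) -> float:
        """Enclosed volume of the undeformed cap, m^3."""
        return self.cap_volume * self.R1**3


@dataclass(frozen=True)
class CapsuleConfiguration:
    """Solved deformed shape at one depth; lengths in units of R1."""

    z_tilde: float
    r_contact: float  # contact-circle radius
    z_contact: float  # contact-circle height above the base plane
    R_free: float  # free spherical-segment radius
    zc_free: float  # free-segment centre height
    area: float  # total apical area (contact + free), units R1^2
    area_contact: float
    volume: float  # enclosed volume, units R1^3


def _slab_volume(R: float, zc: float, z1: float, z2: float) -> float:
    """Volume of revolution of the sphere (centre zc, radius R) slices z1..z2."""
    return np.pi * (R * R * (z2 - z1) - ((z2 - zc) ** 3 - (z1 - zc) ** 3) / 3.0)


def _free_sphere(a: float, r_cc: float, z_cc: float) -> tuple[float, float]:
    """Sphere through the base circle (a, 0) and contact circle (r_cc, z_cc)."""
    if z_cc <= 0:
        raise ValueError("contact circle below the base plane")
    zc = (r_cc * r_cc + z_cc * z_cc - a * a) / (2.0 * z_cc)
    R2 = float(np.hypot(a, zc))
    return R2, zc


def _configuration(geom: CapsuleGeometry, z_tilde: float, x: float) -> CapsuleConfiguration:
    """Shape for trial contact parameter x (probe-dependent meaning)."""
    a = geom.base_radius
    z_apex = geom.cap_height - z_tilde
    probe = geom.probe
    if probe.kind == "sphere":
        rho = probe.R_p / geom.R1
        phi = x
        r_cc = rho * np.sin(phi)
        z_cc = z_apex + rho * (1.0 - np.cos(phi))
        area_contact = 2.0 * np.pi * rho * rho * (1.0 - np.cos(phi))
        zp = z_apex + rho
        dimple = _slab_volume(rho, zp, z_apex, z_cc)
    elif probe.kind == "cone":
        r_cc = x
        z_cc = z_apex + r_cc / np.tan(probe.half_angle)
        area_contact = np.pi * r_cc * r_cc / np.sin(probe.half_angle)
        dimple = np.pi * (z_cc - z_apex) ** 3 * np.tan(probe.half_angle) ** 2 / 3.0
    else:  # flat punch
        r_cc = x
        z_cc = z_apex
        area_contact = np.pi * r_cc * r_cc
        dimple = 0.0

    R2, zc = _free_sphere(a, r_cc, z_cc)
    volume = _slab_volume(R2, zc, 0.0, z_cc) - dimple
    area = area_contact + 2.0 * np.pi * R2 * z_cc
    return CapsuleConfiguration(
        z_tilde=z_tilde, r_contact=r_cc, z_contact=z_cc, R_free=R2, zc_free=zc,
        area=area, area_contact=area_contact, volume=volume,
    )


def solve_configuration(geom: CapsuleGeometry, z_tilde: float) -> CapsuleConfiguration:
    """Volume-conserving deformed configuration at reduced depth z_tilde.

    The contact extent (probe wrap angle or contact radius) is the single
    unknown; it is bracketed by a scan and solved by Brent's method on the
    constant-volume constraint.  All shape functionals are closed-form, so
    the volume residual is limited only by the root tolerance.
    """
    if z_tilde < 0:
        raise ValueError("z_tilde must be non-negative")
    if z_tilde >= geom.cap_height:
        raise ValueError(
            f"z_tilde={z_tilde:.4g} reaches the base plane (cap height "
            f"{geom.cap_height:.4g}); probe too deep"
        )
    if z_tilde == 0.0:
        a = geom.base_radius
        return CapsuleConfiguration(
            z_tilde=0.0, r_contact=0.0, z_contact=geom.cap_height,
            R_free=1.0, zc_free=(geom.cap_height**2 - a * a) / (2 * geom.cap_height),
            area=geom.cap_area, area_contact=0.0, volume=geom.cap_volume,
        )

    if geom.probe.kind == "sphere":
        x_hi = np.pi * 0.999
    else:
        x_hi = geom.base_radius * 0.999

    V0 = geom.cap_volume

    def residual(x: float) -> float:
        return _configuration(geom, z_tilde, x).volume - V0

    # bracket: residual < 0 at tiny contact (flattened cap loses volume)
    xs = np.linspace(1e-9, x_hi, 200)
    lo = xs[0]
    f_lo = residual(lo)
    hi = None
    for x in xs[1:]:
        try:
            f_x = residual(x)
        except ValueError:
            break
        if np.sign(f_x) != np.sign(f_lo):
            hi = x
            break
        lo, f_lo = x, f_x
    if hi is None:
        raise ValueError(
            f"no volume-conserving configuration at z_tilde={z_tilde:.4g}; "
            "probe too deep for this capsule"
        )
    x_root = brentq(residual, lo, hi, xtol=_BRENT_XTOL, rtol=8.9e-16)
    return _configuration(geom, z_tilde, x_root)


@dataclass
class ShapeFunctionTable:
    """Tabulated shape function g_cap(z~) and area dilation alpha(z~)."""

    z_tilde: np.ndarray
    g: np.ndarray
    alpha: np.ndarray
    geometry: CapsuleGeometry

    def __post_init__(self) -> None:
        self.z_tilde = np.asarray(self.z_tilde, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self._g_interp = PchipInterpolator(self.z_tilde, self.g)
        self._a_interp = PchipInterpolator(self.z_tilde, self.alpha)

    @property
    def z_max(self) -> float:
        """Maximum tabulated depth, m."""
        return float(self.z_tilde[-1] * self.geometry.R1)


def build_shape_table(
    geom: CapsuleGeometry,
    z_max: float,
    n: int = 200,
) -> ShapeFunctionTable:
    """Tabulate g_cap and alpha on n nodes over depths [0, z_max] (m).

    alpha is referenced to the apical cap area (the basal disc is constant
    and drops out of dA/dz).  g_cap is obtained by centred differencing of
    the area on a half-step refined stencil, so 2 pi g_cap R1 sigma equals
    the virtual-work force sigma dA/dz at constant volume.
    """
    zt_max = z_max / geom.R1
    if not 0 < zt_max < geom.cap_height:
        raise ValueError("z_max must be positive and below the cap height")
    if n < 50:
        raise ValueError("need at least 50 grid nodes")

    zt = np.linspace(0.0, zt_max, n)
    A0 = geom.cap_area
    h = min(zt[1] / 4.0, 1e-3)

    g = np.empty(n)
    alpha = np.empty(n)
    g[0] = 0.0
    alpha[0] = 0.0
    for i, z in enumerate(zt[1:], start=1):
        alpha[i] = (solve_configuration(geom, z).area - A0) / A0
        a_plus = solve_configuration(geom, z + h / 2).area
        a_minus = solve_configuration(geom, z - h / 2).area
        g[i] = (a_plus - a_minus) / h / (2.0 * np.pi)
    return ShapeFunctionTable(z_tilde=zt, g=g, alpha=alpha, geometry=geom)


def evaluate(table: ShapeFunctionTable, z: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(g_cap, alpha) at depth z (m) by monotone-cubic interpolation.

    Exact at table nodes; raises for depths outside the tabulated range
    (no extrapolation).
    """
    zt = np.asarray(z, dtype=float) / table.geometry.R1
    if np.any(zt < table.z_tilde[0] - 1e-12) or np.any(zt > table.z_tilde[-1] + 1e-12):
        raise ValueError(
            f"depth outside tabulated range [0, {table.z_max:.3e} m]; "
            "rebuild the table with a larger z_max"
        )
    zt = np.clip(zt, table.z_tilde[0], table.z_tilde[-1])
    return table._g_interp(zt), table._a_interp(zt)


# ----------------------------------------------------------------------
# text serialization: tab-separated (z~, g, alpha) with a geometry header

def write_shape_table(table: ShapeFunctionTable, path: str | Path) -> None:
    geom = table.geometry
    lines = [
        f"# R1: {geom.R1!r}",
        f"# theta_c: {geom.theta_c!r}",
        f"# probe_kind: {geom.probe.kind}",
    ]
    if geom.probe.R_p is not None:
        lines.append(f"# probe_R_p: {geom.probe.R_p!r}")
    if geom.probe.half_angle is not None:
        lines.append(f"# probe_half_angle: {geom.probe.half_angle!r}")
    lines.append("z_tilde\tg_cap\talpha")
    for z, g, a in zip(table.z_tilde, table.g, table.alpha):
        lines.append(f"{z:.16e}\t{g:.16e}\t{a:.16e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shape_table(path: str | Path) -> ShapeFunctionTable:
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("z_tilde"):
            rows.append([float(v) for v in line.split("\t")])
    data = np.asarray(rows)
    probe = Probe(
        kind=meta["probe_kind"],
        R_p=float(meta["probe_R_p"]) if "probe_R_p" in meta else None,
        half_angle=float(meta["probe_half_angle"]) if "probe_half_angle" in meta else None,
    )
    geom = CapsuleGeometry(R1=float(meta["R1"]), probe=probe, theta_c=float(meta["theta_c"]))
    return ShapeFunctionTable(z_tilde=data[:, 0], g=data[:, 1], alpha=data[:, 2], geometry=geom)
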