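"""Force-curve container and the tab-separated text dialect.

A curve is the sampled record of one indentation experiment: time, piezo
position and force, with each sample labelled by protocol phase (approach,
optional dwell at constant piezo position, retract).  The text format is
tab-separated columns ``t[s]  z[m]  force[N]`` preceded by ``# key: value``
header lines carrying the cantilever spring constant, velocities, setpoint
and phase boundaries; the writer emits the identical dialect the reader
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["ForceCurve", "read_force_curve", "write_force_curve"]

PHASES = ("approach", "dwell", "retract")


@dataclass
class ForceCurve:
    """Sampled (t, z_piezo, force) with per-sample phase labels.

    ``z`` is the piezo extension toward the sample (m), increasing during
    approach.  ``force`` is the cantilever force (N).  Phases must be
    contiguous in the order approach -> [dwell] -> retract.
    """

    t: np.ndarray
    z: np.ndarray
    force: np.ndarray
    phase: np.ndarray  # array of str labels from PHASES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.t.size
        if not (self.z.size == self.force.size == self.phase.size == n):
            raise ValueError("t, z, force and phase must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")
        seen = [p for p in PHASES if np.any(self.phase == p)]
        # contiguity: each present phase occupies one run, in protocol order
        runs = []
        for i, p in enumerate(self.phase):
            if not runs or runs[-1][0] != p:
                runs.append([p, i])
        if [r[0] for r in runs] != seen:
            raise ValueError("phases must be contiguous in approach->dwell->retract order")

    def indices(self, phase: str) -> np.ndarray:
        """Sample indices belonging to one phase."""
        return np.flatnonzero(self.phase == phase)

    def with_force(self, force: np.ndarray) -> "ForceCurve":
        return replace(self, force=np.asarray(force, dtype=float))


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    lines = []
    for key, val in curve.metadata.items():
        lines.append(f"# {key}: {val}")
    bounds = []
    for p in PHASES:
        idx = curve.indices(p)
        if idx.size:
            bounds.append(f"{p}:{idx[0]}-{idx[-1]}")
    lines.append(f"# phases: {','.join(bounds)}")
    lines.append("t\tz\tforce")
    for t, z, f in zip(curve.t, curve.z, curve.force):
        lines.append(f"{t:.9e}\t{z:.9e}\t{f:.9e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_force_curve(path: str | Path) -> ForceCurve:
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line and not line.startswith("t\t"):
            rows.append([float(v) for v in line.split("\t")])
    data = np.asarray(rows)
    phase = np.empty(len(data), dtype=object)
    for chunk in meta.pop("phases").split(","):
        name, _, span = chunk.partition(":")
        lo, hi = (int(v) for v in span.split("-"))
        phase[lo : hi + 1] = name
    # numeric metadata back to float where possible
    parsed: dict[str, object] = {}
    for k, v in meta.items():
        try:
            parsed[k] = float(v)
        except ValueError:
            parsed[k] = v
    return ForceCurve(t=data[:, 0], z=data[:, 1], force=data[:, 2], phase=phase, metadata=parsed)
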