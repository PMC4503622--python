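"""Shape library: minimum-energy solutions over a (da, v) grid.

The grid convention is half-open on both axes, [start, stop) with a
fixed step, so the canonical survey da in [0.5, 1.6) x v in [0.6, 1.0)
at 0.01 steps enumerates exactly 110 x 40 = 4400 conditions (inclusive
stops would give 111 x 41 = 4551).

Within each v row the grid is traversed in ascending da with
continuation: every condition is warm-started from the converged
neighbor with the nearest smaller da, falling back to the full
multi-start search.  Budded shapes are hard to reach from a sphere
directly, which is why continuation ascends da.  Conditions that cannot
be met — deep stomatocytes stop being star-shaped, extreme (v, da)
pairs are geometrically infeasible — are recorded in ``non_converged``
rather than silently skipped: the entry count always equals the grid
cardinality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import GeometricMeasures
from .minimize import (
    InfeasibleConstraintsError,
    OptimizerSettings,
    ShapeConstraints,
    ShapeSolution,
    minimize_shape,
)
from .shapes import SHPShape


class EmptyGridError(ValueError):
    """Grid specification enumerates no conditions."""


@dataclass(frozen=True)
class GridSpec:
    """Half-open (da, v) grid: values start, start+step, ... < stop."""

    da_start: float
    da_stop: float
    da_step: float
    v_start: float
    v_stop: float
    v_step: float

    def __post_init__(self):
        if self.da_step <= 0 or self.v_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.da_stop <= self.da_start or self.v_stop <= self.v_start:
            raise EmptyGridError("grid ranges must be non-empty")

    @staticmethod
    def _axis(start: float, stop: float, step: float) -> np.ndarray:
        # half-open [start, stop): count by ceiling so ranges that are not
        # an exact multiple of the step still include every value < stop
        n = int(np.ceil((stop - start) / step - 1e-9))
        vals = start + step * np.arange(n)
        vals = vals[vals < stop - 1e-9 * max(1.0, abs(stop))]
        return np.round(vals, 10)

    def da_values(self) -> np.ndarray:
        return self._axis(self.da_start, self.da_stop, self.da_step)

    def v_values(self) -> np.ndarray:
        return self._axis(self.v_start, self.v_stop, self.v_step)

    @property
    def cardinality(self) -> int:
        return len(self.da_values()) * len(self.v_values())


def _key(da: float, v: float) -> tuple[float, float]:
    return (round(float(da), 6), round(float(v), 6))


@dataclass
class ShapeLibrary:
    """Converged minimum-energy solutions indexed by (da, v)."""

    grid_spec: GridSpec
    entries: dict = field(default_factory=dict)
    non_converged: list = field(default_factory=list)
    settings: OptimizerSettings = field(default_factory=OptimizerSettings)

    def get(self, da: float, v: float) -> ShapeSolution:
        return self.entries[_key(da, v)]

    def converged_entries(self):
        return {k: s for k, s in self.entries.items() if s.converged}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        entries = []
        for (da, v), sol in sorted(self.entries.items()):
            rec = {
                "da": da,
                "v": v,
                "converged": sol.converged,
                "coefficients": None if sol.measures is None
                else list(map(float, sol.shape.coefficients)),
                "shape_class": sol.shape_class,
                "lobe_volume_ratio": sol.lobe_volume_ratio,
                "runner_up_energy": sol.runner_up_energy,
                "measures": sol.measures.as_dict() if sol.measures is not None else None,
            }
            entries.append(rec)
        return {
            "grid_spec": {
                "da_start": self.grid_spec.da_start, "da_stop": self.grid_spec.da_stop,
                "da_step": self.grid_spec.da_step, "v_start": self.grid_spec.v_start,
                "v_stop": self.grid_spec.v_stop, "v_step": self.grid_spec.v_step,
            },
            "settings": {
                "max_degree": self.settings.max_degree,
                "quadrature_order": self.settings.order(),
            },
            "entries": entries,
            "non_converged": [list(k) for k in self.non_converged],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "ShapeLibrary":
        data = json.loads(Path(path).read_text())
        gs = GridSpec(**data["grid_spec"])
        settings = OptimizerSettings(max_degree=data["settings"]["max_degree"])
        lib = cls(grid_spec=gs, settings=settings)
        for rec in data["entries"]:
            constraints = ShapeConstraints(rec["v"], rec["da"])
            if rec["coefficients"] is not None:
                shape = SHPShape(settings.max_degree, np.asarray(rec["coefficients"]))
                measures = GeometricMeasures(**rec["measures"])
            else:
                from .shapes import sphere_shape

                shape, measures = sphere_shape(1.0, settings.max_degree), None
            sol = ShapeSolution(
                shape=shape, measures=measures, constraints=constraints,
                converged=rec["converged"], shape_class=rec["shape_class"],
                lobe_volume_ratio=rec["lobe_volume_ratio"],
                runner_up_energy=rec["runner_up_energy"],
            )
            lib.entries[_key(rec["da"], rec["v"])] = sol
        lib.non_converged = [tuple(k) for k in data["non_converged"]]
        return lib


def build_library(
    grid_spec: GridSpec,
    settings: OptimizerSettings = OptimizerSettings(),
    progress: bool = False,
) -> ShapeLibrary:
    """Solve every grid condition with ascending-da continuation per v row.

    After repeated failures in a row (the deep-stomatocyte regime at low
    da), the expensive multi-start search is replaced by a single cheap
    attempt from a dimpled-sphere prototype until a condition converges
    again; every skipped or failed condition is recorded.
    """
    if grid_spec.cardinality == 0:
        raise EmptyGridError("grid enumerates no conditions")

    from . import starts as _starts

    lib = ShapeLibrary(grid_spec=grid_spec, settings=settings)
    L = settings.max_degree
    dimple = SHPShape(L, _starts.dimple_start(L, 0.5))

    for v in grid_spec.v_values():
        prev: ShapeSolution | None = None
        failure_streak = 0
        for da in grid_spec.da_values():
            v_f, da_f = float(v), float(da)
            try:
                cons = ShapeConstraints(v_f, da_f)
            except ValueError:
                lib.entries[_key(da_f, v_f)] = ShapeSolution(
                    shape=dimple, measures=None,
                    constraints=ShapeConstraints(min(v_f, 1.0), max(da_f, 1e-6)),
                    converged=False,
                )
                lib.non_converged.append(_key(da_f, v_f))
                continue
            try:
                if prev is not None:
                    sol = minimize_shape(cons, initial=prev.shape, settings=settings)
                elif failure_streak >= 2:
                    sol = minimize_shape(cons, initial=dimple, settings=settings)
                else:
                    sol = minimize_shape(cons, settings=settings)
            except InfeasibleConstraintsError:
                sol = ShapeSolution(shape=dimple, measures=None,
                                    constraints=cons, converged=False)
            lib.entries[_key(da_f, v_f)] = sol
            if sol.converged:
                prev = sol
                failure_streak = 0
            else:
                failure_streak += 1
                lib.non_converged.append(_key(da_f, v_f))
            if progress:
                status = sol.shape_class if sol.converged else "failed"
                print(f"  (da={da_f:.3f}, v={v_f:.3f}) -> {status}", flush=True)
    return lib


# -- exports ----------------------------------------------------------------


def solution_to_mesh(solution: ShapeSolution, n_theta: int = 96, n_phi: int = 64):
    """Triangulated surface-of-revolution mesh of a converged solution."""
    import trimesh

    from .classify import meridian_profile

    p = meridian_profile(solution.shape, n=n_theta)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    ring_x = np.outer(p.rho, np.cos(phi))
    ring_y = np.outer(p.rho, np.sin(phi))
    ring_z = np.repeat(p.z[:, None], n_phi, axis=1)
    verts = np.column_stack([ring_x.ravel(), ring_y.ravel(), ring_z.ravel()])
    a = solution.shape.coefficients
    north = np.array([[0.0, 0.0, float(np.sum(a))]])          # r at theta=0
    south = np.array([[0.0, 0.0, -float(np.sum(a * (-1.0) ** np.arange(len(a))))]])
    verts = np.vstack([north, verts, south])
    faces = []
    idx = lambda i, j: 1 + i * n_phi + (j % n_phi)
    for j in range(n_phi):
        faces.append([0, idx(0, j), idx(0, j + 1)])
    for i in range(n_theta - 1):
        for j in range(n_phi):
            faces.append([idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)])
            faces.append([idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)])
    last = len(verts) - 1
    for j in range(n_phi):
        faces.append([idx(n_theta - 1, j + 1), idx(n_theta - 1, j), last])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def export_ply(solution: ShapeSolution, path) -> None:
    solution_to_mesh(solution).export(str(path))


def export_profile_csv(solution: ShapeSolution, path, n: int = 512) -> None:
    """Meridian profile table (z, rho) of a converged solution."""
    import pandas as pd

    from .classify import meridian_profile

    p = meridian_profile(solution.shape, n=n)
    pd.DataFrame({"z": p.z, "rho": p.rho}).to_csv(path, index=False)
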