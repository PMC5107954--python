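"""VEGF concentration fields sampled at continuous positions.

The default environment is a spatially constant 20 ng/ml field; linear and
radial gradient families are provided as configurable variants, plus a
voxel-grid field (trilinear interpolation) for user-supplied concentration
maps.  Concentrations are evaluated analytically — no per-voxel storage for
the built-in kinds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, OutOfDomainError

CONSTANT = "constant"
LINEAR = "linear_gradient"
RADIAL = "radial_gradient"
VOXEL = "voxel_grid"


@dataclass
class VegfField:
    """Parametric VEGF field (ng/ml).

    ``constant`` returns ``base_concentration`` everywhere.  ``linear_gradient``
    interpolates from ``min_concentration`` at one domain face to
    ``max_concentration`` at the opposite face along ``gradient_axis``.
    ``radial_gradient`` is ``max_concentration`` at ``center`` decaying
    linearly to ``min_concentration`` at distance ``radial_extent``.
    """

    kind: str = CONSTANT
    base_concentration: float = 20.0
    gradient_axis: tuple = (1.0, 0.0, 0.0)
    min_concentration: float = 0.0
    max_concentration: float = 20.0
    center: Optional[tuple] = None
    radial_extent: Optional[float] = None
    # voxel-grid kind
    grid: Optional[np.ndarray] = None
    voxel_size: float = 10.0
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind not in (CONSTANT, LINEAR, RADIAL, VOXEL):
            raise ConfigurationError(f"vegf.kind: unknown field kind {self.kind!r}")
        if self.kind == CONSTANT and self.base_concentration < 0:
            raise ConfigurationError("vegf.base_concentration must be >= 0")
        if self.kind in (LINEAR, RADIAL):
            if self.min_concentration < 0 or self.max_concentration < 0:
                raise ConfigurationError("vegf concentrations must be >= 0")
        if self.kind == VOXEL and self.grid is None:
            raise ConfigurationError("vegf.grid required for voxel_grid kind")


def vegf_at(field: VegfField, position, domain) -> float:
    """Concentration (ng/ml) at an in-domain position.

    Raises ``OutOfDomainError`` outside the closed domain bounds.
    """
    p = np.asarray(position, dtype=float)
    domain = np.asarray(domain, dtype=float)
    if np.any(p < -1e-9) or np.any(p > domain + 1e-9):
        raise OutOfDomainError(f"position {p} outside domain {domain}")
    return float(vegf_samples(field, p[None, :], domain)[0])


def vegf_samples(field: VegfField, positions: np.ndarray, domain) -> np.ndarray:
    """Vectorized sampling; positions outside the domain read as 0 ng/ml.

    The zero value outside the tumor space is what tip-cell filopodia sense
    when probing across the boundary, disfavouring outward candidates.
    """
    P = np.asarray(positions, dtype=float)
    domain = np.asarray(domain, dtype=float)
    inside = np.all(P >= 0.0, axis=1) & np.all(P <= domain, axis=1)
    out = np.zeros(len(P))
    if field.kind == CONSTANT:
        out[inside] = field.base_concentration
    elif field.kind == LINEAR:
        axis = np.asarray(field.gradient_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        # fraction of the way from the min face to the max face
        span = float(domain @ np.abs(axis))
        s = (P @ axis - min(0.0, float(domain @ np.minimum(axis, 0.0)))) / span
        c = field.min_concentration + \
            (field.max_concentration - field.min_concentration) * np.clip(s, 0, 1)
        out[inside] = c[inside]
    elif field.kind == RADIAL:
        center = (np.asarray(field.center, dtype=float)
                  if field.center is not None else domain / 2.0)
        extent = (field.radial_extent if field.radial_extent is not None
                  else float(np.min(domain)) / 2.0)
        r = np.linalg.norm(P - center, axis=1)
        c = field.max_concentration - \
            (field.max_concentration - field.min_concentration) * \
            np.clip(r / extent, 0, 1)
        out[inside] = c[inside]
    else:  # VOXEL
        out[inside] = _trilinear(field, P[inside])
    return out


def _trilinear(field: VegfField, P: np.ndarray) -> np.ndarray:
    g = np.asarray(field.grid, dtype=float)
    v = float(field.voxel_size)
    o = np.asarray(field.origin, dtype=float)
    # sample positions in voxel-center coordinates
    x = (P - o) / v - 0.5
    x = np.clip(x, 0.0, np.array(g.shape) - 1.0 - 1e-12)
    i0 = np.floor(x).astype(int)
    f = x - i0
    i1 = np.minimum(i0 + 1, np.array(g.shape) - 1)
    c = np.zeros(len(P))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ii = np.where(dx, i1[:, 0], i0[:, 0])
                jj = np.where(dy, i1[:, 1], i0[:, 1])
                kk = np.where(dz, i1[:, 2], i0[:, 2])
                w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                     * np.where(dy, f[:, 1], 1 - f[:, 1])
                     * np.where(dz, f[:, 2], 1 - f[:, 2]))
                c += w * g[ii, jj, kk]
    return c


def load_voxel_field(array_path, sidecar_path=None) -> VegfField:
    """Load a user-supplied voxel VEGF field.

    ``array_path`` is a NumPy ``.npy`` file holding a 3D array of
    concentrations (ng/ml); the JSON sidecar (default: same stem + ``.json``)
    gives ``voxel_size`` (um) and ``origin`` (um).
    """
    array_path = Path(array_path)
    grid = np.load(array_path)
    if grid.ndim != 3:
        raise ConfigurationError("voxel VEGF array must be 3-dimensional")
    sidecar_path = (Path(sidecar_path) if sidecar_path is not None
                    else array_path.with_suffix(".json"))
    meta = json.loads(Path(sidecar_path).read_text())
    return VegfField(kind=VOXEL, grid=grid,
                     voxel_size=float(meta.get("voxel_size", 10.0)),
                     origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))))
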