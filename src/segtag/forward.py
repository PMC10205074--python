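"""Parametric quasi-dipolar toy forward model.

Stands in for an anatomical single-shell head model: sensors on a spherical
cap pick up the tangential field of current dipoles on a regular source
grid, with distance-decaying, orientation-dependent gain.  Ground-truth
geometry and labeled regions of interest (ROIs) make beamformer
localization testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ToyForwardModel", "make_forward_model"]


@dataclass
class ToyForwardModel:
    sensor_positions: np.ndarray     # (n_sensors, 3), cm
    source_positions: np.ndarray     # (n_sources, 3), cm, regular grid
    leadfield: np.ndarray            # (n_sensors, n_sources * 3)
    roi_labels: dict[str, np.ndarray]
    grid_spacing_cm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.leadfield)):
            raise ValueError("leadfield must be finite")
        norms = np.linalg.norm(self.leadfield.reshape(self.n_sensors, -1, 3), axis=(0, 2))
        if np.any(norms == 0):
            raise ValueError("every source must have a non-zero leadfield")
        for name, idx in self.roi_labels.items():
            if np.any(idx < 0) or np.any(idx >= self.n_sources):
                raise ValueError(f"ROI {name!r} has out-of-range source indices")

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]

    def leadfield_for(self, source: int) -> np.ndarray:
        """(n_sensors, 3) gain matrix of one source."""
        return self.leadfield[:, 3 * source:3 * source + 3]


def _fibonacci_cap(n: int, radius: float, z_min: float = 0.15) -> np.ndarray:
    """Quasi-uniform sensor positions on the upper spherical cap."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z ** 2)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _dipole_gain(src: np.ndarray, sensors: np.ndarray,
                 pickup: np.ndarray) -> np.ndarray:
    """(n_sensors, 3) gain of the three unit dipole orientations at ``src``.

    Field of orientation e at sensor i: (e x d) / |d|^3 projected onto the
    sensor pickup direction, d = sensor - source.
    """
    d = sensors - src                           # (n, 3)
    r3 = np.linalg.norm(d, axis=1) ** 3         # (n,)
    # (e_k x d_i) . p_i = e_k . (d_i x p_i)
    dxp = np.cross(d, pickup)                   # (n, 3)
    return dxp / r3[:, None]


def make_forward_model(n_sensors: int = 32, grid_shape: tuple[int, int, int] = (6, 6, 4),
                       seed: int = 0, grid_spacing_cm: float = 0.8,
                       sensor_radius_cm: float = 7.0,
                       grid_center_cm: tuple[float, float, float] = (0.0, 0.0, 1.0)
                       ) -> ToyForwardModel:
    """Build a toy MEG forward model with labeled ROIs.

    Sources lie on a regular ``grid_shape`` grid (spacing 0.8 cm by
    default) centered in the head; sensors sit on a spherical cap with
    slightly tilted (non-radial) pickup directions so no orientation is
    magnetically silent.  ROIs: ``auditory_left``/``auditory_right`` at the
    lateral extremes plus ``frontal`` and ``posterior`` control regions.
    """
    if n_sensors < 8:
        raise ValueError("need at least 8 sensors")
    if int(np.prod(grid_shape)) < 27:
        raise ValueError("grid must contain at least 27 sources")
    rng = np.random.default_rng(seed)

    sensors = _fibonacci_cap(n_sensors, sensor_radius_cm)
    sensors += rng.normal(scale=0.05, size=sensors.shape)  # placement jitter

    axes = [grid_spacing_cm * (np.arange(n) - (n - 1) / 2) + c
            for n, c in zip(grid_shape, grid_center_cm)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sources = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    dmin = np.min(np.linalg.norm(sensors[:, None] - sources[None], axis=2))
    if dmin < 0.5:
        raise ValueError("degenerate geometry: sensor and source nearly coincide")

    radial = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    tilt = rng.normal(scale=1.0, size=sensors.shape)
    tilt -= (tilt * radial).sum(1, keepdims=True) * radial
    tilt /= np.linalg.norm(tilt, axis=1, keepdims=True)
    pickup = radial + 0.5 * tilt
    pickup /= np.linalg.norm(pickup, axis=1, keepdims=True)

    lead = np.empty((n_sensors, sources.shape[0] * 3))
    for j, src in enumerate(sources):
        lead[:, 3 * j:3 * j + 3] = _dipole_gain(src, sensors, pickup)

    zc = grid_center_cm[2]
    centers = {
        "auditory_left": np.array([axes[0][0], 0.0, zc]),
        "auditory_right": np.array([axes[0][-1], 0.0, zc]),
        "frontal": np.array([0.0, axes[1][-1], zc]),
        "posterior": np.array([0.0, axes[1][0], zc]),
    }
    k = max(2, sources.shape[0] // 12)
    rois: dict[str, np.ndarray] = {}
    used: set[int] = set()
    for name, c in centers.items():
        order = np.argsort(np.linalg.norm(sources - c, axis=1), kind="stable")
        idx = [int(i) for i in order if int(i) not in used][:k]
        used.update(idx)
        rois[name] = np.array(sorted(idx))

    return ToyForwardModel(sensors, sources, lead, rois, grid_spacing_cm)
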