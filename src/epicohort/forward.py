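"""Source-to-sensor forward model for SEEG.

The gain from region j to sensor k is the sum over the region's mesh
vertices of vertex area divided by squared vertex-sensor distance,

    g[j, k] = sum_i  a_i / d_{i,k}^2 ,

with a_i the one-third-rule vertex area.  Dipole orientation is
deliberately ignored; no normalization is applied, so simulated SEEG
amplitudes are in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import ElectrodeSet, SurfaceMesh


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex area: one third of the area of all adjacent triangles.

    Isolated vertices get area 0; degenerate triangles contribute 0.
    The total equals the mesh surface area exactly.
    """
    tri_areas = mesh.triangle_areas()
    areas = np.zeros(mesh.n_vertices)
    for corner in range(3):
        np.add.at(areas, mesh.triangles[:, corner], tri_areas / 3.0)
    return areas


@dataclass
class GainMatrix:
    """Region-to-sensor gain (R x N, entries >= 0, units 1/mm^2)."""

    values: np.ndarray
    region_labels: list[str]
    sensor_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_labels), len(self.sensor_labels)):
            raise ValueError("gain shape must be (n_regions, n_sensors)")


def compute_gain(mesh: SurfaceMesh, sensors: ElectrodeSet,
                 region_labels: list[str] | None = None) -> GainMatrix:
    """Inverse-square distance gain, vertex-area weighted."""
    areas = vertex_areas(mesh)
    pos = sensors.positions                       # (N, 3)
    d2 = ((mesh.vertices[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    if np.any(d2 <= 0):
        raise ValueError("a sensor coincides with a mesh vertex (d = 0)")
    contrib = areas[:, None] / d2                 # (V, N)
    n_regions = int(mesh.region_of_vertex.max()) + 1
    values = np.zeros((n_regions, len(pos)))
    np.add.at(values, mesh.region_of_vertex, contrib)
    if region_labels is None:
        region_labels = [f"region-{i:03d}" for i in range(n_regions)]
    return GainMatrix(values, list(region_labels), sensors.labels)


def project_to_sensors(gain: GainMatrix | np.ndarray,
                       source: np.ndarray) -> np.ndarray:
    """Map source activity (R x T) to sensor time series (N x T)."""
    g = gain.values if isinstance(gain, GainMatrix) else np.asarray(gain)
    source = np.asarray(source)
    if source.ndim != 2 or source.shape[0] != g.shape[0]:
        raise ValueError(
            f"source must be (R={g.shape[0]}) x T, got {source.shape}")
    return g.T @ source


@dataclass
class BipolarMontage:
    """Adjacent-contact channel pairs, e.g. channel ``B1-2 = B1 - B2``."""

    pairs: list[tuple[str, str, str]]  # (channel label, positive, negative)

    @property
    def channel_labels(self) -> list[str]:
        return [p[0] for p in self.pairs]


def make_bipolar_montage(electrodes: ElectrodeSet) -> BipolarMontage:
    """All adjacent same-shaft pairs, deep-to-superficial."""
    pairs = []
    for shaft in electrodes.shafts:
        cs = electrodes.shaft_contacts(shaft)
        for a, b in zip(cs[:-1], cs[1:]):
            idx_b = b.label[len(shaft):]
            pairs.append((f"{a.label}-{idx_b}", a.label, b.label))
    return BipolarMontage(pairs)


def bipolar(sensor_ts: np.ndarray, sensor_labels: list[str],
            montage: BipolarMontage) -> np.ndarray:
    """Form bipolar channels (positive minus negative contact)."""
    index = {lab: i for i, lab in enumerate(sensor_labels)}
    rows = []
    for _, pos_lab, neg_lab in montage.pairs:
        if pos_lab not in index or neg_lab not in index:
            raise KeyError(f"unknown contact in pair {pos_lab}-{neg_lab}")
        rows.append(sensor_ts[index[pos_lab]] - sensor_ts[index[neg_lab]])
    return np.array(rows)
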