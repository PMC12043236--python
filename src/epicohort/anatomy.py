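"""Synthetic structural scaffold of a virtual patient.

Generates the anatomy that a real pipeline would derive from T1-MRI,
DW-MRI and post-implantation CT: a region parcellation with per-region
surface meshes, a region-to-region connectome, and an SEEG electrode
implantation.  The geometry is deliberately simple (one small closed
sphere per region) because the forward model only consumes vertex
positions, vertex areas and the vertex-to-region assignment.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull


@dataclass
class RegionParcellation:
    """Named brain regions represented as point-like network nodes.

    Attributes
    ----------
    region_labels : list of str
        Unique region names.
    centers : ndarray, shape (R, 3)
        Region centers in mm.
    cortical_flag : ndarray of bool, shape (R,)
        Whether each region is cortical (subcortical regions use the
        same mesh representation).
    """

    region_labels: list[str]
    centers: np.ndarray
    cortical_flag: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.cortical_flag = np.asarray(self.cortical_flag, dtype=bool)
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if self.centers.shape != (self.n_regions, 3):
            raise ValueError("centers must have shape (R, 3)")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class SurfaceMesh:
    """Triangulated surface with a region assignment per vertex."""

    vertices: np.ndarray       # (V, 3) mm
    triangles: np.ndarray      # (T, 3) vertex indices
    region_of_vertex: np.ndarray  # (V,) region index

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.region_of_vertex = np.asarray(self.region_of_vertex, dtype=int)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        a = self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 1]]
        c = self.vertices[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class Connectome:
    """Region-to-region structural coupling weights.

    ``weights`` is symmetric with an exactly zero diagonal and is
    max-normalized so its largest entry equals one (the convention used
    for streamline-count matrices throughout).
    """

    weights: np.ndarray
    tract_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        self.weights = w
        if self.tract_lengths is not None:
            self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_raw(cls, raw: np.ndarray,
                 tract_lengths: np.ndarray | None = None) -> "Connectome":
        """Symmetrize, zero the diagonal, then max-normalize (in that order)."""
        w = np.asarray(raw, dtype=float)
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        m = w.max()
        if m > 0:
            w = w / m
        return cls(weights=w, tract_lengths=tract_lengths)


@dataclass
class Contact:
    label: str
    shaft: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class ElectrodeSet:
    """SEEG implantation: contacts grouped on straight shafts.

    Each shaft carries 10-18 point contacts at a constant 1.5 or 5 mm
    spacing; the 2 mm physical contact length is metadata only.
    """

    contacts: list[Contact] = field(default_factory=list)
    contact_length_mm: float = 2.0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.contacts]
        if len(set(labels)) != len(labels):
            raise ValueError("contact labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.contacts]

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.contacts])

    @property
    def shafts(self) -> list[str]:
        seen: list[str] = []
        for c in self.contacts:
            if c.shaft not in seen:
                seen.append(c.shaft)
        return seen

    def shaft_contacts(self, shaft: str) -> list[Contact]:
        return [c for c in self.contacts if c.shaft == shaft]

    def position_of(self, label: str) -> np.ndarray:
        for c in self.contacts:
            if c.label == label:
                return c.position
        raise KeyError(f"unknown contact label {label!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def generate_parcellation_geometry(
    n_regions: int = 162,
    vertices_per_region: int = 30,
    seed: int = 0,
    region_radius_mm: float = 4.0,
    brain_radius_mm: float = 60.0,
    subcortical_fraction: float = 0.11,
) -> tuple[RegionParcellation, SurfaceMesh]:
    """Generate a synthetic parcellation with one closed spherical patch
    per region.

    Region centers are drawn inside a ball of ``brain_radius_mm`` with a
    minimum pairwise separation; each region surface is the convex hull
    of ``vertices_per_region`` jittered points on a sphere of
    ``region_radius_mm`` around its center.  Pure function of
    (arguments, seed).
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if vertices_per_region < 4:
        raise ValueError("vertices_per_region must be >= 4 for a closed mesh")
    rng = np.random.default_rng(seed)

    min_sep = 2.2 * region_radius_mm
    centers = np.empty((n_regions, 3))
    placed = 0
    attempts = 0
    while placed < n_regions:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place region centers; "
                               "reduce n_regions or region_radius_mm")
        p = rng.uniform(-brain_radius_mm, brain_radius_mm, 3)
        if np.linalg.norm(p) > brain_radius_mm:
            continue
        if placed and (np.linalg.norm(centers[:placed] - p, axis=1) < min_sep).any():
            continue
        centers[placed] = p
        placed += 1

    # innermost regions flagged subcortical
    n_sub = int(round(subcortical_fraction * n_regions))
    depth_order = np.argsort(np.linalg.norm(centers, axis=1))
    cortical = np.ones(n_regions, dtype=bool)
    cortical[depth_order[:n_sub]] = False

    labels = [f"region-{i:03d}" for i in range(n_regions)]

    verts, tris, rov = [], [], []
    base = _fibonacci_sphere(vertices_per_region)
    offset = 0
    for j in range(n_regions):
        pts = base + rng.normal(0.0, 0.02, base.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = centers[j] + region_radius_mm * pts
        hull = ConvexHull(pts)  # closed triangulation; all points on hull
        verts.append(pts)
        tris.append(hull.simplices + offset)
        rov.append(np.full(len(pts), j))
        offset += len(pts)

    parc = RegionParcellation(labels, centers, cortical)
    mesh = SurfaceMesh(np.vstack(verts), np.vstack(tris), np.concatenate(rov))
    return parc, mesh


def generate_connectome(n_regions: int, density: float = 0.3,
                        seed: int = 0,
                        centers: np.ndarray | None = None) -> Connectome:
    """Random symmetric connectome emulating streamline counts.

    Off-diagonal magnitudes are log-normal (heavy-tailed, like streamline
    counts), sparsified to the requested expected ``density``, zeroed on
    the diagonal and max-normalized.  Optional ``centers`` give Euclidean
    tract lengths.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mag = rng.lognormal(mean=0.0, sigma=1.0, size=(n_regions, n_regions))
    mask = rng.random((n_regions, n_regions)) < density
    raw = np.triu(mag * mask, k=1)
    raw = raw + raw.T
    if raw.max() == 0:  # pathological draw at tiny R/density
        raw[0, 1] = raw[1, 0] = 1.0
    tl = None
    if centers is not None:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        tl = d
    return Connectome.from_raw(raw, tract_lengths=tl)


def generate_electrode_implantation(
    parcellation: RegionParcellation,
    n_shafts: int = 8,
    seed: int = 0,
    entry_radius_mm: float = 70.0,
) -> ElectrodeSet:
    """Straight SEEG shafts of 10-18 equidistant contacts aimed at
    random region centers.

    Contact 1 is the deepest (clinical convention); spacing is 1.5 mm
    for most shafts and 5 mm occasionally, mirroring the two clinical
    electrode models.
    """
    if n_shafts < 1:
        raise ValueError("n_shafts must be >= 1")
    if n_shafts > 26:
        raise ValueError("at most 26 shafts (single-letter naming)")
    rng = np.random.default_rng(seed)
    contacts: list[Contact] = []
    R = parcellation.n_regions
    for s in range(n_shafts):
        letter = string.ascii_uppercase[s]
        target = parcellation.centers[rng.integers(R)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        entry = target + entry_radius_mm * direction
        n_contacts = int(rng.integers(10, 19))
        spacing = 1.5 if rng.random() < 0.75 else 5.0
        unit = (entry - target) / np.linalg.norm(entry - target)
        # tip sits slightly past the target, contacts run back toward entry
        tip = target - 1.0 * unit + rng.normal(0.0, 0.5, 3)
        for k in range(n_contacts):
            pos = tip + spacing * k * unit
            contacts.append(Contact(f"{letter}{k + 1}", letter, pos))
    return ElectrodeSet(contacts=contacts)
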