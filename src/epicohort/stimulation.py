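"""Clinical SEEG stimulation: waveform and spatial field model.

A bipolar, charge-balanced biphasic pulse train is delivered between two
adjacent contacts (anode q+, cathode q-).  The contacts are treated as
point charges; the electric-field magnitude

    |E(r)| = | q / (4 pi eps) * ( (r - r+)/|r - r+|^3 - (r - r-)/|r - r-|^3 ) |

is evaluated at every mesh vertex, averaged per region with vertex-area
weights (mirroring the gain-matrix aggregation), and max-normalized to
give dimensionless per-region stimulus weights.  The Istim input to the
dynamics is the outer product of those weights with the pulse waveform,
times a scalar gain calibrated against a reference amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .anatomy import ElectrodeSet, SurfaceMesh
from .forward import vertex_areas


@dataclass
class StimulusSpec:
    """Clinical stimulation parameter set (one train)."""

    anode: str            # contact label, q+
    cathode: str          # contact label, q-
    frequency_hz: float   # 1 or 50 Hz clinically
    amplitude_ma: float   # 0.5-5 mA clinically
    pulse_width_ms: float  # per phase, 0.5-3 ms clinically
    duration_s: float
    onset_s: float = 0.0  # into the simulation

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.amplitude_ma <= 0:
            raise ValueError("amplitude must be positive")
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")
        if 2 * self.pulse_width_ms * self.frequency_hz > 1000.0:
            raise ValueError("biphasic pulses do not fit the pulse period")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FieldWeights:
    """Per-region stimulus weights in [0, 1] (max-normalized |E|)."""

    weights: np.ndarray
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")


def build_pulse_train(spec: StimulusSpec, dt: float) -> np.ndarray:
    """Biphasic pulse train sampled at ``dt`` ms over the train duration.

    Each pulse is a positive phase of ``pulse_width_ms`` immediately
    followed by an equal negative phase, repeated at ``frequency_hz``
    and scaled by ``amplitude_ma``; the total sum is exactly zero (zero
    net charge).
    """
    phase_samples = int(round(spec.pulse_width_ms / dt))
    if phase_samples < 1:
        raise ValueError("pulse width shorter than one integration step")
    period_samples = int(round(1000.0 / spec.frequency_hz / dt))
    n_pulses = int(round(spec.duration_s * spec.frequency_hz))
    n_total = int(round(spec.duration_s * 1000.0 / dt))
    wave = np.zeros(n_total)
    for p in range(n_pulses):
        start = p * period_samples
        pos = slice(start, min(start + phase_samples, n_total))
        neg = slice(start + phase_samples,
                    min(start + 2 * phase_samples, n_total))
        wave[pos] = spec.amplitude_ma
        wave[neg] = -spec.amplitude_ma
    return wave


def electric_field_magnitude(points: np.ndarray, pos_charge: np.ndarray,
                             neg_charge: np.ndarray, q: float = 1.0,
                             epsilon: float = 1.0) -> np.ndarray:
    """Point-source dipole field magnitude at each row of ``points``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dp = points - np.asarray(pos_charge, dtype=float)
    dn = points - np.asarray(neg_charge, dtype=float)
    rp = np.linalg.norm(dp, axis=1)
    rn = np.linalg.norm(dn, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        field = dp / rp[:, None] ** 3 - dn / rn[:, None] ** 3
    field *= q / (4.0 * np.pi * epsilon)
    mag = np.linalg.norm(field, axis=1)
    mag[(rp == 0) | (rn == 0)] = np.nan
    return mag


def field_weights(electrodes: ElectrodeSet, spec: StimulusSpec,
                  mesh: SurfaceMesh, epsilon: float = 1.0,
                  q: float | None = None,
                  normalize: bool = True) -> FieldWeights:
    """Area-weighted mean field magnitude per region, max-normalized.

    ``q`` defaults to the stimulus amplitude in mA (the absolute scale
    is arbitrary: the weights are normalized and the overall gain into
    the model is a separate calibrated scalar).  Vertices coinciding
    with a charge are excluded from the region mean.  With
    ``normalize=False`` the raw field magnitudes are returned, which is
    what a location sweep needs: there the scaling calibrated for the
    reference pair is held fixed, so a pair farther from any source
    region delivers a genuinely weaker dose.
    """
    r_pos = electrodes.position_of(spec.anode)
    r_neg = electrodes.position_of(spec.cathode)
    if q is None:
        q = spec.amplitude_ma
    mag = electric_field_magnitude(mesh.vertices, r_pos, r_neg, q, epsilon)
    areas = vertex_areas(mesh)
    n_regions = int(mesh.region_of_vertex.max()) + 1
    weights = np.zeros(n_regions)
    for j in range(n_regions):
        sel = mesh.region_of_vertex == j
        m = mag[sel]
        a = areas[sel]
        ok = np.isfinite(m)
        if not ok.any():
            raise ValueError(f"all evaluation points of region {j} "
                             "coincide with a charge")
        weights[j] = np.average(m[ok], weights=a[ok]) if a[ok].sum() > 0 \
            else m[ok].mean()
    if normalize:
        peak = weights.max()
        if peak > 0:
            weights = weights / peak
    return FieldWeights(weights=weights, epsilon=epsilon)


def istim_timecourse(weights: FieldWeights | np.ndarray,
                     waveform: np.ndarray) -> np.ndarray:
    """Outer product: region weights x waveform -> (R, T) Istim matrix."""
    w = weights.weights if isinstance(weights, FieldWeights) else np.asarray(weights)
    return np.outer(w, np.asarray(waveform, dtype=float))
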