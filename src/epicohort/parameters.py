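"""EZ hypotheses and their mapping onto model parameters.

The epileptogenic-zone (EZ) hypothesis assigns each region a normalized
epileptogenicity value ev in [0, 1]; it is the ground-truth parameter
object of every simulation.  Three affine maps translate ev into model
parameters, one per simulated condition:

* spontaneous seizures:  x0 = -2.2 + ev            (range [-2.2, -1.2])
* stimulated seizures:   x0 = -2.2 + 0.13 ev       (sub-critical,
  range [-2.2, -2.07]) and m_thresh = 10 - 9.5 ev  (range [10, 0.5],
  epileptogenic regions get the lower thresholds)
* interictal spikes:     x0 = -3 + 0.2 ev          (range [-3, -2.8])
  with Iext1 raised to 6.0 and additive noise for irregular spiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import INTERICTAL_NOISE

ZONE_CLASSES = ("EZ", "PZ", "HZ")


@dataclass
class EZHypothesis:
    """Per-region normalized epileptogenicity.

    ``zones`` optionally classifies regions as EZ (epileptogenic), PZ
    (propagation) or HZ (healthy); ``tag`` records provenance
    (VEPhypothesis / ClinicalHypothesis / Randomized).
    """

    ev: np.ndarray
    zones: list[str] | None = None
    tag: str = "VEPhypothesis"

    def __post_init__(self) -> None:
        self.ev = np.asarray(self.ev, dtype=float)
        if self.ev.ndim != 1:
            raise ValueError("ev must be a vector")
        if ((self.ev < 0) | (self.ev > 1)).any():
            raise ValueError("epileptogenicity values must lie in [0, 1]")
        if self.zones is not None:
            if len(self.zones) != len(self.ev):
                raise ValueError("zones length must match ev")
            bad = set(self.zones) - set(ZONE_CLASSES)
            if bad:
                raise ValueError(f"unknown zone classes: {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.ev)


def map_spontaneous(hypothesis: EZHypothesis) -> np.ndarray:
    """Excitability per region for the spontaneous-seizure condition."""
    return -2.2 + 1.0 * hypothesis.ev


def map_stimulated(hypothesis: EZHypothesis) -> tuple[np.ndarray, np.ndarray]:
    """(x0, m_thresh) per region for the stimulated-seizure condition.

    x0 stays sub-critical everywhere so that seizures arise only through
    stimulation; the seizure threshold decreases with epileptogenicity.
    """
    x0 = -2.2 + 0.13 * hypothesis.ev
    mthresh = 10.0 - 9.5 * hypothesis.ev
    return x0, mthresh


def map_interictal(hypothesis: EZHypothesis) -> tuple[np.ndarray, float, np.ndarray]:
    """(x0, Iext1, noise) for the interictal condition.

    Epileptogenic regions sit just below the (Iext1 = 6) seizure
    threshold, where stochastic forcing of the fast population produces
    frequent spikes; healthy regions are further from threshold and
    spike rarely.
    """
    x0 = -3.0 + 0.2 * hypothesis.ev
    return x0, 6.0, INTERICTAL_NOISE.copy()


def make_hypothesis(n_regions: int, n_ez: int = 2, n_pz: int = 3,
                    seed: int = 0, tag: str = "VEPhypothesis",
                    near: np.ndarray | None = None,
                    centers: np.ndarray | None = None) -> EZHypothesis:
    """Sparse synthetic EZ/PZ/HZ hypothesis.

    EZ regions get ev in [0.9, 1] (autonomously seizing under the
    spontaneous map), PZ regions ev in [0.05, 0.13] (sub-critical but
    elevated), HZ regions 0.  If ``near``/``centers`` are given, EZ
    regions are the ones closest to ``near``, emulating a focal EZ.
    """
    if n_ez + n_pz > n_regions:
        raise ValueError("n_ez + n_pz cannot exceed n_regions")
    rng = np.random.default_rng(seed)
    if near is not None and centers is not None:
        order = np.argsort(np.linalg.norm(centers - near, axis=1))
        picks = order[:n_ez + n_pz]
    else:
        picks = rng.choice(n_regions, size=n_ez + n_pz, replace=False)
    ev = np.zeros(n_regions)
    zones = ["HZ"] * n_regions
    for i in picks[:n_ez]:
        ev[i] = rng.uniform(0.9, 1.0)
        zones[i] = "EZ"
    for i in picks[n_ez:]:
        ev[i] = rng.uniform(0.05, 0.13)
        zones[i] = "PZ"
    return EZHypothesis(ev=ev, zones=zones, tag=tag)


def make_randomized_hypothesis(cohort: dict[str, EZHypothesis],
                               patient_id: str, n_draws: int = 3,
                               seed: int = 0) -> list[EZHypothesis]:
    """Draw EZ hypotheses from *other* patients of a cohort.

    Used to build the randomized control cohort: each draw replaces the
    patient's own hypothesis with another patient's, never its own.
    """
    if patient_id not in cohort:
        raise KeyError(f"unknown patient {patient_id!r}")
    others = [pid for pid in sorted(cohort) if pid != patient_id]
    if not others:
        raise ValueError("randomized cohort needs at least 2 patients")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_draws):
        donor = others[rng.integers(len(others))]
        h = cohort[donor]
        out.append(EZHypothesis(ev=h.ev.copy(), zones=list(h.zones or []) or None,
                                tag="Randomized"))
    return out
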