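"""Virtual-patient orchestration.

Builds complete synthetic patients (anatomy + connectome + implantation
+ gain + EZ hypothesis), runs the three simulation types (spontaneous
seizures, stimulation-induced seizures, interictal activity), sweeps
stimulation location and amplitude, and writes a BIDS-iEEG-style cohort
tree.  Every run derives its RNG seed from the patient seed and a run
counter (seed * 1000 + counter), so a whole cohort is reproducible from
one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .anatomy import (Connectome, ElectrodeSet, RegionParcellation,
                      SurfaceMesh, generate_connectome,
                      generate_electrode_implantation,
                      generate_parcellation_geometry)
from .dynamics import (EpileptorParameters, NetworkModelSpec, SimResult,
                       StimulationExtensionParameters, integrate)
from .evaluation import Recording, seizure_mask_of_recording
from .forward import (BipolarMontage, GainMatrix, bipolar, compute_gain,
                      make_bipolar_montage, project_to_sensors)
from .parameters import (EZHypothesis, make_hypothesis,
                         make_randomized_hypothesis, map_interictal,
                         map_spontaneous, map_stimulated)
from .stimulation import (FieldWeights, StimulusSpec, build_pulse_train,
                          field_weights)

SESSIONS = {"spontaneous": "ses-01", "stimulated": "ses-02",
            "interictal": "ses-03"}
#: output scale: model units -> microvolt-like arbitrary units
SEEG_SCALE = 100.0


@dataclass
class PatientBundle:
    """One virtual patient's structural scaffold and hypotheses."""

    patient_id: str
    parcellation: RegionParcellation
    mesh: SurfaceMesh
    connectome: Connectome
    electrodes: ElectrodeSet
    gain: GainMatrix
    montage: BipolarMontage
    hypotheses: dict[str, EZHypothesis]
    K: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        R = self.parcellation.n_regions
        if self.connectome.n_regions != R:
            raise ValueError("connectome size does not match parcellation")
        if self.gain.values.shape != (R, len(self.electrodes.contacts)):
            raise ValueError("gain shape must be (R, n_contacts)")

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions


@dataclass
class RunRecord:
    """One simulated recording plus everything needed to re-simulate it."""

    patient_id: str
    session: str
    task: str
    hypothesis_tag: str
    run_index: int
    seed: int
    seeg: Recording
    source: SimResult
    parameters: dict
    stimulus: StimulusSpec | None = None
    markers: list[tuple[str, str, int]] = field(default_factory=list)


def make_virtual_patient(patient_id: str = "sub-001", n_regions: int = 10,
                         vertices_per_region: int = 30, n_shafts: int = 4,
                         n_ez: int = 1, n_pz: int = 2, K: float = 1.0,
                         seed: int = 0,
                         ez_near_electrodes: bool = True) -> PatientBundle:
    """Build a complete synthetic patient.

    With ``ez_near_electrodes`` the EZ regions are those closest to the
    first shaft's deep contact, emulating an implantation that samples
    the epileptogenic zone (as clinical implantations are designed to).
    """
    parc, mesh = generate_parcellation_geometry(
        n_regions, vertices_per_region, seed=seed)
    conn = generate_connectome(n_regions, density=0.3, seed=seed + 1,
                               centers=parc.centers)
    elec = generate_electrode_implantation(parc, n_shafts, seed=seed + 2)
    gain = compute_gain(mesh, elec, parc.region_labels)
    montage = make_bipolar_montage(elec)
    near = elec.contacts[0].position if ez_near_electrodes else None
    hyp = make_hypothesis(n_regions, n_ez=n_ez, n_pz=n_pz, seed=seed + 3,
                          tag="VEPhypothesis", near=near,
                          centers=parc.centers)
    clin = make_hypothesis(n_regions, n_ez=n_ez, n_pz=n_pz, seed=seed + 4,
                           tag="ClinicalHypothesis", near=near,
                           centers=parc.centers)
    return PatientBundle(patient_id, parc, mesh, conn, elec, gain, montage,
                         {"VEPhypothesis": hyp, "ClinicalHypothesis": clin},
                         K=K, seed=seed)


def _seeg_from_source(bundle: PatientBundle, source: SimResult,
                      artifact: np.ndarray | None = None,
                      artifact_contacts: tuple[str, str] | None = None,
                      artifact_gain: float = 10.0) -> Recording:
    """Project source activity to bipolar SEEG channels."""
    monopolar = project_to_sensors(bundle.gain, source.source_signal())
    monopolar = SEEG_SCALE * monopolar
    if artifact is not None and artifact_contacts is not None:
        labels = bundle.electrodes.labels
        wave = artifact[:monopolar.shape[1]]
        for lab, sign in zip(artifact_contacts, (1.0, -1.0)):
            monopolar[labels.index(lab), :len(wave)] += \
                sign * artifact_gain * wave
    data = bipolar(monopolar, bundle.electrodes.labels, bundle.montage)
    return Recording(data, bundle.montage.channel_labels, source.fs)


def _seizure_markers(rec: Recording) -> list[tuple[str, str, int]]:
    """Model-derived seizure onset/offset markers (envelope detector)."""
    try:
        feat, _ = seizure_mask_of_recording(rec)
    except ValueError:
        return []
    if feat.flags is None or not feat.flags.any():
        return []
    onset = int(feat.onsets[feat.flags].min())
    offset = int(feat.offsets[feat.flags].max())
    return [("Comment", "seizure onset", onset + 1),
            ("Comment", "seizure offset", offset + 1)]


def run_spontaneous(bundle: PatientBundle,
                    hypothesis_tag: str = "VEPhypothesis",
                    duration_s: float = 60.0, seed: int = 0,
                    noise: float | np.ndarray = 0.0,
                    hypothesis: EZHypothesis | None = None,
                    run_index: int = 1) -> RunRecord:
    """Simulate a spontaneous seizure recording (session ses-01)."""
    hyp = hypothesis or bundle.hypotheses[hypothesis_tag]
    x0 = map_spontaneous(hyp)
    params = EpileptorParameters(x0=x0)
    spec = NetworkModelSpec(bundle.connectome, K=bundle.K, params=params,
                            noise=noise, seed=seed)
    source = integrate(spec, duration_s * 1000.0)
    seeg = _seeg_from_source(bundle, source)
    rec = RunRecord(
        bundle.patient_id, SESSIONS["spontaneous"], "spontaneous",
        hyp.tag, run_index, seed, seeg, source,
        parameters={"mode": "spontaneous", "x0": x0, "K": bundle.K,
                    "dt_ms": spec.dt, "noise": spec.noise_vector(),
                    "duration_s": duration_s, "seed": seed,
                    "ev": hyp.ev, "hypothesis_tag": hyp.tag},
        markers=_seizure_markers(seeg))
    return rec


def run_interictal(bundle: PatientBundle,
                   hypothesis_tag: str = "VEPhypothesis",
                   duration_s: float = 120.0, seed: int = 0,
                   noise: np.ndarray | None = None,
                   hypothesis: EZHypothesis | None = None,
                   run_index: int = 1) -> RunRecord:
    """Simulate interictal activity with spikes (session ses-03)."""
    hyp = hypothesis or bundle.hypotheses[hypothesis_tag]
    x0, iext1, default_noise = map_interictal(hyp)
    params = EpileptorParameters(x0=x0, Iext1=iext1)
    spec = NetworkModelSpec(bundle.connectome, K=bundle.K, params=params,
                            noise=default_noise if noise is None else noise,
                            seed=seed)
    source = integrate(spec, duration_s * 1000.0, burn_in_ms=30000.0)
    seeg = _seeg_from_source(bundle, source)
    return RunRecord(
        bundle.patient_id, SESSIONS["interictal"], "interictal",
        hyp.tag, run_index, seed, seeg, source,
        parameters={"mode": "interictal", "x0": x0, "Iext1": iext1,
                    "K": bundle.K, "dt_ms": spec.dt,
                    "noise": spec.noise_vector(),
                    "duration_s": duration_s, "seed": seed,
                    "ev": hyp.ev, "hypothesis_tag": hyp.tag})


def run_stimulated(bundle: PatientBundle, stimulus: StimulusSpec,
                   hypothesis_tag: str = "VEPhypothesis",
                   duration_s: float = 40.0, seed: int = 0,
                   stim_scale: float = 1.0,
                   noise: float | np.ndarray = 0.0,
                   hypothesis: EZHypothesis | None = None,
                   run_index: int = 1,
                   field_reference: StimulusSpec | None = None) -> RunRecord:
    """Simulate a stimulation run (session ses-02).

    The stimulus waveform (scaled by the calibrated ``stim_scale``) is
    weighted across regions by the electric-field model and drives the
    7D Epileptor-stimulation network.  The raw waveform is added to the
    two stimulating contacts as a visible artifact.

    ``field_reference`` pins the field normalization to another
    (reference) contact pair: the per-region weights are then raw field
    magnitudes divided by the reference pair's maximum, so moving the
    stimulation away from the sources weakens the delivered dose
    instead of being silently re-normalized.  Location sweeps use this.
    """
    hyp = hypothesis or bundle.hypotheses[hypothesis_tag]
    x0, mthresh = map_stimulated(hyp)
    params = EpileptorParameters(x0=x0)
    stim_params = StimulationExtensionParameters(mthresh=mthresh)
    # finer step: the deep-ictal stimulated regime is stiffer than the
    # spontaneous one (see dynamics z_floor note)
    spec = NetworkModelSpec(bundle.connectome, K=bundle.K, params=params,
                            stim_params=stim_params, noise=noise, seed=seed,
                            dt=0.02)
    if field_reference is None:
        weights = field_weights(bundle.electrodes, stimulus, bundle.mesh)
    else:
        raw = field_weights(bundle.electrodes, stimulus, bundle.mesh,
                            q=1.0, normalize=False)
        ref_raw = field_weights(bundle.electrodes, field_reference,
                                bundle.mesh, q=1.0, normalize=False)
        weights = FieldWeights(raw.weights / ref_raw.weights.max())
    n_steps = int(round(duration_s * 1000.0 / spec.dt))
    wave = np.zeros(n_steps)
    train = stim_scale * build_pulse_train(stimulus, spec.dt)
    i0 = int(round(stimulus.onset_s * 1000.0 / spec.dt))
    i1 = min(i0 + len(train), n_steps)
    wave[i0:i1] = train[:i1 - i0]
    source = integrate(spec, duration_s * 1000.0,
                       stimulus=(weights.weights, wave), record_every=50)
    artifact = wave[::source.record_every]
    seeg = _seeg_from_source(bundle, source, artifact=artifact,
                             artifact_contacts=(stimulus.anode,
                                                stimulus.cathode))
    fs = source.fs
    stim_off = stimulus.onset_s + stimulus.duration_s
    markers = [("Stimulus", "stim on", int(stimulus.onset_s * fs) + 1),
               ("Stimulus", "stim off", int(stim_off * fs) + 1)]
    return RunRecord(
        bundle.patient_id, SESSIONS["stimulated"], "stimulated",
        hyp.tag, run_index, seed, seeg, source,
        parameters={"mode": "stimulated", "x0": x0, "mthresh": mthresh,
                    "K": bundle.K, "dt_ms": spec.dt,
                    "noise": spec.noise_vector(), "duration_s": duration_s,
                    "seed": seed, "ev": hyp.ev, "hypothesis_tag": hyp.tag,
                    "stim_scale": stim_scale,
                    "stimulus": stimulus.to_dict(),
                    "field_weights": weights.weights},
        stimulus=stimulus, markers=markers)


def induced_seizure(record: RunRecord, x1_ptp_threshold: float = 2.0) -> bool:
    """Did a seizure follow the stimulus?

    True when any region's x1 swings through a full down/up excursion
    (peak-to-peak above ``x1_ptp_threshold``) after stimulus offset.
    """
    if record.stimulus is None:
        raise ValueError("record carries no stimulus")
    fs = record.source.fs
    stop = record.stimulus.onset_s + record.stimulus.duration_s
    x1 = record.source.var("x1")[:, int(stop * fs):]
    return bool(np.ptp(x1, axis=1).max() > x1_ptp_threshold)


def calibrate_stim_scale(bundle: PatientBundle, stimulus: StimulusSpec,
                         hypothesis_tag: str = "VEPhypothesis",
                         duration_s: float = 30.0, seed: int = 0,
                         headroom: float = 1.2,
                         rel_tol: float = 0.1) -> float:
    """Calibrate the stimulus-to-model gain at the reference amplitude.

    Finds (by doubling and bisection) the minimal scale at which the
    reference stimulus induces a seizure, then returns it with a small
    ``headroom`` factor so the reference amplitude reliably induces
    while clearly weaker stimuli do not -- the same adjustment a
    modeler makes against the empirical stimulated seizure.
    """
    def induces(scale: float) -> bool:
        try:
            rec = run_stimulated(bundle, stimulus, hypothesis_tag,
                                 duration_s=duration_s, seed=seed,
                                 stim_scale=scale)
        except RuntimeError:
            # numerically overwhelming stimulus: certainly supra-threshold
            return True
        return induced_seizure(rec)

    lo, hi = 0.0, 1.0 / 64.0
    for _ in range(16):
        if induces(hi):
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError("stimulation fails to induce a seizure at any "
                           "tested scale; check the hypothesis/stimulus")
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if induces(mid):
            hi = mid
        else:
            lo = mid
    return headroom * hi


def sweep_stimulation_amplitude(bundle: PatientBundle,
                                reference: StimulusSpec,
                                amplitudes=(0.5, 1.0, 3.0, 4.0),
                                hypothesis_tag: str = "VEPhypothesis",
                                stim_scale: float = 1.0,
                                duration_s: float = 40.0,
                                seed: int = 0) -> list[RunRecord]:
    """One stimulated run per amplitude, everything else fixed."""
    if any(a <= 0 for a in amplitudes):
        raise ValueError("amplitudes must be positive")
    records = []
    for i, amp in enumerate(amplitudes):
        spec = StimulusSpec(reference.anode, reference.cathode,
                            reference.frequency_hz, amp,
                            reference.pulse_width_ms, reference.duration_s,
                            reference.onset_s)
        records.append(run_stimulated(bundle, spec, hypothesis_tag,
                                      duration_s=duration_s, seed=seed,
                                      stim_scale=stim_scale,
                                      run_index=i + 1))
    return records


DISTANCE_GROUPS = ("Dist1", "Dist2", "Dist3", "Dist4")


def group_pairs_by_distance(bundle: PatientBundle, reference: StimulusSpec
                            ) -> dict[str, list[tuple[str, str]]]:
    """Adjacent contact pairs grouped by midpoint distance (cm) from the
    reference pair midpoint: Dist1 <=1, Dist2 (1,2], Dist3 (2,3],
    Dist4 >3.  The reference pair itself is excluded."""
    ref_mid = 0.5 * (bundle.electrodes.position_of(reference.anode)
                     + bundle.electrodes.position_of(reference.cathode))
    groups: dict[str, list[tuple[str, str]]] = {g: [] for g in DISTANCE_GROUPS}
    for _, pos_lab, neg_lab in bundle.montage.pairs:
        if {pos_lab, neg_lab} == {reference.anode, reference.cathode}:
            continue
        mid = 0.5 * (bundle.electrodes.position_of(pos_lab)
                     + bundle.electrodes.position_of(neg_lab))
        d_cm = np.linalg.norm(mid - ref_mid) / 10.0
        if d_cm <= 1.0:
            groups["Dist1"].append((pos_lab, neg_lab))
        elif d_cm <= 2.0:
            groups["Dist2"].append((pos_lab, neg_lab))
        elif d_cm <= 3.0:
            groups["Dist3"].append((pos_lab, neg_lab))
        else:
            groups["Dist4"].append((pos_lab, neg_lab))
    return groups


def sweep_stimulation_location(bundle: PatientBundle,
                               reference: StimulusSpec,
                               n_per_group: int = 10,
                               hypothesis_tag: str = "VEPhypothesis",
                               stim_scale: float = 1.0,
                               duration_s: float = 40.0,
                               seed: int = 0
                               ) -> dict[str, list[RunRecord]]:
    """Up to ``n_per_group`` stimulation runs per distance group.

    Pairs are sampled without replacement within each group; empty
    groups yield empty lists (with a warning), so up to
    4 * n_per_group runs result.
    """
    import warnings
    rng = np.random.default_rng(seed)
    groups = group_pairs_by_distance(bundle, reference)
    out: dict[str, list[RunRecord]] = {}
    counter = 0
    for gname in DISTANCE_GROUPS:
        pairs = groups[gname]
        if not pairs:
            warnings.warn(f"no contact pairs in group {gname}")
            out[gname] = []
            continue
        take = min(n_per_group, len(pairs))
        picks = rng.choice(len(pairs), size=take, replace=False)
        recs = []
        for p in picks:
            counter += 1
            anode, cathode = pairs[p]
            spec = StimulusSpec(anode, cathode, reference.frequency_hz,
                                reference.amplitude_ma,
                                reference.pulse_width_ms,
                                reference.duration_s, reference.onset_s)
            recs.append(run_stimulated(bundle, spec, hypothesis_tag,
                                       duration_s=duration_s,
                                       seed=seed, stim_scale=stim_scale,
                                       run_index=counter,
                                       field_reference=reference))
        out[gname] = recs
    return out


# ---------------------------------------------------------------------------
# BIDS-iEEG style output
# ---------------------------------------------------------------------------

def write_bids(records: list[RunRecord], root, bundles=None) -> list[Path]:
    """Write a cohort tree of BrainVision runs plus derivatives.

    ``sub-XXX/ses-0N/ieeg/`` holds the BrainVision triplet and
    channels/electrodes TSVs per run; ``derivatives/sub-XXX/struct``
    and ``.../parameters`` hold the connectome zip, gain, hypothesis
    and the per-run parameter sidecar plus source-level series.
    Duplicate (patient, session, tag, run) combinations are an error.
    """
    root = Path(root)
    bundles = {b.patient_id: b for b in (bundles or [])}
    seen = set()
    written = []
    for rec in records:
        key = (rec.patient_id, rec.session, rec.hypothesis_tag, rec.run_index)
        if key in seen:
            raise ValueError(f"duplicate run {key}")
        seen.add(key)
        ieeg = root / rec.patient_id / rec.session / "ieeg"
        ieeg.mkdir(parents=True, exist_ok=True)
        stem = (f"{rec.patient_id}_{rec.session}_task-{rec.task}"
                f"_acq-{rec.hypothesis_tag}_run-{rec.run_index:02d}")
        cio.write_brainvision(ieeg / (stem + "_ieeg"), rec.seeg.data,
                              rec.seeg.fs, rec.seeg.channel_labels,
                              markers=rec.markers)
        bundle = bundles.get(rec.patient_id)
        if bundle is not None:
            pos = np.array([0.5 * (bundle.electrodes.position_of(p)
                                   + bundle.electrodes.position_of(n))
                            for _, p, n in bundle.montage.pairs])
            cio.write_channels_tsv(ieeg / (stem + "_channels.tsv"),
                                   rec.seeg.channel_labels, pos)
            cio.write_electrodes_tsv(ieeg / (stem + "_electrodes.tsv"),
                                     bundle.electrodes)
        deriv = root / "derivatives" / rec.patient_id
        params_dir = deriv / "parameters"
        params_dir.mkdir(parents=True, exist_ok=True)
        cio.write_json_sidecar(params_dir / (stem + "_parameters.json"),
                               rec.parameters)
        np.save(params_dir / (stem + "_source.npy"), rec.source.data)
        cio.write_json_sidecar(
            params_dir / (stem + "_source.json"),
            {"dt_ms": rec.source.dt, "record_every": rec.source.record_every,
             "fs": rec.source.fs, "variables": list(rec.source.variables)})
        if bundle is not None:
            struct = deriv / "struct"
            struct.mkdir(parents=True, exist_ok=True)
            zpath = struct / f"{rec.patient_id}_connectome.zip"
            if not zpath.exists():
                cio.write_connectome_zip(zpath, bundle.connectome,
                                         bundle.parcellation)
                cio.write_gain_tsv(struct / f"{rec.patient_id}_gain.tsv",
                                   bundle.gain)
            hyp = bundle.hypotheses.get(rec.hypothesis_tag)
            if hyp is not None:
                cio.write_hypothesis_tsv(
                    params_dir / f"{rec.patient_id}_{rec.hypothesis_tag}.tsv",
                    bundle.parcellation.region_labels, hyp)
        written.append(ieeg / (stem + "_ieeg.vhdr"))
    return written


# ---------------------------------------------------------------------------
# study helpers (the in-silico experiments)
# ---------------------------------------------------------------------------

def make_stimulation_patient(seed: int = 0, n_regions: int = 10,
                             n_shafts: int = 4) -> tuple[PatientBundle,
                                                         StimulusSpec]:
    """Synthetic patient for the stimulation studies.

    One region with ev = 1 sits next to the first shaft's deep
    contacts; the reference stimulus is applied through that shaft's
    two deepest contacts at 50 Hz, 2 mA, 1 ms pulse width, 4 s -- the
    typical clinical high-frequency protocol.
    """
    bundle = make_virtual_patient("sub-001", n_regions=n_regions,
                                  n_shafts=n_shafts, n_ez=1, n_pz=2,
                                  seed=seed, ez_near_electrodes=True)
    hyp = bundle.hypotheses["VEPhypothesis"]
    ez_idx = int(np.argmax(hyp.ev))
    ev = hyp.ev.copy()
    ev[ez_idx] = 1.0
    bundle.hypotheses["VEPhypothesis"] = EZHypothesis(
        ev=ev, zones=hyp.zones, tag=hyp.tag)
    shaft = bundle.electrodes.shafts[0]
    c1, c2 = bundle.electrodes.shaft_contacts(shaft)[:2]
    reference = StimulusSpec(anode=c1.label, cathode=c2.label,
                             frequency_hz=50.0, amplitude_ma=2.0,
                             pulse_width_ms=1.0, duration_s=4.0,
                             onset_s=5.0)
    return bundle, reference


def amplitude_study(seed: int = 0, amplitudes=(0.5, 1.0, 2.0, 3.0, 4.0),
                    duration_s: float = 30.0) -> dict:
    """Seizure induction across stimulation amplitudes.

    Calibrates the stimulus gain at the 2 mA reference, then runs each
    amplitude and reports the induced-seizure indicator per amplitude.
    """
    bundle, reference = make_stimulation_patient(seed)
    scale = calibrate_stim_scale(bundle, reference, duration_s=duration_s,
                                 seed=bundle.seed * 1000 + 1)
    records = sweep_stimulation_amplitude(
        bundle, reference, amplitudes=amplitudes, stim_scale=scale,
        duration_s=duration_s, seed=bundle.seed * 1000 + 2)
    induced = [induced_seizure(r) for r in records]
    return {"amplitudes_ma": list(amplitudes), "induced": induced,
            "stim_scale": scale, "records": records}


def location_study(seed: int = 0, n_per_group: int = 3,
                   duration_s: float = 30.0) -> dict:
    """Mask correlation against the reference run across distance groups.

    The reference stimulation run (pseudo-empirical) is compared to
    runs stimulated at pairs increasingly far from the reference pair;
    reported is the mean mask correlation per distance group.
    """
    from .evaluation import compare_recordings
    bundle, reference = make_stimulation_patient(seed)
    scale = calibrate_stim_scale(bundle, reference, duration_s=duration_s,
                                 seed=bundle.seed * 1000 + 1)
    ref_run = run_stimulated(bundle, reference, duration_s=duration_s,
                             seed=bundle.seed * 1000 + 2, stim_scale=scale)
    post = reference.onset_s + reference.duration_s
    sweeps = sweep_stimulation_location(
        bundle, reference, n_per_group=n_per_group, stim_scale=scale,
        duration_s=duration_s, seed=bundle.seed * 1000 + 3)
    means, counts = {}, {}
    for gname, recs in sweeps.items():
        vals = []
        for rec in recs:
            rep = compare_recordings(rec.seeg, ref_run.seeg,
                                     post_stimulus_s=post)
            vals.append(rep.correlation)
        means[gname] = float(np.mean(vals)) if vals else np.nan
        counts[gname] = len(vals)
    return {"mean_correlation": means, "counts": counts,
            "stim_scale": scale, "records": sweeps, "reference": ref_run}


def vec_rc_study(n_patients: int = 5, n_rc_draws: int = 3, seed: int = 0,
                 duration_s: float = 60.0,
                 noise: float = 0.01, n_perm: int = 200000) -> dict:
    """Personalized (VEC) vs randomized (RC) cohort separation.

    For each synthetic patient a noisy simulation serves as
    pseudo-empirical reference; a re-simulation with the same EZ
    hypothesis (different noise realization) forms the VEC group and
    simulations with hypotheses drawn from other patients form the RC
    group.  Mask correlations against the reference are compared with
    the one-sided permutation test (H1: mean(VEC) > mean(RC)).
    """
    from .evaluation import compare_recordings, permutation_test
    noise_vec = np.array([0.0, 0.0, noise, noise, 0.0, 0.0])
    bundles = [make_virtual_patient(f"sub-{i + 1:03d}", seed=seed + 10 * i)
               for i in range(n_patients)]
    cohort = {b.patient_id: b.hypotheses["VEPhypothesis"] for b in bundles}
    vec_scores, rc_scores = [], []
    for i, bundle in enumerate(bundles):
        base = bundle.seed * 1000
        emp = run_spontaneous(bundle, duration_s=duration_s, seed=base + 1,
                              noise=noise_vec)
        vec = run_spontaneous(bundle, duration_s=duration_s, seed=base + 2,
                              noise=noise_vec)
        vec_scores.append(_mask_corr_or_zero(vec, emp))
        draws = make_randomized_hypothesis(cohort, bundle.patient_id,
                                           n_draws=n_rc_draws, seed=base + 3)
        for j, rand_hyp in enumerate(draws):
            rc = run_spontaneous(bundle, duration_s=duration_s,
                                 seed=base + 4 + j, noise=noise_vec,
                                 hypothesis=rand_hyp)
            rc_scores.append(_mask_corr_or_zero(rc, emp))
    p = permutation_test(vec_scores, rc_scores, n_perm=n_perm, seed=seed)
    return {"vec": vec_scores, "rc": rc_scores,
            "mean_vec": float(np.mean(vec_scores)),
            "mean_rc": float(np.mean(rc_scores)), "p_value": p}


def _mask_corr_or_zero(sim: RunRecord, emp: RunRecord) -> float:
    from .evaluation import compare_recordings
    return compare_recordings(sim.seeg, emp.seeg).correlation
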