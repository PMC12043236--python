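"""Virtual-patient runs, sweeps and BIDS output."""

import numpy as np
import pytest
from click.testing import CliRunner

import epicohort as ec
from epicohort.cli import main as cli_main
from epicohort.evaluation import detect_spikes
from epicohort.io import ParseError, read_brainvision, read_connectome_zip
from epicohort.parameters import EZHypothesis


def test_patient_bundle_is_consistent(patient):
    assert patient.n_regions == 10
    assert patient.gain.values.shape == (10, len(patient.electrodes.contacts))
    assert patient.connectome.weights.max() == 1.0
    # EZ regions sit near the first shaft (implantation samples the EZ)
    hyp = patient.hypotheses["VEPhypothesis"]
    ez = int(np.argmax(hyp.ev))
    d = np.linalg.norm(patient.parcellation.centers
                       - patient.electrodes.contacts[0].position, axis=1)
    assert d[ez] == d.min()


def test_spontaneous_run_basics(patient, spontaneous_run):
    rec = spontaneous_run
    assert rec.session == "ses-01"
    assert rec.seeg.n_channels == len(patient.montage.pairs)
    assert rec.seeg.fs == pytest.approx(1000.0)
    # the EZ-driven seizure is visible: seizure markers were produced
    assert any("seizure" in m[1] for m in rec.markers)


def test_spontaneous_run_reproducible(patient, spontaneous_run):
    again = ec.run_spontaneous(patient, duration_s=20.0, seed=11)
    assert np.array_equal(again.seeg.data, spontaneous_run.seeg.data)


def test_all_healthy_hypothesis_stays_subcritical(patient):
    quiet = EZHypothesis(ev=np.zeros(10))
    rec = ec.run_spontaneous(patient, hypothesis=quiet, duration_s=20.0, seed=3)
    x1 = rec.source.var("x1")
    assert np.ptp(x1, axis=1).max() < 0.5  # no seizure oscillation anywhere


def test_interictal_quiet_without_noise_or_excitability(patient):
    quiet = EZHypothesis(ev=np.zeros(10))
    rec = ec.run_interictal(patient, hypothesis=quiet, duration_s=30.0,
                            seed=3, noise=np.zeros(6))
    counts = [len(detect_spikes(rec.seeg.data[i], rec.seeg.fs))
              for i in range(rec.seeg.n_channels)]
    assert sum(counts) == 0


def test_interictal_spikes_cluster_near_epileptogenic_regions(patient,
                                                              interictal_run):
    rec = interictal_run
    hyp = patient.hypotheses["VEPhypothesis"]
    counts = np.array([len(detect_spikes(rec.seeg.data[i], rec.seeg.fs))
                       for i in range(rec.seeg.n_channels)])
    assert counts.sum() > 0
    # per-channel epileptogenicity exposure: ev-weighted share of the
    # bipolar gain
    labels = patient.electrodes.labels
    gains = np.array([np.abs(patient.gain.values[:, labels.index(p)]
                             - patient.gain.values[:, labels.index(n)])
                      for _, p, n in patient.montage.pairs])
    share = (gains * hyp.ev).sum(axis=1) / gains.sum(axis=1)
    own = np.corrcoef(counts, share)[0, 1]
    rng = np.random.default_rng(5)
    shuffled = [np.corrcoef(counts,
                            (gains * rng.permutation(hyp.ev)).sum(1)
                            / gains.sum(1))[0, 1] for _ in range(20)]
    assert own > np.mean(shuffled)
    assert own > 0.5


def test_stimulated_run_and_istim_window(patient):
    bundle, reference = ec.make_stimulation_patient(seed=0)
    scale = ec.calibrate_stim_scale(bundle, reference, seed=1)
    rec = ec.run_stimulated(bundle, reference, duration_s=20.0, seed=2,
                            stim_scale=scale)
    assert rec.session == "ses-02"
    m = rec.source.var("m")
    fs = rec.source.fs
    pre = m[:, :int(reference.onset_s * fs) - 1]
    assert np.abs(pre).max() == 0.0          # m accumulates only under stimulus
    assert m.max() > 0.0
    assert any(mk[0] == "Stimulus" for mk in rec.markers)
    assert ec.induced_seizure(rec)


def test_amplitude_sweep_reference_amplitude_reproduces(patient):
    bundle, reference = ec.make_stimulation_patient(seed=0)
    recs = ec.sweep_stimulation_amplitude(
        bundle, reference, amplitudes=(reference.amplitude_ma,),
        stim_scale=0.05, duration_s=15.0, seed=9)
    direct = ec.run_stimulated(bundle, reference, duration_s=15.0, seed=9,
                               stim_scale=0.05)
    assert np.array_equal(recs[0].seeg.data, direct.seeg.data)


def test_location_groups_partition_pairs(patient):
    bundle, reference = ec.make_stimulation_patient(seed=0)
    groups = ec.cohort.group_pairs_by_distance(bundle, reference)
    all_pairs = [p for g in groups.values() for p in g]
    ref_pair = {reference.anode, reference.cathode}
    assert all(set(p) != ref_pair for p in all_pairs)
    assert len(all_pairs) == len(bundle.montage.pairs) - 1
    # interval membership: a pair whose midpoint sits 2.5 cm away is Dist3
    for pos, neg in groups["Dist3"]:
        mid = 0.5 * (bundle.electrodes.position_of(pos)
                     + bundle.electrodes.position_of(neg))
        ref_mid = 0.5 * (bundle.electrodes.position_of(reference.anode)
                         + bundle.electrodes.position_of(reference.cathode))
        assert 2.0 < np.linalg.norm(mid - ref_mid) / 10.0 <= 3.0


def test_write_bids_round_trip_and_run_numbering(tmp_path, patient,
                                                 spontaneous_run):
    run2 = ec.run_spontaneous(patient, duration_s=20.0, seed=12, run_index=2)
    paths = ec.write_bids([spontaneous_run, run2], tmp_path, bundles=[patient])
    assert "run-01" in paths[0].name and "run-02" in paths[1].name
    data, fs, labels, markers = read_brainvision(paths[0])
    assert np.array_equal(
        data, spontaneous_run.seeg.data.astype(np.float32).astype(float))
    assert labels == spontaneous_run.seeg.channel_labels
    assert fs == pytest.approx(1000.0)
    # structural sidecars round-trip
    conn, parc = read_connectome_zip(
        tmp_path / "derivatives" / "sub-001" / "struct" / "sub-001_connectome.zip")
    assert np.allclose(conn.weights, patient.connectome.weights)
    assert parc.region_labels == patient.parcellation.region_labels
    with pytest.raises(ValueError, match="duplicate"):
        ec.write_bids([spontaneous_run, spontaneous_run], tmp_path / "x")


def test_written_brainvision_opens_in_mne(tmp_path, patient, spontaneous_run):
    mne = pytest.importorskip("mne")
    paths = ec.write_bids([spontaneous_run], tmp_path, bundles=[patient])
    raw = mne.io.read_raw_brainvision(paths[0], preload=True, verbose="error")
    assert np.allclose(raw.get_data() * 1e6, spontaneous_run.seeg.data,
                       rtol=1e-5, atol=1e-3)


def test_connectome_zip_missing_weights_is_parse_error(tmp_path):
    import zipfile
    bad = tmp_path / "bad.zip"
    with zipfile.ZipFile(bad, "w") as zf:
        zf.writestr("centres.txt", "r0 0 0 0\nr1 1 1 1\n")
    with pytest.raises(ParseError, match="weights"):
        read_connectome_zip(bad)


def test_cli_fixtures_writes_struct_bundle(tmp_path):
    runner = CliRunner()
    result = runner.invoke(cli_main, ["fixtures", "--n-patients", "1",
                                      "--n-regions", "6", "--seed", "1",
                                      "--out", str(tmp_path)])
    assert result.exit_code == 0, result.output
    struct = tmp_path / "derivatives" / "sub-001" / "struct"
    assert (struct / "sub-001_connectome.zip").exists()
    assert (struct / "sub-001_gain.tsv").exists()
    assert (struct / "sub-001_electrodes.tsv").exists()
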