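"""File formats of the cohort.

Structural data uses the whitespace-delimited text tables of the
TVB-style connectome bundle (a zip of ``weights.txt``, ``centres.txt``,
``tract_lengths.txt``, ``cortical.txt``); sensors and gain use BIDS-iEEG
style TSVs; simulated SEEG is written as BrainVision triplets
(text ``.vhdr`` header, text ``.vmrk`` markers, float32 multiplexed
``.eeg`` binary).  Signal units are arbitrary (model units scaled to a
microvolt-like range); the headers declare them accordingly.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import Connectome, Contact, ElectrodeSet, RegionParcellation
from .forward import GainMatrix


class ParseError(ValueError):
    """Raised when an on-disk bundle is malformed."""


# ---------------------------------------------------------------------------
# connectome zip bundle
# ---------------------------------------------------------------------------

def write_connectome_zip(path, connectome: Connectome,
                         parcellation: RegionParcellation) -> None:
    """TVB-compatible zip of whitespace-delimited text tables."""
    path = Path(path)
    R = connectome.n_regions
    tl = connectome.tract_lengths
    if tl is None:
        tl = np.zeros((R, R))
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        buf = _io.StringIO()
        np.savetxt(buf, connectome.weights, fmt="%.10g")
        zf.writestr("weights.txt", buf.getvalue())
        buf = _io.StringIO()
        np.savetxt(buf, tl, fmt="%.10g")
        zf.writestr("tract_lengths.txt", buf.getvalue())
        lines = [f"{lab} {x:.6f} {y:.6f} {z:.6f}"
                 for lab, (x, y, z) in zip(parcellation.region_labels,
                                           parcellation.centers)]
        zf.writestr("centres.txt", "\n".join(lines) + "\n")
        zf.writestr("cortical.txt", "\n".join(
            str(int(f)) for f in parcellation.cortical_flag) + "\n")


def read_connectome_zip(path) -> tuple[Connectome, RegionParcellation]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        for required in ("weights.txt", "centres.txt"):
            if required not in names:
                raise ParseError(f"{path.name}: missing {required}")
        try:
            weights = np.loadtxt(_io.StringIO(zf.read("weights.txt").decode()))
        except ValueError as exc:
            raise ParseError(f"{path.name}: bad weights.txt: {exc}") from exc
        labels, centers = [], []
        for line in zf.read("centres.txt").decode().splitlines():
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path.name}: bad centres.txt line: {line!r}")
            labels.append(parts[0])
            centers.append([float(v) for v in parts[1:]])
        tl = None
        if "tract_lengths.txt" in names:
            tl = np.loadtxt(_io.StringIO(zf.read("tract_lengths.txt").decode()))
        if "cortical.txt" in names:
            cortical = np.loadtxt(
                _io.StringIO(zf.read("cortical.txt").decode())).astype(bool)
        else:
            cortical = np.ones(len(labels), dtype=bool)
    conn = Connectome(weights=weights, tract_lengths=tl)
    parc = RegionParcellation(labels, np.array(centers), np.atleast_1d(cortical))
    if conn.n_regions != parc.n_regions:
        raise ParseError(f"{path.name}: weights/centres size mismatch")
    return conn, parc


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_gain_tsv(path, gain: GainMatrix) -> None:
    """R rows x N columns of tab-separated floats."""
    np.savetxt(path, gain.values, fmt="%.10g", delimiter="\t")


def read_gain_tsv(path, region_labels=None, sensor_labels=None) -> GainMatrix:
    try:
        values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    except ValueError as exc:
        raise ParseError(f"{Path(path).name}: bad gain TSV: {exc}") from exc
    R, N = values.shape
    return GainMatrix(values,
                      region_labels or [f"region-{i:03d}" for i in range(R)],
                      sensor_labels or [f"s{k}" for k in range(N)])


def write_electrodes_tsv(path, electrodes: ElectrodeSet) -> None:
    rows = [{"name": c.label, "x": c.position[0], "y": c.position[1],
             "z": c.position[2]} for c in electrodes.contacts]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_electrodes_tsv(path) -> ElectrodeSet:
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ParseError(f"{Path(path).name}: missing columns {missing}")
    contacts = []
    for _, row in df.iterrows():
        label = str(row["name"])
        shaft = label.rstrip("0123456789")
        contacts.append(Contact(label, shaft,
                                np.array([row["x"], row["y"], row["z"]])))
    return ElectrodeSet(contacts=contacts)


def write_channels_tsv(path, labels: list[str],
                       positions: np.ndarray | None = None,
                       units: str = "arbitrary") -> None:
    rows = []
    for i, lab in enumerate(labels):
        row = {"name": lab, "type": "SEEG", "units": units}
        if positions is not None:
            row.update(x=positions[i, 0], y=positions[i, 1], z=positions[i, 2])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hypothesis_tsv(path, region_labels, hypothesis) -> None:
    df = pd.DataFrame({"region": region_labels, "ev": hypothesis.ev})
    if hypothesis.zones is not None:
        df["zone"] = hypothesis.zones
    df.to_csv(path, sep="\t", index=False)


def read_hypothesis_tsv(path):
    from .parameters import EZHypothesis
    df = pd.read_csv(path, sep="\t")
    if "ev" not in df.columns:
        raise ParseError(f"{Path(path).name}: missing 'ev' column")
    zones = list(df["zone"]) if "zone" in df.columns else None
    return EZHypothesis(ev=df["ev"].to_numpy(), zones=zones)


def write_json_sidecar(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def read_json_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """\
Brain Vision Data Exchange Header File Version 1.0
; Written by epicohort

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us:.6f}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<idx>=<name>,<reference>,<resolution>,<unit>
{channel_lines}
"""

_VMRK_TEMPLATE = """\
Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
; Mk<idx>=<type>,<description>,<position>,<points>,<channel>
{marker_lines}
"""


def write_brainvision(stem_path, data: np.ndarray, fs: float,
                      channel_labels: list[str], unit: str = "µV",
                      markers: list[tuple[str, str, int]] | None = None) -> None:
    """Write a BrainVision triplet ``<stem>.vhdr/.vmrk/.eeg``.

    ``data`` is channels x time and stored as multiplexed little-endian
    float32 with resolution 1.  ``markers`` are (type, description,
    sample-position) tuples; a New Segment marker is always first.
    """
    stem_path = Path(stem_path)
    data = np.atleast_2d(np.asarray(data))
    if data.shape[0] != len(channel_labels):
        raise ValueError("one label per channel required")
    stem = stem_path.name
    escaped = [lab.replace(",", "\\,") for lab in channel_labels]
    ch_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,{unit}" for i, lab in enumerate(escaped))
    vhdr = _VHDR_TEMPLATE.format(stem=stem, n_channels=data.shape[0],
                                 sampling_interval_us=1e6 / fs,
                                 channel_lines=ch_lines)
    stem_path.with_suffix(".vhdr").write_text(vhdr)
    mk = [("New Segment", "", 1)]
    mk += list(markers or [])
    mk_lines = "\n".join(
        f"Mk{i + 1}={typ},{desc},{pos},1,0" for i, (typ, desc, pos) in enumerate(mk))
    vmrk = _VMRK_TEMPLATE.format(stem=stem, marker_lines=mk_lines)
    stem_path.with_suffix(".vmrk").write_text(vmrk)
    data.T.astype("<f4").tofile(stem_path.with_suffix(".eeg"))


def read_brainvision(vhdr_path) -> tuple[np.ndarray, float, list[str],
                                         list[tuple[str, str, int]]]:
    """Read a BrainVision triplet back: (data, fs, labels, markers)."""
    vhdr_path = Path(vhdr_path)
    header: dict[str, str] = {}
    channels: list[str] = []
    section = None
    for line in vhdr_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        if section == "Channel Infos" and key.startswith("Ch"):
            channels.append(value.split(",")[0].replace("\\,", ","))
        else:
            header[key] = value
    if header.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ParseError(f"{vhdr_path.name}: unsupported BinaryFormat")
    if header.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ParseError(f"{vhdr_path.name}: unsupported DataOrientation")
    n_ch = int(header["NumberOfChannels"])
    if n_ch != len(channels):
        raise ParseError(f"{vhdr_path.name}: channel count mismatch")
    fs = 1e6 / float(header["SamplingInterval"])
    raw = np.fromfile(vhdr_path.parent / header["DataFile"], dtype="<f4")
    data = raw.reshape(-1, n_ch).T.astype(float)
    markers: list[tuple[str, str, int]] = []
    vmrk = vhdr_path.parent / header["MarkerFile"]
    if vmrk.exists():
        for line in vmrk.read_text().splitlines():
            if line.startswith("Mk") and "=" in line:
                parts = line.split("=", 1)[1].split(",")
                markers.append((parts[0], parts[1], int(parts[2])))
    return data, fs, channels, markers
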