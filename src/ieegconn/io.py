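"""Readers and writers for the standard formats the pipeline touches.

BIDS-iEEG style TSV sidecars (electrodes, channels, events) are handled with
pandas; recordings are read through MNE (BrainVision or EDF) and written as
BrainVision (text header/marker files plus IEEE float32 multiplexed binary —
the one iEEG format for which an independent reader is available here);
masks through nibabel (NIfTI); streamlines through nibabel.streamlines
(MRtrix TCK).  Networks and count matrices travel as labelled TSV adjacency
tables (tab-delimited, UTF-8, LF).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .effective import SpesDataset
from .networks import BinaryNetwork, ElectrodeSet, VoxelMask
from .structural import CountMatrix

__all__ = [
    "read_electrodes_tsv",
    "write_electrodes_tsv",
    "read_channels_tsv",
    "write_channels_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "load_electrode_set",
    "read_spes_recording",
    "write_brainvision",
    "read_mask_nifti",
    "write_mask_nifti",
    "read_tck",
    "write_tck",
    "read_network_tsv",
    "write_network_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
]

_TSV = dict(sep="\t", index=False, na_rep="n/a")


def _read_tsv(path, required):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except Exception as exc:  # pragma: no cover - message formatting
        raise ValueError(f"{path}: could not parse TSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def read_electrodes_tsv(path) -> pd.DataFrame:
    """BIDS electrodes.tsv with at least name, x, y, z (scanner RAS mm)."""
    df = _read_tsv(path, ("name", "x", "y", "z"))
    for i, row in df.iterrows():
        if not np.all(np.isfinite([row["x"], row["y"], row["z"]])):
            raise ValueError(f"{path}: row {i} ({row['name']}) has non-finite "
                             "coordinates")
    return df


def write_electrodes_tsv(path, electrodes: ElectrodeSet):
    df = electrodes.to_frame()
    df["size"] = "n/a"
    df["soz"] = np.where(electrodes.soz, "yes", "no")
    df[["name", "x", "y", "z", "size", "soz"]].to_csv(path, **_TSV)


def read_channels_tsv(path, bad_statuses=("bad",)) -> pd.DataFrame:
    """BIDS channels.tsv; ``status`` in ``bad_statuses`` marks exclusion."""
    df = _read_tsv(path, ("name",))
    if "status" not in df.columns:
        df["status"] = "good"
    df["included"] = ~df["status"].astype(str).str.lower().isin(
        tuple(s.lower() for s in bad_statuses)
    )
    return df


def write_channels_tsv(path, electrodes: ElectrodeSet):
    pd.DataFrame({
        "name": electrodes.labels,
        "type": "ECOG" if electrodes.modality == "ECoG" else "SEEG",
        "units": "uV",
        "status": np.where(electrodes.included, "good", "bad"),
    }).to_csv(path, **_TSV)


def read_events_tsv(path, fs: float = None) -> pd.DataFrame:
    """BIDS events.tsv with electrical stimulation sites.

    Requires ``onset`` (s) and ``electrical_stimulation_site`` ("A-B");
    ``sample`` is used when present, otherwise derived from onset and ``fs``.
    """
    df = _read_tsv(path, ("onset", "electrical_stimulation_site"))
    out = pd.DataFrame({
        "onset_s": df["onset"].astype(float),
        "site": df["electrical_stimulation_site"].astype(str),
    })
    for i, site in enumerate(out["site"]):
        parts = site.split("-")
        if len(parts) != 2 or not all(parts):
            raise ValueError(
                f"{path}: row {i}: malformed stimulation site {site!r}"
            )
    if "sample" in df.columns:
        out["onset_sample"] = df["sample"].astype(int)
    elif fs is not None:
        out["onset_sample"] = np.rint(out["onset_s"] * fs).astype(int)
    else:
        raise ValueError(f"{path}: no 'sample' column and no sampling "
                         "frequency supplied")
    cur = df.get("electrical_stimulation_current")
    out["current_ma"] = (pd.to_numeric(cur, errors="coerce") * 1e3
                         if cur is not None else np.nan)
    return out.sort_values("onset_sample", ignore_index=True)


def write_events_tsv(path, events: pd.DataFrame, fs: float):
    pd.DataFrame({
        "onset": events["onset_sample"] / fs,
        "duration": 0.001,
        "sample": events["onset_sample"].astype(int),
        "trial_type": "electrical_stimulation",
        "electrical_stimulation_site": events["site"],
        "electrical_stimulation_current":
            events.get("current_ma", pd.Series(np.nan, index=events.index))
            .astype(float) / 1e3,
    }).to_csv(path, **_TSV)


def load_electrode_set(
    electrodes_tsv,
    channels_tsv=None,
    modality: str = "sEEG",
    soz_column: str = "soz",
) -> ElectrodeSet:
    """Assemble an ElectrodeSet from BIDS sidecars.

    Inclusion flags come from channels.tsv ``status`` (good/bad); SOZ flags
    from a ``soz`` column of electrodes.tsv when present (yes/no).
    """
    elec = read_electrodes_tsv(electrodes_tsv)
    labels = elec["name"].astype(str).tolist()
    coords = elec[["x", "y", "z"]].to_numpy(dtype=float)
    included = np.ones(len(labels), dtype=bool)
    if channels_tsv is not None:
        chan = read_channels_tsv(channels_tsv)
        status = dict(zip(chan["name"].astype(str), chan["included"]))
        unknown = [l for l in labels if l not in status]
        if unknown:
            raise ValueError(
                f"{channels_tsv}: electrodes missing from channels.tsv: "
                f"{unknown}"
            )
        included = np.array([status[l] for l in labels], dtype=bool)
    soz = np.zeros(len(labels), dtype=bool)
    if soz_column in elec.columns:
        soz = elec[soz_column].astype(str).str.lower().isin(
            ("yes", "true", "1")
        ).to_numpy()
    return ElectrodeSet(labels, coords, modality, included=included, soz=soz)


# ---------------------------------------------------------------------------
# recordings


def write_brainvision(stem, data_uv: np.ndarray, fs: float, ch_names):
    """Write a BrainVision trio (<stem>.vhdr/.vmrk/.eeg), IEEE float32, uV.

    Data are multiplexed float32 in microvolts with unit resolution, which
    MNE's BrainVision reader recovers exactly (up to float32 precision).
    """
    stem = Path(stem)
    name = stem.name
    n_ch = len(ch_names)
    if data_uv.shape[0] != n_ch:
        raise ValueError("data rows must match channel names")
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(ch_names, start=1):
        header.append(f"Ch{i}={ch},,1,µV")
    stem.with_suffix(".vhdr").write_text("\n".join(header) + "\n",
                                         encoding="utf-8")
    marker = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    stem.with_suffix(".vmrk").write_text("\n".join(marker) + "\n",
                                         encoding="utf-8")
    stem.with_suffix(".eeg").write_bytes(
        np.asarray(data_uv, dtype="<f4").T.tobytes()
    )
    return stem.with_suffix(".vhdr")


def read_spes_recording(
    recording_path,
    events_tsv,
    modality: str,
    channels_tsv=None,
) -> SpesDataset:
    """Load a BrainVision or EDF recording plus its stimulation events."""
    import mne

    path = Path(recording_path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"{path}: unsupported recording format "
                         f"{path.suffix!r} (expected .vhdr or .edf)")
    data_uv = raw.get_data() * 1e6  # MNE stores volts
    events = read_events_tsv(events_tsv, fs=raw.info["sfreq"])
    ch_names = list(raw.ch_names)
    known = set(ch_names)
    for i, site in enumerate(events["site"]):
        a, b = site.split("-")
        if a not in known or b not in known:
            raise ValueError(
                f"{events_tsv}: row {i}: site {site!r} names channels absent "
                "from the recording"
            )
    return SpesDataset(data_uv, raw.info["sfreq"], ch_names, events, modality)


# ---------------------------------------------------------------------------
# masks and streamlines


def read_mask_nifti(path) -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask(np.asanyarray(img.dataobj) > 0, img.affine)


def write_mask_nifti(path, mask: VoxelMask):
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_tck(path) -> list:
    """Streamlines from an MRtrix TCK file, as (n_points, 3) mm arrays."""
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tck.streamlines]


def write_tck(path, streamlines):
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


# ---------------------------------------------------------------------------
# networks and counts


def write_network_tsv(path, net: BinaryNetwork):
    net.to_frame().to_csv(path, sep="\t", index_label="node")


def read_network_tsv(path) -> BinaryNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: adjacency row and column labels differ")
    return BinaryNetwork(tuple(df.columns.astype(str)),
                         df.to_numpy().astype(bool))


def write_counts_tsv(path, counts: CountMatrix):
    counts.to_frame().to_csv(path, sep="\t", index_label="node")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: count-matrix row and column labels differ")
    return CountMatrix(tuple(df.columns.astype(str)),
                       df.to_numpy().astype(int))


def write_json(path, obj):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n",
                          encoding="utf-8")
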