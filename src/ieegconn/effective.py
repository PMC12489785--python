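"""Effective network reconstruction from single pulse electrical stimulation.

Adjacent electrode-contact pairs are stimulated with trains of ten monophasic
pulses at 0.2 Hz.  Responses on the remaining channels are epoched (-2 s to
+2 s), re-referenced against the lowest-variance channels, averaged into an
evoked response potential (ERP) per stimulated pair and channel, and screened
for cortico-cortical evoked potentials (CCEPs): an early deflection within
9-100 ms whose amplitude exceeds a modality-specific multiple of the baseline
standard deviation (2.6x for ECoG, negative polarity only; 3.5x for sEEG,
either polarity).  Every detected CCEP draws undirected edges from both
contacts of the stimulus pair to the responding contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import BinaryNetwork

__all__ = [
    "SpesDataset",
    "Trial",
    "ERP",
    "CcepDetection",
    "epoch_trials",
    "rereference",
    "average_erp",
    "detect_ccep",
    "detect_all_cceps",
    "build_effective_network",
    "DETECTION_WINDOW_MS",
    "K_ECOG",
    "K_SEEG",
]

logger = logging.getLogger(__name__)

#: CCEP search window after the stimulus, in ms.
DETECTION_WINDOW_MS = (9.0, 100.0)
#: Baseline-SD multiples for detection.
K_ECOG = 2.6
K_SEEG = 3.5
#: Baseline window relative to the stimulus, in s (100 ms pre-stimulus guard).
BASELINE_WINDOW_S = (-2.0, -0.1)


@dataclass
class SpesDataset:
    """Multichannel SPES recording plus the stimulation event list.

    ``events`` needs columns ``onset_sample``, ``site`` (e.g. ``"G01-G02"``)
    and optionally ``current_ma``; events must be sorted by onset and the
    site labels must name channels of the recording.
    """

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    ch_names: list
    events: pd.DataFrame
    modality: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        self.ch_names = [str(c) for c in self.ch_names]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel names must match data rows")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.modality not in ("ECoG", "sEEG"):
            raise ValueError(f"unknown modality {self.modality!r}")
        ev = self.events
        if not np.all(np.diff(ev["onset_sample"].to_numpy()) >= 0):
            raise ValueError("events must be sorted by onset")
        known = set(self.ch_names)
        for site in ev["site"]:
            a, b = parse_stim_site(site)
            if a not in known or b not in known:
                raise ValueError(f"stimulated site {site!r} names unknown channels")


def parse_stim_site(site: str):
    """Split an ``"A01-A02"`` stimulation-site label into its two contacts."""
    parts = str(site).split("-")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed stimulation site label {site!r}")
    return parts[0], parts[1]


@dataclass
class Trial:
    """All epochs of one stimulus pair: (n_epochs, n_channels, n_times)."""

    stim_pair: tuple  # (anode label, cathode label)
    epochs: np.ndarray
    times: np.ndarray  # s, relative to stimulus
    ch_names: list
    n_dropped: int = 0

    @property
    def stim_indices(self):
        return tuple(self.ch_names.index(c) for c in self.stim_pair)


def epoch_trials(
    data: SpesDataset,
    window=(-2.0, 2.0),
) -> list:
    """Cut per-pulse epochs around every stimulus, grouped by stimulus pair.

    Epoch windows are half-open sample intervals [onset + w0*fs, onset + w1*fs);
    events whose window falls outside the recording are dropped and counted.
    Channels belonging to the stimulated pair are kept in the array but marked
    non-analyzable downstream via ``Trial.stim_indices``.
    """
    fs = data.fs
    s0 = int(round(window[0] * fs))
    s1 = int(round(window[1] * fs))
    n_samples = data.data.shape[1]
    times = np.arange(s0, s1) / fs

    trials = []
    for site, group in data.events.groupby("site", sort=False):
        pair = parse_stim_site(site)
        kept, dropped = [], 0
        for onset in group["onset_sample"].to_numpy():
            onset = int(onset)
            lo, hi = onset + s0, onset + s1
            if lo < 0 or hi > n_samples:
                dropped += 1
                continue
            kept.append(data.data[:, lo:hi])
        if dropped:
            logger.warning(
                "stim pair %s: dropped %d epochs at the recording edge",
                site, dropped,
            )
        if not kept:
            continue
        epochs = np.stack(kept, axis=0)
        trials.append(Trial(pair, epochs, times, list(data.ch_names), dropped))
    return trials


def rereference(trial: Trial, fraction: float = 0.10) -> Trial:
    """Subtract the per-sample median of the lowest-variance channels.

    Non-stimulated channels are ranked by their variance over the trial's
    concatenated epochs; the lowest ``max(1, round(fraction * n))`` channels
    form the reference, whose per-sample median (per epoch) is subtracted
    from every channel.  Removes activity common to the quietest channels
    while preserving local evoked responses.
    """
    stim = set(trial.stim_indices)
    candidates = [i for i in range(len(trial.ch_names)) if i not in stim]
    if len(candidates) < 2:
        raise ValueError("re-referencing requires at least 2 analyzable channels")
    flat = trial.epochs.transpose(1, 0, 2).reshape(len(trial.ch_names), -1)
    variances = flat.var(axis=1)
    n_ref = max(1, int(round(fraction * len(candidates))))
    order = sorted(candidates, key=lambda i: (variances[i], i))
    ref_idx = order[:n_ref]
    ref = np.median(trial.epochs[:, ref_idx, :], axis=1, keepdims=True)
    return Trial(
        trial.stim_pair,
        trial.epochs - ref,
        trial.times,
        trial.ch_names,
        trial.n_dropped,
    )


@dataclass
class ERP:
    """Averaged evoked response for one (stimulus pair, channel)."""

    stim_pair: tuple
    channel: str
    waveform: np.ndarray  # baseline-median-corrected average, microvolts
    times: np.ndarray  # s relative to stimulus
    fs: float
    baseline_median: float
    baseline_sd: float
    n_epochs: int


def average_erp(
    epochs: np.ndarray,
    times: np.ndarray,
    fs: float,
    stim_pair=("?", "?"),
    channel="?",
    baseline_window=BASELINE_WINDOW_S,
) -> ERP:
    """Average epochs of one channel and baseline-correct the result.

    ``epochs`` is (n_epochs, n_times) for a single channel.  The pointwise
    mean is taken, the median of the averaged trace over the baseline window
    is subtracted, and the baseline SD is computed on the corrected average.
    The baseline window excludes the last 100 ms before the stimulus as a
    guard against stimulus-artifact bleed.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("at least one epoch required")
    avg = epochs.mean(axis=0)
    in_base = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not np.any(in_base):
        raise ValueError("baseline window contains no samples")
    base_med = float(np.median(avg[in_base]))
    corrected = avg - base_med
    base_sd = float(corrected[in_base].std())
    return ERP(
        stim_pair=tuple(stim_pair),
        channel=str(channel),
        waveform=corrected,
        times=np.asarray(times, dtype=float),
        fs=float(fs),
        baseline_median=base_med,
        baseline_sd=base_sd,
        n_epochs=epochs.shape[0],
    )


@dataclass
class CcepDetection:
    """Outcome of CCEP screening for one (stimulus pair, channel)."""

    stim_pair: tuple
    channel: str
    detected: bool
    latency_ms: float
    amplitude_uv: float
    z: float
    analyzable: bool = True


def detect_ccep(
    erp: ERP,
    modality: str,
    window_ms=DETECTION_WINDOW_MS,
    k: float = None,
) -> CcepDetection:
    """Screen an averaged response for a cortico-cortical evoked potential.

    The signed extremum within ``window_ms`` after the stimulus is located
    (most negative sample for ECoG; largest absolute deflection for sEEG).
    A CCEP is declared when its magnitude exceeds ``k`` times the baseline
    SD, with k = 2.6 for ECoG and 3.5 for sEEG by default.  Latency,
    amplitude and z are reported whether or not the threshold is met.
    """
    if modality not in ("ECoG", "sEEG"):
        raise ValueError(f"unknown modality {modality!r}")
    if k is None:
        k = K_ECOG if modality == "ECoG" else K_SEEG
    if erp.baseline_sd <= 0:
        logger.warning(
            "stim %s -> %s: zero baseline SD, flagged not analyzable",
            erp.stim_pair, erp.channel,
        )
        return CcepDetection(
            erp.stim_pair, erp.channel, False, float("nan"), float("nan"),
            float("nan"), analyzable=False,
        )
    t_ms = erp.times * 1000.0
    in_win = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    seg = erp.waveform[in_win]
    seg_t = t_ms[in_win]
    if modality == "ECoG":
        idx = int(np.argmin(seg))  # negative sharp potential only
    else:
        idx = int(np.argmax(np.abs(seg)))
    amplitude = float(seg[idx])
    latency = float(seg_t[idx])
    z = abs(amplitude) / erp.baseline_sd
    if modality == "ECoG":
        detected = (amplitude < 0) and (z > k)
    else:
        detected = z > k
    return CcepDetection(erp.stim_pair, erp.channel, bool(detected),
                         latency, amplitude, z)


def detect_all_cceps(
    data: SpesDataset,
    reref_fraction: float = 0.10,
    window_ms=DETECTION_WINDOW_MS,
    k: float = None,
) -> pd.DataFrame:
    """Run the full per-trial chain: epoch, re-reference, average, detect.

    Returns one row per (stimulus pair, analyzable channel) with columns
    ``stim_a, stim_b, channel, detected, latency_ms, amplitude_uv, z``.
    Channels of the stimulated pair are excluded from their own trial.
    """
    rows = []
    for trial in epoch_trials(data):
        trial = rereference(trial, fraction=reref_fraction)
        stim = set(trial.stim_indices)
        for ci, ch in enumerate(trial.ch_names):
            if ci in stim:
                continue
            erp = average_erp(
                trial.epochs[:, ci, :], trial.times, data.fs,
                stim_pair=trial.stim_pair, channel=ch,
            )
            det = detect_ccep(erp, data.modality, window_ms=window_ms, k=k)
            rows.append(
                {
                    "stim_a": trial.stim_pair[0],
                    "stim_b": trial.stim_pair[1],
                    "channel": ch,
                    "detected": det.detected,
                    "latency_ms": det.latency_ms,
                    "amplitude_uv": det.amplitude_uv,
                    "z": det.z,
                    "analyzable": det.analyzable,
                }
            )
    return pd.DataFrame(rows)


def build_effective_network(detections: pd.DataFrame, labels) -> BinaryNetwork:
    """Symmetrized effective network from CCEP detections.

    For every detected CCEP on channel c during stimulation of pair (a, b),
    undirected edges (a, c) and (b, c) are added: responses are treated as
    bi-directional, discarding direction to allow comparison with the
    structural network.  Detections on channels outside ``labels`` (excluded
    contacts) are ignored with a warning.
    """
    labels = tuple(str(x) for x in labels)
    known = set(labels)
    edges = []
    n_skipped = 0
    for row in detections.itertuples(index=False):
        if not row.detected:
            continue
        if row.channel not in known or row.stim_a not in known \
                or row.stim_b not in known:
            n_skipped += 1
            continue
        for stim in (row.stim_a, row.stim_b):
            if stim != row.channel:
                edges.append((stim, row.channel))
    if n_skipped:
        logger.warning(
            "ignored %d detections involving excluded contacts", n_skipped
        )
    return BinaryNetwork.from_edges(labels, edges)
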