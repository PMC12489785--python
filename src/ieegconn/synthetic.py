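"""Synthetic iEEG cohorts with controllable ground truth.

Every input the pipeline consumes can be generated here with a planted
ground truth: electrode geometries (subdural grids and depth shafts), a
grey-white-matter boundary voxel mask, a pair of binary truth networks with
an exactly planted Jaccard index, streamline counts that binarize back to
the structural truth, SPES recordings whose averaged responses reproduce the
effective truth, and a multi-patient node table with planted fixed effects
and between-patient variance.  This makes construction, similarity and
modelling verifiable end-to-end without any clinical data.

Identifiability of the effective truth
--------------------------------------
Reconstruction draws edges from *both* contacts of a stimulus pair to each
responding contact, so pairwise stimulation can only resolve connectivity at
the resolution of stimulation-pair blocks.  The planted effective network is
therefore block-structured over disjoint adjacent stimulation pairs (and has
no within-pair edges), which makes exact round-trip recovery well defined.

Background model
----------------
The ongoing activity is a common-frequency sinusoidal rhythm with a distinct
amplitude per channel, plus optional white Gaussian noise.  With the noise
turned off the recording is deterministic and the detector's z-statistic on
non-connected channels is exactly sqrt(2), below every detection threshold,
so a noiseless round trip recovers the planted networks edge for edge.  (A
purely Gaussian background could not achieve this: the z-statistic is
amplitude-scale invariant, so its false-alarm rate would not vanish with the
noise level.)
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import BinaryNetwork, ContactAreaSet, ElectrodeSet, VoxelMask
from .structural import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_electrodes",
    "stim_pairs",
    "generate_boundary_mask",
    "generate_truth_networks",
    "generate_streamline_counts",
    "generate_streamlines",
    "generate_spes_recording",
    "generate_cohort_table",
    "simulate_patient",
]


@dataclass
class SimConfig:
    """Ground-truth configuration for one synthetic patient / cohort.

    Geometry defaults follow clinical hardware: 10 mm grid pitch for ECoG
    and 3.5 or 5 mm within-shaft pitch for sEEG.  Network densities and
    their overlap default to the cohort-level medians of the study
    conditions (d_SC = 0.20, d_EC = 0.23, overlap chosen so the planted
    Jaccard index is ~0.25).  SPES timing is ten monophasic pulses per pair
    at 0.2 Hz.
    """

    modality: str = "sEEG"
    # ECoG grid geometry
    grid_rows: int = 8
    grid_cols: int = 8
    grid_pitch_mm: float = 10.0
    # sEEG shaft geometry
    n_shafts: int = 8
    contacts_per_shaft: int = 8
    shaft_pitch_mm: float = 3.5
    shaft_spacing_mm: float = 12.0
    # boundary mask
    mask_shape: tuple = None  # derived from geometry when None
    voxel_size_mm: float = 1.0
    # planted networks
    d_sc: float = 0.20
    d_ec: float = 0.23
    overlap: float = 0.43
    # SPES recording
    fs: float = 2048.0
    n_pulses: int = 10
    inter_pulse_s: float = 5.0
    response_uv: float = 500.0
    latency_ms: float = 30.0
    response_width_ms: float = 20.0
    noise_uv: float = 5.0
    background_uv: float = 10.0
    background_hz: float = 10.0
    # cohort / multilevel model
    n_patients: int = 13
    nodes_per_patient: int = 66
    beta_ecd: float = 0.13
    beta_np: float = -0.13
    intercept_sd: float = 0.37 ** 0.5
    residual_sd: float = 0.63 ** 0.5
    soz_fraction: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("ECoG", "sEEG"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not (0.0 <= self.d_sc <= 1.0 and 0.0 <= self.d_ec <= 1.0):
            raise ValueError("target densities must lie in [0, 1]")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap fraction must lie in [0, 1]")
        if self.n_contacts < 1:
            raise ValueError("geometry must yield at least 1 contact")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_contacts(self) -> int:
        if self.modality == "ECoG":
            return self.grid_rows * self.grid_cols
        return self.n_shafts * self.contacts_per_shaft

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


@dataclass
class SyntheticTruth:
    """Planted structural/effective networks and their exact Jaccard index."""

    sc_true: BinaryNetwork
    ec_true: BinaryNetwork
    planted_ji: float
    stim_pairs: list = field(default_factory=list)

    @property
    def sc_degrees(self) -> np.ndarray:
        return self.sc_true.adjacency.sum(axis=1)

    @property
    def ec_degrees(self) -> np.ndarray:
        return self.ec_true.adjacency.sum(axis=1)


# ---------------------------------------------------------------------------
# geometry


def generate_electrodes(config: SimConfig) -> ElectrodeSet:
    """Deterministic electrode coordinates for the configured geometry.

    ECoG contacts are coplanar on a ``grid_rows x grid_cols`` grid at the
    configured pitch; sEEG contacts are collinear per shaft, shafts parallel
    and evenly spaced.  Labels are ``G01..`` for grids and ``A01.., B01..``
    per shaft.
    """
    if config.modality == "ECoG":
        rows, cols = config.grid_rows, config.grid_cols
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be positive")
        labels, coords = [], []
        k = 0
        for r in range(rows):
            for c in range(cols):
                k += 1
                labels.append(f"G{k:02d}")
                coords.append(
                    (c * config.grid_pitch_mm, r * config.grid_pitch_mm, 0.0)
                )
    else:
        if config.n_shafts < 1 or config.contacts_per_shaft < 1:
            raise ValueError("shaft geometry must be positive")
        if config.n_shafts > len(string.ascii_uppercase):
            raise ValueError("at most 26 shafts supported")
        labels, coords = [], []
        for s in range(config.n_shafts):
            letter = string.ascii_uppercase[s]
            for c in range(config.contacts_per_shaft):
                labels.append(f"{letter}{c + 1:02d}")
                coords.append(
                    (c * config.shaft_pitch_mm, s * config.shaft_spacing_mm, 0.0)
                )
    return ElectrodeSet(labels, np.array(coords, dtype=float), config.modality)


def stim_pairs(config: SimConfig, electrodes: ElectrodeSet = None) -> list:
    """Disjoint adjacent stimulation pairs along each grid row / shaft.

    Consecutive contacts are paired (1-2, 3-4, ...) within each row or
    shaft; a trailing unpaired contact is never stimulated.
    """
    if electrodes is None:
        electrodes = generate_electrodes(config)
    labels = electrodes.labels
    if config.modality == "ECoG":
        run = config.grid_cols
    else:
        run = config.contacts_per_shaft
    pairs = []
    for start in range(0, len(labels), run):
        chunk = labels[start:start + run]
        for i in range(0, len(chunk) - 1, 2):
            pairs.append((chunk[i], chunk[i + 1]))
    return pairs


def generate_boundary_mask(config: SimConfig,
                           electrodes: ElectrodeSet = None) -> VoxelMask:
    """Synthetic grey-white matter boundary surrounding the electrodes.

    The boundary is modelled as a voxel shell at 2-6 mm from each contact,
    guaranteeing well over 64 true voxels within 10 mm of every contact so
    full-size contact areas are always constructible.  The affine maps
    0-based voxel indices to mm with isotropic voxels.
    """
    if electrodes is None:
        electrodes = generate_electrodes(config)
    vox = config.voxel_size_mm
    if vox <= 0:
        raise ValueError("voxel size must be positive")
    margin = 8.0
    lo = electrodes.coords.min(axis=0) - margin
    hi = electrodes.coords.max(axis=0) + margin
    if config.mask_shape is None:
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / vox)) + 1 for d in range(3))
    else:
        shape = tuple(int(s) for s in config.mask_shape)
        if any(s <= 0 for s in shape):
            raise ValueError("mask shape must be positive")
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = lo
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = grid * vox + lo
    dmin = np.full(len(centers), np.inf)
    for coord in electrodes.coords:
        d = np.linalg.norm(centers - coord, axis=1)
        np.minimum(dmin, d, out=dmin)
    data = ((dmin >= 2.0) & (dmin <= 6.0)).reshape(shape)
    return VoxelMask(data, affine)


# ---------------------------------------------------------------------------
# truth networks


def generate_truth_networks(config: SimConfig,
                            electrodes: ElectrodeSet = None) -> SyntheticTruth:
    """Plant SC and EC truth networks with an exactly known Jaccard index.

    Edge counts are rounded to the nearest feasible integers for the target
    densities; the intersection holds ``overlap * min(E_SC, E_EC)`` edges
    (rounded), drawn from the effective network's edges, so the planted
    Jaccard index |I| / (E_SC + E_EC - |I|) is exact by construction.  The
    effective truth is block-structured over stimulation pairs (see module
    docstring); the structural truth is unconstrained.
    """
    if electrodes is None:
        electrodes = generate_electrodes(config)
    rng = config.rng(salt=1)
    labels = tuple(electrodes.included_subset().labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 included contacts")
    m_total = n * (n - 1) // 2
    pairs = stim_pairs(config, electrodes)
    if len(pairs) < 2:
        raise ValueError("need at least 2 stimulation pairs for an EC truth")

    # effective edges come in 4-edge blocks between stimulation pairs
    n_blocks_max = len(pairs) * (len(pairs) - 1) // 2
    n_blocks = int(round(config.d_ec * m_total / 4.0))
    if n_blocks > n_blocks_max:
        raise ValueError(
            f"target d_EC={config.d_ec} infeasible: needs {n_blocks} "
            f"stimulation-pair blocks, only {n_blocks_max} exist"
        )
    block_ids = rng.choice(n_blocks_max, size=n_blocks, replace=False)
    all_blocks = [
        (i, j) for i in range(len(pairs)) for j in range(i + 1, len(pairs))
    ]
    ec_edges = []
    for b in block_ids:
        pi, pj = all_blocks[b]
        for a in pairs[pi]:
            for c in pairs[pj]:
                ec_edges.append((a, c))
    e_ec = len(ec_edges)

    e_sc = int(round(config.d_sc * m_total))
    n_inter = int(round(config.overlap * min(e_sc, e_ec)))
    if e_sc - n_inter > m_total - e_ec:
        raise ValueError(
            f"infeasible (d_SC={config.d_sc}, d_EC={config.d_ec}, "
            f"overlap={config.overlap}): {e_sc - n_inter} SC-only edges "
            f"requested but only {m_total - e_ec} non-EC pairs exist"
        )

    inter_idx = rng.choice(e_ec, size=n_inter, replace=False)
    sc_edges = [ec_edges[i] for i in inter_idx]
    ec_edge_set = {frozenset(e) for e in ec_edges}
    complement = [
        (labels[i], labels[j])
        for i in range(n) for j in range(i + 1, n)
        if frozenset((labels[i], labels[j])) not in ec_edge_set
    ]
    extra_idx = rng.choice(len(complement), size=e_sc - n_inter, replace=False)
    sc_edges += [complement[i] for i in extra_idx]

    sc = BinaryNetwork.from_edges(labels, sc_edges)
    ec = BinaryNetwork.from_edges(labels, ec_edges)
    union = e_sc + e_ec - n_inter
    planted = n_inter / union if union else 0.0
    return SyntheticTruth(sc, ec, planted, stim_pairs=pairs)


# ---------------------------------------------------------------------------
# structural inputs


def generate_streamline_counts(
    truth: SyntheticTruth,
    areas: ContactAreaSet,
    fp_rate: float = 0.0,
    seed=None,
) -> CountMatrix:
    """Streamline counts consistent with the structural truth.

    For every true structural edge the count is drawn so that the density
    count / (VEA_i + VEA_j) strictly exceeds 0.1; non-edges receive counts at
    or below the threshold, except a Bernoulli(``fp_rate``) fraction planted
    as false positives.
    """
    rng = np.random.default_rng(seed)
    labels = list(truth.sc_true.labels)
    veas = np.array([areas.vea(lab) for lab in labels])
    if np.any(veas <= 0):
        bad = [labels[i] for i in np.nonzero(veas <= 0)[0]]
        raise ValueError(f"contacts with empty areas cannot carry counts: {bad}")
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    adj = truth.sc_true.adjacency
    for i in range(n):
        for j in range(i + 1, n):
            v = veas[i] + veas[j]
            cap = int(np.floor(0.1 * v))  # largest count with density <= 0.1
            if adj[i, j]:
                c = cap + 1 + rng.poisson(0.1 * v)
            elif fp_rate > 0 and rng.random() < fp_rate:
                c = cap + 1
            else:
                c = int(rng.integers(0, max(cap // 2, 1)))
            counts[i, j] = counts[j, i] = c
    return CountMatrix(tuple(labels), counts)


def generate_streamlines(
    counts: CountMatrix,
    areas: ContactAreaSet,
    mask: VoxelMask,
    seed=None,
) -> list:
    """Synthetic streamlines whose endpoint counts reproduce ``counts``.

    For each pair (i, j) with count c, c three-point streamlines are
    generated from a random voxel of area i to a random voxel of area j
    (endpoints jittered within the voxel), suitable for TCK round-trips.
    """
    rng = np.random.default_rng(seed)
    labels = list(counts.labels)
    streamlines = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            c = int(counts.counts[i, j])
            if c == 0:
                continue
            vox_i = areas.voxels[labels[i]]
            vox_j = areas.voxels[labels[j]]
            for _ in range(c):
                a = mask.voxel_centers_mm(vox_i[rng.integers(len(vox_i))])[0]
                b = mask.voxel_centers_mm(vox_j[rng.integers(len(vox_j))])[0]
                a = a + rng.uniform(-0.3, 0.3, 3) * mask.voxel_volume ** (1 / 3)
                b = b + rng.uniform(-0.3, 0.3, 3) * mask.voxel_volume ** (1 / 3)
                mid = (a + b) / 2.0
                streamlines.append(np.vstack([a, mid, b]))
    return streamlines


# ---------------------------------------------------------------------------
# SPES recording


def _response_kernel(fs: float, latency_ms: float, width_ms: float,
                     n_times: int) -> np.ndarray:
    """Negative damped half-sine deflection starting at the given latency."""
    t = np.arange(n_times) / fs * 1000.0  # ms after stimulus
    width = max(width_ms, 1.0)
    phase = (t - latency_ms) / width
    kern = np.where((phase >= 0) & (phase <= 1),
                    -np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    kern *= np.exp(-np.clip(phase, 0, None) * 0.5)
    return kern


def generate_spes_recording(
    truth: SyntheticTruth,
    electrodes: ElectrodeSet,
    config: SimConfig,
) -> "SpesDataset":
    """Synthesize a SPES recording consistent with the effective truth.

    For every stimulation pair, ``n_pulses`` pulses are delivered at
    0.2 Hz (5 s apart).  Channels connected in the effective truth to either
    stimulated contact carry a negative damped half-sine deflection of the
    configured amplitude and latency; all channels carry the sinusoidal
    background (common frequency/phase, channel-specific amplitude), a
    stimulus-artifact spike at t = 0, and optional white Gaussian noise.
    """
    from .effective import SpesDataset  # local import to avoid cycles

    if config.fs < 512:
        raise ValueError("sampling frequency must be at least 512 Hz")
    rng = config.rng(salt=2)
    inc = electrodes.included_subset()
    labels = list(inc.labels)
    if tuple(labels) != truth.ec_true.labels:
        raise ValueError("electrode labels do not match the planted truth")
    index = {lab: k for k, lab in enumerate(labels)}
    n_ch = len(labels)
    fs = config.fs
    pairs = truth.stim_pairs
    pad = 3.0
    total_s = 2 * pad + len(pairs) * config.n_pulses * config.inter_pulse_s
    n_samples = int(round(total_s * fs))
    t = np.arange(n_samples) / fs

    # common-frequency background with channel-specific amplitudes on a grid
    # that no reference median can exactly cancel
    amps = config.background_uv * (1.0 + (np.arange(n_ch) + 1) / (n_ch + 1))
    data = amps[:, None] * np.sin(2 * np.pi * config.background_hz * t)[None, :]

    n_resp = int(round(0.2 * fs))  # 200 ms kernel support
    kernel = _response_kernel(fs, config.latency_ms, config.response_width_ms,
                              n_resp)
    events = []
    adj = truth.ec_true.adjacency
    for k, (a, b) in enumerate(pairs):
        targets = np.nonzero(adj[index[a]] | adj[index[b]])[0]
        targets = [c for c in targets if labels[c] not in (a, b)]
        for m in range(config.n_pulses):
            onset_s = pad + (k * config.n_pulses + m) * config.inter_pulse_s
            onset = int(round(onset_s * fs))
            events.append(
                {"onset_sample": onset, "onset_s": onset / fs,
                 "site": f"{a}-{b}", "current_ma": 2.0}
            )
            stop = min(onset + n_resp, n_samples)
            for c in targets:
                data[c, onset:stop] += config.response_uv * kernel[: stop - onset]
            # stimulus artifact spike at t = 0 on every channel
            data[:, onset] += 800.0
    if config.noise_uv > 0:
        data += rng.normal(0.0, config.noise_uv, size=data.shape)
    events = pd.DataFrame(events).sort_values("onset_sample",
                                              ignore_index=True)
    return SpesDataset(data, fs, labels, events, config.modality)


# ---------------------------------------------------------------------------
# cohort table


def generate_cohort_table(config: SimConfig, seed=None) -> pd.DataFrame:
    """Multi-patient node table with planted fixed effects.

    The outcome follows SCD = beta_ECD * ECD + beta_NP * NP + u_patient + eps
    with u ~ N(0, intercept_sd^2) and eps ~ N(0, residual_sd^2); the ECD and
    NP predictors are iid standard normal (already standardized), so the
    planted variance decomposition is exact.  VEA and SOZ columns are
    generated with zero true effect.
    """
    if config.n_patients < 2:
        raise ValueError("cohort needs at least 2 patients")
    rng = np.random.default_rng(seed if seed is not None
                                else (config.seed, 3))
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        n = config.nodes_per_patient
        u = rng.normal(0.0, config.intercept_sd)
        ecd = rng.standard_normal(n)
        prox = rng.standard_normal(n)
        eps = rng.normal(0.0, config.residual_sd, n)
        scd = config.beta_ecd * ecd + config.beta_np * prox + u + eps
        rows.append(pd.DataFrame({
            "patient": pid,
            "node": [f"n{i + 1:03d}" for i in range(n)],
            "sc_degree": scd,
            "ec_degree": ecd,
            "proximity": prox,
            "vea": rng.uniform(40.0, 64.0, n),
            "soz": (rng.random(n) < config.soz_fraction).astype(float),
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# one-call patient simulation


def simulate_patient(config: SimConfig, fp_rate: float = 0.0) -> dict:
    """Generate every input of one synthetic patient.

    Returns a dict with electrodes, mask, contact areas, planted truth,
    streamline counts and the SPES recording, all mutually consistent.
    """
    from .contact_areas import build_contact_areas

    electrodes = generate_electrodes(config)
    mask = generate_boundary_mask(config, electrodes)
    areas = build_contact_areas(electrodes, mask)
    truth = generate_truth_networks(config, electrodes)
    counts = generate_streamline_counts(
        truth, areas, fp_rate=fp_rate, seed=config.rng(salt=4)
    )
    spes = generate_spes_recording(truth, electrodes, config)
    return {
        "electrodes": electrodes,
        "mask": mask,
        "areas": areas,
        "truth": truth,
        "counts": counts,
        "spes": spes,
    }
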