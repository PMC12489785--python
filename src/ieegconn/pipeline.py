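"""Run configuration and stage orchestration for one patient / cohort.

``run_patient`` composes the stages on in-memory objects (the library path);
``run_pipeline`` reads a RunConfig pointing at files on disk, runs the same
stages, and writes every intermediate artifact with a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contact_areas as ca
from . import effective as eff
from . import io as iio
from . import similarity as sim
from . import structural as st
from . import topology as topo
from .networks import ElectrodeSet, VoxelMask

__all__ = ["RunConfig", "run_patient", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seed for a single-patient pipeline run."""

    electrodes_tsv: str = None
    channels_tsv: str = None
    events_tsv: str = None
    recording: str = None
    mask_nifti: str = None
    tck: str = None
    counts_tsv: str = None
    modality: str = "sEEG"
    output_dir: str = "out"
    density_threshold: float = st.DENSITY_THRESHOLD
    k_ecog: float = eff.K_ECOG
    k_seeg: float = eff.K_SEEG
    window_ms: tuple = eff.DETECTION_WINDOW_MS
    max_voxels: int = 64
    search_radius_mm: float = 20.0
    reref_fraction: float = 0.10
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for name in ("density_threshold", "k_ecog", "k_seeg",
                     "reref_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**cfg)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is not
        part of the analysis identity)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_patient(
    electrodes: ElectrodeSet,
    mask: VoxelMask,
    spes: "eff.SpesDataset",
    counts: "st.CountMatrix" = None,
    streamlines=None,
    config: RunConfig = None,
) -> dict:
    """Full single-patient analysis on in-memory objects.

    Builds contact areas, the binary structural network (from a count matrix
    or raw streamlines), the effective network from CCEP detections, the
    similarity summary, and the per-node metric table.
    """
    config = config or RunConfig()
    areas = ca.build_contact_areas(
        electrodes, mask, max_voxels=config.max_voxels,
        search_radius_mm=config.search_radius_mm,
    )
    if counts is None:
        if streamlines is None:
            raise ValueError("either a count matrix or streamlines required")
        counts = st.count_streamlines(streamlines, areas, mask)
    dens = st.streamline_density(counts, areas)
    sc = st.binarize_structural(dens, counts.labels,
                                threshold=config.density_threshold)
    k = config.k_ecog if spes.modality == "ECoG" else config.k_seeg
    detections = eff.detect_all_cceps(
        spes, reref_fraction=config.reref_fraction,
        window_ms=config.window_ms, k=k,
    )
    ec = eff.build_effective_network(detections, sc.labels)
    similarity = sim.compare_networks(
        sc, ec, n_permutations=config.n_permutations, seed=config.seed
    )
    inc = electrodes.included_subset()
    prox = ca.node_proximity(electrodes)
    nodes = pd.DataFrame({
        "node": list(sc.labels),
        "sc_degree": topo.degree(sc),
        "ec_degree": topo.degree(ec),
        "proximity": prox,
        "vea": [areas.vea(l) for l in sc.labels],
        "soz": inc.soz.astype(float),
        "sc_betweenness": topo.betweenness_centrality(sc),
        "ec_betweenness": topo.betweenness_centrality(ec),
    })
    logger.info(
        "patient summary: %d nodes, %d SC edges, %d EC edges, JI=%.3f",
        sc.n_nodes, sc.n_edges, ec.n_edges, similarity.ji,
    )
    return {
        "areas": areas,
        "counts": counts,
        "density": dens,
        "sc": sc,
        "ec": ec,
        "detections": detections,
        "similarity": similarity,
        "nodes": nodes,
    }


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline run; writes all artifacts to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    electrodes = iio.load_electrode_set(
        config.electrodes_tsv, config.channels_tsv, modality=config.modality
    )
    mask = iio.read_mask_nifti(config.mask_nifti)
    spes = iio.read_spes_recording(
        config.recording, config.events_tsv, config.modality,
        channels_tsv=config.channels_tsv,
    )
    counts = streamlines = None
    if config.counts_tsv:
        counts = iio.read_counts_tsv(config.counts_tsv)
    elif config.tck:
        streamlines = iio.read_tck(config.tck)
    else:
        raise ValueError("config must provide counts_tsv or tck")

    result = run_patient(electrodes, mask, spes, counts=counts,
                         streamlines=streamlines, config=config)

    tag = config.config_hash()
    result["areas"].to_frame().assign(config_hash=tag).to_csv(
        out / "contact_areas.tsv", sep="\t", index=False
    )
    iio.write_counts_tsv(out / "streamline_counts.tsv", result["counts"])
    iio.write_network_tsv(out / "structural_adjacency.tsv", result["sc"])
    iio.write_network_tsv(out / "effective_adjacency.tsv", result["ec"])
    result["detections"].assign(config_hash=tag).to_csv(
        out / "detections.tsv", sep="\t", index=False
    )
    result["nodes"].assign(config_hash=tag).to_csv(
        out / "node_table.tsv", sep="\t", index=False
    )
    iio.write_json(out / "similarity.json",
                   {**result["similarity"].to_dict(), "config_hash": tag})
    iio.write_json(out / "provenance.json",
                   {"config": asdict(config), "config_hash": tag})
    return result
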