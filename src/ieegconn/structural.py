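"""Structural network construction from streamline endpoint counts.

Streamlines whose first point lies in one contact area and whose last point
lies in another are counted per unordered pair of contacts.  The streamline
density normalizes the count by the volume of the two involved contact areas,
and an edge is formed when the density exceeds 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import BinaryNetwork, ContactAreaSet, VoxelMask

__all__ = [
    "CountMatrix",
    "count_streamlines",
    "streamline_density",
    "binarize_structural",
]

logger = logging.getLogger(__name__)

#: Streamline-density threshold above which a structural edge is formed.
DENSITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class CountMatrix:
    """Symmetric non-negative streamline counts between contact areas."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        c = np.asarray(self.counts)
        if c.shape != (len(labels), len(labels)):
            raise ValueError("counts must be square and match labels")
        if np.any(c < 0):
            raise ValueError("streamline counts must be non-negative")
        if np.any(np.diag(c) != 0):
            raise ValueError("count matrix must have a zero diagonal")
        if not np.array_equal(c, c.T):
            raise ValueError("count matrix must be symmetric")
        object.__setattr__(self, "counts", c.astype(int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def count_streamlines(
    streamlines,
    areas: ContactAreaSet,
    mask: VoxelMask,
) -> CountMatrix:
    """Count streamlines connecting pairs of contact areas.

    Parameters
    ----------
    streamlines : iterable of (n_points, 3) arrays
        Streamline point sequences in the mask's mm space (as read from an
        MRtrix TCK file, e.g. by :func:`ieegconn.io.read_tck`).
    areas : ContactAreaSet
        Contact areas whose voxels define seed/termination membership.
    mask : VoxelMask
        Supplies the mm -> voxel-index transform.

    A streamline increments count(i, j) iff its first point falls in a voxel
    of area i and its last point in a voxel of area j with i != j.
    Streamlines with fewer than two points are skipped (count reported via
    the logger); endpoints outside every area are ignored.
    """
    labels = list(areas.labels)
    index = {lab: k for k, lab in enumerate(labels)}
    voxel_owner = {}
    for lab in labels:
        for tup in map(tuple, areas.voxels[lab]):
            voxel_owner[tup] = index[lab]

    counts = np.zeros((len(labels), len(labels)), dtype=int)
    n_short = 0
    for sl in streamlines:
        pts = np.asarray(sl, dtype=float)
        if pts.ndim != 2 or len(pts) < 2:
            n_short += 1
            continue
        ends = mask.mm_to_voxel(pts[[0, -1]])
        i = voxel_owner.get(tuple(ends[0]))
        j = voxel_owner.get(tuple(ends[1]))
        if i is None or j is None or i == j:
            continue
        counts[i, j] += 1
        counts[j, i] += 1
    if n_short:
        logger.warning("skipped %d streamlines with fewer than 2 points", n_short)
    return CountMatrix(tuple(labels), counts)


def streamline_density(
    counts: CountMatrix,
    areas: ContactAreaSet,
    denominator: str = "sum",
) -> np.ndarray:
    """Streamline count normalized by the volume of both contact areas.

    density(i, j) = counts(i, j) / (VEA_i + VEA_j) by default.  The source
    description ("divided by the volume of the two involved electrode contact
    areas") leaves the combination ambiguous; the symmetric sum is the
    default and ``denominator`` may be set to ``"mean"`` instead.
    """
    veas = np.array([areas.vea(lab) for lab in counts.labels])
    c = counts.counts.astype(float)
    empty = veas <= 0
    if np.any(empty & (c.sum(axis=0) > 0)):
        bad = [counts.labels[i] for i in np.nonzero(empty & (c.sum(axis=0) > 0))[0]]
        raise ValueError(
            f"contacts with empty areas participate in nonzero counts: {bad}"
        )
    if denominator == "sum":
        denom = veas[:, None] + veas[None, :]
    elif denominator == "mean":
        denom = (veas[:, None] + veas[None, :]) / 2.0
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(denom > 0, c / denom, 0.0)
    np.fill_diagonal(dens, 0.0)
    return dens


def binarize_structural(
    density: np.ndarray,
    labels,
    threshold: float = DENSITY_THRESHOLD,
) -> BinaryNetwork:
    """Form a structural edge wherever the density strictly exceeds the threshold.

    The comparison is strict ("exceeded"): density exactly at the threshold
    does not form an edge.  The diagonal is forced to zero.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("densities must be non-negative")
    if not np.allclose(density, density.T):
        raise ValueError("density matrix must be symmetric")
    adj = density > threshold
    np.fill_diagonal(adj, False)
    return BinaryNetwork(tuple(labels), adj)
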