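"""Shared network and electrode containers.

All connectivity in this package is represented as an undirected, unweighted
graph over electrode contacts: a symmetric boolean adjacency matrix with a
zero diagonal and a fixed node (label) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinaryNetwork", "ElectrodeSet", "VoxelMask", "ContactAreaSet"]


@dataclass(frozen=True)
class BinaryNetwork:
    """Symmetric binary connectivity network over labelled contact nodes.

    Parameters
    ----------
    labels : tuple of str
        Node labels, order fixed (defines row/column order of ``adjacency``).
    adjacency : ndarray of bool, shape (N, N)
        Symmetric adjacency with zero diagonal.
    """

    labels: tuple
    adjacency: np.ndarray

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if adj.shape[0] != len(labels):
            raise ValueError("adjacency size does not match number of labels")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        adj = adj.copy()
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> frozenset:
        """Edges as a frozenset of unordered label pairs."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return frozenset(
            frozenset((self.labels[i], self.labels[j])) for i, j in zip(ii, jj)
        )

    @classmethod
    def from_edges(cls, labels, edges) -> "BinaryNetwork":
        """Build a network from an iterable of (label_a, label_b) pairs."""
        labels = tuple(str(x) for x in labels)
        index = {lab: k for k, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=bool)
        for a, b in edges:
            i, j = index[str(a)], index[str(b)]
            if i == j:
                raise ValueError(f"self-loop on node {a!r} not allowed")
            adj[i, j] = adj[j, i] = True
        return cls(labels, adj)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.adjacency.astype(int), index=self.labels, columns=self.labels
        )

    def same_nodes(self, other: "BinaryNetwork") -> bool:
        return self.labels == other.labels


@dataclass
class ElectrodeSet:
    """Labelled electrode contacts with scanner-space mm coordinates.

    ``included`` marks contacts in grey matter with clean signals; excluded
    contacts carry no network node.  ``soz`` marks contacts on the clinically
    delineated seizure onset zone.
    """

    labels: list
    coords: np.ndarray  # (N, 3) mm, scanner RAS
    modality: str  # "ECoG" or "sEEG"
    included: np.ndarray = None
    soz: np.ndarray = None

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("contact labels must be unique")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must have shape (n_contacts, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("contact coordinates must be finite")
        if self.modality not in ("ECoG", "sEEG"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n = len(self.labels)
        if self.included is None:
            self.included = np.ones(n, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
        if self.soz is None:
            self.soz = np.zeros(n, dtype=bool)
        else:
            self.soz = np.asarray(self.soz, dtype=bool)
        if self.included.shape != (n,) or self.soz.shape != (n,):
            raise ValueError("included/soz flags must match number of contacts")

    @property
    def n_contacts(self) -> int:
        return len(self.labels)

    def included_subset(self) -> "ElectrodeSet":
        """Restrict to included contacts (the network nodes)."""
        m = self.included
        return ElectrodeSet(
            [l for l, keep in zip(self.labels, m) if keep],
            self.coords[m],
            self.modality,
            included=np.ones(int(m.sum()), dtype=bool),
            soz=self.soz[m],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.labels,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "included": self.included.astype(int),
                "soz": self.soz.astype(int),
            }
        )


@dataclass
class VoxelMask:
    """Binary 3-D voxel mask with a voxel-index -> mm affine.

    Voxel indices are 0-based; world coordinates are scanner RAS mm, with the
    affine mapping a voxel index (i, j, k, 1) to the voxel *centre* in mm,
    following the NIfTI convention.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def true_voxel_indices(self) -> np.ndarray:
        """(M, 3) integer indices of true voxels."""
        return np.argwhere(self.data)

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """mm coordinates of voxel centres for (M, 3) integer indices."""
        indices = np.atleast_2d(indices)
        homog = np.hstack([indices, np.ones((len(indices), 1))])
        return (homog @ self.affine.T)[:, :3]

    def mm_to_voxel(self, coords_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each mm coordinate."""
        coords_mm = np.atleast_2d(np.asarray(coords_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.hstack([coords_mm, np.ones((len(coords_mm), 1))])
        return np.rint((homog @ inv.T)[:, :3]).astype(int)


@dataclass
class ContactAreaSet:
    """Per-contact voxel sets on the grey-white matter boundary.

    Each included contact owns a pairwise-disjoint set of boundary voxels
    (at most ``max_voxels``); its VEA is the voxel count times the voxel
    volume, hence at most 64 mm^3 at 1 mm isotropic resolution.
    """

    labels: list
    voxels: dict  # label -> (m, 3) int array of voxel indices
    voxel_volume: float
    flagged: dict = field(default_factory=dict)  # label -> reason string

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.voxels = {str(k): np.asarray(v, dtype=int).reshape(-1, 3)
                       for k, v in self.voxels.items()}
        seen = set()
        for lab in self.labels:
            for tup in map(tuple, self.voxels.get(lab, np.empty((0, 3), int))):
                if tup in seen:
                    raise ValueError(f"voxel {tup} assigned to more than one contact")
                seen.add(tup)

    def n_voxels(self, label: str) -> int:
        return len(self.voxels.get(str(label), ()))

    def vea(self, label: str) -> float:
        """Volume of the electrode contact area in mm^3."""
        return self.n_voxels(label) * self.voxel_volume

    def veas(self) -> np.ndarray:
        return np.array([self.vea(lab) for lab in self.labels])

    def centroid(self, label: str) -> np.ndarray:
        vox = self.voxels[str(label)]
        if len(vox) == 0:
            return np.full(3, np.nan)
        return vox.mean(axis=0)

    def nonempty_labels(self) -> list:
        return [lab for lab in self.labels if self.n_voxels(lab) > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contact": self.labels,
                "n_voxels": [self.n_voxels(l) for l in self.labels],
                "vea_mm3": [self.vea(l) for l in self.labels],
            }
        )
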