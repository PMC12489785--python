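"""Structural node construction: electrode contact areas on the boundary mask.

Each included electrode contact is projected onto the grey-white matter
boundary by claiming its nearest boundary voxels (Euclidean distance from the
contact mm coordinate to voxel centres).  At most 64 voxels are assigned per
contact; voxels contested by several contacts go to the nearest one, so areas
can end up smaller than 64 mm^3.  The resulting contact areas serve as the
structural-network nodes and define the VEA covariate.
"""

from __future__ import annotations

import logging

import numpy as np

from .networks import ContactAreaSet, ElectrodeSet, VoxelMask

__all__ = ["apply_affine", "build_contact_areas", "node_proximity"]

logger = logging.getLogger(__name__)


def apply_affine(coords, transform) -> np.ndarray:
    """Apply a 4x4 affine transform to (N, 3) mm coordinates.

    Used to move electrode coordinates between co-registered spaces; the
    transform itself is an input, never estimated here.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("transform is singular")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    homog = np.hstack([coords, np.ones((len(coords), 1))])
    return (homog @ transform.T)[:, :3]


def build_contact_areas(
    electrodes: ElectrodeSet,
    mask: VoxelMask,
    max_voxels: int = 64,
    search_radius_mm: float = 20.0,
) -> ContactAreaSet:
    """Assign each included contact its nearest boundary voxels.

    Parameters
    ----------
    electrodes : ElectrodeSet
        Only contacts with ``included`` set receive an area.
    mask : VoxelMask
        Binary grey-white matter boundary mask.
    max_voxels : int
        Maximum voxels per contact area (64 -> VEA of at most 64 mm^3 at
        1 mm isotropic voxels).
    search_radius_mm : float
        Contacts whose nearest boundary voxel lies beyond this radius are
        flagged and receive an empty area.

    Notes
    -----
    Assignment is two-stage: each contact first claims its ``max_voxels``
    nearest in-mask voxels (within the search radius); voxels claimed by more
    than one contact are then given to the strictly nearest contact (ties
    broken by ascending contact index).  Areas are not refilled after losing
    contested voxels, so they can shrink below ``max_voxels``.
    """
    true_idx = mask.true_voxel_indices()
    if len(true_idx) == 0:
        raise ValueError("boundary mask contains no true voxels")
    centers = mask.voxel_centers_mm(true_idx)

    inc = electrodes.included_subset()
    labels = inc.labels
    claims = {}  # voxel row index -> list of (distance, contact order)
    flagged = {}
    for ci, (lab, coord) in enumerate(zip(labels, inc.coords)):
        d = np.linalg.norm(centers - coord, axis=1)
        in_range = np.nonzero(d <= search_radius_mm)[0]
        if len(in_range) == 0:
            flagged[lab] = (
                f"no boundary voxel within {search_radius_mm:g} mm"
            )
            logger.warning(
                "contact %s: %s; dropped from structural network",
                lab, flagged[lab],
            )
            continue
        order = in_range[np.argsort(d[in_range], kind="stable")][:max_voxels]
        for v in order:
            claims.setdefault(int(v), []).append((d[v], ci))

    assigned = {lab: [] for lab in labels}
    for v, claimants in claims.items():
        # nearest contact wins; ties by lowest contact index
        _, winner = min(claimants, key=lambda t: (t[0], t[1]))
        assigned[labels[winner]].append(true_idx[v])

    voxels = {
        lab: (np.array(rows, dtype=int) if rows else np.empty((0, 3), int))
        for lab, rows in assigned.items()
    }
    for lab in labels:
        if lab not in flagged and len(voxels[lab]) == 0:
            flagged[lab] = "all claimed voxels reassigned to nearer contacts"
            logger.warning(
                "contact %s: empty area after contention; dropped from "
                "structural network", lab,
            )
    return ContactAreaSet(labels, voxels, mask.voxel_volume, flagged=flagged)


def node_proximity(electrodes: ElectrodeSet) -> np.ndarray:
    """Median Euclidean distance (mm) from each included node to all others.

    A node sitting centrally in a dense sampling has a low proximity value;
    peripheral or isolated nodes have high values.  Used as a spatial-sampling
    covariate in the group model.
    """
    inc = electrodes.included_subset()
    coords = inc.coords
    n = len(coords)
    if n < 2:
        raise ValueError("node proximity requires at least 2 included contacts")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(np.delete(dist[i], i))
    return out
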