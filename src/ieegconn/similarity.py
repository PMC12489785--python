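"""Inter-modal similarity between two binary networks.

The structural (SC) and effective (EC) networks of one patient share a node
set; their agreement is summarized by the Jaccard index of their edge sets,
the Jaccard index expected under density-matched random edge placement, a
density-preserving permutation test, and the log10 ratio of
structural-only to effective-only edges in the symmetric difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .networks import BinaryNetwork

__all__ = [
    "SimilarityResult",
    "density",
    "jaccard_index",
    "expected_jaccard",
    "jaccard_significance",
    "symmetric_difference_ratio",
    "compare_networks",
]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    """Similarity summary between one patient's SC and EC networks."""

    ji: float
    ji_expected: float
    d_sc: float
    d_ec: float
    ratio_sc_ec: float  # log10(|SC-only| / |EC-only|), may be +-inf or nan
    p_value: float
    n_intersection: int
    n_union: int
    n_sc_only: int
    n_ec_only: int
    both_empty: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def density(net: BinaryNetwork) -> float:
    """Network density: sum of the adjacency over N(N-1) ordered pairs.

    Equals 2E / (N(N-1)) for E undirected edges; 1 for the complete graph.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return float(net.adjacency.sum()) / (n * (n - 1))


def _check_same_nodes(sc: BinaryNetwork, ec: BinaryNetwork):
    if sc.labels != ec.labels:
        raise ValueError("networks must share an identical, ordered node set")


def jaccard_index(sc: BinaryNetwork, ec: BinaryNetwork) -> float:
    """|edges(SC) ∩ edges(EC)| / |edges(SC) ∪ edges(EC)| over unordered pairs.

    Returns 0.0 (with a warning) when both networks are empty.
    """
    _check_same_nodes(sc, ec)
    a = np.triu(sc.adjacency, k=1)
    b = np.triu(ec.adjacency, k=1)
    union = int(np.sum(a | b))
    if union == 0:
        warnings.warn("both networks empty; Jaccard index undefined, returning 0")
        return 0.0
    return int(np.sum(a & b)) / union


def expected_jaccard(d_sc: float, d_ec: float) -> float:
    """Expected Jaccard index under random edge placement at given densities.

    JI_expected = d_SC * d_EC / (d_SC + d_EC - d_SC * d_EC).
    """
    if not (0.0 <= d_sc <= 1.0 and 0.0 <= d_ec <= 1.0):
        raise ValueError("densities must lie in [0, 1]")
    if d_sc == 0.0 and d_ec == 0.0:
        raise ValueError("expected Jaccard undefined when both densities are 0")
    return d_sc * d_ec / (d_sc + d_ec - d_sc * d_ec)


def jaccard_significance(
    sc: BinaryNetwork,
    ec: BinaryNetwork,
    n_permutations: int = 10_000,
    seed=None,
    return_null: bool = False,
):
    """Permutation test of the Jaccard index against density-matched chance.

    Each permutation places the observed number of SC and EC edges uniformly
    at random over the unordered node pairs and recomputes the Jaccard index;
    the p-value is (1 + #{JI_perm >= JI_obs}) / (B + 1).  The null mean of the
    permuted JI matches the closed-form expected Jaccard index.

    Returns the p-value, or (p-value, null JI samples) if ``return_null``.
    """
    _check_same_nodes(sc, ec)
    e_sc, e_ec = sc.n_edges, ec.n_edges
    if e_sc == 0 or e_ec == 0:
        raise ValueError("permutation test requires both networks nonempty")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} gives a coarse p-value resolution"
        )
    n = sc.n_nodes
    m = n * (n - 1) // 2
    ji_obs = jaccard_index(sc, ec)
    rng = np.random.default_rng(seed)

    # vectorized: one uniform draw per pair, smallest e ranks = chosen edges
    null = np.empty(n_permutations)
    batch = max(1, min(n_permutations, 50_000_000 // max(m, 1)))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        r1 = rng.random((b, m)).argpartition(e_sc - 1, axis=1)[:, :e_sc]
        r2 = rng.random((b, m)).argpartition(e_ec - 1, axis=1)[:, :e_ec]
        sel1 = np.zeros((b, m), dtype=bool)
        sel2 = np.zeros((b, m), dtype=bool)
        rows = np.arange(b)[:, None]
        sel1[rows, r1] = True
        sel2[rows, r2] = True
        inter = np.sum(sel1 & sel2, axis=1)
        null[done:done + b] = inter / (e_sc + e_ec - inter)
        done += b

    p = (1 + int(np.sum(null >= ji_obs))) / (n_permutations + 1)
    if return_null:
        return p, null
    return p


def symmetric_difference_ratio(sc: BinaryNetwork, ec: BinaryNetwork) -> float:
    """log10 ratio of structural-only to effective-only edge counts.

    0 means equal numbers of modality-exclusive edges; -1 means ten times
    more effective-only than structural-only edges.  Returns +inf / -inf when
    one side of the symmetric difference is empty, and NaN (with a warning)
    when both are.
    """
    _check_same_nodes(sc, ec)
    a = np.triu(sc.adjacency, k=1)
    b = np.triu(ec.adjacency, k=1)
    sc_only = int(np.sum(a & ~b))
    ec_only = int(np.sum(b & ~a))
    if sc_only == 0 and ec_only == 0:
        warnings.warn("symmetric difference empty; ratio undefined (NaN)")
        return float("nan")
    if ec_only == 0:
        return float("inf")
    if sc_only == 0:
        return float("-inf")
    return float(np.log10(sc_only / ec_only))


def compare_networks(
    sc: BinaryNetwork,
    ec: BinaryNetwork,
    n_permutations: int = 10_000,
    seed=None,
) -> SimilarityResult:
    """Full inter-modal similarity summary for one patient."""
    _check_same_nodes(sc, ec)
    a = np.triu(sc.adjacency, k=1)
    b = np.triu(ec.adjacency, k=1)
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    sc_only = int(np.sum(a & ~b))
    ec_only = int(np.sum(b & ~a))
    d_sc = density(sc)
    d_ec = density(ec)
    both_empty = union == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ji = jaccard_index(sc, ec)
        ratio = symmetric_difference_ratio(sc, ec)
    ji_exp = expected_jaccard(d_sc, d_ec) if (d_sc or d_ec) else float("nan")
    if sc.n_edges and ec.n_edges:
        p = jaccard_significance(sc, ec, n_permutations=n_permutations, seed=seed)
    else:
        p = float("nan")
    return SimilarityResult(
        ji=ji,
        ji_expected=ji_exp,
        d_sc=d_sc,
        d_ec=d_ec,
        ratio_sc_ec=ratio,
        p_value=p,
        n_intersection=inter,
        n_union=union,
        n_sc_only=sc_only,
        n_ec_only=ec_only,
        both_empty=both_empty,
    )
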