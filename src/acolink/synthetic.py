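"""Synthetic data generators.

Real lncRNA-protein interaction catalogs exhibit group structure:
families of lncRNAs bind overlapping sets of RNA-binding proteins.  The
block-network generator emulates exactly that — lncRNA blocks matched
to protein blocks, dense edges inside a matched pair, sparse background
noise elsewhere — so the full pipeline (clustering of association
profiles, similarity, propagation, cross-validation) is testable
without external downloads.  Ground-truth lncRNA block labels are
returned for clustering validation.

The Gaussian-blob generator produces separable point clouds in
arbitrary dimension for exercising the clustering stage directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import InteractionNetwork

__all__ = ["BlockNetworkSpec", "generate_block_network", "generate_blobs"]


@dataclass
class BlockNetworkSpec:
    """Parameters of the planted-block bipartite network.

    Defaults describe the standard simulation scenario: 100 lncRNAs x 50
    proteins in 5 matched blocks, within-block edge probability 0.30,
    background edge probability 0.01.
    """

    n_lncrna: int = 100
    n_protein: int = 50
    n_blocks: int = 5
    p_within: float = 0.30
    p_background: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lncrna < 1 or self.n_protein < 1:
            raise ValueError("network dimensions must be positive")
        if not 1 <= self.n_blocks <= min(self.n_lncrna, self.n_protein):
            raise ValueError("n_blocks must lie in [1, min(n_lncrna, n_protein)]")
        if not 0 <= self.p_background < self.p_within <= 1:
            raise ValueError("need 0 <= p_background < p_within <= 1")


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    """Near-equal contiguous block assignment (sizes differ by <= 1)."""
    labels = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(n), n_blocks)):
        labels[chunk] = b
    return labels


def generate_block_network(spec: BlockNetworkSpec | None = None):
    """Draw a planted-block bipartite network.

    Returns
    -------
    net : InteractionNetwork
    labels : ndarray of int
        True lncRNA block labels, for clustering validation.
    """
    if spec is None:
        spec = BlockNetworkSpec()
    rng = np.random.default_rng(spec.seed)
    lab_l = _block_labels(spec.n_lncrna, spec.n_blocks)
    lab_p = _block_labels(spec.n_protein, spec.n_blocks)
    p = np.where(
        lab_l[:, None] == lab_p[None, :], spec.p_within, spec.p_background
    )
    adj = (rng.random((spec.n_lncrna, spec.n_protein)) < p).astype(np.int8)
    width_l = len(str(spec.n_lncrna))
    width_p = len(str(spec.n_protein))
    net = InteractionNetwork(
        [f"L{i + 1:0{width_l}d}" for i in range(spec.n_lncrna)],
        [f"P{j + 1:0{width_p}d}" for j in range(spec.n_protein)],
        adj,
    )
    return net, lab_l


def generate_blobs(
    n_per_cluster: int = 30,
    dims: int = 2,
    n_clusters: int = 3,
    center_sep: float = 10.0,
    sigma: float = 1.0,
    seed: int | None = None,
):
    """Isotropic Gaussian clusters with pairwise center separation >= center_sep.

    Centers are placed deterministically at ``i * center_sep`` along the
    first axis, so consecutive centers are exactly ``center_sep`` apart
    and all other pairs farther.  Returns ``(points, labels)``.
    """
    if center_sep <= 0 or sigma <= 0:
        raise ValueError("center_sep and sigma must be positive")
    if n_per_cluster < 1 or n_clusters < 1 or dims < 1:
        raise ValueError("counts and dimension must be positive")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, dims))
    centers[:, 0] = np.arange(n_clusters) * center_sep
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    points = centers[labels] + rng.normal(
        0.0, sigma, size=(n_clusters * n_per_cluster, dims)
    )
    return points, labels
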