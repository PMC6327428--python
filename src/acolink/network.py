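"""Bipartite lncRNA-protein interaction networks.

The central data object is :class:`InteractionNetwork`, a binary ``n x m``
adjacency matrix over an ordered list of lncRNA identifiers (rows) and
protein identifiers (columns).  Row vectors are lncRNA *association
profiles*, column vectors are protein association profiles; every
downstream stage (clustering, similarity, propagation) consumes these
profiles rather than raw sequences.

File formats
------------
Edge list (TSV or CSV): one ``lncRNA_id<sep>protein_id`` pair per line,
``#``-prefixed comment lines ignored.  Two optional header lines,
``#lncrnas: id1,id2,...`` and ``#proteins: ...``, enumerate identifiers so
that isolated nodes (all-zero rows/columns, which arise under edge
masking) survive a round trip.  A third column, if present, is ignored
with a warning — the network is unweighted.

Dense adjacency: labeled CSV with protein ids as the column header and
lncRNA ids in the first column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "AssociationProfile",
    "read_edge_list",
    "write_edge_list",
    "read_dense_csv",
    "write_dense_csv",
    "lncrna_profiles",
    "protein_profiles",
]


@dataclass
class InteractionNetwork:
    """Binary bipartite interaction network.

    Parameters
    ----------
    lncrna_ids : list of str
        Unique row identifiers, in fixed order.
    protein_ids : list of str
        Unique column identifiers, in fixed order.
    adjacency : ndarray of shape (n, m)
        Entries in {0, 1}; ``adjacency[i, j] == 1`` iff lncRNA ``i`` is
        known to interact with protein ``j``.
    """

    lncrna_ids: list[str]
    protein_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2:
            raise ValueError("adjacency must be a 2-d matrix")
        n, m = adj.shape
        if n < 1 or m < 1:
            raise ValueError("network needs at least one lncRNA and one protein")
        if len(self.lncrna_ids) != n or len(self.protein_ids) != m:
            raise ValueError(
                f"id/adjacency shape mismatch: {len(self.lncrna_ids)} lncRNA ids, "
                f"{len(self.protein_ids)} protein ids, adjacency {adj.shape}"
            )
        if len(set(self.lncrna_ids)) != n:
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.protein_ids)) != m:
            raise ValueError("duplicate protein identifiers")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be exactly 0 or 1")
        self.adjacency = adj.astype(np.int8)
        self.lncrna_ids = list(self.lncrna_ids)
        self.protein_ids = list(self.protein_ids)

    # -- basic accessors -------------------------------------------------
    @property
    def n_lncrnas(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.adjacency.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def positive_edges(self) -> np.ndarray:
        """Known interacting (row, column) index pairs, row-major order."""
        return np.argwhere(self.adjacency == 1)

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(
            list(self.lncrna_ids), list(self.protein_ids), self.adjacency.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.lncrna_ids == other.lncrna_ids
            and self.protein_ids == other.protein_ids
            and np.array_equal(self.adjacency, other.adjacency)
        )


@dataclass
class AssociationProfile:
    """A node's binary interaction vector (one adjacency row or column)."""

    owner_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.int8)


def lncrna_profiles(net: InteractionNetwork) -> list[AssociationProfile]:
    """Row profiles, in ``lncrna_ids`` order."""
    return [
        AssociationProfile(lid, net.adjacency[i, :])
        for i, lid in enumerate(net.lncrna_ids)
    ]


def protein_profiles(net: InteractionNetwork) -> list[AssociationProfile]:
    """Column profiles, in ``protein_ids`` order."""
    return [
        AssociationProfile(pid, net.adjacency[:, j])
        for j, pid in enumerate(net.protein_ids)
    ]


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def _split_fields(line: str, dialect: str) -> list[str]:
    if dialect == "csv":
        return [f.strip() for f in line.split(",")]
    # TSV: accept tabs or runs of spaces so hand-written files parse
    return line.split()


def read_edge_list(path, dialect: str = "tsv") -> InteractionNetwork:
    """Read a bipartite edge list into an :class:`InteractionNetwork`.

    Identifiers are ordered by first appearance (header enumeration first,
    then edge lines).  Duplicate pairs collapse to a single edge with a
    warning; a third column is ignored with a warning.

    Raises
    ------
    ValueError
        On a malformed line (fewer than two fields, with its line number)
        or an empty file.
    """
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}; choose 'tsv' or 'csv'")
    lnc_order: dict[str, int] = {}
    prot_order: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    n_dup = 0
    n_extra = 0
    seen: set[tuple[str, str]] = set()

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for key, order in (("#lncrnas:", lnc_order), ("#proteins:", prot_order)):
                    if line.lower().startswith(key):
                        for ident in line[len(key):].split(","):
                            ident = ident.strip()
                            if ident and ident not in order:
                                order[ident] = len(order)
                continue
            fields = _split_fields(line, dialect)
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected "
                    f"'lncRNA_id{_SEPS[dialect]}protein_id', got {line!r}"
                )
            if len(fields) > 2:
                n_extra += 1
            lnc, prot = fields[0], fields[1]
            if lnc not in lnc_order:
                lnc_order[lnc] = len(lnc_order)
            if prot not in prot_order:
                prot_order[prot] = len(prot_order)
            if (lnc, prot) in seen:
                n_dup += 1
                continue
            seen.add((lnc, prot))
            pairs.append((lnc, prot))

    if not lnc_order or not prot_order:
        raise ValueError(f"{path}: empty edge list (no edges and no id headers)")
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate edge line(s)")
    if n_extra:
        warnings.warn(
            f"{path}: ignored extra column(s) on {n_extra} line(s); "
            "the network is unweighted"
        )

    lncrna_ids = list(lnc_order)
    protein_ids = list(prot_order)
    adj = np.zeros((len(lncrna_ids), len(protein_ids)), dtype=np.int8)
    for lnc, prot in pairs:
        adj[lnc_order[lnc], prot_order[prot]] = 1
    return InteractionNetwork(lncrna_ids, protein_ids, adj)


def write_edge_list(net: InteractionNetwork, path, dialect: str = "tsv") -> None:
    """Write ``net`` so that :func:`read_edge_list` reproduces it exactly.

    Identifier headers are always emitted so isolated nodes round-trip.
    """
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}; choose 'tsv' or 'csv'")
    sep = _SEPS[dialect]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#lncrnas: " + ",".join(net.lncrna_ids) + "\n")
        fh.write("#proteins: " + ",".join(net.protein_ids) + "\n")
        for i, j in net.positive_edges():
            fh.write(f"{net.lncrna_ids[i]}{sep}{net.protein_ids[j]}\n")


# ---------------------------------------------------------------------------
# dense adjacency I/O
# ---------------------------------------------------------------------------

def read_dense_csv(path) -> InteractionNetwork:
    """Read a labeled dense adjacency CSV (lncRNA rows, protein columns)."""
    df = pd.read_csv(path, index_col=0)
    return InteractionNetwork(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(),
    )


def write_dense_csv(net: InteractionNetwork, path) -> None:
    df = pd.DataFrame(net.adjacency, index=net.lncrna_ids, columns=net.protein_ids)
    df.to_csv(path)
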