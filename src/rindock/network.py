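"""Residue-contact networks.

A protein is represented as an undirected, unweighted graph: one node per
residue (its Cα atom, or Cβ with Cα standing in for glycine), and an edge
between two residues whenever the selected atoms are within the distance
cutoff (default 8.5 Å, inclusive).  Neighbor search uses a k-d tree; the
brute-force all-pairs scan is kept in the test suite as the oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueID, STANDARD_AMINO_ACIDS, Structure

__all__ = ["ResidueNetwork", "build_network", "write_edge_list"]

DEFAULT_CUTOFF = 8.5


@dataclass
class ResidueNetwork:
    """A residue contact graph plus the provenance of its construction."""

    graph: nx.Graph
    atom_mode: str  # "CA" or "CB"
    cutoff: float

    @property
    def nodes(self) -> list[ResidueID]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[ResidueID, ResidueID]]:
        return list(self.graph.edges)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def _node_atom(residue, atom_mode: str):
    if atom_mode == "CA":
        return residue.ca
    if atom_mode == "CB":
        return residue.cb  # Cα for glycine, handled by Residue.cb
    raise ValueError(f"unknown atom mode {atom_mode!r}; expected 'CA' or 'CB'")


def build_network(
    structure: Structure,
    atom_mode: str = "CA",
    cutoff: float = DEFAULT_CUTOFF,
    standard_only: bool = True,
) -> ResidueNetwork:
    """Build the residue network of a structure.

    Residues missing the selected atom are excluded from the node set with a
    warning.  Non-standard residues are excluded by default
    (``standard_only``).  The distance comparison is inclusive (≤ cutoff).
    """
    ids: list[ResidueID] = []
    coords: list[np.ndarray] = []
    for res in structure.residues:
        if standard_only and res.res_type not in STANDARD_AMINO_ACIDS:
            continue
        atom = _node_atom(res, atom_mode)
        if atom is None:
            warnings.warn(f"residue {res.residue_id} lacks a {atom_mode} atom; excluded")
            continue
        ids.append(res.residue_id)
        coords.append(atom.coords)
    if len(ids) < 2:
        raise ValueError("need at least 2 residues with the selected atom")

    g = nx.Graph()
    g.add_nodes_from(ids)
    pts = np.vstack(coords)
    if cutoff > 0:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(r=cutoff):  # pairs at distance <= cutoff
            g.add_edge(ids[i], ids[j])
    return ResidueNetwork(graph=g, atom_mode=atom_mode, cutoff=cutoff)


def write_edge_list(net: ResidueNetwork, path: str | Path) -> None:
    """Dump the network as one edge per line: two residue IDs, tab separated."""
    with open(path, "w") as fh:
        for (c1, n1, i1), (c2, n2, i2) in net.graph.edges:
            fh.write(f"{c1}/{n1}{i1}\t{c2}/{n2}{i2}\n")
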