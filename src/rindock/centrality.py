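"""Per-residue network topology parameters.

Four node measures are computed on the residue network:

* **closeness** — (N−1) / Σ_y d(x, y) with unweighted shortest-path hop
  counts.  On disconnected graphs each component's closeness is scaled by
  (n_comp − 1)/(N − 1) (Wasserman–Faust), keeping values comparable across
  proteins of different sizes; the unscaled within-component value is
  available via ``wf_scaling=False``.
* **degree** — fraction of the other N−1 nodes a node touches (the raw edge
  count is available via ``normalized=False``).
* **betweenness** — fraction of all-pairs shortest paths passing through the
  node, endpoints excluded, normalized by (N−1)(N−2)/2.
* **inverted clustering** — 1 / clustering coefficient.  High values track
  binding sites.  Nodes with fewer than two neighbors or with no triangles
  have no defined value: they carry NaN, are excluded from top-k ranking and
  contribute 0 to pose scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .network import ResidueNetwork
from .structure import ResidueID, Structure

__all__ = [
    "PARAMETERS",
    "CentralityProfile",
    "closeness",
    "degree",
    "betweenness",
    "clustering_inv",
    "compute_profile",
]

PARAMETERS = ("closeness", "degree", "betweenness", "clustering_inv")


def closeness(net: ResidueNetwork, wf_scaling: bool = True) -> dict[ResidueID, float]:
    """Closeness centrality (N−1)/Σd per node; 0 for isolated nodes."""
    return dict(nx.closeness_centrality(net.graph, wf_improved=wf_scaling))


def degree(net: ResidueNetwork, normalized: bool = True) -> dict[ResidueID, float]:
    """Degree as the fraction of other nodes connected (or the raw count)."""
    if normalized:
        return dict(nx.degree_centrality(net.graph))
    return {n: float(d) for n, d in net.graph.degree()}


def betweenness(net: ResidueNetwork) -> dict[ResidueID, float]:
    """Shortest-path betweenness, endpoints excluded, pair-normalized."""
    return dict(nx.betweenness_centrality(net.graph, normalized=True, endpoints=False))


def clustering_inv(net: ResidueNetwork) -> dict[ResidueID, float]:
    """Inverse clustering coefficient; NaN where clustering is undefined or 0."""
    out: dict[ResidueID, float] = {}
    for node, c in nx.clustering(net.graph).items():
        out[node] = 1.0 / c if c > 0 else math.nan
    return out


@dataclass
class CentralityProfile:
    """The four topology parameters per residue, plus construction provenance."""

    values: dict[str, dict[ResidueID, float]]
    atom_mode: str
    cutoff: float

    def parameter(self, name: str) -> dict[ResidueID, float]:
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; expected one of {PARAMETERS}"
            ) from None

    def value(self, name: str, residue_id: ResidueID) -> float:
        """Value of one parameter for one residue; NaN if absent/undefined."""
        return self.parameter(name).get(residue_id, math.nan)

    @property
    def residue_ids(self) -> list[ResidueID]:
        return list(self.values["closeness"].keys())

    def to_frame(self, structure: Optional[Structure] = None) -> pd.DataFrame:
        types = (
            {r.residue_id: r.res_type for r in structure.residues} if structure else {}
        )
        rows = []
        for rid in self.residue_ids:
            rows.append(
                {
                    "chain": rid[0],
                    "resseq": rid[1],
                    "icode": rid[2] or ".",
                    "res_type": types.get(rid, "UNK"),
                    **{p: self.values[p].get(rid, math.nan) for p in PARAMETERS},
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, structure: Optional[Structure] = None) -> None:
        df = self.to_frame(structure)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def compute_profile(net: ResidueNetwork) -> CentralityProfile:
    """All four topology parameters of a residue network."""
    return CentralityProfile(
        values={
            "closeness": closeness(net),
            "degree": degree(net),
            "betweenness": betweenness(net),
            "clustering_inv": clustering_inv(net),
        },
        atom_mode=net.atom_mode,
        cutoff=net.cutoff,
    )
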