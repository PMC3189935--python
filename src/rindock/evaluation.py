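"""Near-native labeling, top-N success rates and stratified reporting.

A pose is near-native when its ligand Cα-RMSD to the reference complex is
strictly below the threshold (10 Å).  RMSD is computed without superposition:
all poses share the receptor frame, so the deviation of the posed ligand from
the crystallographic ligand is itself the quantity of interest.  The top-N
success rate of a scoring method is the percentage of cases whose N
best-scoring poses include a near-native one, over cases that have at least
one near-native pose at all.

Reports can be stratified by user-supplied complex type, by unbound/bound
conformational change (bins < 0.5, [0.5, 1.5), ≥ 1.5 Å — the middle bin is
left-closed), by anisotropy class (oblate/spherical/prolate) and by
configurable interface-area bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import Structure

__all__ = [
    "SuccessReport",
    "ligand_rmsd",
    "success_rate",
    "success_report",
    "stratify",
    "rmsd_bin",
    "read_case_metadata",
]


def ligand_rmsd(reference_ligand: Structure, posed_ligand: Structure) -> float:
    """Cα-RMSD of the posed ligand to the reference, matched by residue ID."""
    ref = {r.residue_id: r.ca.coords for r in reference_ligand.residues if r.ca}
    dev2 = []
    for res in posed_ligand.residues:
        if res.ca is not None and res.residue_id in ref:
            d = res.ca.coords - ref[res.residue_id]
            dev2.append(float(d @ d))
    if not dev2:
        raise ValueError("no matched Cα pairs between reference and posed ligand")
    return math.sqrt(sum(dev2) / len(dev2))


def success_rate(best_ranks: Sequence[int], n: int) -> float:
    """Percentage of cases whose best near-native rank is within the top N."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if not best_ranks:
        raise ValueError("no cases")
    return 100.0 * sum(1 for r in best_ranks if r <= n) / len(best_ranks)


@dataclass
class SuccessReport:
    """Top-N success rates for N = 1..max_n over one stratum of cases."""

    stratum: str
    n_cases: int
    rates: dict[int, float]  # N -> percentage

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n_cases": self.n_cases,
            "rates": {str(k): v for k, v in self.rates.items()},
        }


def success_report(
    best_ranks: Sequence[int], stratum: str = "all", max_n: int = 10
) -> SuccessReport:
    return SuccessReport(
        stratum=stratum,
        n_cases=len(best_ranks),
        rates={n: success_rate(best_ranks, n) for n in range(1, max_n + 1)},
    )


def rmsd_bin(unbound_bound_rmsd: float) -> str:
    """Conformational-change bin: small < 0.5 ≤ medium < 1.5 ≤ large (Å)."""
    if unbound_bound_rmsd < 0.5:
        return "small"
    if unbound_bound_rmsd < 1.5:
        return "medium"
    return "large"


def stratify(
    best_ranks: Sequence[int],
    labels: Sequence[str],
    max_n: int = 10,
) -> dict[str, SuccessReport]:
    """One SuccessReport per stratum label, labels aligned with best_ranks."""
    if len(best_ranks) != len(labels):
        raise ValueError("one stratum label per case is required")
    strata: dict[str, list[int]] = {}
    for rank, label in zip(best_ranks, labels):
        strata.setdefault(label, []).append(rank)
    return {
        label: success_report(ranks, stratum=label, max_n=max_n)
        for label, ranks in sorted(strata.items())
    }


def read_case_metadata(path: str | Path) -> pd.DataFrame:
    """Case metadata TSV: case_id, complex_type, unbound_bound_rmsd, interface_area."""
    df = pd.read_csv(path, sep="\t")
    required = {"case_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def write_reports(
    reports: dict[str, SuccessReport], tsv_path: str | Path, json_path: Optional[str | Path] = None
) -> None:
    rows = []
    for label, rep in reports.items():
        for n, rate in rep.rates.items():
            rows.append(
                {"stratum": label, "n_cases": rep.n_cases, "top_n": n, "success_pct": rate}
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.2f")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps({k: v.to_dict() for k, v in reports.items()}, indent=2)
        )
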