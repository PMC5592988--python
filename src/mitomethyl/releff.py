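"""Composite mtDNA replicative-efficiency statistic.

mtDNA copy number per cell expressed against the 5mC/5hmC enrichment
ratio at the PolgA exon-2 CpG island: efficiency = copies / (5mC/5hmC)
= copies * 5hmC / 5mC. 5mC marks methylation (replication restraint) and
5hmC active demethylation, so high efficiency means many mtDNA copies
per unit of net methylation pressure at the replication-licensing locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ReplicativeEfficiency", "replicative_efficiency", "efficiency_timecourse"]


@dataclass(frozen=True)
class ReplicativeEfficiency:
    copies_per_cell: float
    e5mc: float
    e5hmc: float
    efficiency: Optional[float]  # None when e5mc == 0 (undefined, flagged)

    @property
    def defined(self) -> bool:
        return self.efficiency is not None


def replicative_efficiency(
    copies_per_cell: float, e5mc: float, e5hmc: float
) -> ReplicativeEfficiency:
    """copies / (5mC/5hmC); e5mc = 0 leaves the statistic undefined (flagged).

    ``e5mc`` and ``e5hmc`` are percent-input enrichments at the same amplicon
    (PolgA exon 2); their common scale cancels, so the statistic is invariant
    to rescaling both enrichments.
    """
    if e5hmc <= 0:
        raise ValueError("5hmC enrichment must be positive")
    if e5mc < 0:
        raise ValueError("5mC enrichment must be >= 0")
    if copies_per_cell < 0:
        raise ValueError("copies per cell must be >= 0")
    eff = None if e5mc == 0 else copies_per_cell * e5hmc / e5mc
    return ReplicativeEfficiency(copies_per_cell, e5mc, e5hmc, eff)


def efficiency_timecourse(inputs: pd.DataFrame) -> pd.DataFrame:
    """Per-line, per-day efficiencies with within-day rank ordering.

    ``inputs`` is long-format with columns line, day, copies_per_cell, e5mc,
    e5hmc (one row per line x day). Returns the same table with
    ``efficiency`` (NaN where undefined) and ``rank_within_day`` (1 = highest
    efficiency that day).
    """
    required = {"line", "day", "copies_per_cell", "e5mc", "e5hmc"}
    missing = required - set(inputs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = inputs.copy()
    effs = []
    for _, row in out.iterrows():
        r = replicative_efficiency(
            float(row["copies_per_cell"]), float(row["e5mc"]), float(row["e5hmc"])
        )
        effs.append(np.nan if r.efficiency is None else r.efficiency)
    out["efficiency"] = effs
    out["rank_within_day"] = (
        out.groupby("day")["efficiency"].rank(ascending=False, method="min")
    )
    return out.sort_values(["day", "line"]).reset_index(drop=True)
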