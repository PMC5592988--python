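"""Differential-methylation calling from two-channel MeDIP CpG arrays.

The filter cascade mirrors the study design: per-probe log2(Cy5/Cy3)
ratios (methylated fraction over input), probe Z-scores computed against
the Gaussian distribution of probes with similar melting temperature
(Tm-quantile bins), a fourfold between-group cutoff on mean differential
ratios (|delta log2| > 2) combined with a |Z| > 5 cutoff in the group
driving the difference, probe-to-gene aggregation over annotated
CpG-island intervals, and classification of line-exclusive hyper/
hypomethylated gene sets across the four cell lines.

The reference Gaussian per Tm bin is estimated robustly by default
(median and MAD) so that it describes the unaffected probe population
even when many probes are truly differential; the classical mean /
sample-SD estimator is available as ``method="classical"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

LINES = ("mus", "spretus", "dunni", "pahari")

__all__ = [
    "compute_log_ratios",
    "compute_tm_binned_zscores",
    "call_differential_probes",
    "annotate_probes",
    "aggregate_probes_to_genes",
    "AggregationSummary",
    "classify_line_specific",
    "call_per_line",
    "preprocess_array",
]

_MAD_TO_SD = 1.4826022185056018  # 1 / Phi^-1(3/4): MAD -> SD for a Gaussian


def compute_log_ratios(probes: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Add ``log2_ratio`` = log2(max(Cy5, floor) / max(Cy3, floor)).

    The intensity floor (default 1.0 arbitrary unit) avoids -inf on
    background-subtracted zeros. Probes with a missing channel are flagged
    ``valid=False`` and excluded downstream.
    """
    if floor <= 0:
        raise ValueError("intensity floor must be positive")
    out = probes.copy()
    cy3 = pd.to_numeric(out["Cy3"], errors="coerce")
    cy5 = pd.to_numeric(out["Cy5"], errors="coerce")
    valid = cy3.notna() & cy5.notna()
    ratio = np.log2(np.maximum(cy5, floor) / np.maximum(cy3, floor))
    out["log2_ratio"] = ratio.where(valid)
    out["valid"] = valid
    return out


def _bin_z(values: np.ndarray, method: str) -> np.ndarray:
    if method == "classical":
        mean = values.mean()
        sd = values.std(ddof=1) if values.size > 1 else 0.0
        if sd == 0:
            return np.zeros_like(values)
        return (values - mean) / sd
    if method == "robust":
        center = np.median(values)
        dev = values - center
        scale = _MAD_TO_SD * np.median(np.abs(dev))
        if scale == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(dev == 0, 0.0, np.sign(dev) * np.inf)
            return z
        return dev / scale
    raise ValueError("method must be 'robust' or 'classical'")


def compute_tm_binned_zscores(
    probes: pd.DataFrame,
    n_bins: int = 10,
    method: str = "robust",
) -> pd.DataFrame:
    """Add per-probe ``z_score`` computed within Tm quantile bins.

    Probes are stratified into ``n_bins`` equal-count melting-temperature
    bins; within each bin the Z-score is the probe's distance from the bin's
    Gaussian reference in reference-SD units. ``method="robust"`` (default)
    estimates the reference as median / 1.4826*MAD; ``method="classical"``
    uses mean / sample SD with the SD=0 -> z=0 rule. Bins with fewer than two
    valid probes leave z undefined (NaN) and flag ``z_defined=False``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    out = probes.copy()
    if "log2_ratio" not in out.columns:
        raise ValueError("run compute_log_ratios first (log2_ratio missing)")
    valid = out["log2_ratio"].notna()
    if "valid" in out.columns:
        valid &= out["valid"].astype(bool)

    tm = pd.to_numeric(out["Tm"], errors="coerce")
    bins = pd.Series(pd.qcut(tm[valid], q=min(n_bins, valid.sum()), labels=False,
                             duplicates="drop"), index=out.index[valid])

    z = pd.Series(np.nan, index=out.index, dtype=float)
    defined = pd.Series(False, index=out.index)
    for _, idx in bins.groupby(bins).groups.items():
        vals = out.loc[idx, "log2_ratio"].to_numpy(dtype=float)
        if vals.size < 2:
            continue
        z.loc[idx] = _bin_z(vals, method)
        defined.loc[idx] = True
    out["z_score"] = z
    out["z_defined"] = defined
    return out


def call_differential_probes(
    group_a: Sequence[pd.DataFrame],
    group_b: Sequence[pd.DataFrame],
    fold_cut: float = 2.0,
    z_cut: float = 5.0,
) -> pd.DataFrame:
    """Differential probes between two replicate groups via the filter cascade.

    Cascade: (1) the between-group difference of mean log2 ratios must exceed
    ``fold_cut`` in absolute value (fourfold at the default 2); (2) the
    probe's |Z| (median across the replicate arrays of the group driving the
    difference, i.e. the group with the larger mean |ratio|) must exceed
    ``z_cut``. Returns the called probes with signed direction.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups need at least one replicate array")

    def stack(group, col):
        frames = [df.set_index("ProbeID")[col] for df in group]
        return pd.concat(frames, axis=1)

    ratios_a = stack(group_a, "log2_ratio")
    ratios_b = stack(group_b, "log2_ratio")
    if not ratios_a.index.equals(ratios_b.index):
        ratios_b = ratios_b.reindex(ratios_a.index)
    z_a = stack(group_a, "z_score").reindex(ratios_a.index)
    z_b = stack(group_b, "z_score").reindex(ratios_a.index)

    mean_a = ratios_a.mean(axis=1)
    mean_b = ratios_b.mean(axis=1)
    delta = mean_a - mean_b

    drive_a = mean_a.abs() >= mean_b.abs()
    z_med_a = z_a.median(axis=1)
    z_med_b = z_b.median(axis=1)
    z_drive = z_med_a.where(drive_a, z_med_b)

    called = (delta.abs() > fold_cut) & (z_drive.abs() > z_cut)
    result = pd.DataFrame(
        {
            "ProbeID": delta.index,
            "mean_diff": delta.to_numpy(),
            "z": z_drive.to_numpy(),
            "direction": np.where(delta > 0, "hyper", "hypo"),
        }
    )
    return result[called.to_numpy()].reset_index(drop=True)


def annotate_probes(probes: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """Assign probes to genes by half-open interval overlap with CpG islands.

    ``islands`` is BED-like (Chr, Start, End, LocusID, GeneID). A probe
    annotates a locus/gene if its [Start, End) interval overlaps the island's.
    Unannotated probes get empty locus/gene and are reported separately by the
    aggregation step. Assumes islands do not overlap each other.
    """
    out = probes.copy()
    out["LocusID"] = ""
    out["GeneID"] = ""
    for chrom, isl in islands.groupby("Chr"):
        isl = isl.sort_values("Start")
        starts = isl["Start"].to_numpy()
        ends = isl["End"].to_numpy()
        sel = out["Chr"] == chrom
        if not sel.any():
            continue
        p_start = out.loc[sel, "Start"].to_numpy()
        p_end = out.loc[sel, "End"].to_numpy()
        idx = np.searchsorted(starts, p_start, side="right") - 1
        hit = np.full(p_start.size, -1)
        for cand in (idx, idx + 1):
            ok = (cand >= 0) & (cand < starts.size)
            ov = np.zeros(p_start.size, dtype=bool)
            c = np.clip(cand, 0, starts.size - 1)
            ov[ok] = (p_start[ok] < ends[c[ok]]) & (starts[c[ok]] < p_end[ok])
            hit = np.where((hit < 0) & ov, c, hit)
        loc = np.where(hit >= 0, isl["LocusID"].to_numpy()[np.clip(hit, 0, None)], "")
        gen = np.where(hit >= 0, isl["GeneID"].to_numpy()[np.clip(hit, 0, None)], "")
        out.loc[sel, "LocusID"] = loc
        out.loc[sel, "GeneID"] = gen
    return out


@dataclass(frozen=True)
class AggregationSummary:
    n_probes_called: int
    n_loci: int
    n_known_genes: int
    n_unannotated_probes: int


def aggregate_probes_to_genes(
    probe_calls: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_universe: Optional[Iterable[str]] = None,
) -> Tuple[pd.DataFrame, AggregationSummary]:
    """Gene-level methylation status from probe-level calls.

    Gene status follows the direction of its called probes; conflicting
    directions resolve by majority, with ties -> unchanged plus a conflict
    flag. ``annotation`` maps ProbeID -> LocusID/GeneID (empty GeneID =
    unnamed locus). Genes in ``gene_universe`` without called probes are
    reported as unchanged. The summary carries probe/locus/known-gene counts.
    """
    ann = annotation.set_index("ProbeID")[["LocusID", "GeneID"]]
    merged = probe_calls.join(ann, on="ProbeID")
    merged["LocusID"] = merged["LocusID"].fillna("")
    merged["GeneID"] = merged["GeneID"].fillna("")
    unannot = int((merged["LocusID"] == "").sum())
    annotated = merged[merged["LocusID"] != ""]

    rows = []
    for gene, grp in annotated[annotated["GeneID"] != ""].groupby("GeneID"):
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        if n_hyper > n_hypo:
            status, conflict = "hyper", n_hypo > 0
        elif n_hypo > n_hyper:
            status, conflict = "hypo", n_hyper > 0
        else:
            status, conflict = "unchanged", True
        rows.append(
            {
                "gene_id": gene,
                "status": status,
                "mean_diff": float(grp["mean_diff"].mean()),
                "max_abs_z": float(grp["z"].abs().max()),
                "n_probes": len(grp),
                "conflict": conflict,
            }
        )
    calls = pd.DataFrame(
        rows, columns=["gene_id", "status", "mean_diff", "max_abs_z", "n_probes", "conflict"]
    )
    if gene_universe is not None:
        missing = sorted(set(gene_universe) - set(calls["gene_id"]))
        if missing:
            filler = pd.DataFrame(
                {
                    "gene_id": missing,
                    "status": "unchanged",
                    "mean_diff": 0.0,
                    "max_abs_z": 0.0,
                    "n_probes": 0,
                    "conflict": False,
                }
            )
            calls = pd.concat([calls, filler], ignore_index=True)
    calls = calls.sort_values("gene_id").reset_index(drop=True)
    summary = AggregationSummary(
        n_probes_called=len(probe_calls),
        n_loci=int(annotated["LocusID"].nunique()),
        n_known_genes=int(
            annotated.loc[annotated["GeneID"] != "", "GeneID"].nunique()
        ),
        n_unannotated_probes=unannot,
    )
    return calls, summary


def classify_line_specific(
    calls_by_line: Mapping[str, pd.DataFrame],
) -> Tuple[Dict[str, Dict[str, set]], pd.DataFrame]:
    """Line-exclusive hyper/hypo gene sets plus the shared-gene table.

    A gene is exclusive to a line iff it is called (either direction) in that
    line and unchanged in every other line. Genes called in two or more lines
    are reported in the intersection table.
    """
    lines = list(calls_by_line)
    status = pd.DataFrame(
        {
            line: df.set_index("gene_id")["status"]
            for line, df in calls_by_line.items()
        }
    ).fillna("unchanged")
    called = status != "unchanged"
    n_called = called.sum(axis=1)

    exclusive: Dict[str, Dict[str, set]] = {
        line: {"hyper": set(), "hypo": set()} for line in lines
    }
    excl_genes = status.index[n_called == 1]
    for gene in excl_genes:
        line = called.columns[called.loc[gene].to_numpy()][0]
        exclusive[line][status.loc[gene, line]].add(gene)

    shared = status.loc[n_called >= 2].copy()
    shared.insert(0, "n_lines_called", n_called[n_called >= 2])
    shared = shared.reset_index().rename(columns={"index": "gene_id"})
    return exclusive, shared


def preprocess_array(
    probes: pd.DataFrame,
    floor: float = 1.0,
    n_bins: int = 10,
    z_method: str = "robust",
) -> pd.DataFrame:
    """Log ratios + Tm-binned Z-scores for one array (convenience)."""
    return compute_tm_binned_zscores(
        compute_log_ratios(probes, floor=floor), n_bins=n_bins, method=z_method
    )


def call_per_line(
    arrays_by_line: Mapping[str, Sequence[pd.DataFrame]],
    annotation: pd.DataFrame,
    fold_cut: float = 2.0,
    z_cut: float = 5.0,
    n_bins: int = 10,
    z_method: str = "robust",
    floor: float = 1.0,
    gene_universe: Optional[Iterable[str]] = None,
) -> Tuple[Dict[str, pd.DataFrame], Dict[str, Dict[str, set]], pd.DataFrame]:
    """Full per-line pipeline: one-vs-rest calls, aggregation, exclusivity.

    Each line's replicate arrays are compared against the pooled replicates
    of all other lines. Returns (gene calls per line, exclusive sets per line,
    shared-gene table).
    """
    prepped = {
        line: [preprocess_array(df, floor, n_bins, z_method) for df in dfs]
        for line, dfs in arrays_by_line.items()
    }
    if gene_universe is None:
        gene_universe = sorted(
            g for g in annotation["GeneID"].dropna().unique() if g != ""
        )
    calls_by_line: Dict[str, pd.DataFrame] = {}
    for line in prepped:
        rest = [df for other, dfs in prepped.items() if other != line for df in dfs]
        probe_calls = call_differential_probes(
            prepped[line], rest, fold_cut=fold_cut, z_cut=z_cut
        )
        calls_by_line[line], _ = aggregate_probes_to_genes(
            probe_calls, annotation, gene_universe=gene_universe
        )
    exclusive, shared = classify_line_specific(calls_by_line)
    return calls_by_line, exclusive, shared
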