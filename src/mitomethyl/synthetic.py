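"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators emulate the four study data streams: two-channel CpG-island
array probe tables with line-specific planted hyper/hypomethylation,
qPCR Ct tables produced from known standard curves, clock-like
multiple-sequence alignments evolved under GTR+Gamma from a known dated
tree, and linear-plus-noise plate-reader kinetic traces. Fixing the seed
makes every generator byte-reproducible, and zero-noise output is
recovered exactly by the matching analysis stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .phylo import EigenGtr, GtrModel

LINES = ("mus", "spretus", "dunni", "pahari")

PROBE_COLUMNS = ["ProbeID", "Chr", "Start", "End", "Tm", "Cy3", "Cy5"]

__all__ = [
    "LINES",
    "ArrayTruth",
    "SimConfig",
    "default_truth",
    "gen_cpg_arrays",
    "write_arrays",
    "read_probe_table",
    "read_annotation",
    "gen_qpcr_tables",
    "gen_clock_alignment",
    "write_fasta",
    "read_fasta",
    "gen_kinetic_trace",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class ArrayTruth:
    """One planted differentially methylated gene in one cell line."""

    gene_id: str
    line: str
    direction: str  # "hyper" or "hypo"
    planted_log2_shift: float

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.line not in LINES:
            raise ValueError(f"unknown line {self.line!r}; expected one of {LINES}")
        if self.direction == "hyper" and not self.planted_log2_shift > 0:
            raise ValueError("hyper shift must be > 0")
        if self.direction == "hypo" and not self.planted_log2_shift < 0:
            raise ValueError("hypo shift must be < 0")


@dataclass(frozen=True)
class SimConfig:
    """Array-simulation configuration.

    n_probes is derived (n_genes * probes_per_gene); Tm is drawn uniformly on
    ``tm_range`` (default 70-90 C, a plausible CpG-island probe range that
    exercises Tm binning); baseline log2 ratio is 0 for unaffected probes with
    planted shifts applied additively in log space.
    """

    n_genes: int = 500
    probes_per_gene: int = 2
    tm_range: Tuple[float, float] = (70.0, 90.0)
    noise_sd: float = 0.3
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.probes_per_gene < 1 or self.n_replicates < 1:
            raise ValueError("n_genes, probes_per_gene and n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.tm_range[0] < self.tm_range[1]:
            raise ValueError("tm_range must be an increasing interval")

    @property
    def n_probes(self) -> int:
        return self.n_genes * self.probes_per_gene


def _gene_ids(n_genes: int) -> List[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def default_truth(
    cfg: SimConfig,
    n_per_line: int = 20,
    shift_magnitude: float = 3.0,
    lines: Sequence[str] = LINES,
    seed: Optional[int] = None,
) -> List[ArrayTruth]:
    """Line-specific planted truth: disjoint genes, half hyper / half hypo.

    The default of 20 genes per line at |log2 shift| = 3 (eightfold) plants
    effects comfortably above the fourfold calling cutoff, mimicking strong
    line-specific differential methylation.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    genes = _gene_ids(cfg.n_genes)
    total = n_per_line * len(lines)
    if total > cfg.n_genes:
        raise ValueError("more planted genes than simulated genes")
    chosen = rng.choice(cfg.n_genes, size=total, replace=False)
    truth = []
    for li, line in enumerate(lines):
        for k in range(n_per_line):
            gid = genes[chosen[li * n_per_line + k]]
            direction = "hyper" if k % 2 == 0 else "hypo"
            shift = shift_magnitude if direction == "hyper" else -shift_magnitude
            truth.append(ArrayTruth(gid, line, direction, shift))
    return truth


def gen_cpg_arrays(
    cfg: SimConfig,
    truth: Sequence[ArrayTruth],
    lines: Sequence[str] = LINES,
    base_intensity: float = 1000.0,
) -> Tuple[Dict[Tuple[str, int], pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate two-channel CpG-array probe tables for each line/replicate.

    Each probe's log2(Cy5/Cy3) ratio is baseline 0 plus the planted shift (in
    the planted line only) plus N(0, noise_sd); Cy3 is held at a constant base
    intensity and Cy5 derived from the ratio. Genes occupy disjoint CpG-island
    intervals (0-based half-open) with ``probes_per_gene`` probes inside each.

    Returns (arrays, annotation, truth_table): ``arrays`` maps (line,
    replicate) to a probe DataFrame with columns ProbeID/Chr/Start/End/Tm/
    Cy3/Cy5; ``annotation`` is a BED-like probe->locus->gene table; the truth
    table is the planted-truth CSV payload.
    """
    genes = _gene_ids(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for t in truth:
        if t.gene_id not in gene_index:
            raise ValueError(f"truth references unknown gene {t.gene_id!r}")
        if t.line not in lines:
            raise ValueError(f"truth references unknown line {t.line!r}")
    seen = set()
    for t in truth:
        if (t.gene_id, t.line) in seen:
            raise ValueError(f"duplicate truth entry for {(t.gene_id, t.line)}")
        seen.add((t.gene_id, t.line))

    rng = np.random.default_rng(cfg.rng_seed)
    ppg = cfg.probes_per_gene
    n_probes = cfg.n_probes
    island_len = 1000
    gene_pitch = 2000
    probe_len = 60

    probe_ids = [f"p{i:06d}" for i in range(n_probes)]
    gene_of_probe = np.repeat(np.arange(cfg.n_genes), ppg)
    within = np.tile(np.arange(ppg), cfg.n_genes)
    starts = gene_of_probe * gene_pitch + within * (island_len // max(ppg, 1))
    ends = starts + probe_len
    tm = rng.uniform(cfg.tm_range[0], cfg.tm_range[1], size=n_probes)

    shift = np.zeros((len(lines), n_probes))
    line_index = {ln: i for i, ln in enumerate(lines)}
    for t in truth:
        shift[line_index[t.line], gene_of_probe == gene_index[t.gene_id]] = (
            t.planted_log2_shift
        )

    annotation = pd.DataFrame(
        {
            "Chr": "chrS",
            "Start": gene_of_probe * gene_pitch,
            "End": gene_of_probe * gene_pitch + island_len,
            "ProbeID": probe_ids,
            "LocusID": [f"locus_{genes[g]}" for g in gene_of_probe],
            "GeneID": [genes[g] for g in gene_of_probe],
        }
    )

    arrays: Dict[Tuple[str, int], pd.DataFrame] = {}
    for li, line in enumerate(lines):
        for rep in range(cfg.n_replicates):
            noise = (
                rng.normal(0.0, cfg.noise_sd, size=n_probes)
                if cfg.noise_sd > 0
                else np.zeros(n_probes)
            )
            ratio = shift[li] + noise
            cy3 = np.full(n_probes, base_intensity)
            cy5 = base_intensity * np.exp2(ratio)
            arrays[(line, rep)] = pd.DataFrame(
                {
                    "ProbeID": probe_ids,
                    "Chr": "chrS",
                    "Start": starts,
                    "End": ends,
                    "Tm": tm,
                    "Cy3": cy3,
                    "Cy5": cy5,
                }
            )

    truth_table = pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "line": t.line,
                "direction": t.direction,
                "planted_log2_shift": t.planted_log2_shift,
            }
            for t in truth
        ]
    )
    return arrays, annotation, truth_table


def write_arrays(
    arrays: Mapping[Tuple[str, int], pd.DataFrame],
    annotation: pd.DataFrame,
    truth_table: pd.DataFrame,
    out_dir: str,
) -> None:
    """Write probe TSVs (one per line/replicate), annotation TSV and truth CSV."""
    os.makedirs(out_dir, exist_ok=True)
    for (line, rep), df in arrays.items():
        df.to_csv(
            os.path.join(out_dir, f"array_{line}_rep{rep}.tsv"),
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    annotation.to_csv(
        os.path.join(out_dir, "annotation.tsv"), sep="\t", index=False
    )
    truth_table.to_csv(os.path.join(out_dir, "truth.csv"), index=False)


def read_probe_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path} missing columns {sorted(missing)}")
    return df


def read_annotation(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def evaluate_recovery(
    calls_by_line: Mapping[str, pd.DataFrame],
    truth_table: pd.DataFrame,
    n_genes: int,
) -> Dict[str, float]:
    """Sensitivity/specificity of gene-level calls against planted truth.

    A planted (gene, line, direction) counts as recovered only when called
    with the matching direction; any call on a non-planted (gene, line) pair
    is a false positive. Returns sensitivity, specificity and the raw counts.
    """
    truth_set = {
        (r.gene_id, r.line, r.direction) for r in truth_table.itertuples()
    }
    planted_pairs = {(g, l) for g, l, _ in truth_set}
    called = set()
    for line, df in calls_by_line.items():
        for r in df[df["status"] != "unchanged"].itertuples():
            called.add((r.gene_id, line, r.status))
    tp = len(called & truth_set)
    fp = len({(g, l) for g, l, _ in called} - planted_pairs)
    n_null = n_genes * len(calls_by_line) - len(planted_pairs)
    return {
        "sensitivity": tp / len(truth_set) if truth_set else float("nan"),
        "specificity": 1.0 - fp / n_null if n_null else float("nan"),
        "true_positives": float(tp),
        "false_positives": float(fp),
        "n_planted": float(len(truth_set)),
        "n_null": float(n_null),
    }


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def gen_qpcr_tables(
    slope: float,
    intercept: float,
    quantities: Mapping[str, float],
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: Optional[int] = None,
    target: str = "target",
    condition: str = "unknown",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table from a known standard curve: Ct = intercept + slope*log10(q) + noise.

    Returns (ct_table, truth); the truth table records the generating curve,
    its implied amplification efficiency and the true quantities.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for name, q in quantities.items():
        if not q > 0:
            raise ValueError(f"quantity for {name!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for name, q in quantities.items():
        base_ct = intercept + slope * np.log10(q)
        for rep in range(n_replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": name,
                    "target": target,
                    "condition": condition,
                    "replicate": rep,
                    "ct": base_ct + noise,
                }
            )
    ct_table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {
                "sample": name,
                "true_quantity": q,
                "slope": slope,
                "intercept": intercept,
                "efficiency": 10 ** (-1.0 / slope) - 1.0,
            }
            for name, q in quantities.items()
        ]
    )
    return ct_table, truth


# ---------------------------------------------------------------------------
# Clock-like sequence evolution
# ---------------------------------------------------------------------------


def _check_ultrametric(tree: dendropy.Tree, rtol: float = 1e-6) -> float:
    depths = []
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    for leaf in tree.leaf_node_iter():
        depths.append(leaf.root_distance)
    depths = np.asarray(depths, dtype=float)
    span = depths.max()
    if span > 0 and (depths.max() - depths.min()) > rtol * span:
        raise ValueError("input tree is not ultrametric in time")
    return float(span)


def gen_clock_alignment(
    tree: "dendropy.Tree | str",
    model: GtrModel,
    rate: float,
    n_sites: int,
    seed: Optional[int] = None,
) -> Tuple[Dict[str, str], Dict[Tuple[str, ...], float]]:
    """Evolve sequences site-wise under GTR+Gamma along a dated, clock-like tree.

    ``tree`` carries branch lengths in time units (e.g. Mya) and must be
    ultrametric; ``rate`` converts time to expected substitutions/site. Each
    site draws one of the model's discrete Gamma categories. Returns the
    alignment (taxon -> sequence) and the true node ages keyed by sorted tip
    labels.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    else:
        tree = tree.clone(depth=1)
    if rate < 0:
        raise ValueError("substitution rate must be >= 0")
    depth = _check_ultrametric(tree)

    rng = np.random.default_rng(seed)
    eig = EigenGtr(model)
    k = len(eig.rates)
    site_cat = rng.integers(0, k, size=n_sites)
    pi = np.asarray(model.base_freqs)

    seqs: Dict[str, np.ndarray] = {}
    true_ages: Dict[Tuple[str, ...], float] = {}

    root_state = rng.choice(4, size=n_sites, p=pi)
    states = {id(tree.seed_node): root_state}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        t = (node.edge.length or 0.0) * rate
        if t == 0.0:
            child = parent.copy()
        else:
            pmats = eig.prob(t)  # (K,4,4)
            cum = pmats.cumsum(axis=2)
            cum /= cum[:, :, -1:]
            child = np.empty(n_sites, dtype=np.int64)
            u = rng.random(n_sites)
            for cat in range(k):
                m = site_cat == cat
                if not m.any():
                    continue
                rows = cum[cat][parent[m]]
                child[m] = (rows < u[m, None]).sum(axis=1)
        states[id(node)] = child

    # ages: time from node down to (ultrametric) tips
    tree.calc_node_root_distances()
    nuc = np.array(list("ACGT"))
    for node in tree.preorder_node_iter():
        tips = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        age = depth - (node.root_distance or 0.0)
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(nuc[states[id(node)]])
        else:
            true_ages[tips] = float(age)
    return seqs, true_ages


def write_fasta(alignment: Mapping[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------


def gen_kinetic_trace(
    rate: float,
    intercept: float = 0.0,
    duration_min: float = 30.0,
    interval_s: float = 30.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Linear absorbance trace A(t) = intercept + rate*t(min) + N(0, noise_sd).

    The default 30-min read at 30-s intervals yields 61 points (endpoint
    included), matching a standard plate-reader kinetic protocol.
    """
    n_steps = duration_min * 60.0 / interval_s
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("duration must be an integral number of intervals")
    rng = np.random.default_rng(seed)
    t_s = np.arange(int(round(n_steps)) + 1) * interval_s
    t_min = t_s / 60.0
    noise = rng.normal(0.0, noise_sd, size=t_s.size) if noise_sd > 0 else 0.0
    return pd.DataFrame(
        {"time_s": t_s, "absorbance": intercept + rate * t_min + noise}
    )
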