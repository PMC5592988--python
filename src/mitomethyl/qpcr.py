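"""qPCR-derived quantities.

Absolute quantification against external standard curves (mtDNA copies
per cell via the beta-actin nuclear reference), delta-delta-Ct relative
expression, MeDIP/ChIP percent-input enrichment, and the Fluidigm
delta-Ct expression matrix with euclidean hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import linregress, ttest_ind

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify_from_curve",
    "copies_per_cell",
    "mean_ct",
    "ddct_fold_change",
    "percent_input",
    "fluidigm_matrix",
    "fluidigm_welch",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR dilution series: Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r2: float = 1.0

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("inverted curve: slope must be negative")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10^(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def efficiency_plausible(self) -> bool:
        return 0.0 < self.efficiency <= 1.1


def fit_standard_curve(
    log10_copies: Sequence[float], ct: Sequence[float]
) -> StandardCurve:
    """OLS fit of a dilution series (log10 copies vs Ct)."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    fit = linregress(x, y)
    curve = StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))
    if not curve.efficiency_plausible:
        warnings.warn(
            f"implausible amplification efficiency {curve.efficiency:.3f} "
            "(expected 0 < eff <= 1.1)"
        )
    return curve


def quantify_from_curve(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept)/slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copies_per_cell(
    mtdna_quantity: float,
    beta_actin_quantity: float,
    actin_copies_per_genome: float = 2.0,
) -> float:
    """mtDNA copies per cell against the beta-actin nuclear reference.

    beta-actin is a single locus on a diploid genome, i.e. 2 copies/cell by
    default (configurable): copies/cell = mtDNA / (actin / 2).
    """
    if beta_actin_quantity <= 0:
        raise ValueError("beta-actin quantity must be positive")
    if mtdna_quantity < 0:
        raise ValueError("mtDNA quantity must be >= 0")
    return mtdna_quantity / (beta_actin_quantity / actin_copies_per_genome)


def mean_ct(cts: Iterable[float]) -> float:
    """Arithmetic mean of replicate Cts, excluding non-detects (NaN)."""
    arr = np.asarray(list(cts), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no detected Ct values")
    return float(arr.mean())


def ddct_fold_change(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: 2^-ddCt."""
    for v in (ct_target_cond, ct_ref_cond, ct_target_calib, ct_ref_calib):
        if v is None or np.isnan(v):
            raise ValueError("all four mean Cts must be present")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_calib - ct_ref_calib)
    return float(2.0 ** (-ddct))


def percent_input(
    ct_ip: float, ct_input: float, input_fraction: float = 0.1
) -> float:
    """ChIP/MeDIP enrichment as percent of input.

    The input Ct is first adjusted for the fraction of chromatin saved as
    input (Ct_input - log2(1/fraction)); enrichment is then
    100 * 2^(adjusted_input_ct - ct_ip). Full recovery of the adjusted input
    is 100%; one cycle above it is 50%.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted - ct_ip))


def _cluster_or_none(mat: np.ndarray):
    if mat.shape[0] < 2:
        return None
    return linkage(mat, method="average", metric="euclidean")


def fluidigm_matrix(
    ct_table: pd.DataFrame,
    housekeeping: str = "18S",
    ct_ceiling: float = 40.0,
) -> Tuple[pd.DataFrame, Optional[np.ndarray], Optional[np.ndarray]]:
    """Housekeeping-normalised expression matrix with euclidean clustering.

    Input columns: sample, target, ct (replicates averaged beforehand or
    given per row; they are averaged here). Non-detects (NaN Ct) are imputed
    to ``ct_ceiling``. Output: genes x samples matrix of delta-Ct
    (Ct_gene - Ct_housekeeping per sample) plus average-linkage euclidean
    linkage matrices for rows (genes) and columns (samples). Samples missing
    the housekeeping target are dropped with a warning.
    """
    df = ct_table.copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce").fillna(ct_ceiling)
    wide = df.groupby(["target", "sample"])["ct"].mean().unstack("sample")
    if housekeeping not in wide.index:
        raise ValueError(f"housekeeping target {housekeeping!r} absent from table")
    hk = wide.loc[housekeeping]
    missing = hk.index[hk.isna()]
    if len(missing):
        warnings.warn(f"dropping samples without housekeeping Ct: {list(missing)}")
        wide = wide.drop(columns=missing)
        hk = hk.drop(index=missing)
    mat = wide.drop(index=housekeeping) - hk
    mat = mat.fillna(ct_ceiling - hk)
    row_linkage = _cluster_or_none(mat.to_numpy())
    col_linkage = _cluster_or_none(mat.to_numpy().T)
    return mat, row_linkage, col_linkage


def fluidigm_welch(
    matrix: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Welch's t-test per gene on delta-Ct between two sample groups.

    A plain two-group statistic (NOT a moderated/limma fit) on the
    housekeeping-normalised matrix; reports the delta-Ct difference, the
    implied fold change (2^-diff) and the Welch p-value per gene.
    """
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    stat, pval = ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "delta_ct_diff": diff,
            "fold_change": 2.0 ** (-diff),
            "t_welch": stat,
            "p_value": pval,
        }
    ).set_index("gene")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (ultrametric heights)."""
    root = to_tree(Z)

    def rec(node, parent_dist) -> str:
        blen = (parent_dist - node.dist) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{blen:.10g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{blen:.10g}"

    return rec(root, root.dist) + ";"
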