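"""Plate-reader assay arithmetic.

Alpha-ketoglutarate quantification by linear standard-curve inversion,
MDH2 specific activity from kinetic absorbance traces via the
extinction-coefficient formula U = (rA * Vcuvette) / (l * xi * Vsample *
rho), and fold changes against untreated controls.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["akg_quantity", "kinetic_rate", "mdh2_activity", "fold_change"]

XI_DEFAULT = 37.0  # extinction coefficient of the reagent dye, /mM/cm


def akg_quantity(corrected_absorbance: float, intercept: float, slope: float) -> float:
    """nmol alpha-KG by inverting the standard line: (A - intercept) / slope."""
    if slope == 0:
        raise ValueError("standard-curve slope must be nonzero")
    return (corrected_absorbance - intercept) / slope


def _r2(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(slope per x-unit, R^2); a residual-free fit counts as R^2 = 1."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    resid = y - (ym + slope * (x - xm))
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    if ss_res <= 1e-300 * max(1.0, abs(ym)):
        return slope, 1.0
    if ss_tot == 0.0:
        return slope, 1.0
    return slope, 1.0 - ss_res / ss_tot


def kinetic_rate(
    trace: pd.DataFrame, r2_threshold: float = 0.99
) -> Tuple[float, Tuple[int, int]]:
    """Initial-rate slope (AU/min) over the maximal linear prefix of a trace.

    ``trace`` has columns time_s and absorbance. The window grows from the
    first 3 points; the candidate window is the longest initial window whose
    fit R^2 stays >= ``r2_threshold``, after which trailing points whose
    absolute residual exceeds 3x the window RMSE are trimmed (R^2 alone is
    insensitive to a few plateau points when the linear signal span is large,
    so the trim removes systematic end-of-window curvature). If even 3 points
    fail the threshold the 3-point window is used. Returns
    (slope_per_min, (start, stop) indices).
    """
    t = pd.to_numeric(trace["time_s"], errors="coerce").to_numpy(dtype=float) / 60.0
    a = pd.to_numeric(trace["absorbance"], errors="coerce").to_numpy(dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    stop = 3
    for cand in range(3, t.size + 1):
        _, r2 = _r2(t[:cand], a[:cand])
        if r2 >= r2_threshold:
            stop = cand
    while stop > 3:
        x, y = t[:stop], a[:stop]
        slope, _ = _r2(x, y)
        resid = y - (y.mean() + slope * (x - x.mean()))
        rmse = np.sqrt((resid**2).sum() / max(stop - 2, 1))
        if abs(resid[-1]) > 3.0 * rmse:
            stop -= 1
        else:
            break
    slope, _ = _r2(t[:stop], a[:stop])
    return float(slope), (0, stop)


def mdh2_activity(
    r_a: float,
    v_cuvette: float,
    path_l: float,
    v_sample: float,
    rho: float,
    xi: float = XI_DEFAULT,
) -> float:
    """MDH2 specific activity U = (rA * Vcuvette) / (l * xi * Vsample * rho).

    r_a in AU/min, volumes in mL, path length in cm, xi in /mM/cm (default
    37 for the reagent dye), rho the protein mass concentration in mg/mL;
    U is umol/min per mg protein.
    """
    for name, v in (
        ("path_l", path_l),
        ("xi", xi),
        ("v_sample", v_sample),
        ("rho", rho),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if v_cuvette <= 0:
        raise ValueError("v_cuvette must be positive")
    return (r_a * v_cuvette) / (path_l * xi * v_sample * rho)


def fold_change(treated: float, untreated: float) -> float:
    """Fold change relative to the untreated control of the same line."""
    if untreated <= 0:
        raise ValueError("untreated value must be positive")
    return treated / untreated
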