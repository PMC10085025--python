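"""Phenotype estimators.

Petite frequency from colony counts, maximal growth rate (Vmax) from OD600
growth curves, a colony-size growth proxy, and qPCR relative expression via
1/Ct residual normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "petite_frequency",
    "vmax_sliding",
    "colony_growth_proxy",
    "qpcr_relative_expression",
    "strain_petite_means",
]


@dataclass
class GrowthCurve:
    """An OD600 time series for a single culture.

    Parameters
    ----------
    time_h :
        Sampling times in hours, strictly increasing.
    od :
        OD600 readings, same length as ``time_h``.
    """

    time_h: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.shape != self.od.shape:
            raise ValueError("time_h and od must be 1-D arrays of equal length")
        if self.time_h.size >= 2 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time points must be strictly increasing")

    def __len__(self) -> int:
        return self.time_h.size


def petite_frequency(petite_count: int, total_count: int) -> float:
    """Percent of colonies that are petite: ``100 * petite / total``.

    Raises
    ------
    ValueError
        If ``total_count`` is zero/negative or counts are inconsistent.
    """
    if total_count < 1:
        raise ValueError(f"total_count must be >= 1, got {total_count}")
    if not 0 <= petite_count <= total_count:
        raise ValueError(
            f"petite_count must be in [0, total_count], got {petite_count}/{total_count}"
        )
    return 100.0 * petite_count / total_count


def vmax_sliding(curve: GrowthCurve, window: int = 5) -> float:
    """Maximal growth rate: the highest OLS slope over sliding windows.

    An ordinary-least-squares line is fitted to every contiguous window of
    ``window`` consecutive readings (slopes use the actual time values, so
    irregular sampling is handled); the maximum slope, in OD/h, is returned.

    Raises
    ------
    ValueError
        If the curve has fewer than ``window`` points.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(curve)
    if n < window:
        raise ValueError(f"need at least {window} points, got {n}")
    t, y = curve.time_h, curve.od
    # vectorised per-window OLS slope: cov(t, y) / var(t)
    idx = np.arange(n - window + 1)[:, None] + np.arange(window)[None, :]
    tw, yw = t[idx], y[idx]
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    return float(slopes.max())


def colony_growth_proxy(colony_sizes) -> float:
    """Growth proxy from replicate colony sizes: max minus min (same units)."""
    sizes = np.asarray(colony_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one colony size")
    return float(sizes.max() - sizes.min())


def qpcr_relative_expression(
    ct_candidate, ct_control
) -> np.ndarray:
    """Relative expression as residuals of a 1/Ct vs 1/Ct regression.

    Fits ``1/Ct_candidate ~ 1/Ct_control`` by OLS across samples and returns
    the residuals. Regressing reciprocal Ct values against the control gene
    absorbs sample-to-sample differences in RNA extraction and cDNA synthesis
    efficiency; a higher residual corresponds to higher starting mRNA.

    Raises
    ------
    ValueError
        If fewer than 3 samples, non-positive Ct values, or a constant
        control (regression undefined).
    """
    cand = np.asarray(ct_candidate, dtype=float)
    ctrl = np.asarray(ct_control, dtype=float)
    if cand.shape != ctrl.shape or cand.ndim != 1:
        raise ValueError("candidate and control Ct vectors must match in length")
    if cand.size < 3:
        raise ValueError("need at least 3 samples per gene")
    if np.any(cand <= 0) or np.any(ctrl <= 0):
        raise ValueError("Ct values must be positive")
    x, y = 1.0 / ctrl, 1.0 / cand
    if np.ptp(x) == 0:
        raise ValueError("control 1/Ct is constant; regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def strain_petite_means(counts: pd.DataFrame) -> pd.DataFrame:
    """Average petite frequency (percent) per strain × mitotype.

    Parameters
    ----------
    counts :
        Long-format table with columns ``strain_id``, ``mitotype``,
        ``petite_count``, ``total_count`` (one row per replicate assay).

    Returns
    -------
    DataFrame with columns ``strain_id``, ``mitotype``, ``petite_pct``
    (mean of per-replicate percentages), ``petite_logit`` (empirical logit
    of the pooled counts, ``log((k + 1/2) / (n - k + 1/2))``, a
    variance-stabilising alternative response for multiplicative
    architectures), ``petite_count`` and ``total_count`` (summed over
    replicates, for binomial modelling).
    """
    required = {"strain_id", "mitotype", "petite_count", "total_count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["total_count"] < 1).any():
        raise ValueError("total_count must be >= 1 in every replicate")
    df = counts.copy()
    df["petite_pct"] = 100.0 * df["petite_count"] / df["total_count"]
    out = (
        df.groupby(["strain_id", "mitotype"], sort=True, as_index=False)
        .agg(
            petite_pct=("petite_pct", "mean"),
            petite_count=("petite_count", "sum"),
            total_count=("total_count", "sum"),
        )
    )
    out["petite_logit"] = np.log(
        (out["petite_count"] + 0.5) / (out["total_count"] - out["petite_count"] + 0.5)
    )
    return out
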