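"""Relative gene expression from qPCR Ct tables by the ddCt method.

Quantification cycle (Ct) values are first clamped: any detected Ct above the
threshold (35 cycles, set after water controls) and any undetected well (no
signal after 50 cycles) is set to 35. Replicate Ct values are averaged within
each (sample, gene) condition before the ddCt arithmetic — mean-of-Ct, i.e.
geometric-mean in expression space. Relative expression is

    2 ** -((Ct_goi - Ct_housekeeping) - (Ct_goi_ref - Ct_housekeeping_ref))

against a reference sample, and fold changes are ratios of relative
expression between treated and untreated conditions. No amplification-
efficiency correction is applied.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "CT_THRESHOLD",
    "clamp_ct",
    "clamp_plate",
    "relative_expression",
    "fold_change",
    "analyze_plate",
]

CT_THRESHOLD = 35.0


def clamp_ct(ct: float | None, threshold: float = CT_THRESHOLD) -> float:
    """Clamp one Ct value: above-threshold or undetected (NaN/None) -> threshold.

    Idempotent; detected values must lie in (0, 50].
    """
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return threshold
    ct = float(ct)
    if not 0.0 < ct <= 50.0:
        raise ValueError(f"detected ct must lie in (0, 50], got {ct}")
    return min(ct, threshold)


def clamp_plate(plate: pd.DataFrame, threshold: float = CT_THRESHOLD) -> pd.DataFrame:
    """Clamp every record of a plate; adds a boolean ``clamped`` column."""
    out = plate.copy()
    ct = out["ct"].to_numpy(float)
    detected = ~np.isnan(ct)
    if np.any((ct[detected] <= 0) | (ct[detected] > 50)):
        raise ValueError("detected ct values must lie in (0, 50]")
    clamped = ~detected | (ct > threshold)
    out["ct"] = np.where(clamped, threshold, ct)
    out["clamped"] = clamped
    return out


def relative_expression(
    ct_goi: float, ct_gapdh: float, ct_goi_ref: float, ct_gapdh_ref: float
) -> float:
    """2^-ddCt with ddCt = (ct_goi - ct_gapdh) - (ct_goi_ref - ct_gapdh_ref).

    Inputs are condition-mean Ct values, already clamped.
    """
    ddct = (ct_goi - ct_gapdh) - (ct_goi_ref - ct_gapdh_ref)
    return 2.0**-ddct


def fold_change(rel_treated: float, rel_untreated: float) -> float:
    """Ratio of relative expression, treated over untreated."""
    if not rel_untreated > 0 or not rel_treated > 0:
        raise ValueError("relative expression values must be positive")
    return rel_treated / rel_untreated


def analyze_plate(
    plate: pd.DataFrame,
    reference_sample: str,
    housekeeping: str = "GAPDH",
    threshold: float = CT_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample, per-gene relative expression vs. a reference sample.

    ``plate`` follows the qPCR table contract (sample, gene, replicate, ct;
    NaN ct = undetected). Returns one row per (sample, gene-of-interest) with
    relative_expression, n_replicates_used and n_clamped.
    """
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate is missing columns {sorted(missing)}")
    clamped = clamp_plate(plate, threshold)
    grouped = clamped.groupby(["sample", "gene"], sort=False).agg(
        mean_ct=("ct", "mean"),
        n_replicates_used=("ct", "size"),
        n_clamped=("clamped", "sum"),
    )

    def mean_ct(sample: str, gene: str) -> float:
        try:
            return float(grouped.loc[(sample, gene), "mean_ct"])
        except KeyError:
            raise ValueError(f"no records for sample={sample!r} gene={gene!r}")

    samples = clamped["sample"].unique()
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} not on plate")
    ref_gapdh = mean_ct(reference_sample, housekeeping)

    rows = []
    for sample in samples:
        gapdh = mean_ct(sample, housekeeping)
        genes = clamped.loc[clamped["sample"] == sample, "gene"].unique()
        for gene in genes:
            if gene == housekeeping:
                continue
            ref_goi = mean_ct(reference_sample, gene)
            info = grouped.loc[(sample, gene)]
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "relative_expression": relative_expression(
                        info["mean_ct"], gapdh, ref_goi, ref_gapdh
                    ),
                    "n_replicates_used": int(info["n_replicates_used"]),
                    "n_clamped": int(info["n_clamped"]),
                }
            )
    return pd.DataFrame(rows)
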