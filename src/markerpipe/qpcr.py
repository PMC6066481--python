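"""RT-qPCR quantification: standard curves and normalized copy numbers.

Cq values for a plasmid dilution series are regressed on log10 copy number
to calibrate a standard curve per gene; unknown wells are converted to copy
numbers by inverting the curve, and the target gene is normalized to the
control gene as

    NCN = scale_factor * target_copies / control_copies

with ``scale_factor`` defaulting to 100, the Europe-Against-Cancer
reporting convention for fusion-transcript assays normalized on a control
gene such as ABL1.  Replicate wells are averaged on the Cq scale before
conversion; the replicate standard deviation is kept for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CurveOrientationError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedNcnError,
)

__all__ = [
    "StandardCurve",
    "NcnValue",
    "fit_standard_curve",
    "cq_to_copies",
    "compute_ncn",
    "quantify_plate",
]

DEFAULT_SCALE_FACTOR = 100.0


@dataclass(frozen=True)
class StandardCurve:
    """Calibration line Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # E = 10**(-1/slope) - 1; 1.0 means perfect doubling

    def __post_init__(self):
        if self.slope >= 0:
            raise CurveOrientationError("standard-curve slope must be negative")


@dataclass(frozen=True)
class NcnValue:
    target_copies: float
    control_copies: float
    ncn: float


def fit_standard_curve(dilution_copies, cq, allow_positive_slope=False) -> StandardCurve:
    """Ordinary least squares of Cq on log10(copies).

    Requires at least three distinct dilution levels.  A non-negative
    fitted slope indicates a mis-oriented or failed curve and raises
    :class:`CurveOrientationError` unless explicitly allowed.
    """
    copies = np.asarray(dilution_copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.shape != cq.shape or copies.ndim != 1:
        raise InvalidInputError("dilution_copies and cq must be aligned 1-d arrays")
    if np.any(copies <= 0):
        raise InvalidInputError("dilution copies must be positive")
    if np.unique(copies).size < 3:
        raise InsufficientDataError(
            "need >= 3 distinct dilution levels for a standard curve"
        )
    res = stats.linregress(np.log10(copies), cq)
    if res.slope >= 0 and not allow_positive_slope:
        raise CurveOrientationError(
            f"fitted slope {res.slope:.3f} is not negative; check plate orientation"
        )
    r2 = float(res.rvalue**2)
    efficiency = float(10 ** (-1.0 / res.slope) - 1.0) if res.slope < 0 else np.nan
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        efficiency=efficiency,
    )


def cq_to_copies(cq: float, curve: StandardCurve) -> float:
    """Invert the calibration line: copies = 10**((cq - intercept) / slope)."""
    return float(10 ** ((cq - curve.intercept) / curve.slope))


def compute_ncn(
    target_copies: float,
    control_copies: float,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
) -> NcnValue:
    """Normalized copy number of the target relative to the control gene."""
    if target_copies < 0:
        raise InvalidInputError("target copies must be >= 0")
    if control_copies <= 0:
        raise UndefinedNcnError(
            "control gene yielded no copies; sample is non-evaluable"
        )
    return NcnValue(
        target_copies=float(target_copies),
        control_copies=float(control_copies),
        ncn=float(scale_factor * target_copies / control_copies),
    )


def quantify_plate(
    wells: pd.DataFrame,
    target_gene: str = "TARGET",
    control_gene: str = "CONTROL",
    scale_factor: float = DEFAULT_SCALE_FACTOR,
) -> pd.DataFrame:
    """Full plate pipeline: fit both standard curves, convert unknowns, NCN.

    ``wells`` is the long-format table written by the synthetic generator
    (columns well, sample_id, gene, role, known_copies, cq).  Returns one
    row per sample with copies, NCN, replicate-SD QC columns and an
    ``evaluable`` flag (False when the control gene failed to amplify).
    """
    required = {"sample_id", "gene", "role", "known_copies", "cq"}
    if not required.issubset(wells.columns):
        raise InvalidInputError(f"wells table needs columns {sorted(required)}")

    curves = {}
    for gene in (target_gene, control_gene):
        std = wells[(wells["gene"] == gene) & (wells["role"] == "standard")]
        if std.empty:
            raise InsufficientDataError(f"no standard wells for gene {gene}")
        curves[gene] = fit_standard_curve(std["known_copies"], std["cq"])

    rows = []
    unknowns = wells[wells["role"] == "unknown"]
    for sid, sub in unknowns.groupby("sample_id", sort=False):
        rec = {"sample_id": sid}
        copies = {}
        for gene in (target_gene, control_gene):
            cqs = sub.loc[sub["gene"] == gene, "cq"].to_numpy(dtype=float)
            cqs = cqs[np.isfinite(cqs)]
            tag = "target" if gene == target_gene else "control"
            if cqs.size == 0:
                copies[gene] = np.nan
                rec[f"{tag}_cq_mean"] = np.nan
                rec[f"{tag}_cq_sd"] = np.nan
                continue
            rec[f"{tag}_cq_mean"] = cqs.mean()
            rec[f"{tag}_cq_sd"] = cqs.std(ddof=1) if cqs.size > 1 else 0.0
            copies[gene] = cq_to_copies(cqs.mean(), curves[gene])
        rec["target_copies"] = copies[target_gene]
        rec["control_copies"] = copies[control_gene]
        evaluable = np.isfinite(copies[control_gene]) and copies[control_gene] > 0
        rec["evaluable"] = evaluable
        if evaluable:
            tgt = copies[target_gene] if np.isfinite(copies[target_gene]) else 0.0
            rec["ncn"] = scale_factor * tgt / copies[control_gene]
        else:
            rec["ncn"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["curves"] = curves
    return out
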