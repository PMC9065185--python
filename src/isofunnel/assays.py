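"""Closed-form bench-assay computations.

Four small formulas used to report the wet-lab readouts downstream of the
sequencing pipeline: relative qPCR quantity (RQ = 2^-ΔΔCt after double
normalization to a reference gene and a calibrator condition),
Δcytotoxicity (percentage-point change in drug cytotoxicity with vs without
particle exposure; positive means resistance), background-subtracted
percent-of-control proliferation, and caliper tumor volume
(width² × length × 0.5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ComputationError, DataError


def relative_quantity(delta_delta_ct):
    """RQ = 2^(-ΔΔCt); ΔΔCt in cycles, RQ a positive fold change."""
    ddct = np.asarray(delta_delta_ct, dtype=float)
    if not np.isfinite(ddct).all():
        raise ComputationError("ΔΔCt must be finite")
    out = np.power(2.0, -ddct)
    return out.item() if out.ndim == 0 else out


def delta_cytotoxicity(pct_with_ps, pct_without_ps):
    """Δcytotoxicity = %cytotoxicity with PS − %cytotoxicity without PS.

    Positive values indicate drug resistance, negative drug sensitivity.
    """
    a = np.asarray(pct_with_ps, dtype=float)
    b = np.asarray(pct_without_ps, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ComputationError("cytotoxicity percentages must be finite")
    out = a - b
    return out.item() if out.ndim == 0 else out


def percent_of_control(fi_sample, fi_background, fi_control):
    """Background-subtracted fluorescence as percent of the control well."""
    s = np.asarray(fi_sample, dtype=float)
    b = np.asarray(fi_background, dtype=float)
    c = np.asarray(fi_control, dtype=float)
    denom = c - b
    if (np.asarray(denom) <= 0).any():
        raise ComputationError("control intensity must exceed background")
    out = 100.0 * (s - b) / denom
    return out.item() if out.ndim == 0 else out


def tumor_volume(width_mm, length_mm):
    """Caliper tumor volume in mm³: width² × length × 0.5."""
    w = np.asarray(width_mm, dtype=float)
    ln = np.asarray(length_mm, dtype=float)
    if (w <= 0).any() or (ln <= 0).any():
        raise ComputationError("tumor dimensions must be positive")
    out = w**2 * ln * 0.5
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# table-level helpers


def qpcr_relative_quantities(
    table: pd.DataFrame, calibrator_group: str = "control"
) -> pd.DataFrame:
    """Per-group RQ from a long Ct table.

    Expects columns ``group``, ``target_ct`` and ``reference_ct``.  ΔCt is
    target − reference per well; the calibrator group's mean ΔCt anchors
    ΔΔCt, so the calibrator's RQ is 1 by construction.
    """
    required = {"group", "target_ct", "reference_ct"}
    if not required <= set(table.columns):
        raise DataError(f"qPCR table needs columns {sorted(required)}")
    if calibrator_group not in set(table["group"]):
        raise DataError(f"calibrator group {calibrator_group!r} absent")
    dct = table["target_ct"] - table["reference_ct"]
    calib = dct[table["group"] == calibrator_group].mean()
    mean_dct = dct.groupby(table["group"]).mean()
    out = pd.DataFrame({"delta_ct": mean_dct})
    out["delta_delta_ct"] = out["delta_ct"] - calib
    out["rq"] = relative_quantity(out["delta_delta_ct"].values)
    return out


def cytotoxicity_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-drug Δcytotoxicity from a long plate table.

    Expects columns ``drug``, ``condition`` (``with_ps``/``without_ps``) and
    ``pct_cytotoxicity``; well replicates are averaged per cell.
    """
    required = {"drug", "condition", "pct_cytotoxicity"}
    if not required <= set(table.columns):
        raise DataError(f"cytotoxicity table needs columns {sorted(required)}")
    means = table.groupby(["drug", "condition"])["pct_cytotoxicity"].mean()
    wide = means.unstack("condition")
    if not {"with_ps", "without_ps"} <= set(wide.columns):
        raise DataError("table must contain with_ps and without_ps conditions")
    wide["delta_cytotoxicity"] = delta_cytotoxicity(
        wide["with_ps"].values, wide["without_ps"].values
    )
    wide["call"] = np.where(wide["delta_cytotoxicity"] > 0, "resistance",
                            np.where(wide["delta_cytotoxicity"] < 0,
                                     "sensitivity", "none"))
    return wide
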