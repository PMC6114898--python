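"""Plate-reader fluorescence normalisation.

Raw fluorescence (FP) and optical density (OD) are background-corrected as

    (FP/OD)_corrected = (FP - FP_bg) / (OD - OD_bg)

with FP_bg from a no-fluorescent-protein control strain and OD_bg from a
medium blank.  Relative protein expression of a riboregulator strain is

    100 * (FP/OD)_corrected,with / (FP/OD)_corrected,without   [%]

Replicates are combined as a ratio of means (the defining equation is
written on single corrected values; the replicate convention is stated in
the output metadata) with the standard deviation propagated by the delta
method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tirnakit")

ROLES = ("sample", "medium_blank", "no_fp_control")


class PlateError(ValueError):
    pass


@dataclass
class ExpressionSummary:
    strain: str
    corrected_mean: float
    corrected_sd: float
    n: int
    relative_expression: float | None = None  # percent
    relative_sd: float | None = None


def corrected_fpod(fp: float, od: float, fp_bg: float, od_bg: float) -> float:
    """Background-corrected fluorescence per OD for one well."""
    if od <= od_bg:
        raise PlateError(
            f"invalid well: OD ({od}) must exceed the medium blank ({od_bg})"
        )
    return (fp - fp_bg) / (od - od_bg)


def relative_expression(
    with_reg: np.ndarray | list, without_reg: np.ndarray | list
) -> tuple[float, float]:
    """(percent, sd) of expression with riboregulator relative to without.

    Ratio of replicate means; sd propagated by the delta method using the
    replicate standard deviations (ddof=1).
    """
    w = np.asarray(with_reg, dtype=float)
    wo = np.asarray(without_reg, dtype=float)
    if w.size == 0 or wo.size == 0:
        raise PlateError("empty replicate set")
    m_w, m_wo = w.mean(), wo.mean()
    if m_wo <= 0:
        raise PlateError("reference (without riboregulator) mean must be positive")
    rel = 100.0 * m_w / m_wo
    s_w = w.std(ddof=1) if w.size > 1 else 0.0
    s_wo = wo.std(ddof=1) if wo.size > 1 else 0.0
    if m_w == 0.0:
        sd = 100.0 * s_w / m_wo
    else:
        sd = abs(rel) * np.sqrt((s_w / m_w) ** 2 + (s_wo / m_wo) ** 2)
    return float(rel), float(sd)


def analyze_plate(
    records: pd.DataFrame, reference_strain: str
) -> pd.DataFrame:
    """Summarise a long-format plate table.

    ``records`` columns: strain, FP, OD, role (sample | medium_blank |
    no_fp_control); one row per well.  Background values are the means of
    the control wells.  Wells with OD <= OD_bg are flagged and excluded.
    Returns one row per sample strain with corrected FP/OD (mean, sd, n) and
    relative expression (%) against ``reference_strain``.
    """
    required = {"strain", "FP", "OD", "role"}
    if not required.issubset(records.columns):
        raise PlateError(f"plate table must have columns {sorted(required)}")
    bad_roles = set(records["role"]) - set(ROLES)
    if bad_roles:
        raise PlateError(f"unknown roles {sorted(bad_roles)}")
    od_bg = records.loc[records["role"] == "medium_blank", "OD"].mean()
    fp_bg = records.loc[records["role"] == "no_fp_control", "FP"].mean()
    if np.isnan(od_bg) or np.isnan(fp_bg):
        raise PlateError("plate table needs medium_blank and no_fp_control wells")
    samples = records[records["role"] == "sample"]
    corrected: dict[str, list[float]] = {}
    for _, row in samples.iterrows():
        try:
            val = corrected_fpod(row["FP"], row["OD"], fp_bg, od_bg)
        except PlateError as exc:
            logger.warning("strain %s: %s (well excluded)", row["strain"], exc)
            continue
        corrected.setdefault(row["strain"], []).append(val)
    if reference_strain not in corrected:
        raise PlateError(f"reference strain {reference_strain!r} has no valid wells")
    ref = np.asarray(corrected[reference_strain])
    rows = []
    for strain, vals in corrected.items():
        arr = np.asarray(vals)
        rel, rel_sd = relative_expression(arr, ref)
        rows.append(
            {
                "strain": strain,
                "corrected_mean": arr.mean(),
                "corrected_sd": arr.std(ddof=1) if arr.size > 1 else 0.0,
                "n": arr.size,
                "relative_expression": rel,
                "relative_sd": rel_sd,
            }
        )
    out = pd.DataFrame(rows).set_index("strain")
    out.attrs["convention"] = "ratio of replicate means; delta-method sd"
    out.attrs["reference_strain"] = reference_strain
    return out
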