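"""Anthropometric status and weight-perception classification.

BMI is computed from measured weight (corrected for the weight of the
school uniform, 100 g by default) and height.  Anthropometric status is a
band of the BMI-for-age percentile relative to the WHO 2007 growth
reference; the percentile itself is an *input* — either precomputed, or
derived from a user-supplied LMS reference table via :func:`lms_percentile`.

The divergence between measured and perceived weight (DMPW) compares the
measured status with the adolescent's self-perception ("How do you feel
about your weight?").  Both scales are collapsed to three ordinal levels —
thin(0) / normal(1) / fat(2), with overweight and obese sharing level 2
because the perception scale tops out at "fat/very fat" — and the
comparison is ordinal:

* Agreed          perceived level == measured level
* Underestimated  perceived level <  measured level
* Overestimated   perceived level >  measured level

Two structural impossibilities follow: an underweight subject cannot
underestimate, and an overweight or obese subject cannot overestimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "STATUSES",
    "PERCEPTION_RESPONSES",
    "DMPW_LABELS",
    "AnthropometryError",
    "compute_bmi",
    "classify_status",
    "collapse_perception",
    "perceived_level",
    "measured_level",
    "classify_dmpw",
    "annotate_cohort",
    "dmpw_frequency_table",
    "lms_percentile",
]

STATUSES = ("underweight", "normal", "overweight", "obese")
PERCEPTION_RESPONSES = ("very thin", "thin", "normal", "fat", "very fat")
COLLAPSED_LEVELS = ("thin", "normal", "fat")
DMPW_LABELS = ("Agreed", "Underestimated", "Overestimated")

#: Percentile bands (closed-left) for BMI-for-age status.
STATUS_BANDS = ((0.0, 3.0), (3.0, 85.0), (85.0, 97.0), (97.0, 100.0))

_COLLAPSE = {
    "very thin": "thin",
    "thin": "thin",
    "normal": "normal",
    "fat": "fat",
    "very fat": "fat",
}
_LEVEL_OF_COLLAPSED = {"thin": 0, "normal": 1, "fat": 2}
#: Overweight and obese share the top measured level; see module docstring.
_LEVEL_OF_STATUS = {"underweight": 0, "normal": 1, "overweight": 2, "obese": 2}


class AnthropometryError(ValueError):
    """Invalid anthropometric or perception input."""


def compute_bmi(
    measured_weight_kg: float, height_m: float, uniform_mass_kg: float = 0.1
) -> float:
    """BMI (kg/m^2) after subtracting the uniform's weight from the scale reading."""
    if height_m <= 0:
        raise AnthropometryError(f"nonpositive height: {height_m!r}")
    corrected = measured_weight_kg - uniform_mass_kg
    if corrected <= 0:
        raise AnthropometryError(
            f"corrected weight nonpositive: {measured_weight_kg!r} - {uniform_mass_kg!r}"
        )
    return corrected / height_m**2


def classify_status(percentile: float) -> str:
    """Map a BMI-for-age percentile to an anthropometric status band.

    Bands are closed on the left: [0,3) underweight, [3,85) normal,
    [85,97) overweight, [97,100] obese.
    """
    if not 0.0 <= percentile <= 100.0:
        raise AnthropometryError(f"percentile out of [0,100]: {percentile!r}")
    if percentile < 3.0:
        return "underweight"
    if percentile < 85.0:
        return "normal"
    if percentile < 97.0:
        return "overweight"
    return "obese"


def collapse_perception(response: str) -> str:
    """Collapse the 5-level perception response to thin / normal / fat."""
    try:
        return _COLLAPSE[response]
    except KeyError:
        raise AnthropometryError(
            f"unknown perception response {response!r}; "
            f"expected one of {PERCEPTION_RESPONSES}"
        ) from None


def perceived_level(response: str) -> int:
    """Ordinal perceived level 0/1/2 from a raw or collapsed response."""
    collapsed = _COLLAPSE.get(response, response)
    try:
        return _LEVEL_OF_COLLAPSED[collapsed]
    except KeyError:
        raise AnthropometryError(f"unknown perception level {response!r}") from None


def measured_level(status: str) -> int:
    """Ordinal measured level 0/1/2 from anthropometric status."""
    try:
        return _LEVEL_OF_STATUS[status]
    except KeyError:
        raise AnthropometryError(
            f"unknown status {status!r}; expected one of {STATUSES}"
        ) from None


def classify_dmpw(status: str, perception: str) -> str:
    """Classify the divergence between measured and perceived weight.

    ``perception`` may be a raw 5-level response or a collapsed level.
    """
    m = measured_level(status)
    p = perceived_level(perception)
    if p == m:
        return "Agreed"
    return "Underestimated" if p < m else "Overestimated"


def annotate_cohort(
    cohort: pd.DataFrame, uniform_mass_kg: float = 0.1, overwrite: bool = False
) -> pd.DataFrame:
    """Add derived columns (bmi, status, dmpw) to a cohort table.

    Expects columns ``weight_kg`` (scale reading, uniform included),
    ``height_m``, ``bmi_for_age_percentile``, ``perceived_response``.
    Existing derived columns are kept unless ``overwrite`` is set.
    """
    out = cohort.copy()
    if overwrite or "bmi" not in out.columns:
        out["bmi"] = [
            compute_bmi(w, h, uniform_mass_kg)
            for w, h in zip(out["weight_kg"], out["height_m"])
        ]
    if overwrite or "status" not in out.columns:
        out["status"] = [classify_status(p) for p in out["bmi_for_age_percentile"]]
    if overwrite or "dmpw" not in out.columns:
        out["dmpw"] = [
            classify_dmpw(s, r)
            for s, r in zip(out["status"], out["perceived_response"])
        ]
    return out


def dmpw_frequency_table(
    subjects: pd.DataFrame, by: str | None = None, ndigits: int = 1
) -> pd.DataFrame:
    """Counts and percentages of subjects by DMPW, optionally cross-tabulated.

    Parameters
    ----------
    subjects : DataFrame
        Must carry a ``dmpw`` column.
    by : str, optional
        A categorical column (e.g. ``sex`` or ``status``); when given the
        table has one (dmpw, level) row per cell with within-DMPW and
        within-level percentages, supporting the usual stacked-bar panels.
    ndigits : int
        Rounding applied to the percentage columns (1 decimal by default).
    """
    if len(subjects) == 0:
        raise AnthropometryError("empty cohort")
    if "dmpw" not in subjects.columns:
        raise AnthropometryError("cohort lacks a 'dmpw' column")
    n = len(subjects)
    labels = [l for l in DMPW_LABELS if l in set(subjects["dmpw"])]
    if by is None:
        counts = subjects["dmpw"].value_counts().reindex(labels).astype(int)
        table = pd.DataFrame(
            {
                "dmpw": labels,
                "count": counts.to_numpy(),
                "percent": np.round(100.0 * counts.to_numpy() / n, ndigits),
            }
        )
        return table
    cross = (
        subjects.groupby(["dmpw", by], observed=True).size().rename("count").reset_index()
    )
    totals_dmpw = cross.groupby("dmpw")["count"].transform("sum")
    totals_by = cross.groupby(by)["count"].transform("sum")
    cross["percent_within_dmpw"] = np.round(100.0 * cross["count"] / totals_dmpw, ndigits)
    cross[f"percent_within_{by}"] = np.round(100.0 * cross["count"] / totals_by, ndigits)
    cross["percent_of_total"] = np.round(100.0 * cross["count"] / n, ndigits)
    return cross


def lms_percentile(
    bmi: float, L: float, M: float, S: float
) -> float:
    """BMI-for-age percentile from LMS reference parameters.

    Standard LMS z-score: z = ((bmi/M)**L - 1) / (L*S) for L != 0,
    z = ln(bmi/M)/S for L == 0; percentile = 100 * Phi(z).
    """
    if bmi <= 0 or M <= 0 or S <= 0:
        raise AnthropometryError("bmi, M and S must be positive")
    if abs(L) < 1e-12:
        z = np.log(bmi / M) / S
    else:
        z = ((bmi / M) ** L - 1.0) / (L * S)
    return float(100.0 * sps.norm.cdf(z))
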