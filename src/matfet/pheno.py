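"""Pregnancy phenotype definitions: eligibility filtering and case/control labels.

All thresholds are in days with completed weeks converted as weeks x 7:
37 weeks = 259 d, 39 weeks = 273 d, 41 weeks = 287 d, 42 weeks = 294 d.
Eligible pregnancies are singleton live births with spontaneous onset of
delivery lasting 140-310 days (20-44 completed weeks), free of maternal
complications and congenital malformations.  ICD-10 codes O60 (preterm
labor) and O48 (post-term pregnancy) are honored prefix-wise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GD_MIN = 140     # < 140 d excluded (20 completed weeks)
GD_MAX = 310     # > 310 d excluded (44 completed weeks)
PRETERM_CUT = 259        # case: spontaneous delivery < 259 d (37 wk)
TERM_CONTROL_LO = 273    # controls: 273-294 d (39-42 wk)
TERM_CONTROL_HI = 294
POSTTERM_CUT = 294       # case: delivery > 294 d (42 wk)
FULLTERM_HI = 287        # PGS validation full-term: [273, 287) d (39 to <41 wk)

ONSETS = ("spontaneous", "induced", "planned_cesarean")


def _icd_match(codes, prefix: str) -> pd.Series:
    def match(c) -> bool:
        if c is None or (isinstance(c, float) and np.isnan(c)):
            return False
        items = c if isinstance(c, (list, set, tuple)) else str(c).split(";")
        return any(str(x).strip().upper().startswith(prefix) for x in items if str(x).strip())

    return codes.apply(match)


def filter_eligible(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the cohort inclusion rules; returns (retained, exclusion counts).

    Rules, applied in order with the first failing rule recorded per row:
    missing GD; GD < 140 d; GD > 310 d; non-singleton; not live born;
    non-spontaneous onset; maternal complication; congenital malformation.
    """
    rec = records.copy()
    gd = pd.to_numeric(rec.get("gestational_duration"), errors="coerce")
    reasons = pd.Series(pd.NA, index=rec.index, dtype="string")

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal reasons
        reasons = reasons.mask(reasons.isna() & mask, reason)

    flag(gd.isna(), "missing_gd")
    flag(gd < GD_MIN, "gd_below_140")
    flag(gd > GD_MAX, "gd_above_310")
    if "plurality" in rec:
        flag(pd.to_numeric(rec["plurality"], errors="coerce").fillna(1) != 1, "non_singleton")
    if "live_birth" in rec:
        flag(~rec["live_birth"].astype(bool), "not_live_birth")
    if "onset" in rec:
        flag(rec["onset"] != "spontaneous", "non_spontaneous_onset")
    if "complication_flag" in rec:
        flag(rec["complication_flag"].astype(bool), "complication")
    if "malformation_flag" in rec:
        flag(rec["malformation_flag"].astype(bool), "malformation")

    counts = reasons.value_counts()
    retained = rec[reasons.isna()].copy()
    return retained, counts


def label_preterm(records: pd.DataFrame, controls_spontaneous_only: bool = False) -> pd.Series:
    """Spontaneous preterm delivery labels: 1 = case, 0 = control, NA otherwise.

    Cases: spontaneous delivery < 259 d or ICD-10 O60.  Controls: delivery
    at 273-294 d; medically initiated deliveries in that window count as
    controls unless ``controls_spontaneous_only``.
    """
    gd = pd.to_numeric(records.get("gestational_duration"), errors="coerce")
    onset = records.get("onset", pd.Series("spontaneous", index=records.index))
    icd_o60 = (
        _icd_match(records["icd_codes"], "O60")
        if "icd_codes" in records
        else pd.Series(False, index=records.index)
    )
    spont = onset == "spontaneous"
    case = (spont & (gd < PRETERM_CUT)) | icd_o60
    control = (gd >= TERM_CONTROL_LO) & (gd <= TERM_CONTROL_HI) & ~case
    if controls_spontaneous_only:
        control &= spont
    out = pd.Series(pd.NA, index=records.index, dtype="Int64")
    out[control] = 0
    out[case] = 1
    return out


def label_postterm(records: pd.DataFrame) -> pd.Series:
    """Post-term delivery labels: case if GD > 294 d or ICD-10 O48; control
    if spontaneous delivery at 273-294 d; NA otherwise."""
    gd = pd.to_numeric(records.get("gestational_duration"), errors="coerce")
    onset = records.get("onset", pd.Series("spontaneous", index=records.index))
    icd_o48 = (
        _icd_match(records["icd_codes"], "O48")
        if "icd_codes" in records
        else pd.Series(False, index=records.index)
    )
    case = (gd > POSTTERM_CUT) | icd_o48
    control = (
        (onset == "spontaneous")
        & (gd >= TERM_CONTROL_LO)
        & (gd <= TERM_CONTROL_HI)
        & ~case
    )
    out = pd.Series(pd.NA, index=records.index, dtype="Int64")
    out[control] = 0
    out[case] = 1
    return out


def dichotomize_for_validation(records: pd.DataFrame) -> pd.Series:
    """Score-validation dichotomy: preterm (< 259 d, i.e. < 37 wk) vs
    full term (273 d <= GD < 287 d, i.e. >= 39 and < 41 wk); NA otherwise."""
    gd = pd.to_numeric(records.get("gestational_duration"), errors="coerce")
    out = pd.Series(pd.NA, index=records.index, dtype="Int64")
    out[(gd >= TERM_CONTROL_LO) & (gd < FULLTERM_HI)] = 0
    out[gd < PRETERM_CUT] = 1
    return out
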