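"""Outcome and exposure definitions.

Three binary disability outcomes are derived from the six Katz activities of
daily living (ADL) items — bathing, dressing, toileting, transferring,
preparing a meal, self-feeding — each scored 0 (no difficulty) to 4
(inability to do it alone), plus a direct self-report question:

* ``disabled`` — any restriction in performing an ADL (any item >= 1);
* ``severely_disabled`` — inability to perform at least one ADL alone
  (any item == 4);
* ``self_reported`` — affirmative answer to "Do you consider that you have
  a disability?".

Chronic-condition exposures are 12 ICD-10 condition groups derived from a
checklist of 52 disorders.  A checklist entry counts as disease only if it
was physician-diagnosed (symptom items such as back pain, neck pain and
headache are exempt), was treated during the previous year (where the
treatment rule applies), and is not a stroke left without sequelae.
Obesity is derived from height and weight as BMI >= 30 kg/m2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ADL_ITEMS = (
    "bathing",
    "dressing",
    "toileting",
    "transferring",
    "preparing_meal",
    "self_feeding",
)

CONDITION_GROUPS = (
    "cancer",
    "cardiovascular",
    "dermatological",
    "digestive",
    "endocrine",
    "musculoskeletal",
    "neurological",
    "psychiatric",
    "respiratory",
    "sensorial",
    "sequelae_of_injury",
    "urological",
)

BMI_OBESITY_THRESHOLD = 30.0


class OutcomeError(ValueError):
    """Raised on invalid ADL profiles or unknown checklist codes."""


@dataclass(frozen=True)
class DisabilityStatus:
    self_reported: bool
    disabled: bool
    severely_disabled: bool


@dataclass(frozen=True)
class ChecklistEntry:
    """One reported disorder from the 52-item checklist."""

    code: str
    physician_diagnosed: bool = False
    treated_last_year: bool = False
    stroke_without_sequelae: bool = False


def load_condition_mapping() -> pd.DataFrame:
    """Return the bundled code -> condition-group mapping table.

    Columns: ``code, label, group, symptom_exempt, treatment_rule_applies``.
    Users may supply an edited copy to :func:`map_conditions`.
    """
    with resources.files("comorbid_aaf.data").joinpath("condition_groups.csv").open() as fh:
        tbl = pd.read_csv(fh)
    tbl["symptom_exempt"] = tbl["symptom_exempt"].astype(bool)
    tbl["treatment_rule_applies"] = tbl["treatment_rule_applies"].astype(bool)
    return tbl


def classify_disability(
    adl: Sequence[Optional[int]],
    self_report_answer: bool,
    missing_policy: str = "error",
) -> DisabilityStatus:
    """Classify one respondent's disability status from the six ADL items.

    Parameters
    ----------
    adl
        Six item scores, each in {0,1,2,3,4}; ``None``/NaN marks a missing
        item.
    self_report_answer
        Answer to the self-reported-disability question.
    missing_policy
        ``"error"`` (default) refuses missing items; ``"available_case"``
        treats a missing item as 0, restricting the definitions to the
        observed items.
    """
    if len(adl) != len(ADL_ITEMS):
        raise OutcomeError(f"expected {len(ADL_ITEMS)} ADL items, got {len(adl)}")
    scores = []
    for name, v in zip(ADL_ITEMS, adl):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            if missing_policy == "error":
                raise OutcomeError(f"missing ADL item: {name}")
            elif missing_policy == "available_case":
                v = 0
            else:
                raise OutcomeError(f"unknown missing_policy: {missing_policy!r}")
        iv = int(v)
        if iv != v or not 0 <= iv <= 4:
            raise OutcomeError(f"ADL item {name} out of range 0-4: {v!r}")
        scores.append(iv)
    disabled = any(s >= 1 for s in scores)
    severe = any(s == 4 for s in scores)
    return DisabilityStatus(
        self_reported=bool(self_report_answer),
        disabled=disabled,
        severely_disabled=severe,
    )


def classify_disability_table(
    adl_table: pd.DataFrame,
    self_report: pd.Series,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Vectorised :func:`classify_disability` over a table of respondents.

    ``adl_table`` must carry the six columns named in :data:`ADL_ITEMS`.
    Returns a frame with boolean columns ``self_reported``, ``disabled``,
    ``severely_disabled``.
    """
    missing_cols = [c for c in ADL_ITEMS if c not in adl_table.columns]
    if missing_cols:
        raise OutcomeError(f"missing ADL columns: {missing_cols}")
    items = adl_table.loc[:, list(ADL_ITEMS)]
    if items.isna().any().any():
        if missing_policy == "error":
            bad = items.columns[items.isna().any()].tolist()
            raise OutcomeError(f"missing ADL item values in columns: {bad}")
        items = items.fillna(0)
    arr = items.to_numpy()
    if ((arr < 0) | (arr > 4) | (arr != np.floor(arr))).any():
        raise OutcomeError("ADL items must be integers in 0-4")
    out = pd.DataFrame(index=adl_table.index)
    out["self_reported"] = self_report.astype(bool).to_numpy()
    out["disabled"] = (arr >= 1).any(axis=1)
    out["severely_disabled"] = (arr == 4).any(axis=1)
    return out


def _entry_qualifies(entry: ChecklistEntry, row: pd.Series) -> bool:
    if entry.code == "stroke" and entry.stroke_without_sequelae:
        return False
    diagnosed = entry.physician_diagnosed or row["symptom_exempt"]
    treated = entry.treated_last_year or not row["treatment_rule_applies"]
    return bool(diagnosed and treated)


def map_conditions(
    checklist: Iterable[ChecklistEntry],
    height_m: Optional[float] = None,
    weight_kg: Optional[float] = None,
    mapping: Optional[pd.DataFrame] = None,
) -> Mapping[str, Optional[bool]]:
    """Collapse a raw disorder checklist into the 12 condition-group flags.

    A group flag is True iff at least one member disorder qualifies under
    the diagnosis / treatment / stroke-sequelae rules.  Obesity (endocrine
    group) is derived from height and weight; if both group members are
    absent *and* height/weight are unavailable the endocrine flag is
    returned as ``None`` (unknown) rather than False.
    """
    if mapping is None:
        mapping = load_condition_mapping()
    idx = mapping.set_index("code")
    profile: dict[str, Optional[bool]] = {g: False for g in CONDITION_GROUPS}
    for entry in checklist:
        if entry.code not in idx.index:
            raise OutcomeError(f"unknown checklist code: {entry.code!r}")
        row = idx.loc[entry.code]
        if _entry_qualifies(entry, row):
            profile[str(row["group"])] = True

    bmi_known = height_m is not None and weight_kg is not None
    if bmi_known:
        if height_m <= 0:
            raise OutcomeError("height must be positive")
        if weight_kg / height_m**2 >= BMI_OBESITY_THRESHOLD:
            profile["endocrine"] = True
    elif not profile["endocrine"]:
        # obesity status cannot be ruled out without anthropometry
        profile["endocrine"] = None
    return profile
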