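"""End-to-end analysis pipeline and report writers.

Given respondent microdata (or a synthetic-survey spec), the pipeline runs
the weight chain, derives the three disability outcomes from the ADL items
and the self-report answer, and, per disability definition and age class,
produces: weighted prevalence tables, gross attributable-fraction tables
(Levin AF with Fleiss-style CIs), the low-AF grouping into "other diseases",
and the average-attributable-fraction table with ranks and expected
prevented-case counts.  All randomness flows from one config seed; two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import af as af_mod
from . import weighting
from .aaf import AAFResult, aaf_analysis
from .outcomes import ADL_ITEMS, classify_disability_table
from .synthetic import AGE_CLASSES, age_class_of

logger = logging.getLogger(__name__)

DEFINITIONS = ("self_reported", "disability", "severe")

_OUTCOME_COLUMN = {
    "self_reported": "self_reported",
    "disability": "disabled",
    "severe": "severely_disabled",
}

DEFAULT_COVARIATES = (
    "sex",
    "residence",
    "marital_status",
    "living_alone",
    "education_level",
)


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    microdata: Optional[str] = None
    output_dir: str = "results"
    definitions: Sequence[str] = DEFINITIONS
    age_classes: Sequence[str] = ("total",) + AGE_CLASSES
    conditions: Optional[Sequence[str]] = None
    covariates: Sequence[str] = DEFAULT_COVARIATES
    propensity_predictors: Sequence[str] = ("age", "sex", "presumed_severity")
    margins: Optional[Mapping[str, Mapping[object, float]]] = None
    af_group_threshold: float = af_mod.DEFAULT_AF_GROUP_THRESHOLD
    group_per_age_class: bool = False
    aaf_mode: str = "exact"
    n_perms: int = 5000
    rounding: int = 10_000
    sum_mode: str = "raw"  # or "sum_of_rounded"
    seed: int = 0

    def validate(self) -> None:
        if not self.definitions:
            raise PipelineError("definitions must be nonempty")
        bad = [d for d in self.definitions if d not in DEFINITIONS]
        if bad:
            raise PipelineError(f"unknown definitions: {bad}")
        if not 0 <= self.af_group_threshold < 1:
            raise PipelineError("af_group_threshold must lie in [0,1)")
        if self.sum_mode not in ("raw", "sum_of_rounded"):
            raise PipelineError(f"unknown sum_mode: {self.sum_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise PipelineError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    prevalence: pd.DataFrame
    gross_af: pd.DataFrame
    grouping: dict
    aaf_tables: dict[tuple[str, str], AAFResult]
    run_log: dict


def _ensure_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Derive outcome flags from ADL items + self-report when absent."""
    needed = {"self_reported", "disabled", "severely_disabled"}
    if needed <= set(records.columns):
        return records
    if not set(ADL_ITEMS) <= set(records.columns):
        raise PipelineError(
            "microdata must carry either the outcome flags or the six ADL "
            f"item columns {list(ADL_ITEMS)}"
        )
    status = classify_disability_table(records, records["self_reported_disabled"])
    out = records.copy()
    for col in ("self_reported", "disabled", "severely_disabled"):
        out[col] = status[col]
    return out


def _subset(records: pd.DataFrame, age_class: str) -> pd.DataFrame:
    if age_class == "total":
        return records
    return records.loc[records["age_class"] == age_class]


def run_analysis(
    config: RunConfig, records: Optional[pd.DataFrame] = None
) -> ReportBundle:
    """Execute the full weighting -> outcomes -> AF -> AAF analysis.

    ``records`` may be passed directly (e.g. a synthetic survey table);
    otherwise ``config.microdata`` is read as CSV.
    """
    config.validate()
    run_log: dict = {"seed": config.seed, "stages": {}}
    if records is None:
        if config.microdata is None:
            raise PipelineError("either records or config.microdata is required")
        records = pd.read_csv(config.microdata)
    records = records.copy()
    if "age_class" not in records.columns:
        records["age_class"] = age_class_of(records["age"].to_numpy())

    # weight chain
    if "responded" in records.columns:
        records, cal_report = weighting.build_weight_chain(
            records, list(config.propensity_predictors), config.margins
        )
        run_log["stages"]["weighting"] = {
            "n_respondents": int(len(records)),
            "calibration": None
            if cal_report is None
            else {
                "iterations": cal_report.n_iterations,
                "max_relative_margin_error": cal_report.max_relative_margin_error,
            },
        }
    elif "calibrated_weight" not in records.columns:
        w = records.get("design_weight", pd.Series(1.0, index=records.index))
        records["calibrated_weight"] = w
        run_log["stages"]["weighting"] = {"note": "no response indicator; weights passed through"}

    records = _ensure_outcomes(records)

    if config.conditions is not None:
        conditions = list(config.conditions)
    else:
        from .outcomes import CONDITION_GROUPS

        conditions = [c for c in CONDITION_GROUPS if c in records.columns]
    if not conditions:
        raise PipelineError("no condition columns found in the microdata")

    wcol = "calibrated_weight"
    strata = "stratum_id" if "stratum_id" in records.columns else None

    # weighted prevalence per condition x age class
    prev_rows = []
    for ac in config.age_classes:
        sub = _subset(records, ac)
        for c in conditions:
            p, (lo, hi) = af_mod.weighted_prevalence(sub, c, wcol, strata=strata)
            prev_rows.append(
                {"age_class": ac, "condition": c, "prevalence": p, "ci_low": lo, "ci_high": hi}
            )
    prevalence = pd.DataFrame(prev_rows)

    # gross AF per definition x age class x condition
    af_rows = []
    for d in config.definitions:
        outcome = _OUTCOME_COLUMN[d]
        for ac in config.age_classes:
            sub = _subset(records, ac)
            for c in conditions:
                r = af_mod.af_from_table(
                    sub, c, outcome, wcol, strata=strata, definition=d, age_class=ac
                )
                af_rows.append(dataclasses.asdict(r))
    gross_af = pd.DataFrame(af_rows)

    # grouping: union of low-AF conditions across age classes (default),
    # decided per definition on the per-age-class gross AFs
    grouping: dict = {}
    aaf_tables: dict[tuple[str, str], AAFResult] = {}
    for d in config.definitions:
        outcome = _OUTCOME_COLUMN[d]
        daf = gross_af.loc[gross_af["definition"] == d]
        per_class = daf.loc[daf["age_class"] != "total"]
        if per_class.empty:
            per_class = daf
        max_af = per_class.groupby("condition", sort=False)["af"].max()
        retained = [c for c in conditions if max_af[c] > config.af_group_threshold]
        grouped = [c for c in conditions if max_af[c] <= config.af_group_threshold]
        if not retained:
            raise PipelineError(f"[af:{d}] all conditions at or below grouping threshold")
        grouping[d] = {"retained": retained, "grouped": grouped}
        for ac in config.age_classes:
            sub = _subset(records, ac)
            if config.group_per_age_class:
                sub_af = daf.loc[daf["age_class"] == ac].set_index("condition")["af"]
                retained_ac, grouped_ac = af_mod.group_low_af(
                    dict(sub_af), config.af_group_threshold
                )
            else:
                retained_ac, grouped_ac = retained, grouped
            sub = af_mod.apply_grouping(sub, grouped_ac)
            factors = retained_ac + ([af_mod.OTHER_GROUP_NAME] if grouped_ac else [])
            covs = list(config.covariates)
            if ac == "total" and "age_class" not in covs:
                covs = covs + ["age_class"]  # pooled run adjusts on age class
            try:
                res = aaf_analysis(
                    sub,
                    outcome,
                    factors,
                    covs,
                    wcol,
                    mode=config.aaf_mode,
                    n_perms=config.n_perms,
                    seed=config.seed,
                    definition=d,
                    age_class=ac,
                    round_to=config.rounding,
                )
            except Exception as exc:
                raise PipelineError(f"[aaf:{d}/{ac}] {exc}") from exc
            aaf_tables[(d, ac)] = res
    run_log["stages"]["grouping"] = grouping
    run_log["stages"]["aaf"] = {
        f"{d}/{ac}": {"af_all": r.af_all, "sum_of_aafs": r.sum_of_aafs}
        for (d, ac), r in aaf_tables.items()
    }
    return ReportBundle(prevalence, gross_af, grouping, aaf_tables, run_log)


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}"


def write_report(bundle: ReportBundle, out_dir: str | Path, sum_mode: str = "raw") -> list[Path]:
    """Write the report bundle: one tidy CSV per table plus run metadata.

    Percentages are formatted to one decimal; raw values are retained in
    ``*_raw`` columns.  The AAF sums row defaults to the sum of unrounded
    values, formatted afterwards (``sum_mode="raw"``); ``"sum_of_rounded"``
    sums the printed one-decimal entries instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    prev = bundle.prevalence.copy()
    prev["prevalence_raw"] = prev.pop("prevalence")
    prev["prevalence"] = prev["prevalence_raw"].map(_fmt_pct)
    p = out / "prevalence.csv"
    prev.to_csv(p, index=False)
    written.append(p)

    gaf = bundle.gross_af.copy()
    gaf["af_raw"] = gaf.pop("af")
    gaf["af"] = gaf["af_raw"].map(_fmt_pct)
    p = out / "gross_af.csv"
    gaf.to_csv(p, index=False)
    written.append(p)

    frames = []
    for (d, ac), res in bundle.aaf_tables.items():
        t = res.to_frame()
        t["aaf_raw"] = t.pop("aaf")
        t["aaf"] = t["aaf_raw"].map(_fmt_pct)
        if sum_mode == "raw":
            total = t["aaf_raw"].sum()
        else:
            total = sum(float(v) for v in t["aaf"]) / 100.0
        sums = pd.DataFrame(
            [
                {
                    "rank": "",
                    "factor": "SUM",
                    "aaf_raw": total,
                    "aaf": _fmt_pct(total),
                    "expected_prevented_raw": t["expected_prevented_raw"].sum(),
                    "expected_prevented_rounded": t["expected_prevented_rounded"].sum(),
                    "definition": d,
                    "age_class": ac,
                    "mode": res.mode,
                }
            ]
        )
        frames.append(pd.concat([t, sums], ignore_index=True))
    aaf_out = pd.concat(frames, ignore_index=True)
    p = out / "aaf.csv"
    aaf_out.to_csv(p, index=False)
    written.append(p)

    meta = {
        "run_log": bundle.run_log,
        "grouping": bundle.grouping,
        "table_hashes": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in written
        },
    }
    p = out / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, default=float))
    written.append(p)
    return written
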