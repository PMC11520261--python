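"""New-user cohort construction from raw claim tables.

Implements the curation rules of a sustained-use, intention-to-treat,
active-comparator design:

* arm = the drug class received earliest whose first fill is followed by a
  second fill of the same class 6-12 months later (sustained use); ties on
  the first-fill date are broken by a fixed class-priority order;
* inclusion: at least one HbA1c result, >= 1 year of qualifying insurance
  coverage, no heart-failure diagnosis strictly before the index date, and
  not likely type-1 diabetes;
* outcome: time from the index date (first fill of the assigned class) to
  the first post-index heart-failure phecode, censored at the last
  follow-up date;
* baseline covariates from a 1-year lookback window ``[index-365, index)``:
  most recent lab values, phecode counts, auxiliary-medication fill counts
  and disease duration.

All dates are integer days; 1 year = 365 days, 6 months = 183 days.
Lookback windows are half-open (``[index-365, index)``) and follow-up is
closed on the left (index-day diagnoses count as post-index).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from drclaims.exceptions import ConfigError, DataError

__all__ = [
    "HF_PHECODES",
    "EXCLUSION_ORDER",
    "assign_treatment_group",
    "apply_inclusion_exclusion",
    "compute_follow_up",
    "extract_baseline_features",
    "build_cohort",
]

HF_PHECODES = ("428.1", "428.2", "428.3", "428.4")

#: First-failing-reason attribution order for the attrition table.
EXCLUSION_ORDER = ("no_arm", "no_hba1c", "coverage", "t1dm", "prior_hf")

SUSTAIN_MIN_DAYS = 183
SUSTAIN_MAX_DAYS = 365
LOOKBACK_DAYS = 365

AUX_MED_CLASSES = ("metformin", "statins", "sulfonylureas", "thiazolidinediones")


def assign_treatment_group(
    rx_claims: pd.DataFrame,
    classes_of_interest: Sequence[str],
    class_priority: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each patient to its earliest sustained drug class.

    A class is *sustained* for a patient when a second fill of that class
    occurs in ``[first_fill + 183, first_fill + 365]`` days.  Among
    sustained classes the earliest first fill wins; exact ties on the
    first-fill date are broken by ``class_priority`` (default: the order of
    ``classes_of_interest``).  Patients with no sustained class get
    ``arm_class = None``.

    Returns a frame with columns ``patient_id``, ``arm_class``,
    ``index_date`` covering every patient present in ``rx_claims``.
    """
    classes = list(classes_of_interest)
    if class_priority is None:
        class_priority = classes
    priority = {c: k for k, c in enumerate(class_priority)}
    if set(classes) - set(priority):
        raise ConfigError("class_priority must cover all classes_of_interest")

    rx = rx_claims[["patient_id", "fill_date", "drug_class"]].copy()
    all_patients = pd.unique(rx["patient_id"])
    unknown = set(rx["drug_class"].unique()) - set(classes)
    if unknown:
        warnings.warn(
            f"ignoring fills of drug classes outside classes_of_interest: "
            f"{sorted(map(str, unknown))}",
            stacklevel=2,
        )
        rx = rx[rx["drug_class"].isin(classes)]

    empty = pd.DataFrame({"patient_id": all_patients})
    empty["arm_class"] = None
    empty["index_date"] = pd.array([pd.NA] * len(empty), dtype="Int64")
    if rx.empty:
        return empty

    first = (
        rx.groupby(["patient_id", "drug_class"], sort=False)["fill_date"]
        .min()
        .rename("first_fill")
        .reset_index()
    )
    fills = rx.merge(first, on=["patient_id", "drug_class"])
    in_window = (
        (fills["fill_date"] >= fills["first_fill"] + SUSTAIN_MIN_DAYS)
        & (fills["fill_date"] <= fills["first_fill"] + SUSTAIN_MAX_DAYS)
    )
    sustained_flags = (
        in_window.groupby([fills["patient_id"], fills["drug_class"]]).any()
        .rename("sustained")
        .reset_index()
    )
    cand = first.merge(sustained_flags, on=["patient_id", "drug_class"])
    cand = cand[cand["sustained"]].copy()
    cand["prio"] = cand["drug_class"].map(priority)
    cand = cand.sort_values(["patient_id", "first_fill", "prio"], kind="mergesort")
    winners = cand.groupby("patient_id", sort=False).head(1)

    out = pd.DataFrame({"patient_id": all_patients}).merge(
        winners[["patient_id", "drug_class", "first_fill"]],
        on="patient_id",
        how="left",
    )
    out = out.rename(columns={"drug_class": "arm_class", "first_fill": "index_date"})
    out["arm_class"] = out["arm_class"].where(out["arm_class"].notna(), None)
    out["index_date"] = out["index_date"].astype("Int64")
    return out


def _phecode_dx(dx_claims: pd.DataFrame, code_map: pd.DataFrame) -> pd.DataFrame:
    """Map diagnosis codes to phecodes (inner join; unmapped codes dropped)."""
    return dx_claims.merge(code_map, on="code", how="inner")


def _validate_hf_map(code_map: pd.DataFrame, hf_phecodes: Sequence[str]) -> None:
    present = set(code_map["phecode"].astype(str).unique())
    missing = [p for p in hf_phecodes if p not in present]
    if missing:
        raise ConfigError(
            f"hf_code_map has no diagnosis codes mapping to HF phecodes {missing}"
        )


def apply_inclusion_exclusion(
    assignments: pd.DataFrame,
    labs: pd.DataFrame,
    coverage: pd.DataFrame,
    dx_claims: pd.DataFrame,
    hf_code_map: pd.DataFrame,
    *,
    hf_phecodes: Sequence[str] = HF_PHECODES,
    t2dm_phecode: str = "250.2",
    t1dm_phecode: str = "250.1",
    qualifying_plans: Sequence[str] = ("FI", "MAPD"),
    min_coverage_days: int = 365,
    hba1c_lab_name: str = "hba1c",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion/exclusion rules; return (eligible, attrition).

    Rules, attributed in fixed first-failing order:

    1. ``no_arm`` -- no sustained study class;
    2. ``no_hba1c`` -- no HbA1c result anywhere in the stream;
    3. ``coverage`` -- fewer than ``min_coverage_days`` cumulative days of
       qualifying plan coverage (span days counted inclusively, contiguity
       not required);
    4. ``t1dm`` -- likely type-1 diabetes: more T1DM than T2DM diagnosis
       codes, or any T1DM codes with zero T2DM codes;
    5. ``prior_hf`` -- a heart-failure phecode strictly before the index
       date.

    ``eligible`` carries ``patient_id``, ``arm_class``, ``index_date``;
    ``attrition`` tallies input / per-reason excluded / retained counts.
    """
    _validate_hf_map(hf_code_map, hf_phecodes)
    df = assignments.copy()
    pid = df["patient_id"]

    has_hba1c = set(labs.loc[labs["lab_name"] == hba1c_lab_name, "patient_id"])

    qual = coverage[coverage["plan_type"].isin(qualifying_plans)]
    cov_days = (
        (qual["end_date"] - qual["start_date"] + 1)
        .clip(lower=0)
        .groupby(qual["patient_id"])
        .sum()
    )
    enough_coverage = set(cov_days[cov_days >= min_coverage_days].index)

    phe = _phecode_dx(dx_claims, hf_code_map)
    phe["phecode"] = phe["phecode"].astype(str)
    t1_counts = phe[phe["phecode"] == t1dm_phecode].groupby("patient_id").size()
    t2_counts = phe[phe["phecode"] == t2dm_phecode].groupby("patient_id").size()
    t1 = pid.map(t1_counts).fillna(0).to_numpy()
    t2 = pid.map(t2_counts).fillna(0).to_numpy()
    likely_t1dm = (t1 > t2) | ((t1 > 0) & (t2 == 0))

    hf = phe[phe["phecode"].isin([str(p) for p in hf_phecodes])]
    first_hf = hf.groupby("patient_id")["date"].min()
    first_hf_date = pid.map(first_hf)
    index_date = df["index_date"].astype("float64")
    prior_hf = (first_hf_date < index_date).fillna(False).to_numpy()

    reason = np.full(len(df), None, dtype=object)
    checks = [
        ("no_arm", df["arm_class"].isna().to_numpy()),
        ("no_hba1c", ~pid.isin(has_hba1c).to_numpy()),
        ("coverage", ~pid.isin(enough_coverage).to_numpy()),
        ("t1dm", likely_t1dm),
        ("prior_hf", prior_hf),
    ]
    for name, failed in checks:
        reason = np.where((reason == None) & failed, name, reason)  # noqa: E711

    df["exclusion_reason"] = reason
    eligible = df[df["exclusion_reason"].isna()].drop(columns="exclusion_reason")
    eligible = eligible.copy()
    eligible["index_date"] = eligible["index_date"].astype(int)

    tally = {"input": len(df)}
    for name in EXCLUSION_ORDER:
        tally[name] = int((reason == name).sum())
    tally["retained"] = len(eligible)
    attrition = pd.DataFrame(
        {"stage": list(tally.keys()), "n": list(tally.values())}
    )
    return eligible.reset_index(drop=True), attrition


def compute_follow_up(
    eligible: pd.DataFrame,
    dx_claims: pd.DataFrame,
    hf_code_map: pd.DataFrame,
    last_followup_date: pd.Series,
    *,
    hf_phecodes: Sequence[str] = HF_PHECODES,
) -> pd.DataFrame:
    """Attach outcome columns ``follow_up_days`` and ``event``.

    ``event = 1`` with time to the *first* heart-failure phecode on or
    after the index date when one occurs no later than the last follow-up
    date; otherwise ``event = 0`` at the last follow-up date.  Same-day
    events (time 0) are recorded as half a day so all times are positive.

    ``last_followup_date`` is indexed by patient_id (e.g. the latest
    coverage end date).
    """
    df = eligible.copy()
    last = df["patient_id"].map(last_followup_date)
    if last.isna().any():
        bad = df.loc[last.isna(), "patient_id"].tolist()[:5]
        raise DataError(f"missing last_followup_date for patients {bad}")
    if (last < df["index_date"]).any():
        bad = df.loc[last < df["index_date"], "patient_id"].tolist()[:5]
        raise DataError(f"last_followup_date before index_date for patients {bad}")

    phe = _phecode_dx(dx_claims, hf_code_map)
    hf = phe[phe["phecode"].astype(str).isin([str(p) for p in hf_phecodes])]
    hf = hf.merge(df[["patient_id", "index_date"]], on="patient_id")
    hf = hf[hf["date"] >= hf["index_date"]]
    first_hf = hf.groupby("patient_id")["date"].min()

    hf_date = df["patient_id"].map(first_hf)
    has_event = hf_date.notna() & (hf_date <= last)
    time = np.where(has_event, hf_date - df["index_date"], last - df["index_date"])
    time = np.where(time <= 0, 0.5, time.astype(float))

    df["follow_up_days"] = time
    df["event"] = has_event.astype(int)
    return df


def extract_baseline_features(
    eligible: pd.DataFrame,
    patients: pd.DataFrame,
    dx_claims: pd.DataFrame,
    labs: pd.DataFrame,
    rx_claims: pd.DataFrame,
    code_map: pd.DataFrame,
    *,
    lab_names: Sequence[str] = ("hba1c", "cholesterol", "hdl", "ldl"),
    med_classes: Sequence[str] = AUX_MED_CLASSES,
    phecodes: Iterable[str] | None = None,
    t2dm_phecode: str = "250.2",
    epoch_year: float = 2016.0,
) -> pd.DataFrame:
    """Attach baseline covariates from the 1-year lookback window.

    Per patient: age at index (from birth year), demographics from the
    patients table, the most recent value of each lab in
    ``[index-365, index)`` (NaN if none), counts of diagnosis claims per
    phecode in the same window, counts of auxiliary medication fills in the
    window, and disease duration in months (index minus first T2DM
    diagnosis anywhere in the stream).  No covariate uses information on or
    after the index date.
    """
    df = eligible.merge(
        patients[["patient_id", "birth_year", "sex", "medicaid", "rural",
                  "socio_index"]],
        on="patient_id",
        how="left",
    )
    df["age"] = epoch_year + df["index_date"] / 365.0 - df["birth_year"]
    df["male"] = (df["sex"] == "M").astype(int)
    df = df.drop(columns=["birth_year", "sex"])

    idx_df = df[["patient_id", "index_date"]]

    lb = labs.merge(idx_df, on="patient_id")
    lb = lb[
        (lb["date"] >= lb["index_date"] - LOOKBACK_DAYS)
        & (lb["date"] < lb["index_date"])
    ]
    # secondary sort on value makes same-day ties row-order invariant
    lb = lb.sort_values(["date", "value"], kind="mergesort")
    recent = lb.groupby(["patient_id", "lab_name"])["value"].last().unstack()
    for lab in lab_names:
        col = recent[lab] if lab in recent else pd.Series(dtype=float)
        df[lab] = df["patient_id"].map(col)

    phe = _phecode_dx(dx_claims, code_map)
    phe["phecode"] = phe["phecode"].astype(str)
    phe = phe.merge(idx_df, on="patient_id")
    window = phe[
        (phe["date"] >= phe["index_date"] - LOOKBACK_DAYS)
        & (phe["date"] < phe["index_date"])
    ]
    if phecodes is None:
        special = {str(t2dm_phecode), "250.1", *HF_PHECODES}
        phecodes = sorted(set(window["phecode"].unique()) - special)
    counts = (
        window[window["phecode"].isin(list(phecodes))]
        .groupby(["patient_id", "phecode"])
        .size()
        .unstack(fill_value=0)
    )
    for p in phecodes:
        col = counts[p] if p in counts else pd.Series(dtype=float)
        df[p] = df["patient_id"].map(col).fillna(0).astype(int)

    rx = rx_claims.merge(idx_df, on="patient_id")
    rx = rx[
        (rx["fill_date"] >= rx["index_date"] - LOOKBACK_DAYS)
        & (rx["fill_date"] < rx["index_date"])
    ]
    med_counts = (
        rx[rx["drug_class"].isin(list(med_classes))]
        .groupby(["patient_id", "drug_class"])
        .size()
        .unstack(fill_value=0)
    )
    for med in med_classes:
        col = med_counts[med] if med in med_counts else pd.Series(dtype=float)
        df[med] = df["patient_id"].map(col).fillna(0).astype(int)

    first_t2dm = (
        phe[phe["phecode"] == str(t2dm_phecode)].groupby("patient_id")["date"].min()
    )
    dur_days = (df["index_date"] - df["patient_id"].map(first_t2dm)).clip(lower=0)
    df["disease_duration"] = (dur_days / 30.44).fillna(0.0)
    return df


def build_cohort(
    stream,
    *,
    treated_class: str = "insulin",
    comparator_class: str = "GLP1",
    code_map: pd.DataFrame | None = None,
    phecodes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full curation chain on a :class:`~drclaims.simulate.ClaimStream`
    (or any object exposing the five claim tables).

    Returns ``(cohort, attrition)`` where ``cohort`` is restricted to the
    two classes under comparison with ``arm = 1`` for ``treated_class``,
    ``time`` in years, and all baseline covariates attached.
    """
    cmap = stream.code_map if code_map is None else code_map
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # aux med classes are expected
        assignments = assign_treatment_group(
            stream.rx_claims, [treated_class, comparator_class]
        )
    eligible, attrition = apply_inclusion_exclusion(
        assignments, stream.labs, stream.coverage, stream.dx_claims, cmap
    )
    last_followup = stream.coverage.groupby("patient_id")["end_date"].max()
    cohort = compute_follow_up(eligible, stream.dx_claims, cmap, last_followup)
    cohort = extract_baseline_features(
        cohort, stream.patients, stream.dx_claims, stream.labs,
        stream.rx_claims, cmap, phecodes=phecodes,
    )
    cohort["arm"] = (cohort["arm_class"] == treated_class).astype(int)
    cohort["time"] = cohort["follow_up_days"] / 365.0
    return cohort, attrition
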