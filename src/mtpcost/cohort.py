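"""Cohort construction from raw claims: incident-case washout, PARC-based
region classification, covariate coding, and alignment of monthly costs to a
49-month window centered on the CKD diagnosis.

Claims arrive as a long table (CSV) with one row per claim:
``subject_id, month (ISO year-month), cost, codes`` where ``codes`` is a
semicolon-separated list of ICD-10 codes.  Subject attributes (PARC value,
age at diagnosis, sex, income tertile, coverage type, Charlson category,
optional death month) come from a companion table keyed by ``subject_id``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import DIAGNOSIS_TIME, MAX_TIME

logger = logging.getLogger(__name__)

#: default study observation window (calendar months with usable claims)
STUDY_START = pd.Period("2002-01", freq="M")
STUDY_END = pd.Period("2019-12", freq="M")

#: first months carrying the CKD code in these years are excluded
DEFAULT_WASHOUT_YEARS = (2002, 2003)
DEFAULT_TAIL_YEARS = (2018, 2019)

DEFAULT_CKD_PREFIX = "N18"

#: PARC below this (strictly) marks a medically vulnerable region
PARC_VULNERABLE_THRESHOLD = -0.33

#: age bands as reported in the cohort description; the lower edge is
#: inclusive, so age exactly 80 falls in the open top band (configurable)
AGE_BAND_EDGES = (30, 40, 50, 60, 70, 80)
AGE_BAND_LABELS = ("<30", "30-39", "40-49", "50-59", "60-69", "70-79", ">80")

PANEL_COLUMNS = (
    "subject_id", "time", "cost", "region",
    "age", "sex", "income", "coverage", "cci",
)


class CohortError(ValueError):
    """Raised for invalid cohort inputs (bad PARC, malformed claims, ...)."""


def classify_region(parc_value, threshold: float = PARC_VULNERABLE_THRESHOLD):
    """Classify a region as vulnerable from its PARC value.

    PARC (position value for relative composite) summarizes a region's
    health-care level on [-1, 1]; regions strictly below the threshold
    (default -0.33) are medically vulnerable.  Accepts scalars or arrays.
    """
    arr = np.asarray(parc_value, dtype=float)
    if np.any(arr < -1.0) or np.any(arr > 1.0) or not np.all(np.isfinite(arr)):
        raise CohortError("PARC value must lie in [-1, 1]")
    out = np.where(arr < threshold, "vulnerable", "nonvulnerable")
    if np.isscalar(parc_value) or np.ndim(parc_value) == 0:
        return str(out[()])
    return out


def _to_period(col: pd.Series) -> pd.Series:
    if isinstance(col.dtype, pd.PeriodDtype):
        return col
    return pd.PeriodIndex(col.astype(str), freq="M").to_series(index=col.index)


def apply_washout_filter(
    claims: pd.DataFrame,
    ckd_code_prefix: str = DEFAULT_CKD_PREFIX,
    washout_years: Iterable[int] = DEFAULT_WASHOUT_YEARS,
    tail_years: Iterable[int] = DEFAULT_TAIL_YEARS,
    attributes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select incident CKD cases and date their diagnosis.

    A subject's diagnosis month is the FIRST claim month carrying a code
    with the CKD prefix.  Subjects whose first such month falls in the
    washout years (pre-existing disease) or the tail years (insufficient
    follow-up) are excluded, so retained diagnoses are incident cases with
    observable pre- and post-diagnosis windows.

    Returns a subject table with ``subject_id`` and ``diagnosis_month``
    (monthly Period), joined with ``attributes`` when given.  Claims rows
    whose month cannot be parsed are rejected with a logged warning.
    """
    required = {"subject_id", "month", "codes"}
    missing = required - set(claims.columns)
    if missing:
        raise CohortError(f"claims table missing columns: {sorted(missing)}")

    claims = claims.copy()
    month_str = claims["month"].astype(str)
    parsed = pd.PeriodIndex(
        pd.to_datetime(month_str, format="%Y-%m", errors="coerce"), freq="M"
    )
    bad = parsed.isna()
    has_ckd = (
        claims["codes"]
        .fillna("")
        .astype(str)
        .str.split(";")
        .map(lambda cs: any(c.strip().startswith(ckd_code_prefix) for c in cs))
    )
    if bad.any():
        n_bad = int(bad.sum())
        affected = claims.loc[np.asarray(bad) & has_ckd.to_numpy(), "subject_id"].unique()
        logger.warning(
            "%d claim rows with unparseable month dropped; %d CKD-coded subjects affected",
            n_bad, len(affected),
        )
    claims["month"] = parsed
    claims = claims[~np.asarray(bad)]

    ckd = claims[has_ckd.reindex(claims.index, fill_value=False)]
    if ckd.empty:
        return pd.DataFrame(columns=["subject_id", "diagnosis_month"])

    first = ckd.groupby("subject_id", sort=True)["month"].min().rename("diagnosis_month")
    excluded_years = set(washout_years) | set(tail_years)
    years = first.map(lambda p: p.year)
    kept = first[~years.isin(excluded_years)]
    logger.info(
        "washout filter: %d CKD subjects, %d excluded (washout/tail), %d retained",
        len(first), len(first) - len(kept), len(kept),
    )
    subjects = kept.reset_index()
    if attributes is not None:
        subjects = subjects.merge(attributes, on="subject_id", how="left")
        if "death_month" in subjects.columns:
            dm = subjects["death_month"]
            ok = dm.notna()
            if ok.any():
                subjects.loc[ok, "death_month"] = _to_period(dm[ok].astype(str))
    return subjects


def build_cost_panel(
    subjects: pd.DataFrame,
    claims: pd.DataFrame,
    study_start: pd.Period = STUDY_START,
    study_end: pd.Period = STUDY_END,
) -> pd.DataFrame:
    """Align monthly claim totals to the 49-month diagnosis window.

    For each subject, claim costs are summed per calendar month and mapped
    to ``time = 24 + (claim month - diagnosis month)``; the diagnosis month
    is ``time = 24``.  Window months with no claims become explicit
    zero-cost rows (the binary model part needs observed zeros).  Months
    strictly after the subject's death month, or falling outside the study
    observation window, are absent — the panel may be unbalanced.
    """
    if "diagnosis_month" not in subjects.columns:
        raise CohortError("subjects table needs a diagnosis_month column")

    claims = claims.copy()
    claims["month"] = _to_period(claims["month"])
    if (claims["cost"] < 0).any():
        raise CohortError("claim costs must be non-negative")

    monthly = (
        claims.groupby(["subject_id", "month"], sort=False)["cost"].sum().reset_index()
    )

    covar_cols = [
        c for c in ("parc_value", "region", "age", "sex", "income", "coverage", "cci")
        if c in subjects.columns
    ]
    frames = []
    n_dropped = 0
    for row in subjects.itertuples(index=False):
        dx = row.diagnosis_month
        window = pd.period_range(dx - DIAGNOSIS_TIME, dx + DIAGNOSIS_TIME, freq="M")
        times = np.arange(MAX_TIME + 1)
        keep = (window >= study_start) & (window <= study_end)
        death = getattr(row, "death_month", None)
        if death is not None and not pd.isna(death):
            keep &= window <= death
        if not keep.any():
            n_dropped += 1
            continue
        sub = pd.DataFrame({"subject_id": row.subject_id,
                            "month": window[keep], "time": times[keep]})
        frames.append(sub)
    if n_dropped:
        logger.info("build_cost_panel: %d subjects dropped with empty windows", n_dropped)
    if not frames:
        return pd.DataFrame(columns=list(PANEL_COLUMNS))

    panel = pd.concat(frames, ignore_index=True)
    panel = panel.merge(monthly, on=["subject_id", "month"], how="left")
    panel["cost"] = panel["cost"].fillna(0.0)
    panel = panel.drop(columns="month")

    attr = subjects.drop(columns=["diagnosis_month"], errors="ignore")
    attr = attr[["subject_id"] + covar_cols]
    panel = panel.merge(attr, on="subject_id", how="left")
    if "region" not in panel.columns and "parc_value" in panel.columns:
        panel["region"] = classify_region(panel["parc_value"].to_numpy())
    return panel


def age_band(age: float, top_edge_open: bool = True) -> str:
    """Map a continuous age to its reporting band.

    ``top_edge_open`` keeps age exactly 80 in the ``>80`` band (bands are
    lower-edge inclusive); set False to place 80 in ``70-79``.
    """
    if pd.isna(age):
        raise CohortError("age is missing")
    edges = AGE_BAND_EDGES
    for i, edge in enumerate(edges):
        if age < edge or (not top_edge_open and i == len(edges) - 1 and age == edge):
            return AGE_BAND_LABELS[i]
    return AGE_BAND_LABELS[-1]


def categorize_covariates(subjects: pd.DataFrame) -> pd.DataFrame:
    """Code raw covariates for reporting and modelling.

    Adds ``age_band`` (7 bands, continuous age retained) and top-codes the
    Charlson score into ``cci`` category 0 / 1 / 2 ("2" meaning >= 2).
    Subjects with any missing model covariate are excluded with a logged
    count (the model cannot use partially observed rows).
    """
    out = subjects.copy()
    needed = [c for c in ("age", "sex", "cci") if c in out.columns]
    missing_mask = out[needed].isna().any(axis=1) if needed else pd.Series(False, index=out.index)
    if missing_mask.any():
        logger.warning(
            "categorize_covariates: %d subjects excluded for missing covariates",
            int(missing_mask.sum()),
        )
        out = out[~missing_mask].copy()
    if "age" in out.columns:
        out["age_band"] = out["age"].map(age_band)
    if "cci" in out.columns:
        out["cci"] = np.minimum(out["cci"].astype(int), 2)
    return out


def summarize_regions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region subject counts and percentage shares (1-decimal).

    Accepts a subject table or a cost panel (deduplicated by subject).
    """
    cols = ["subject_id", "region"] if "subject_id" in table.columns else ["region"]
    subjects = table[cols].drop_duplicates()
    counts = subjects["region"].value_counts()
    total = int(counts.sum())
    return pd.DataFrame({
        "n": counts,
        "percent": (100.0 * counts / total).round(1),
    })


def read_claims_csv(path) -> pd.DataFrame:
    """Read a claims CSV (subject_id, month, cost, codes)."""
    df = pd.read_csv(path, dtype={"month": str, "codes": str})
    missing = {"subject_id", "month", "cost"} - set(df.columns)
    if missing:
        raise CohortError(f"claims CSV missing columns: {sorted(missing)}")
    return df


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=[c for c in PANEL_COLUMNS if c in panel.columns])


def read_panel_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
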