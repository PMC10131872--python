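"""Segmented interrupted-time-series design matrices for the two model parts.

The cost panel is aligned so that month index ``time`` runs 0..48 with the
CKD diagnosis at ``time = 24``.  The structural part of the design encodes a
piecewise-linear (segmented) trend with a level shift and slope change at
diagnosis, fully interacted with the vulnerable-region indicator:

    intercept, diagnosis, region, time,
    diagnosis:region, diagnosis:after_time,
    region:time, region:after_time

where ``diagnosis = 1[time >= 24]`` and ``after_time = max(0, time - 24)``
(months since diagnosis, 0..24).  Both model parts — the binary
usage part and the overall-mean part — share this column set, followed by
adjustment covariates (age in years, sex with female = 1, and the Charlson
comorbidity category entered as its 0/1/2 score by default).

A note on the region-by-trend terms: because ``after_time > 0`` implies
``diagnosis = 1``, a design carrying both ``region:after_time`` and
``diagnosis:region:after_time`` would contain two identical columns and be
unidentifiable.  The identifiable segmented layout used here interacts
region with the full-window trend (``region:time``) and with the
post-diagnosis clock (``region:after_time``): the 8th coefficient is then
the region difference-in-differences of pre/post slopes, and the sum of
the 7th and 8th is the post-diagnosis region slope gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STRUCTURAL_COLUMNS: tuple[str, ...] = (
    "intercept",
    "diagnosis",
    "region",
    "time",
    "diagnosis:region",
    "diagnosis:after_time",
    "region:time",
    "region:after_time",
)

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "cci")

#: covariates accepted in ``covariate_spec`` and how panel values are coded
_COVARIATE_CODING = {
    "age": "numeric years",
    "sex": "1 = female, 0 = male",
    "cci": "Charlson category score 0 / 1 / 2",
    "income": "ordinal 0 = low, 1 = middle, 2 = high",
    "coverage": "1 = medical aid, 0 = NHI",
}

DIAGNOSIS_TIME = 24  # panel month index of the CKD diagnosis
MAX_TIME = 48


class DesignError(ValueError):
    """Raised for malformed panels or unknown covariate names."""


@dataclass
class DesignMatrices:
    """Per-observation design rows for both parts of the MTP model.

    Rows are sorted by subject (then time); ``subject_starts`` gives the
    offset of each subject's first row so per-subject reductions can use
    ``np.add.reduceat``.
    """

    x1: np.ndarray              # binary-part rows, shape (n_obs, p)
    x2: np.ndarray              # overall-mean-part rows, shape (n_obs, p)
    y: np.ndarray               # cost outcome, shape (n_obs,)
    subject_index: np.ndarray   # int codes 0..n_subjects-1 per row
    subject_ids: np.ndarray     # original labels, length n_subjects
    columns: tuple[str, ...]
    subject_starts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.x1.shape != self.x2.shape or self.x1.shape[0] != len(self.y):
            raise DesignError("x1, x2 and y must have matching row counts")
        if self.subject_starts is None:
            change = np.flatnonzero(np.diff(self.subject_index)) + 1
            self.subject_starts = np.concatenate(([0], change))

    @property
    def n_obs(self) -> int:
        return self.x1.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_params(self) -> int:
        return self.x1.shape[1]

    def to_frame(self, part: str = "x1") -> pd.DataFrame:
        """Audit export: one DataFrame per part with named columns."""
        mat = {"x1": self.x1, "x2": self.x2}[part]
        out = pd.DataFrame(mat, columns=list(self.columns))
        out.insert(0, "subject_id", self.subject_ids[self.subject_index])
        out["cost"] = self.y
        return out

    def to_csv(self, path, part: str = "x1") -> None:
        self.to_frame(part).to_csv(path, index=False)


def _coded_covariate(panel: pd.DataFrame, name: str) -> np.ndarray:
    if name not in _COVARIATE_CODING:
        raise DesignError(
            f"unknown covariate {name!r}; known: {sorted(_COVARIATE_CODING)}"
        )
    if name not in panel.columns:
        raise DesignError(f"panel lacks required covariate column {name!r}")
    col = panel[name]
    if name == "sex":
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            return (col.astype(str) == "female").to_numpy(float)
        return col.to_numpy(float)
    if name == "income":
        if col.dtype == object:
            mapping = {"low": 0.0, "middle": 1.0, "high": 2.0}
            return col.map(mapping).to_numpy(float)
        return col.to_numpy(float)
    if name == "coverage":
        if col.dtype == object:
            return (col.astype(str) == "medical_aid").to_numpy(float)
        return col.to_numpy(float)
    return col.to_numpy(float)


def build_design(
    panel: pd.DataFrame,
    covariate_spec: Sequence[str] = DEFAULT_COVARIATES,
) -> DesignMatrices:
    """Build the segmented-ITS design for both model parts from a cost panel.

    Parameters
    ----------
    panel
        Long-format cost panel with columns ``subject_id``, ``time`` (0..48),
        ``cost``, ``region`` (``"vulnerable"``/``"nonvulnerable"`` or 0/1)
        and the covariates named in ``covariate_spec``.
    covariate_spec
        Adjustment covariates appended after the structural columns.

    Both parts share the same column set; the binary part models
    P(cost > 0) and the overall-mean part models log of the marginal mean.
    """
    required = {"subject_id", "time", "cost", "region"}
    missing = required - set(panel.columns)
    if missing:
        raise DesignError(f"panel missing columns: {sorted(missing)}")

    panel = panel.sort_values(["subject_id", "time"], kind="mergesort")
    time = panel["time"].to_numpy(float)
    if time.min() < 0 or time.max() > MAX_TIME or np.any(time != np.round(time)):
        raise DesignError("time must be integral and within 0..48")

    y = panel["cost"].to_numpy(float)
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise DesignError("cost must be finite and non-negative")

    reg = panel["region"]
    if reg.dtype == object or isinstance(reg.dtype, pd.CategoricalDtype):
        region = (reg.astype(str) == "vulnerable").to_numpy(float)
    else:
        region = reg.to_numpy(float)

    diagnosis = (time >= DIAGNOSIS_TIME).astype(float)
    after = np.maximum(0.0, time - DIAGNOSIS_TIME)

    cols = [
        np.ones_like(time),
        diagnosis,
        region,
        time,
        diagnosis * region,
        diagnosis * after,
        region * time,
        region * after,
    ]
    names = list(STRUCTURAL_COLUMNS)
    for name in covariate_spec:
        cols.append(_coded_covariate(panel, name))
        names.append(name)

    x = np.column_stack(cols)
    if not np.all(np.isfinite(x)):
        raise DesignError("design contains non-finite values (missing covariates?)")

    codes, uniques = pd.factorize(panel["subject_id"], sort=False)
    return DesignMatrices(
        x1=x,
        x2=x.copy(),
        y=y,
        subject_index=codes.astype(np.int64),
        subject_ids=np.asarray(uniques),
        columns=tuple(names),
    )


def read_design_csv(path, part: str = "x1") -> pd.DataFrame:
    """Round-trip reader for the audit CSV written by DesignMatrices.to_csv."""
    return pd.read_csv(path)
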