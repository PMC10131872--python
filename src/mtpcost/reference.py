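"""Reference coefficient estimates for the Korean CKD regional-cost cohort.

These are the published estimates (with 95% confidence limits) of the MTP
segmented model fitted to the restricted national-sample claims cohort
this package's synthetic generator emulates.  They are shipped so that the
contrast and projection machinery can reproduce the derived reporting
quantities (slope-effect grid, region-difference-by-year projection,
trajectory curves) without any access to the underlying data.

The mean-part coefficients are on the log-KRW cost scale.  The published
reporting labels for the last two structural rows ("region by after-time"
and "diagnosis by region by after-time") would name two identical design
columns; they are mapped onto the identifiable layout used throughout
this package (``region:time`` and ``region:after_time`` — see
:mod:`mtpcost.design`), which is the reading consistent with the source's
own description of the 8th coefficient as the pre/post
difference-in-differences between regions.  One printed value is kept
verbatim although internally inconsistent: the binary-part age
coefficient (0.0116) lies outside its own printed interval
(0.0161, 0.0171).  See docs/methods.md.
"""

from __future__ import annotations

from .design import DEFAULT_COVARIATES, STRUCTURAL_COLUMNS
from .inference import FitResult

REFERENCE_COLUMNS = STRUCTURAL_COLUMNS + DEFAULT_COVARIATES

#: binary component: estimate, (lower, upper)
REFERENCE_BINARY = {
    "intercept": (-0.4169, (-0.4501, -0.3835)),
    "diagnosis": (-0.03515, (-0.0668, -0.0035)),
    "region": (0.1875, (0.1533, 0.2218)),
    "time": (0.0260, (0.0244, 0.0275)),
    "diagnosis:region": (-0.1124, (-0.1839, -0.0408)),
    "diagnosis:after_time": (-0.0888, (-0.0910, -0.0867)),
    "region:time": (-0.0151, (-0.0172, -0.0130)),
    "region:after_time": (0.0112, (0.0091, 0.0133)),
    "age": (0.0116, (0.0161, 0.0171)),
    "sex": (-0.0816, (-0.0962, -0.0671)),
    "cci": (0.3348, (0.3257, 0.3440)),
}

#: overall-mean component (log-KRW scale): estimate, (lower, upper)
REFERENCE_MEAN = {
    "intercept": (11.1894, (11.1561, 11.2226)),
    "diagnosis": (0.0123, (-0.0119, 0.0366)),
    "region": (-0.0356, (-0.0611, -0.0101)),
    "time": (0.0652, (0.0641, 0.0664)),
    "diagnosis:region": (0.0884, (0.0332, 0.1435)),
    "diagnosis:after_time": (-0.0825, (-0.0843, -0.0807)),
    "region:time": (0.0178, (0.0159, 0.0197)),
    "region:after_time": (-0.0152, (-0.0171, -0.0133)),
    "age": (-0.0002, (-0.0006, 0.0003)),
    "sex": (-0.0635, (-0.0762, -0.0507)),
    "cci": (0.3734, (0.3650, 0.3818)),
}

#: cohort size by region in the source data
REFERENCE_COHORT = {"vulnerable": 971, "nonvulnerable": 6995}


def reference_fit() -> FitResult:
    """A coefficient-only :class:`FitResult` carrying the published
    estimates and their printed confidence limits (no covariance matrix,
    so derived contrasts are point estimates only)."""
    binary = {k: v[0] for k, v in REFERENCE_BINARY.items()}
    mean = {k: v[0] for k, v in REFERENCE_MEAN.items()}
    ci = {f"binary:{k}": v[1] for k, v in REFERENCE_BINARY.items()}
    ci.update({f"mean:{k}": v[1] for k, v in REFERENCE_MEAN.items()})
    return FitResult.from_estimates(
        REFERENCE_COLUMNS, binary=binary, mean=mean, ci_overrides=ci)
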