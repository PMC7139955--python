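"""Cohort construction filters and characteristics summaries.

Hi-TMB selection keeps samples whose tumor mutational burden is
*strictly* greater than the threshold (default 2 nonsynonymous somatic
variants per Mb); the characteristics summary mirrors the usual
"Table 1" layout for survival cohorts (survival-time strata with
censoring counts, stage distribution, cytoreduction triple, median age
with IQR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CohortFilterSpec:
    tmb_threshold: float = 2.0  # variants per Mb, strict lower bound
    capture_size_mb: float = 38.0  # exome capture footprint used to derive TMB
    require_cytoreduction: bool = False
    min_chemo_courses: int = 0

    def __post_init__(self) -> None:
        if self.tmb_threshold < 0:
            raise ValueError("tmb_threshold must be >= 0")
        if self.capture_size_mb <= 0:
            raise ValueError("capture_size_mb must be > 0")


def compute_tmb(nonsynonymous_count: int, capture_size_mb: float = 38.0) -> float:
    """Nonsynonymous somatic variants per Mb of captured exome."""
    if nonsynonymous_count < 0:
        raise ValueError("variant count must be nonnegative")
    if capture_size_mb <= 0:
        raise ValueError("capture size must be > 0")
    return nonsynonymous_count / capture_size_mb


def hi_tmb_filter(
    tmb: pd.Series, spec: CohortFilterSpec | None = None
) -> list[str]:
    """Sample ids with TMB strictly greater than the threshold.

    Samples with missing TMB are excluded with a warning, not an error.
    """
    spec = spec or CohortFilterSpec()
    missing = tmb[tmb.isna()]
    if len(missing):
        logger.warning(
            "hi_tmb_filter: %d sample(s) with missing TMB excluded: %s",
            len(missing),
            list(map(str, missing.index[:10])),
        )
    keep = tmb[tmb > spec.tmb_threshold]
    logger.info(
        "hi_tmb_filter: %d/%d samples retained at TMB > %g/Mb",
        len(keep),
        len(tmb),
        spec.tmb_threshold,
    )
    return list(map(str, keep.index))


def inclusion_filter(
    clinical: pd.DataFrame, spec: CohortFilterSpec
) -> list[str]:
    """Treatment-based inclusion: cytoreductive surgery performed and at
    least ``min_chemo_courses`` adjuvant chemotherapy courses, read from
    metadata columns (never inferred)."""
    keep = pd.Series(True, index=clinical.index)
    if spec.require_cytoreduction:
        if "cytoreduction_performed" not in clinical.columns:
            raise KeyError("column 'cytoreduction_performed' required by the filter")
        keep &= clinical["cytoreduction_performed"].astype(bool)
    if spec.min_chemo_courses > 0:
        if "chemo_courses" not in clinical.columns:
            raise KeyError("column 'chemo_courses' required by the filter")
        keep &= clinical["chemo_courses"] >= spec.min_chemo_courses
    return list(map(str, clinical.index[keep]))


def cohort_summary(clinical: pd.DataFrame, time_unit: str = "years") -> dict:
    """Table-1-style cohort characteristics.

    Survival times are stratified at 1 and 5 years (with per-stratum
    censoring counts); "minimum % with >= 5-year survival" counts every
    patient observed beyond 5 years — event or censored — over n, the
    conservative lower bound on the long-term survivor fraction.  Age
    quantiles use the same linear-interpolation estimator as signature
    standardization.
    """
    required = ["time", "event"]
    missing = [c for c in required if c not in clinical.columns]
    if missing:
        raise KeyError(f"clinical table missing required column(s): {missing}")
    if len(clinical) == 0:
        raise ValueError("empty cohort")
    t = clinical["time"].to_numpy(dtype=float)
    e = clinical["event"].to_numpy(dtype=float)
    censored = e == 0
    strata = {
        "t<=1y": t <= 1.0,
        "1y<t<=5y": (t > 1.0) & (t <= 5.0),
        "t>5y": t > 5.0,
    }
    n = len(t)
    out: dict = {"n": n, "time_unit": time_unit}
    for name, mask in strata.items():
        out[f"n {name}"] = int(mask.sum())
        out[f"n {name} censored"] = int((mask & censored).sum())
    out["% censored"] = round(100.0 * censored.mean(), 1)
    out["minimum % with >=5-year survival"] = round(100.0 * strata["t>5y"].mean(), 1)
    if "stage" in clinical.columns:
        counts = clinical["stage"].astype(str).value_counts()
        for lev in sorted(counts.index):
            out[f"stage {lev}"] = int(counts[lev])
            out[f"stage {lev} %"] = round(100.0 * counts[lev] / n, 1)
    if "cytoreduction" in clinical.columns:
        levels = ["Optimal", "Suboptimal", "Unknown"]
        triple = [int((clinical["cytoreduction"].astype(str) == l).sum()) for l in levels]
        out["cytoreduction Opt-Subopt-Unknown"] = "-".join(map(str, triple))
    if "age" in clinical.columns:
        age = clinical["age"].to_numpy(dtype=float)
        out["median age"] = float(np.quantile(age, 0.5, method="linear"))
        out["age IQR"] = (
            float(np.quantile(age, 0.25, method="linear")),
            float(np.quantile(age, 0.75, method="linear")),
        )
    return out
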