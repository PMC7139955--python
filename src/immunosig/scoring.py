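"""Signature scoring and percentile standardization.

A signature's raw score for a sample is the weighted average of its
member genes' log2 expression values:

    S_j = sum_g w_g * x_gj / sum_g w_g

Raw scores are standardized per cohort through the affine transform
that recodes the cohort's 15th and 85th percentiles of S to -1 and +1:

    Z_j = (2*S_j - (q15 + q85)) / (q85 - q15)

For approximately Gaussian score distributions a one-unit change in Z
corresponds to roughly one within-cohort standard deviation, which
makes hazard ratios comparable across signatures and cohorts.  Ratio
signatures are formed as differences of raw log2 scores (the log2 of a
geometric-mean ratio) and then standardized the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .matrix import LOG2, ExpressionMatrix

logger = logging.getLogger(__name__)

#: quantile levels used for standardization
Q_LOW = 0.15
Q_HIGH = 0.85


@dataclass
class SignatureDefinition:
    """Named gene set with strictly positive per-gene weights."""

    name: str
    genes: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = [1.0] * len(self.genes)
        if len(self.genes) != len(self.weights):
            raise ValueError(f"{self.name}: |genes| != |weights|")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.name}: duplicate genes")
        if any(w <= 0 for w in self.weights):
            raise ValueError(f"{self.name}: weights must be strictly positive")


@dataclass
class SignatureScores:
    """Raw and standardized per-sample scores for one signature.

    ``q15``/``q85`` are the cohort percentiles of the raw score used by
    the standardization transform; they are retained so the same affine
    map can be applied to held-out samples.
    """

    name: str
    raw: pd.Series
    z: pd.Series | None = None
    q15: float | None = None
    q85: float | None = None
    metadata: dict = field(default_factory=dict)


def load_default_signatures() -> dict[str, SignatureDefinition]:
    """Packaged signature definitions (TCT plus placeholder CLIS/M2TAM
    memberships, shipped as an editable GMT)."""
    from .io import read_gmt

    path = resources.files("immunosig") / "data" / "signatures_placeholder.gmt"
    sets = read_gmt(str(path))
    return {
        name: SignatureDefinition(name, rec["genes"], rec["weights"])
        for name, rec in sets.items()
    }


def raw_score(
    m: ExpressionMatrix,
    sig: SignatureDefinition,
    max_missing: float = 0.10,
) -> pd.Series:
    """Weighted-average log2 score per sample.

    Up to ``max_missing`` of the signature's genes may be absent from
    the matrix (weights are renormalized over the present genes);
    beyond that the call fails, listing the absent genes.
    """
    if m.scale != LOG2:
        raise ValueError("raw_score expects a log2-scale matrix")
    present = [g for g in sig.genes if g in m.values.index]
    absent = [g for g in sig.genes if g not in m.values.index]
    if len(absent) > max_missing * len(sig.genes):
        raise KeyError(
            f"signature {sig.name}: {len(absent)}/{len(sig.genes)} genes "
            f"absent from matrix: {absent[:10]}"
        )
    if absent:
        logger.warning(
            "signature %s: %d gene(s) missing, weights renormalized: %s",
            sig.name,
            len(absent),
            absent,
        )
    w = np.array(
        [wt for g, wt in zip(sig.genes, sig.weights) if g in m.values.index],
        dtype=float,
    )
    x = m.values.loc[present].to_numpy(dtype=float)
    s = (w[:, None] * x).sum(axis=0) / w.sum()
    return pd.Series(s, index=m.values.columns, name=sig.name)


def standardize(raw: pd.Series, name: str | None = None) -> SignatureScores:
    """Affine standardization recoding the cohort 15th/85th raw-score
    percentiles to -1/+1.

    Percentiles use the linear-interpolation quantile estimator.  A
    degenerate cohort (q15 == q85) is rejected.
    """
    values = raw.to_numpy(dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("standardize: fewer than 2 distinct raw scores")
    q15 = float(np.quantile(values, Q_LOW, method="linear"))
    q85 = float(np.quantile(values, Q_HIGH, method="linear"))
    if q15 >= q85:
        raise ValueError(
            f"degenerate cohort: q15 ({q15:g}) >= q85 ({q85:g})"
        )
    z = (2.0 * raw - (q15 + q85)) / (q85 - q15)
    return SignatureScores(
        name=name or str(raw.name),
        raw=raw,
        z=z.rename(raw.name),
        q15=q15,
        q85=q85,
        metadata={"quantile_estimator": "linear"},
    )


def apply_standardization(
    raw: pd.Series, q15: float, q85: float, name: str | None = None
) -> SignatureScores:
    """Apply a frozen standardization (training-cohort q15/q85) to new
    samples — deployment mode; per-cohort re-standardization is the
    default elsewhere."""
    if q15 >= q85:
        raise ValueError("q15 must be < q85")
    z = (2.0 * raw - (q15 + q85)) / (q85 - q15)
    return SignatureScores(name=name or str(raw.name), raw=raw, z=z, q15=q15, q85=q85)


def ratio_score(
    num: pd.Series, den: pd.Series, name: str | None = None
) -> SignatureScores:
    """Ratio signature: difference of raw log2 scores, then standardized.

    On the log2 scale ``S_num - S_den`` is the log2 of a ratio of
    (weighted) geometric means, so constant shifts common to both
    signatures cancel.
    """
    if not num.index.equals(den.index):
        raise ValueError("ratio_score: sample sets differ between numerator and denominator")
    name = name or f"{num.name}:{den.name}"
    s = (num - den).rename(name)
    return standardize(s, name=name)


def dichotomize(z: pd.Series, rule: str = "median") -> pd.Series:
    """Split scores into High/Low at the cohort median.

    Scores exactly at the median go to Low (ties are logged).
    """
    if rule != "median":
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    med = float(z.median())
    groups = pd.Series(
        np.where(z.to_numpy(dtype=float) > med, "High", "Low"),
        index=z.index,
        name=f"{z.name}_group" if z.name else "group",
    )
    n_tie = int((z == med).sum())
    if n_tie:
        logger.info("dichotomize: %d score(s) at the median assigned Low", n_tie)
    if (groups == "High").sum() == 0:
        logger.warning("dichotomize: no sample above the median (constant scores?)")
    logger.info(
        "dichotomize: High=%d Low=%d", (groups == "High").sum(), (groups == "Low").sum()
    )
    return groups


def score_signatures(
    m: ExpressionMatrix,
    signatures: dict[str, SignatureDefinition],
    ratios: list[tuple[str, str]] | None = None,
    max_missing: float = 0.10,
) -> dict[str, SignatureScores]:
    """Score and standardize a collection of signatures, plus optional
    ratio signatures named ``"NUM:DEN"``."""
    out: dict[str, SignatureScores] = {}
    for name, sig in signatures.items():
        out[name] = standardize(raw_score(m, sig, max_missing=max_missing), name=name)
    for num, den in ratios or []:
        if num not in out or den not in out:
            raise KeyError(f"ratio {num}:{den} references unscored signature")
        out[f"{num}:{den}"] = ratio_score(out[num].raw, out[den].raw)
    return out


def scores_frame(scores: dict[str, SignatureScores]) -> pd.DataFrame:
    """Long-to-wide table: per-sample raw (``S_``), standardized
    (``Z_``) scores and High/Low calls per signature."""
    cols = {}
    for name, sc in scores.items():
        cols[f"S_{name}"] = sc.raw
        if sc.z is not None:
            cols[f"Z_{name}"] = sc.z
            cols[f"group_{name}"] = dichotomize(sc.z)
    df = pd.DataFrame(cols)
    df.index.name = "sample_id"
    return df
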