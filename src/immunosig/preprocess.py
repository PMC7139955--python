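"""Expression preprocessing: upper-quartile normalization, log2
transform, probe collapse, per-gene centering, and stratified
subsampling of samples.

Upper-quartile (UQ) normalization rescales each sample by the 75th
percentile of its expression over "generally detected" genes — genes
seen at or above a count threshold in a large fraction of samples.
After the per-sample division, values are multiplied by the cohort mean
of those upper quartiles so that magnitudes remain count-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LINEAR, LOG2, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationLog:
    """Record of what a normalization run did."""

    detected_genes: list[str] = field(default_factory=list)
    sample_upper_quartiles: dict[str, float] = field(default_factory=dict)
    rescale_factor: float = 1.0


def detected_gene_mask(
    m: ExpressionMatrix, detection_count: float = 1.0, detection_fraction: float = 0.75
) -> pd.Series:
    """Boolean mask of genes with value >= detection_count in >=
    detection_fraction of samples."""
    frac = (m.values >= detection_count).mean(axis=1)
    return frac >= detection_fraction


def upper_quartile_normalize(
    m: ExpressionMatrix,
    detection_count: float = 1.0,
    detection_fraction: float = 0.75,
) -> tuple[ExpressionMatrix, NormalizationLog]:
    """Per-sample upper-quartile normalization over generally detected genes.

    Each sample's values are divided by that sample's 75th percentile
    across the detected-gene set and rescaled by the cohort mean of
    those percentiles.  Returns the normalized matrix and a log holding
    the detected-gene set and per-sample quartiles.
    """
    if m.scale != LINEAR:
        raise ValueError("upper-quartile normalization expects a linear-scale matrix")
    mask = detected_gene_mask(m, detection_count, detection_fraction)
    if not mask.any():
        raise ValueError("no gene passes the detection filter")
    detected = m.values.loc[mask.to_numpy()]
    uq = detected.quantile(0.75, axis=0, interpolation="linear")
    zero = uq[uq <= 0]
    if len(zero):
        raise ValueError(
            "detected-gene upper quartile is 0 for sample(s): "
            + ", ".join(map(str, zero.index[:10]))
        )
    rescale = float(uq.mean())
    norm = m.values.div(uq, axis=1) * rescale
    log = NormalizationLog(
        detected_genes=list(map(str, detected.index)),
        sample_upper_quartiles={str(k): float(v) for k, v in uq.items()},
        rescale_factor=rescale,
    )
    logger.info(
        "UQ normalization: %d/%d genes detected, rescale factor %.4g",
        mask.sum(),
        m.n_genes,
        rescale,
    )
    return ExpressionMatrix(norm, LINEAR, m.sample_annotations), log


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + offset); flips the scale flag to log2."""
    if m.scale != LINEAR:
        raise ValueError("matrix is already on the log2 scale")
    if offset <= 0:
        raise ValueError("pseudocount offset must be > 0")
    return ExpressionMatrix(
        np.log2(m.values + offset), LOG2, m.sample_annotations
    )


def collapse_probes(
    m: ExpressionMatrix, probe_map: dict[str, str]
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the retained probe is the one with the greatest
    detection level, taken as the largest mean value across the cohort;
    ties go to the lexicographically smallest probe id.  Returns the
    collapsed matrix and the gene -> chosen-probe record.
    """
    missing = [p for p in m.gene_ids if p not in probe_map]
    if missing:
        raise KeyError(f"probes absent from probe map: {missing[:10]}")
    means = m.values.mean(axis=1)
    chosen: dict[str, str] = {}
    for probe in sorted(m.gene_ids):  # lexicographic scan makes ties deterministic
        gene = probe_map[probe]
        if gene not in chosen or means[probe] > means[chosen[gene]]:
            chosen[gene] = probe
    genes = sorted(chosen)
    collapsed = m.values.loc[[chosen[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene_id")
    for g, p in chosen.items():
        logger.debug("collapse_probes: gene %s <- probe %s", g, p)
    return ExpressionMatrix(collapsed, m.scale, m.sample_annotations), chosen


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (log2 scale only)."""
    if m.scale != LOG2:
        raise ValueError("gene centering expects a log2-scale matrix")
    centered = m.values.sub(m.values.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, LOG2, m.sample_annotations)


def stratified_sample(
    sample_ids: list[str],
    type_labels: list[str],
    cap: int = 200,
    seed: int = 0,
) -> list[str]:
    """Select up to ``cap`` samples per cancer type, uniformly without
    replacement, to prevent large cohorts from dominating the analysis.

    The union is returned in the original order of ``sample_ids``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(sample_ids) != len(type_labels):
        raise ValueError("type_labels must cover all samples")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[str]] = {}
    for sid, lab in zip(sample_ids, type_labels):
        by_type.setdefault(str(lab), []).append(str(sid))
    keep: set[str] = set()
    for lab in sorted(by_type):
        ids = by_type[lab]
        if len(ids) <= cap:
            keep.update(ids)
        else:
            keep.update(rng.choice(ids, size=cap, replace=False))
    return [str(s) for s in sample_ids if str(s) in keep]
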