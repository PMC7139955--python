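"""Gene-by-sample expression container.

The matrix carries an explicit ``scale`` flag (``"linear"`` for
nonnegative counts/intensities, ``"log2"`` for log-transformed values) so
that operations which only make sense on one scale can refuse the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample
        identifiers as columns.
    scale
        ``"linear"`` (values must be nonnegative) or ``"log2"``.
    sample_annotations
        Optional per-sample metadata (e.g. cancer type, cohort), indexed
        by sample identifier.
    """

    values: pd.DataFrame
    scale: str = LINEAR
    sample_annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        if self.scale == LINEAR and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale matrix contains negative values")
        if self.sample_annotations is not None:
            missing = set(map(str, self.values.columns)) - set(
                map(str, self.sample_annotations.index)
            )
            if missing:
                raise ValueError(
                    f"sample annotations missing for {sorted(missing)[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(map(str, self.values.index))

    @property
    def sample_ids(self) -> list[str]:
        return list(map(str, self.values.columns))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(
            self.values.loc[genes].copy(), self.scale, self.sample_annotations
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        ann = self.sample_annotations
        if ann is not None:
            ann = ann.loc[samples].copy()
        return ExpressionMatrix(self.values[samples].copy(), self.scale, ann)

    def copy(self) -> "ExpressionMatrix":
        ann = None
        if self.sample_annotations is not None:
            ann = self.sample_annotations.copy()
        return ExpressionMatrix(self.values.copy(), self.scale, ann)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"scale={self.scale})"
        )


def as_float_array(m: ExpressionMatrix) -> np.ndarray:
    return m.values.to_numpy(dtype=float)
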