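"""Readers and writers for the package's plain-text formats.

Expression matrices travel as TSV with a leading ``gene_id`` column;
gene sets as GMT, optionally with per-gene weights encoded as
``GENE|WEIGHT`` tokens (an extension of the standard tab-separated GMT
dialect); probe maps as two-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix


def read_expression_tsv(
    path: str | Path, scale: str = "linear"
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return df


def write_clinical_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("probe map must have exactly two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Parse a GMT file into ``{set_name: {"description", "genes", "weights"}}``.

    Gene tokens may carry weights as ``GENE|WEIGHT``; unweighted tokens
    get weight 1.0.
    """
    sets: dict[str, dict] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, tokens = fields[0], fields[1], fields[2:]
        genes: list[str] = []
        weights: list[float] = []
        for tok in tokens:
            if not tok:
                continue
            if "|" in tok:
                g, w = tok.split("|", 1)
                genes.append(g)
                weights.append(float(w))
            else:
                genes.append(tok)
                weights.append(1.0)
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = {"description": desc, "genes": genes, "weights": weights}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    lines = []
    for name, rec in sets.items():
        genes = rec["genes"]
        weights = rec.get("weights") or [1.0] * len(genes)
        toks = [
            g if w == 1.0 else f"{g}|{w:g}" for g, w in zip(genes, weights)
        ]
        lines.append("\t".join([name, rec.get("description", "")] + toks))
    Path(path).write_text("\n".join(lines) + "\n")
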