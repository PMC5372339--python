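"""Delimited-text readers/writers for the pipeline's inputs and outputs.

All formats are plain TSV: expression matrices (features x samples, header
row of sample ids, first column feature ids), classification layers in long
(sample, layer, label) or wide (samples x layers) form, two-column label
tables, survival tables, GMT gene sets and YAML run configs. The missing
value token is ``NA`` throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .integration import ClassificationLayer

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_layers",
    "write_labels",
    "read_survival",
    "read_gmt",
    "read_config",
    "write_config",
]

NA_TOKEN = "NA"


class ParseError(ValueError):
    """Malformed input file; the message carries the offending location."""


def read_matrix(path: str | Path, orientation: str = "features_by_samples") -> pd.DataFrame:
    """Read a delimited numeric matrix with identifier checks.

    ``orientation`` is the layout on disk; the returned frame is always
    features x samples. Duplicate identifiers, ragged rows and non-numeric
    cells raise :class:`ParseError` naming the problem.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ParseError(f"{path}: duplicated column identifier: {name!r}")
        seen.add(name)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().astype(str))
        raise ParseError(f"{path}: duplicated row identifiers: {dups}")
    bad = df.dtypes[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad) > 0:
        for col in bad.index:
            offending = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(offending) > 0:
                row = offending.index[0]
                raise ParseError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                    f"{offending.iloc[0]!r}"
                )
        df = df.apply(pd.to_numeric)
    if orientation == "samples_by_features":
        df = df.T
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a features x samples matrix as TSV with NA for missing."""
    matrix.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_layers(path: str | Path) -> list[ClassificationLayer]:
    """Read classification layers from long or wide TSV.

    Long format has columns (sample, layer, label); anything else with a
    sample-id first column is treated as wide (one column per layer).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN])
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["sample", "layer", "label"]:
        df.columns = ["sample", "layer", "label"] + list(df.columns[3:])
        layers = []
        for name, sub in df.groupby("layer", sort=False):
            if sub["sample"].duplicated().any():
                dup = sub.loc[sub["sample"].duplicated(), "sample"].iloc[0]
                raise ParseError(f"{path}: duplicate sample {dup!r} in layer {name!r}")
            layers.append(
                ClassificationLayer(str(name), sub.set_index("sample")["label"])
            )
        return layers
    wide = df.set_index(df.columns[0])
    if wide.index.has_duplicates:
        dup = wide.index[wide.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample identifier {dup!r}")
    return [ClassificationLayer(str(c), wide[c]) for c in wide.columns]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    """Write a two-column (sample, label) TSV."""
    out = labels.rename("label")
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table TSV (sample, time, event, further columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    for col in ("time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: survival table lacks column {col!r}")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs name, description, genes")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
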