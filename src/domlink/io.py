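"""CSV interfaces: long-format intensity/abundance tables plus metadata.

All tables are plain CSV with a stable column order and floats written at
10 significant digits.  Sample identity in the long tables is
(source, replicate, day); the control bottle of each source is replicate 0
and flagged in the metadata table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, IntensityMatrix, SampleKey

__all__ = [
    "SchemaError",
    "write_formulas",
    "write_intensity",
    "write_abundance",
    "write_metadata",
    "write_truth",
    "read_tables",
    "write_table",
]

FLOAT_FORMAT = "%.10g"
DEFAULT_DAYS = (1, 4, 7, 14)


class SchemaError(ValueError):
    """One or more schema violations; all are listed in the message."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index)


def write_formulas(annotations: pd.DataFrame, path) -> None:
    cols = ["c", "h", "n", "o", "s", "p"]
    out = annotations[cols].reset_index()
    write_table(out, path)


def write_metadata(samples: pd.DataFrame, path) -> None:
    out = samples[["source", "replicate", "day", "is_control"]].copy()
    out = out.sort_values(["source", "replicate", "day"]).reset_index(drop=True)
    write_table(out, path)


def _write_long(m, path, feature_col: str, value_col: str) -> None:
    long = m.values.stack()
    long = long[long > 0] if value_col == "intensity" else long
    long.index.names = [feature_col, "sample"]
    long = long.rename(value_col).reset_index()
    meta = m.samples[["source", "replicate", "day"]]
    long = long.join(meta, on="sample").drop(columns="sample")
    long = long[[feature_col, "source", "replicate", "day", value_col]]
    long = long.sort_values([feature_col, "source", "replicate", "day"])
    write_table(long.reset_index(drop=True), path)


def write_intensity(m: IntensityMatrix, path) -> None:
    """Long-format intensity table; zero entries are omitted."""
    _write_long(m, path, "formula_id", "intensity")


def write_abundance(ab: AbundanceMatrix, path) -> None:
    _write_long(ab, path, "species", "abundance")


def write_truth(links: pd.DataFrame, path) -> None:
    cols = ["species", "formula_id", "source", "kind", "rate"]
    write_table(links[cols].sort_values(cols[:3]).reset_index(drop=True), path)


def read_tables(
    intensity_path,
    abundance_path,
    metadata_path,
    days_allowed: tuple[int, ...] | None = DEFAULT_DAYS,
) -> tuple[IntensityMatrix, AbundanceMatrix, pd.DataFrame]:
    """Read and validate the three CSV interfaces.

    Schema violations are collected and reported together, not
    first-failure-only.  Returns the two matrices (normalized flags set if
    columns close to 1) and the metadata table.
    """
    intensity = pd.read_csv(intensity_path)
    abundance = pd.read_csv(abundance_path)
    metadata = pd.read_csv(metadata_path)
    problems: list[str] = []
    _require(intensity, ["formula_id", "source", "replicate", "day", "intensity"],
             "intensity", problems)
    _require(abundance, ["species", "source", "replicate", "day", "abundance"],
             "abundance", problems)
    _require(metadata, ["source", "replicate", "day", "is_control"],
             "metadata", problems)
    if problems:
        raise SchemaError(problems)

    if days_allowed is not None:
        for name, df in (("intensity", intensity), ("abundance", abundance),
                         ("metadata", metadata)):
            bad = sorted(set(df["day"]) - set(days_allowed))
            if bad:
                problems.append(
                    f"{name}: day value(s) {bad} not in allowed {sorted(days_allowed)}"
                )
    if (intensity["intensity"] < 0).any():
        problems.append("intensity: negative intensity values")
    if (abundance["abundance"] < 0).any():
        problems.append("abundance: negative abundance values")
    for name, df, keys in (
        ("intensity", intensity, ["formula_id", "source", "replicate", "day"]),
        ("abundance", abundance, ["species", "source", "replicate", "day"]),
        ("metadata", metadata, ["source", "replicate", "day"]),
    ):
        if df.duplicated(subset=keys).any():
            problems.append(f"{name}: duplicate rows for key {keys}")
    if problems:
        raise SchemaError(problems)

    meta = metadata.copy()
    meta["is_control"] = meta["is_control"].astype(bool)
    keys = [
        SampleKey(str(r.source), int(r.replicate), int(r.day), bool(r.is_control))
        for r in meta.itertuples()
    ]
    key_by_srd = {(k.source, k.replicate, k.day): k for k in keys}

    def pivot(df, feature_col, value_col, allowed_keys):
        cols = {}
        feats = sorted(df[feature_col].unique())
        fpos = {f: i for i, f in enumerate(feats)}
        for (source, rep, day), grp in df.groupby(["source", "replicate", "day"]):
            k = key_by_srd.get((str(source), int(rep), int(day)))
            if k is None:
                raise SchemaError(
                    [f"sample ({source}, {rep}, {day}) absent from metadata"]
                )
            if k not in allowed_keys:
                continue
            col = np.zeros(len(feats))
            col[[fpos[f] for f in grp[feature_col]]] = grp[value_col].to_numpy()
            cols[k] = col
        ordered = [k for k in keys if k in cols]
        values = pd.DataFrame(
            {k.label(): cols[k] for k in ordered},
            index=pd.Index(feats, name=feature_col),
        )
        sums = values.to_numpy().sum(axis=0)
        normalized = bool(np.allclose(sums, 1.0, atol=1e-9, rtol=0)) and len(sums)
        return values, ordered, normalized

    all_keys = set(keys)
    sample_keys = {k for k in keys if not k.is_control}
    ivals, ikeys, inorm = pivot(intensity, "formula_id", "intensity", all_keys)
    avals, akeys, anorm = pivot(abundance, "species", "abundance", sample_keys)
    m = IntensityMatrix.from_keys(ivals, ikeys, normalized=bool(inorm))
    ab = AbundanceMatrix.from_keys(avals, akeys, normalized=bool(anorm))
    return m, ab, meta


def _require(df: pd.DataFrame, cols: list[str], name: str, problems: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        problems.append(f"{name}: missing column(s) {missing}")
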