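"""Shared tabular containers: sample keys and the two compositional matrices.

Samples are bottles of a microcosm experiment identified by (DOM source,
replicate, day); a fourth, bacteria-free bottle per source serves as a
negative control.  Both the formula-intensity table and the species-abundance
table are compositional: once normalized, every sample column sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "IntensityMatrix",
    "AbundanceMatrix",
    "DegenerateSampleError",
]

CLOSURE_TOL = 1e-9


class DegenerateSampleError(ValueError):
    """A sample column has zero total signal and cannot be normalized."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one bottle at one sampling day."""

    source: str
    replicate: int
    day: int
    is_control: bool = False

    def label(self) -> str:
        tag = "c" if self.is_control else "r"
        return f"{self.source}|{tag}{self.replicate}|d{self.day}"

    @staticmethod
    def from_label(label: str) -> "SampleKey":
        source, rep, day = label.rsplit("|", 2)
        return SampleKey(
            source=source,
            replicate=int(rep[1:]),
            day=int(day[1:]),
            is_control=rep.startswith("c"),
        )


def _samples_frame(keys: list[SampleKey]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "source": [k.source for k in keys],
            "replicate": [k.replicate for k in keys],
            "day": [k.day for k in keys],
            "is_control": [k.is_control for k in keys],
        },
        index=[k.label() for k in keys],
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample keys: {dup}")
    return df


@dataclass
class _FeatureMatrix:
    """Features x samples table with per-sample metadata.

    ``values`` is indexed by feature id, with one column per sample label;
    ``samples`` is indexed by sample label with columns
    (source, replicate, day, is_control).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample metadata index disagree")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative entries are not allowed")
        if self.normalized:
            sums = self.values.to_numpy().sum(axis=0)
            if not np.allclose(sums, 1.0, atol=CLOSURE_TOL, rtol=0):
                raise ValueError("normalized matrix columns must each sum to 1")

    @classmethod
    def from_keys(
        cls, values: pd.DataFrame, keys: list[SampleKey], normalized: bool = False
    ):
        meta = _samples_frame(keys)
        values = values.copy()
        values.columns = meta.index
        return cls(values=values, samples=meta, normalized=normalized)

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [
            SampleKey(r.source, int(r.replicate), int(r.day), bool(r.is_control))
            for r in self.samples.itertuples()
        ]

    def subset_samples(self, mask) -> "_FeatureMatrix":
        keep = self.samples.index[np.asarray(mask, dtype=bool)]
        return replace(
            self,
            values=self.values.loc[:, keep],
            samples=self.samples.loc[keep],
        )

    def without_controls(self) -> "_FeatureMatrix":
        return self.subset_samples(~self.samples["is_control"].to_numpy())

    def sources(self) -> list[str]:
        return sorted(self.samples["source"].unique())

    def days(self) -> list[int]:
        return sorted(self.samples["day"].unique())

    def source_samples(self, source: str, include_controls: bool = False) -> pd.Index:
        meta = self.samples
        mask = meta["source"] == source
        if not include_controls:
            mask &= ~meta["is_control"]
        return meta.index[mask]


@dataclass
class IntensityMatrix(_FeatureMatrix):
    """Molecular formulae x samples relative peak intensities."""


@dataclass
class AbundanceMatrix(_FeatureMatrix):
    """Species x samples relative abundances."""
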