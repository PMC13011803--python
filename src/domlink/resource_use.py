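"""Species-vs-formula correlation screen: putative resource use.

The relative abundance of each bacterial species is correlated (midrank
Spearman) with the relative intensity of every eligible molecular formula
across the time series of each DOM source.  The strongest negative
correlations -- the lower 2.5% tail of the pooled signed distribution by
default -- are read as putative resource use.  Per (species, source,
compound class) cells, the proportion of class formulae a species uses
summarizes its niche breadth; a stratified permutation test asks whether
species differ in selection probability, replacing a binomial mixed-effects
model with a design-respecting resampling scheme.  Finally, joint depletion
intersects the species screen with the formula-vs-time screen: formulae
that both track a species negatively and decline over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, IntensityMatrix
from .temporal import (
    ThresholdSpec,
    eligible_formulae,
    percentile_threshold,
    spearman_profile,
)

__all__ = [
    "correlate_species",
    "putative_use",
    "ResourceUseProfile",
    "species_difference_test",
    "SpeciesDifferenceResult",
    "joint_depletion",
    "JointDepletion",
]


def correlate_species(
    ab: AbundanceMatrix, m: IntensityMatrix, min_reps: int = 2
) -> pd.DataFrame:
    """Per-source Spearman correlations between species and formulae.

    For every (species, formula, source) triple, the midrank Spearman
    correlation between the species' relative abundance and the formula's
    relative intensity over the source's replicate samples (pooled across
    days).  Formulae follow the same every-time-point presence rule as the
    time screen; constant series on a source are flagged undefined and
    excluded.

    Returns a DataFrame with columns species, formula_id, source, rho,
    n_points.
    """
    if not m.normalized or not ab.normalized:
        raise ValueError("both matrices must be normalized")
    frames = []
    for source in m.sources():
        cols_m = m.source_samples(source)
        cols_a = ab.source_samples(source)
        common = [c for c in cols_m if c in set(cols_a)]
        if len(common) < 6:
            warnings.warn(
                f"source {source!r} has {len(common)} shared samples (<6); skipped",
                stacklevel=2,
            )
            continue
        fids = eligible_formulae(m, source, min_reps=min_reps)
        if len(fids) == 0:
            continue
        series = m.values.loc[fids, common].to_numpy(dtype=float)
        for species in ab.feature_ids:
            y = ab.values.loc[species, common].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                warnings.warn(
                    f"species {species!r} constant on source {source!r}; excluded",
                    stacklevel=2,
                )
                continue
            rho = spearman_profile(series, y)
            keep = np.isfinite(rho)
            frames.append(
                pd.DataFrame(
                    {
                        "species": species,
                        "formula_id": fids[keep],
                        "source": source,
                        "rho": rho[keep],
                        "n_points": len(common),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["species", "formula_id", "source", "rho", "n_points"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ResourceUseProfile:
    """Putative resource use per (species, source, compound class) cell."""

    #: columns species, source, compound_class, n_class, k_used, proportion_used
    cells: pd.DataFrame
    #: per-species mean of proportion_used across cells
    species_means: pd.Series
    #: the selected (species, formula, source) correlations
    selected: pd.DataFrame
    realized_cutoff: float


def putative_use(
    corrs: pd.DataFrame,
    annotations: pd.DataFrame,
    spec: ThresholdSpec = ThresholdSpec(top_fraction=0.025, sided="negative"),
) -> ResourceUseProfile:
    """Threshold the species screen and profile use per class and source.

    The cutoff is the one-sided negative percentile of the pooled signed
    correlation distribution across all (species, formula, source) triples.
    ``proportion_used`` is k_used / n_class within each cell; cells cover
    every combination of species, source and compound class present among
    the tested formulae (zero counts included).
    """
    flagged, cutoff = percentile_threshold(corrs, spec)
    flagged = flagged.merge(
        annotations["compound_class"].rename("compound_class"),
        left_on="formula_id",
        right_index=True,
        how="left",
    )
    selected = flagged[flagged["selected_neg"]].copy()
    if selected.empty:
        warnings.warn("empty selection: profile of zeros", stacklevel=2)
    cell_n = (
        flagged.groupby(["species", "source", "compound_class"], sort=True)
        .size()
        .rename("n_class")
    )
    cell_k = (
        flagged.groupby(["species", "source", "compound_class"], sort=True)[
            "selected_neg"
        ]
        .sum()
        .rename("k_used")
        .astype(int)
    )
    cells = pd.concat([cell_n, cell_k], axis=1).reset_index()
    cells["proportion_used"] = cells["k_used"] / cells["n_class"]
    means = cells.groupby("species")["proportion_used"].mean()
    return ResourceUseProfile(
        cells=cells,
        species_means=means,
        selected=selected,
        realized_cutoff=cutoff,
    )


@dataclass
class SpeciesDifferenceResult:
    statistic: float
    p_value: float
    contrasts: pd.DataFrame  # species_a, species_b, statistic, p_value
    n_permutations: int
    seed: int | None


def species_difference_test(
    profile: ResourceUseProfile | pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
) -> SpeciesDifferenceResult:
    """Do species differ in their per-cell selection proportions?

    The statistic is the between-species variance of cell-averaged use
    proportions.  The null is built by shuffling species labels of the
    k_used counts independently within each (source, compound class)
    stratum, which preserves every cell's n_class exactly.  Pairwise
    contrasts use |mean_a - mean_b| under the same permutations.
    """
    cells = profile.cells if isinstance(profile, ResourceUseProfile) else profile
    species = sorted(cells["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    # cells as a (stratum x species) array of proportions
    wide = cells.pivot_table(
        index=["source", "compound_class"],
        columns="species",
        values="proportion_used",
    )[species]
    arr = wide.to_numpy(dtype=float)  # strata x species; NaN where untested
    means_obs = np.nanmean(arr, axis=0)
    stat_obs = float(np.var(means_obs))
    pairs = [(a, b) for i, a in enumerate(species) for b in species[i + 1 :]]
    pair_obs = {
        (a, b): abs(means_obs[species.index(a)] - means_obs[species.index(b)])
        for a, b in pairs
    }
    rng = np.random.default_rng(seed)
    count_global = 0
    count_pairs = {p: 0 for p in pairs}
    for _ in range(n_perm):
        perm_arr = arr.copy()
        for row in range(perm_arr.shape[0]):
            rng.shuffle(perm_arr[row])
        means = np.nanmean(perm_arr, axis=0)
        if float(np.var(means)) >= stat_obs - 1e-15:
            count_global += 1
        for (a, b) in pairs:
            d = abs(means[species.index(a)] - means[species.index(b)])
            if d >= pair_obs[(a, b)] - 1e-15:
                count_pairs[(a, b)] += 1
    contrasts = pd.DataFrame(
        [
            {
                "species_a": a,
                "species_b": b,
                "statistic": pair_obs[(a, b)],
                "p_value": (1 + count_pairs[(a, b)]) / (1 + n_perm),
            }
            for a, b in pairs
        ]
    )
    return SpeciesDifferenceResult(
        statistic=stat_obs,
        p_value=(1 + count_global) / (1 + n_perm),
        contrasts=contrasts,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class JointDepletion:
    """Formulae that both track a species negatively and decline with time."""

    #: columns species, source, species_linked, joint_count, fraction_also_declining
    counts: pd.DataFrame
    #: predicted consume links: columns species, formula_id, source
    predicted_links: pd.DataFrame
    species_cutoff: float
    time_cutoff: float


def joint_depletion(
    species_corrs: pd.DataFrame,
    time_corrs: pd.DataFrame,
    species_spec: ThresholdSpec = ThresholdSpec(top_fraction=0.025, sided="negative"),
    time_spec: ThresholdSpec = ThresholdSpec(top_fraction=0.025, sided="negative"),
) -> JointDepletion:
    """Intersect the species screen with the declining-with-time screen.

    Per (species, source): the number of formulae selected in both screens,
    and the fraction of that species' selected formulae that also decline
    over time.  The joint (species, formula, source) triples are the
    screen's predicted consume links.
    """
    shared = set(species_corrs["formula_id"]) & set(time_corrs["formula_id"])
    if not shared:
        raise ValueError("species and time screens cover disjoint formula sets")
    sp_flagged, sp_cut = percentile_threshold(species_corrs, species_spec)
    t_flagged, t_cut = percentile_threshold(time_corrs, time_spec)
    declining = t_flagged[t_flagged["selected_neg"]][["formula_id", "source"]]
    declining_keys = set(map(tuple, declining.to_numpy()))
    linked = sp_flagged[sp_flagged["selected_neg"]].copy()
    linked["declines"] = [
        (f, s) in declining_keys
        for f, s in zip(linked["formula_id"], linked["source"])
    ]
    rows = []
    for (species, source), grp in sp_flagged.groupby(["species", "source"], sort=True):
        sel = linked[(linked["species"] == species) & (linked["source"] == source)]
        n_linked = len(sel)
        joint = int(sel["declines"].sum())
        rows.append(
            {
                "species": species,
                "source": source,
                "species_linked": n_linked,
                "joint_count": joint,
                "fraction_also_declining": joint / n_linked if n_linked else 0.0,
            }
        )
    predicted = linked[linked["declines"]][["species", "formula_id", "source"]]
    return JointDepletion(
        counts=pd.DataFrame(rows),
        predicted_links=predicted.reset_index(drop=True),
        species_cutoff=sp_cut,
        time_cutoff=t_cut,
    )
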