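"""Formula-vs-time correlation screen and compound-class enrichment.

Every eligible molecular formula on every DOM source gets a midrank
Spearman correlation between its relative intensity and the sampling day.
Correlations in the top fraction of the pooled |rho| distribution (default
5%, two-sided) are flagged as putatively produced (positive) or consumed
(negative).  Within each (source, compound class) cell the selected counts
are tested against the equal-split null -- selection probability f/2 for
each direction, 1-f unselected -- with an exact multinomial test, followed
by post hoc exact binomial tests that set the direction verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest, rankdata

from .containers import IntensityMatrix

__all__ = [
    "ThresholdSpec",
    "spearman",
    "spearman_profile",
    "correlate_time",
    "eligible_formulae",
    "percentile_threshold",
    "exact_multinomial_test",
    "MultinomialTestResult",
    "exact_binomial_test",
    "class_enrichment",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Percentile selection rule for a pooled correlation distribution.

    ``top_fraction`` is the selected fraction; ``sided`` is ``"two"``
    (on |rho|, flags split by sign) or ``"negative"`` (lower tail of the
    signed distribution).  ``scope`` records whether pooling is dataset-wide
    or per source.
    """

    top_fraction: float = 0.05
    sided: str = "two"  # "two" | "negative"
    scope: str = "dataset"  # "dataset" | "per-source"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.sided not in ("two", "negative"):
            raise ValueError("sided must be 'two' or 'negative'")
        if self.scope not in ("dataset", "per-source"):
            raise ValueError("scope must be 'dataset' or 'per-source'")


# ---------------------------------------------------------------------------
# Spearman correlation (midrank Pearson)
# ---------------------------------------------------------------------------


def spearman(x, y) -> float:
    """Midrank Spearman correlation of two equal-length series.

    Pearson correlation of average (mid) ranks.  Returns NaN for constant
    series; callers exclude such undefined correlations rather than
    propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_profile(series: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Midrank Spearman of each row of ``series`` against one covariate.

    Vectorized over rows; rows with zero variance yield NaN.
    """
    series = np.asarray(series, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ranks = rankdata(series, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    rc = rankdata(covariate).astype(float)
    rc -= rc.mean()
    denom = np.sqrt((ranks**2).sum(axis=1) * (rc @ rc))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks @ rc) / denom
    rho[np.ptp(series, axis=1) == 0] = np.nan
    return rho


# ---------------------------------------------------------------------------
# Formula-vs-time correlations
# ---------------------------------------------------------------------------


def eligible_formulae(m: IntensityMatrix, source: str, min_reps: int = 2) -> pd.Index:
    """Formulae present (>0) in >= min_reps replicates at every sampling day.

    Control bottles are ignored; a formula failing the rule at any day of
    the source is excluded from that source's screen entirely.
    """
    cols = m.source_samples(source)
    meta = m.samples.loc[cols]
    vals = m.values[cols]
    ok = np.ones(len(m.feature_ids), dtype=bool)
    any_present = np.zeros(len(m.feature_ids), dtype=bool)
    for _, idx in meta.groupby("day").groups.items():
        present = (vals[list(idx)].to_numpy() > 0).sum(axis=1)
        ok &= present >= min_reps
        any_present |= present > 0
    return m.feature_ids[ok & any_present]


def correlate_time(m: IntensityMatrix, min_reps: int = 2) -> pd.DataFrame:
    """Per-source formula-vs-day Spearman correlations.

    All replicate samples of a source are pooled (day as the covariate, so
    3 replicates x 4 days give 12 points).  Formulae failing the
    every-time-point presence rule, and constant series, are excluded.

    Returns a DataFrame with columns formula_id, source, rho, n_points.
    """
    if not m.normalized:
        raise ValueError("correlate_time requires a normalized matrix")
    frames = []
    for source in m.sources():
        cols = m.source_samples(source)
        days = m.samples.loc[cols, "day"].to_numpy(dtype=float)
        if len(np.unique(days)) < 2:
            warnings.warn(f"source {source!r} has <2 time points; skipped", stacklevel=2)
            continue
        fids = eligible_formulae(m, source, min_reps=min_reps)
        if len(fids) == 0:
            continue
        series = m.values.loc[fids, cols].to_numpy(dtype=float)
        rho = spearman_profile(series, days)
        keep = np.isfinite(rho)
        frames.append(
            pd.DataFrame(
                {
                    "formula_id": fids[keep],
                    "source": source,
                    "rho": rho[keep],
                    "n_points": len(cols),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["formula_id", "source", "rho", "n_points"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Percentile thresholding
# ---------------------------------------------------------------------------


def percentile_threshold(
    corrs: pd.DataFrame, spec: ThresholdSpec
) -> tuple[pd.DataFrame, float]:
    """Flag correlations beyond the realized percentile cutoff.

    The cutoff is the k-th most extreme order statistic of the pooled
    distribution in scope, k = ceil(top_fraction * n); ties at the cutoff
    are all kept (>= / <= comparisons).  Two-sided selection splits flags by
    sign (``selected_pos`` / ``selected_neg``); one-sided negative selection
    only sets ``selected_neg``.

    Returns the flagged table and the realized cutoff (on |rho| for
    two-sided, on signed rho for one-sided).
    """
    corrs = corrs.copy()
    rho = corrs["rho"].to_numpy(dtype=float)
    n = len(rho)
    if n < 20:
        raise ValueError(f"need >= 20 finite correlations in scope, got {n}")
    if n < 1 / spec.top_fraction:
        warnings.warn(
            f"only {n} correlations for top_fraction={spec.top_fraction}; "
            "selection may be empty",
            stacklevel=2,
        )
    k = max(1, int(np.ceil(spec.top_fraction * n - 1e-9)))
    if spec.sided == "two":
        cutoff = float(np.sort(np.abs(rho))[::-1][k - 1])
        corrs["selected_pos"] = rho >= cutoff
        corrs["selected_neg"] = rho <= -cutoff
    else:
        cutoff = float(np.sort(rho)[k - 1])
        corrs["selected_pos"] = False
        corrs["selected_neg"] = rho <= cutoff
    return corrs, cutoff


# ---------------------------------------------------------------------------
# Exact multinomial and binomial tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultinomialTestResult:
    p_value: float
    mode: str  # "exact" | "monte-carlo"
    n_draws: int = 0


def _multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Log pmf of count vectors (rows) under Multinomial(n, probs).

    Categories with prob 0 contribute -inf unless their count is 0.
    """
    counts = np.atleast_2d(counts).astype(float)
    n = counts.sum(axis=1)
    out = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), -np.inf)
        terms = counts * logp
        terms = np.where(counts == 0, 0.0, terms)
    return out + terms.sum(axis=1)


def exact_multinomial_test(
    observed,
    probs,
    exact_limit: int = 60,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> MultinomialTestResult:
    """Exact multinomial goodness-of-fit p-value (small-probability ordering).

    p = P(outcome vectors whose multinomial probability is <= that of the
    observed vector).  Full enumeration when the total count is at most
    ``exact_limit``; otherwise a seeded Monte-Carlo estimate from ``n_mc``
    draws, flagged in the result.
    """
    observed = np.asarray(observed, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if observed.ndim != 1 or observed.shape != probs.shape:
        raise ValueError("observed and probs must be 1-D of equal length")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {probs.sum()}")
    n = int(observed.sum())
    k = len(observed)
    if n == 0:
        return MultinomialTestResult(p_value=1.0, mode="exact")
    logp_obs = float(_multinomial_logpmf(observed, probs)[0])
    if n <= exact_limit:
        vectors = np.array(
            [
                _bars_to_counts(bars, n, k)
                for bars in combinations_with_replacement(range(n + 1), k - 1)
            ]
        )
        logp = _multinomial_logpmf(vectors, probs)
        mask = logp <= logp_obs + 1e-12
        p = float(np.exp(logp[mask]).sum())
        return MultinomialTestResult(p_value=min(p, 1.0), mode="exact")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_mc)
    logp = _multinomial_logpmf(draws, probs)
    p = float((logp <= logp_obs + 1e-12).mean())
    return MultinomialTestResult(p_value=max(p, 1.0 / n_mc), mode="monte-carlo", n_draws=n_mc)


def _bars_to_counts(bars: tuple[int, ...], n: int, k: int) -> list[int]:
    edges = (0,) + bars + (n,)
    return [edges[i + 1] - edges[i] for i in range(k)]


def exact_binomial_test(k: int, n: int, p0: float, side: str = "two-sided") -> float:
    """Exact binomial tail p-value.

    ``side`` is ``"greater"``, ``"less"`` or ``"two-sided"``; the two-sided
    p uses the small-probability ordering rule (sum of outcome probabilities
    no larger than the observed outcome's).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if side not in ("greater", "less", "two-sided"):
        raise ValueError("side must be 'greater', 'less' or 'two-sided'")
    return float(binomtest(k, n, p0, alternative=side).pvalue)


# ---------------------------------------------------------------------------
# Class enrichment
# ---------------------------------------------------------------------------


def class_enrichment(
    corrs: pd.DataFrame,
    annotations: pd.DataFrame,
    top_fraction: float = 0.05,
    alpha: float = 0.05,
    categories: str = "three",
    exact_limit: int = 60,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compound-class enrichment of selected correlations, per source.

    Under the null, the selected fraction ``f`` of a class splits equally
    between positive and negative correlations, giving category
    probabilities (f/2, f/2, 1-f) for (selected-positive, selected-negative,
    unselected).  The two-category alternative (positives vs negatives among
    selected formulae only, null 50:50) is available via
    ``categories="two"``.  Cells with an exact multinomial p below ``alpha``
    get post hoc one-sided binomial tests of each direction against
    Binomial(n_class, f/2), which set the verdict.

    Returns one row per (source, compound_class) with counts, p-values and
    verdict in {"preferentially consumed", "preferentially produced",
    "both", "none"}.
    """
    required = {"selected_pos", "selected_neg"}
    if not required <= set(corrs.columns):
        raise ValueError("correlations must be thresholded first")
    ann_class = annotations["compound_class"]
    corrs = corrs.merge(
        ann_class.rename("compound_class"),
        left_on="formula_id",
        right_index=True,
        how="left",
    )
    rows = []
    rng = np.random.default_rng(seed)
    for (source, cls), grp in corrs.groupby(["source", "compound_class"], sort=True):
        n_class = len(grp)
        if n_class == 0:
            continue
        k_pos = int(grp["selected_pos"].sum())
        k_neg = int(grp["selected_neg"].sum())
        if categories == "three":
            obs = [k_pos, k_neg, n_class - k_pos - k_neg]
            probs = [top_fraction / 2, top_fraction / 2, 1 - top_fraction]
        elif categories == "two":
            if k_pos + k_neg == 0:
                continue
            obs = [k_pos, k_neg]
            probs = [0.5, 0.5]
        else:
            raise ValueError("categories must be 'three' or 'two'")
        res = exact_multinomial_test(
            obs, probs, exact_limit=exact_limit,
            seed=int(rng.integers(2**31 - 1)),
        )
        p_pos = exact_binomial_test(k_pos, n_class, top_fraction / 2, "greater")
        p_neg = exact_binomial_test(k_neg, n_class, top_fraction / 2, "greater")
        verdict = "none"
        if res.p_value < alpha:
            produced = p_pos < alpha
            consumed = p_neg < alpha
            if produced and consumed:
                verdict = "both"
            elif produced:
                verdict = "preferentially produced"
            elif consumed:
                verdict = "preferentially consumed"
        rows.append(
            {
                "source": source,
                "compound_class": cls,
                "n_class": n_class,
                "k_pos": k_pos,
                "k_neg": k_neg,
                "p_multinomial": res.p_value,
                "multinomial_mode": res.mode,
                "p_binomial_pos": p_pos,
                "p_binomial_neg": p_neg,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)
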