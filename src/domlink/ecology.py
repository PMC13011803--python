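"""Distance-based community ecology from first principles.

Bray-Curtis dissimilarities, principal coordinate analysis (Gower
double-centering + eigendecomposition), PERMANOVA in the McArdle-Anderson
trace formulation, envfit-style vector fitting, symmetric Procrustes with a
PROTEST permutation test, and distance-based redundancy analysis sharing the
PERMANOVA engine.

Permutation p-values use the add-one convention (1 + #{perm >= obs}) /
(1 + n_perm).  Negative PCoA eigenvalues are counted and excluded from the
proportion-explained denominator but not corrected (no Lingoes/Cailliez).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "PermanovaResult",
    "ProcrustesResult",
    "bray_curtis",
    "pcoa",
    "permanova",
    "envfit_vectors",
    "procrustes_protest",
    "dbrda",
]

_EIG_REL_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


def bray_curtis(m) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  Bounded in [0, 1]
    for non-negative data; a pair of all-zero profiles is undefined.
    """
    values = m if isinstance(m, pd.DataFrame) else m.values
    x = values.to_numpy(dtype=float).T  # samples x features
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        if (den == 0).any():
            j = int(np.nonzero(den == 0)[0][0]) + i + 1
            raise ValueError(
                f"undefined distance: samples {i} and {j} have all-zero profiles"
            )
        d[i, i + 1 :] = d[i + 1 :, i] = num / den
    return DistanceMatrix(labels=list(values.columns), d=d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = J (-0.5 D^2) J with J = I - 11'/n."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


@dataclass
class Ordination:
    """Principal-coordinate scores and eigenvalue bookkeeping."""

    labels: list[str]
    coords: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    prop_explained: np.ndarray  # retained axes, relative to sum of positives
    n_negative_eigenvalues: int


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis of a dissimilarity matrix.

    Axes with eigenvalue above a relative tolerance are retained; scores are
    eigenvectors scaled by sqrt(eigenvalue).  Negative eigenvalues (from
    non-Euclidean dissimilarities such as Bray-Curtis) are counted, warned
    about, and excluded from the proportion-explained denominator.
    """
    if dm.n < 3:
        raise ValueError(f"PCoA needs at least 3 samples, got {dm.n}")
    g = _gower_center(dm.d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(eigval.max(), 0.0) * _EIG_REL_TOL + 1e-15
    keep = eigval > tol
    n_neg = int((eigval < -tol).sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} negative PCoA eigenvalue(s); no correction applied",
            stacklevel=2,
        )
    pos_sum = eigval[eigval > tol].sum()
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    axes = [f"PCo{i + 1}" for i in range(int(keep.sum()))]
    prop = eigval[keep] / pos_sum if pos_sum > 0 else np.zeros(int(keep.sum()))
    return Ordination(
        labels=list(dm.labels),
        coords=pd.DataFrame(coords, index=dm.labels, columns=axes),
        eigenvalues=eigval,
        prop_explained=prop,
        n_negative_eigenvalues=n_neg,
    )


# ---------------------------------------------------------------------------
# PERMANOVA / dbRDA engine
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int | None
    df_model: int
    df_residual: int
    term: str = ""


def _model_matrix(design: pd.DataFrame | pd.Series) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded factors + numeric columns, with rank check."""
    if isinstance(design, pd.Series):
        design = design.to_frame(design.name or "x")
    blocks = [pd.Series(1.0, index=design.index, name="(Intercept)")]
    for col in design.columns:
        s = design[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            blocks.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype("category"), drop_first=True)
            dummies.columns = [f"{col}[{lvl}]" for lvl in dummies.columns]
            blocks.append(dummies.astype(float))
    x = pd.concat(blocks, axis=1)
    arr = x.to_numpy(dtype=float)
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < arr.shape[1]:
        aliased = [x.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient model matrix; aliased columns: {aliased}")
    return arr, list(x.columns)


def _hat_matrix(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _trace_f(g: np.ndarray, h: np.ndarray, q_df: int, resid_df: int) -> tuple[float, float]:
    tr_hg = float((h * g).sum())  # tr(HGH) = tr(HG), H idempotent symmetric
    tr_g = float(np.trace(g))
    f = (tr_hg / q_df) / ((tr_g - tr_hg) / resid_df)
    return f, tr_hg / tr_g


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    strata: pd.Series | None = None,
    term: str = "",
) -> PermanovaResult:
    """Permutational multivariate ANOVA (McArdle-Anderson trace form).

    pseudo-F = [tr(HGH)/q] / [tr((I-H)G(I-H))/(n-q-1)] with G the
    Gower-centered -d^2/2 matrix and H the hat matrix of the predictor model
    matrix; significance from permuting sample labels (rows/columns of G).
    """
    design = _align(design, dm.labels, "design")
    x, _ = _model_matrix(design)
    n = dm.n
    rank = np.linalg.matrix_rank(x)
    q_df = rank - 1
    resid_df = n - rank
    if q_df < 1 or resid_df < 1:
        raise ValueError("design leaves no model or residual degrees of freedom")
    g = _gower_center(dm.d)
    if np.trace(g) <= 1e-12:
        # all samples identical: every permutation gives the same (degenerate)
        # statistic, so the test carries no evidence
        return PermanovaResult(
            pseudo_f=0.0, r2=0.0, p_value=1.0, n_permutations=n_perm,
            seed=seed, df_model=q_df, df_residual=resid_df,
            term=term or ",".join(map(str, design.columns)),
        )
    h = _hat_matrix(x)
    f_obs, r2 = _trace_f(g, h, q_df, resid_df)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = _permute_indices(rng, n, strata, design.index)
        gp = g[np.ix_(perm, perm)]
        f_perm, _ = _trace_f(gp, h, q_df, resid_df)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=f_obs,
        r2=r2,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        df_model=q_df,
        df_residual=resid_df,
        term=term or ",".join(map(str, getattr(design, "columns", ["x"]))),
    )


def _permute_indices(rng, n, strata, index) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    strata = strata.loc[index]
    perm = np.arange(n)
    for _, grp in strata.groupby(strata, sort=False):
        pos = np.asarray([index.get_loc(i) for i in grp.index])
        perm[pos] = pos[rng.permutation(len(pos))]
    return perm


def dbrda(
    dm: DistanceMatrix,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based redundancy analysis.

    Same engine as :func:`permanova`; R2 is the constrained fraction of the
    total inertia, tr(HGH)/tr(G), reported with the pseudo-F and its
    permutation p-value.
    """
    return permanova(dm, predictors, n_perm=n_perm, seed=seed, term="dbRDA")


def _align(table, labels, what):
    table = table.to_frame() if isinstance(table, pd.Series) else table.copy()
    missing = [l for l in labels if l not in table.index]
    if missing:
        raise ValueError(f"{what} rows missing for samples: {missing}")
    return table.loc[list(labels)]


# ---------------------------------------------------------------------------
# envfit-style vector fitting
# ---------------------------------------------------------------------------


def envfit_vectors(
    ordination: Ordination,
    variables: pd.DataFrame,
    n_axes: int = 2,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit numeric variables as arrows onto the first ordination axes.

    Each variable is regressed on the first ``n_axes`` sample scores; the
    arrow is the unit-normalized coefficient vector, r2 the regression R^2,
    and p the permutation tail probability of r2 under row shuffles of the
    variable.  Zero-variance variables are flagged with r2 = 0, p = 1.
    """
    variables = _align(variables, ordination.labels, "variables")
    k = min(n_axes, ordination.coords.shape[1])
    scores = ordination.coords.to_numpy()[:, :k]
    scores = scores - scores.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        out = {"variable": name, "r2": 0.0, "p_value": 1.0, "zero_variance": False}
        for i in range(k):
            out[f"axis{i + 1}"] = 0.0
        if np.ptp(y) == 0 or not np.isfinite(y).all():
            out["zero_variance"] = True
            rows.append(out)
            continue
        r2_obs, coef = _envfit_r2(scores, y)
        direction = coef / np.linalg.norm(coef) if np.linalg.norm(coef) > 0 else coef
        count = 0
        for _ in range(n_perm):
            r2_perm, _ = _envfit_r2(scores, rng.permutation(y))
            if r2_perm >= r2_obs - 1e-12:
                count += 1
        out.update({f"axis{i + 1}": direction[i] for i in range(k)})
        out["r2"] = r2_obs
        out["p_value"] = (1 + count) / (1 + n_perm)
        rows.append(out)
    return pd.DataFrame(rows).set_index("variable")


def _envfit_r2(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    yc = y - y.mean()
    coef, *_ = np.linalg.lstsq(scores, yc, rcond=None)
    fitted = scores @ coef
    sst = float(yc @ yc)
    r2 = float(fitted @ fitted) / sst if sst > 0 else 0.0
    return r2, coef


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesResult:
    m2: float
    protest_r: float
    p_value: float
    n_permutations: int
    seed: int | None


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual sum of squares in [0, 1].

    Both configurations are centered and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of X'Y and m2 = 1 - (sum of singular
    values)^2.
    """
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(1.0 - s.sum() ** 2)


def _center_scale(a: np.ndarray, width: int) -> np.ndarray:
    a = a - a.mean(axis=0)
    norm = np.sqrt((a**2).sum())
    if norm == 0:
        raise ValueError("degenerate (all-identical) configuration")
    a = a / norm
    if a.shape[1] < width:
        a = np.hstack([a, np.zeros((a.shape[0], width - a.shape[1]))])
    return a


def procrustes_protest(
    a: Ordination,
    b: Ordination,
    n_perm: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes comparison of two ordinations with PROTEST.

    Uses the axes each ordination retained (the narrower configuration is
    zero-padded).  Significance comes from permuting the row order of the
    second configuration.
    """
    if list(a.labels) != list(b.labels):
        only_a = set(a.labels) - set(b.labels)
        only_b = set(b.labels) - set(a.labels)
        if only_a or only_b:
            raise ValueError(
                f"sample sets differ: only in first={sorted(only_a)}, "
                f"only in second={sorted(only_b)}"
            )
        raise ValueError("samples must be in matching order")
    width = max(a.coords.shape[1], b.coords.shape[1])
    x = _center_scale(a.coords.to_numpy(), width)
    y = _center_scale(b.coords.to_numpy(), width)
    m2_obs = _procrustes_m2(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[0])
        if _procrustes_m2(x, y[perm]) <= m2_obs + 1e-12:
            count += 1
    return ProcrustesResult(
        m2=m2_obs,
        protest_r=float(np.sqrt(max(0.0, 1.0 - m2_obs))),
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
    )
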