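"""Molecular-formula chemistry: annotation, van Krevelen classes, bulk metrics.

Each molecular formula (element counts C, H, N, O, S, P from ultra-high
resolution mass spectrometry) is annotated with its neutral monoisotopic
mass, H/C and O/C ratios, modified aromaticity index, a putative compound
class from its position in the van Krevelen plane, and a bioavailability
flag (H/C >= 1.5 by default).  Per-sample bulk descriptors are
intensity-weighted means of these quantities over the sample's formulae.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DegenerateSampleError, IntensityMatrix

__all__ = [
    "ElementalFormula",
    "FormulaAnnotation",
    "InvalidFormulaError",
    "COMPOUND_CLASSES",
    "DEFAULT_CLASS_TABLE",
    "BIOAVAILABLE_HC_CUTOFF",
    "parse_formula",
    "annotate",
    "annotate_formulas",
    "assign_compound_class",
    "normalize_tic",
    "replicate_presence_filter",
    "bulk_metrics",
]

# Monoisotopic atomic masses in Da.
MONOISOTOPIC_MASS = {
    "c": 12.000000,
    "h": 1.0078250319,
    "n": 14.0030740052,
    "o": 15.9949146221,
    "s": 31.97207069,
    "p": 30.97376151,
}

#: m/z shift from neutral monoisotopic mass to the [M-H]- ion (Da).
PROTON_MASS = 1.00728

#: Default biolability boundary on the H/C ratio.
BIOAVAILABLE_HC_CUTOFF = 1.5


class InvalidFormulaError(ValueError):
    """Element counts violate C >= 1 and H >= 1."""


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts of one neutral molecular formula (CHNOSP)."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidFormulaError(
                    f"{name.upper()} count must be a non-negative integer, got {v!r}"
                )
        if self.c < 1 or self.h < 1:
            raise InvalidFormulaError(
                f"formula must contain carbon and hydrogen (C{self.c}H{self.h})"
            )

    def __str__(self) -> str:
        # Hill order: C, H, then remaining elements alphabetically.
        parts = []
        for sym, count in (
            ("C", self.c),
            ("H", self.h),
            ("N", self.n),
            ("O", self.o),
            ("P", self.p),
            ("S", self.s),
        ):
            if count == 1:
                parts.append(sym)
            elif count > 1:
                parts.append(f"{sym}{count}")
        return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular-formula string such as ``"C10H12O5"``.

    Element symbols outside CHNOSP are rejected; an omitted count means 1.
    """
    counts = {k: 0 for k in MONOISOTOPIC_MASS}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text.strip()):
        if match.start() != pos:
            raise InvalidFormulaError(f"cannot parse formula string {text!r}")
        if not match.group(0):
            break
        sym = match.group(1).lower()
        if sym not in counts:
            raise InvalidFormulaError(
                f"unsupported element {match.group(1)!r} in {text!r}"
            )
        counts[sym] += int(match.group(2) or 1)
        pos = match.end()
    if pos != len(text.strip()):
        raise InvalidFormulaError(f"cannot parse formula string {text!r}")
    return ElementalFormula(**counts)


# ---------------------------------------------------------------------------
# Compound classes
# ---------------------------------------------------------------------------

#: (class name, hc_min, hc_max, hc_max_inclusive, oc_min, oc_min_inclusive, oc_max)
#: Rectangles are tried top-to-bottom; the first match wins.  hc_min and
#: oc_max are always inclusive.
DEFAULT_CLASS_TABLE: tuple[tuple[str, float, float, bool, float, bool, float], ...] = (
    ("lipid-like", 1.5, 2.0, True, 0.0, True, 0.3),
    ("protein-like", 1.5, 2.2, True, 0.3, False, 0.55),
    ("amino sugar-like", 1.5, 2.2, True, 0.55, False, 0.7),
    ("carbohydrate-like", 1.5, 2.4, True, 0.7, False, 1.2),
    ("unsaturated hydrocarbon-like", 0.7, 1.5, False, 0.0, True, 0.1),
    ("lignin-like", 0.7, 1.5, False, 0.1, False, 0.67),
    ("tannin-like", 0.5, 1.5, False, 0.67, False, 0.97),
    ("condensed aromatic-like", 0.2, 0.7, False, 0.0, True, 0.67),
)

COMPOUND_CLASSES: tuple[str, ...] = tuple(r[0] for r in DEFAULT_CLASS_TABLE) + (
    "unassigned",
)


def assign_compound_class(hc: float, oc: float, table=DEFAULT_CLASS_TABLE) -> str:
    """Assign a van Krevelen compound class from the (H/C, O/C) position.

    The first rectangle of ``table`` that contains the point wins; points in
    no rectangle are ``"unassigned"``.
    """
    for name, hc_lo, hc_hi, hc_hi_incl, oc_lo, oc_lo_incl, oc_hi in table:
        ok_hc = hc_lo <= hc <= hc_hi if hc_hi_incl else hc_lo <= hc < hc_hi
        ok_oc = oc_lo <= oc <= oc_hi if oc_lo_incl else oc_lo < oc <= oc_hi
        if ok_hc and ok_oc:
            return name
    return "unassigned"


@dataclass(frozen=True)
class FormulaAnnotation:
    """Derived chemistry of one molecular formula."""

    formula: ElementalFormula
    neutral_mass: float
    hc: float
    oc: float
    ai_mod: float
    compound_class: str
    bioavailable: bool


def _ai_mod(f: ElementalFormula) -> float:
    """Modified aromaticity index, clamped to [0, 1].

    Negative raw values and non-positive denominators map to 0 (no aromatic
    character); raw values above 1 are reported as 1.
    """
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.h)
    den = f.c - 0.5 * f.o - f.s - f.n - f.p
    if den <= 0 or num <= 0:
        return 0.0
    return min(num / den, 1.0)


def annotate(
    formula: ElementalFormula,
    hc_cutoff: float = BIOAVAILABLE_HC_CUTOFF,
    class_table=DEFAULT_CLASS_TABLE,
) -> FormulaAnnotation:
    """Annotate one formula with mass, ratios, aromaticity, class, lability."""
    mass = sum(
        getattr(formula, el) * m for el, m in MONOISOTOPIC_MASS.items()
    )
    hc = formula.h / formula.c
    oc = formula.o / formula.c
    return FormulaAnnotation(
        formula=formula,
        neutral_mass=mass,
        hc=hc,
        oc=oc,
        ai_mod=_ai_mod(formula),
        compound_class=assign_compound_class(hc, oc, class_table),
        bioavailable=hc >= hc_cutoff,
    )


def annotate_formulas(
    formulas: pd.DataFrame,
    hc_cutoff: float = BIOAVAILABLE_HC_CUTOFF,
    class_table=DEFAULT_CLASS_TABLE,
) -> pd.DataFrame:
    """Annotate a formula table.

    Parameters
    ----------
    formulas
        Indexed by formula_id with either integer columns c,h,n,o,s,p or a
        single ``formula`` column of Hill-notation strings.

    Returns
    -------
    DataFrame indexed by formula_id with columns c,h,n,o,s,p, neutral_mass,
    hc, oc, ai_mod, compound_class, bioavailable.
    """
    rows = {}
    for fid, row in formulas.iterrows():
        if "formula" in formulas.columns and "c" not in formulas.columns:
            ef = parse_formula(str(row["formula"]))
        else:
            ef = ElementalFormula(
                *(int(row.get(k, 0)) for k in ("c", "h", "n", "o", "s", "p"))
            )
        ann = annotate(ef, hc_cutoff=hc_cutoff, class_table=class_table)
        rows[fid] = {
            "c": ef.c,
            "h": ef.h,
            "n": ef.n,
            "o": ef.o,
            "s": ef.s,
            "p": ef.p,
            "neutral_mass": ann.neutral_mass,
            "hc": ann.hc,
            "oc": ann.oc,
            "ai_mod": ann.ai_mod,
            "compound_class": ann.compound_class,
            "bioavailable": ann.bioavailable,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "formula_id"
    return out


# ---------------------------------------------------------------------------
# Intensity-matrix operations
# ---------------------------------------------------------------------------


def normalize_tic(m: IntensityMatrix) -> IntensityMatrix:
    """Normalize each sample column by its total intensity (closure to 1)."""
    vals = m.values.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = list(m.samples.index[zero])
        raise DegenerateSampleError(f"all-zero sample column(s): {bad}")
    out = m.values.divide(totals, axis=1)
    return IntensityMatrix(values=out, samples=m.samples.copy(), normalized=True)


def replicate_presence_filter(
    m: IntensityMatrix, min_reps: int = 2
) -> IntensityMatrix:
    """Keep a formula in a (source, day) group only if present in >= min_reps replicates.

    Presence means intensity > 0.  Intensities of formulae failing the rule
    are zeroed within that group; the matrix is then re-normalized.  Groups
    with fewer than ``min_reps`` replicates (e.g. single control bottles) are
    passed through unfiltered with a warning.
    """
    vals = m.values.copy()
    arr = vals.to_numpy(dtype=float)
    meta = m.samples
    small_groups = []
    for (source, day, is_ctl), idx in meta.groupby(
        ["source", "day", "is_control"], sort=False
    ).groups.items():
        cols = [meta.index.get_loc(i) for i in idx]
        if len(cols) < min_reps:
            small_groups.append((source, day, "control" if is_ctl else "sample"))
            continue
        present = (arr[:, cols] > 0).sum(axis=1)
        drop = present < min_reps
        arr[np.ix_(drop, cols)] = 0.0
    if small_groups:
        warnings.warn(
            f"replicate groups smaller than min_reps={min_reps} passed through "
            f"unfiltered: {small_groups}",
            stacklevel=2,
        )
    filtered = IntensityMatrix(
        values=pd.DataFrame(arr, index=vals.index, columns=vals.columns),
        samples=meta.copy(),
        normalized=False,
    )
    return normalize_tic(filtered)


def bulk_metrics(m: IntensityMatrix, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample intensity-weighted bulk DOM descriptors.

    Weighted means of H/C, O/C, AI_mod and neutral mass; the summed relative
    intensity of bioavailable formulae; and per-compound-class summed
    relative intensities (columns ``class_fraction:<name>``).

    Requires a normalized matrix and an annotation row for every formula.
    """
    if not m.normalized:
        raise ValueError("bulk_metrics requires a TIC-normalized matrix")
    missing = m.feature_ids.difference(annotations.index)
    if len(missing):
        raise KeyError(f"annotations missing for formula ids: {list(missing)[:10]}")
    ann = annotations.loc[m.feature_ids]
    w = m.values.to_numpy(dtype=float)  # formulae x samples, columns sum to 1
    cols = {}
    for name, key in (
        ("weighted_hc", "hc"),
        ("weighted_oc", "oc"),
        ("weighted_aimod", "ai_mod"),
        ("weighted_mass", "neutral_mass"),
    ):
        cols[name] = ann[key].to_numpy(dtype=float) @ w
    cols["bioavailable_fraction"] = (
        ann["bioavailable"].to_numpy(dtype=float) @ w
    )
    for cls in COMPOUND_CLASSES:
        mask = (ann["compound_class"] == cls).to_numpy(dtype=float)
        cols[f"class_fraction:{cls}"] = mask @ w
    out = pd.DataFrame(cols, index=m.samples.index)
    return pd.concat([m.samples, out], axis=1)
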