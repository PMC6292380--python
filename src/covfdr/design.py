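"""Design-matrix construction for the pi0 regression.

Supports the covariate transforms used in genome-wide analyses: linear
terms, natural (restricted) cubic spline bases — linear beyond boundary
knots placed at the covariate extremes, interior knots at equispaced
quantiles — quantile-cut categories (e.g. minor-allele-frequency terciles),
and spline-by-category interactions so a smooth trend in one covariate can
have separate coefficients within categories of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pi0 import DesignMatrix, _numerical_rank

__all__ = [
    "DesignSpec",
    "Term",
    "natural_cubic_spline_basis",
    "cut_terciles",
    "cut_quantile_categories",
    "build_design",
]


@dataclass(frozen=True)
class Term:
    """One design term: a covariate column and how it enters the model.

    transform is one of 'linear', 'natural_spline' (with df),
    'tercile_categories', or 'categories' (observed levels of a categorical
    column).
    """

    column: str
    transform: str = "linear"
    df: int = 3

    _TRANSFORMS = ("linear", "natural_spline", "tercile_categories", "categories")

    def __post_init__(self) -> None:
        if self.transform not in self._TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.df < 1:
            raise ValueError("spline df must be at least 1")


@dataclass(frozen=True)
class DesignSpec:
    """Ordered terms plus optional (spline term, category term) interactions,
    given as pairs of term indices."""

    terms: tuple[Term, ...] = ()
    interactions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "interactions", tuple(tuple(x) for x in self.interactions))
        for i, j in self.interactions:
            if not (0 <= i < len(self.terms) and 0 <= j < len(self.terms)):
                raise ValueError("interaction indices must reference existing terms")

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"column": t.column, "transform": t.transform, "df": t.df}
                for t in self.terms
            ],
            "interactions": [list(x) for x in self.interactions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        terms = tuple(Term(**t) for t in d.get("terms", ()))
        inter = tuple(tuple(x) for x in d.get("interactions", ()))
        return cls(terms=terms, interactions=inter)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DesignSpec":
        return cls.from_dict(json.loads(s))


def natural_cubic_spline_basis(x, df: int) -> np.ndarray:
    """Natural cubic spline basis (df columns, intercept excluded).

    Boundary knots sit at min(x) and max(x); the df - 1 interior knots at
    equispaced quantiles of x.  The basis is cubic between knots and linear
    beyond the boundary knots (zero second and third derivatives outside).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a vector")
    if df < 1:
        raise ValueError("df must be at least 1")
    if np.unique(x).size < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct values for a df={df} natural spline"
        )
    if df == 1:
        return x[:, None].copy()

    probs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(x, probs)
    if np.unique(knots).size != knots.size:
        raise ValueError("degenerate knots: covariate too discrete for requested df")
    return _ns_basis(x, knots)


def _ns_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    # restricted-cubic (truncated power) construction: with K knots the
    # natural-spline space has dimension K; dropping the constant leaves
    # x plus K-2 curvature columns.
    K = knots.size
    t_K, t_Km1 = knots[-1], knots[-2]

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - t_K, 0.0) ** 3
        return num / (t_K - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def cut_quantile_categories(x, n_categories: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Cut a numeric vector into quantile categories.

    Returns integer codes 0..n-1 and the interior cutpoints.  A value equal
    to a cutpoint is assigned to the LOWER category (deterministic tie rule).
    """
    x = np.asarray(x, dtype=float)
    if x.size < n_categories:
        raise ValueError("fewer observations than categories")
    if np.unique(x).size < n_categories:
        raise ValueError("fewer distinct values than categories")
    probs = np.arange(1, n_categories) / n_categories
    cuts = np.quantile(x, probs)
    if np.unique(cuts).size != cuts.size:
        raise ValueError("degenerate categories: tied quantile cutpoints")
    codes = np.sum(x[:, None] > cuts[None, :], axis=1)
    return codes.astype(int), cuts


def cut_terciles(x) -> tuple[np.ndarray, np.ndarray]:
    """Three categories delimited by the empirical 1/3 and 2/3 quantiles."""
    return cut_quantile_categories(x, 3)


def _dummy_block(codes: np.ndarray, name: str) -> tuple[np.ndarray, list[str]]:
    """Reference-coded indicator columns (level 0 is the reference)."""
    levels = np.unique(codes)
    cols = [(codes == lev).astype(float) for lev in levels[1:]]
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    if not cols:
        return np.empty((codes.size, 0)), []
    return np.column_stack(cols), names


def _term_block(cov: pd.DataFrame, t: Term) -> tuple[np.ndarray, list[str]]:
    if t.column not in cov.columns:
        raise KeyError(f"covariate column {t.column!r} not found")
    col = cov[t.column]
    if t.transform == "linear":
        x = np.asarray(col, dtype=float)
        return x[:, None], [t.column]
    if t.transform == "natural_spline":
        B = natural_cubic_spline_basis(np.asarray(col, dtype=float), t.df)
        return B, [f"ns({t.column},{t.df})[{j}]" for j in range(B.shape[1])]
    if t.transform == "tercile_categories":
        codes, _ = cut_terciles(np.asarray(col, dtype=float))
        return _dummy_block(codes, f"tercile({t.column})")
    # categories: use the observed levels of the column
    codes, _ = pd.factorize(np.asarray(col), sort=True)
    return _dummy_block(codes, t.column)


def _category_indicators(cov: pd.DataFrame, t: Term) -> np.ndarray:
    """All-level (one-hot) indicators for a category-type term."""
    if t.transform == "tercile_categories":
        codes, _ = cut_terciles(np.asarray(cov[t.column], dtype=float))
    elif t.transform == "categories":
        codes, _ = pd.factorize(np.asarray(cov[t.column]), sort=True)
    else:
        raise ValueError(f"term {t.column!r} is not categorical")
    levels = np.unique(codes)
    return np.column_stack([(codes == lev).astype(float) for lev in levels])


def build_design(cov: pd.DataFrame, spec: DesignSpec) -> DesignMatrix:
    """Assemble the m x p design: intercept, term blocks, interaction blocks.

    Spline-by-category interactions multiply the spline columns by the
    NON-reference category indicators; together with the main effects this
    gives each category its own spline coefficients.
    """
    if not isinstance(cov, pd.DataFrame):
        cov = pd.DataFrame(cov)
    m = len(cov)
    if m < 2:
        raise ValueError("need at least two rows of covariates")

    blocks: list[np.ndarray] = [np.ones((m, 1))]
    names: list[str] = ["intercept"]
    term_blocks: dict[int, tuple[np.ndarray, list[str]]] = {}
    for i, t in enumerate(spec.terms):
        B, labels = _term_block(cov, t)
        term_blocks[i] = (B, labels)
        blocks.append(B)
        names.extend(labels)

    for i, j in spec.interactions:
        spline_t, cat_t = spec.terms[i], spec.terms[j]
        if cat_t.transform not in ("tercile_categories", "categories"):
            spline_t, cat_t = cat_t, spline_t
        if cat_t.transform not in ("tercile_categories", "categories"):
            raise ValueError("interactions must pair a smooth term with a category term")
        SB, slabels = _term_block(cov, spline_t)
        ind = _category_indicators(cov, cat_t)
        for lev in range(1, ind.shape[1]):
            blocks.append(SB * ind[:, lev : lev + 1])
            names.extend(f"{lab}:{cat_t.column}[{lev}]" for lab in slabels)

    Z = np.column_stack(blocks)
    dm = DesignMatrix(Z, tuple(names))
    rank = _numerical_rank(Z)
    if rank < Z.shape[1]:
        import logging

        logging.getLogger(__name__).warning(
            "design matrix is rank deficient: rank %d < %d columns (%s)",
            rank,
            Z.shape[1],
            ", ".join(names),
        )
    return dm
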