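"""Heuristic stepwise multilinear regression (the "HM" of descriptor-selection QSAR).

A beam-width-B forward selection over descriptor subsets: size-1 models are
ranked by R² (after an F ≥ 1 pre-filter); each larger size extends the beam's
models with descriptors whose pairwise Pearson |r| with every included
descriptor stays below a collinearity cap (0.8 by default).  Every candidate
is an ordinary least-squares fit reported with R², overall F, per-coefficient
t statistics, residual variance s², and exact leave-one-out R²cv.

The model size is chosen where the R²cv gain between consecutive sizes first
drops below a configurable delta — the automated analogue of reading the
statistic-vs-size curves by eye.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from nmqsar.descriptors import DescriptorMatrix


@dataclass(frozen=True)
class LinearModel:
    """An OLS fit with the selection statistics attached."""

    descriptor_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    r2: float
    r2_cv: float
    s2: float
    f_stat: float
    t_stats: np.ndarray  # per-coefficient (excludes intercept)

    def __post_init__(self):
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("coefficient count must equal descriptor-name count")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.descriptor_names),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "t_stats": self.t_stats.tolist(),
            "r2": self.r2,
            "r2_cv": self.r2_cv,
            "s2": self.s2,
            "f_stat": self.f_stat,
        }


@dataclass
class SelectionTrace:
    """Best models per size plus the evidence used to choose among them."""

    best_per_size: dict[int, list[LinearModel]]
    chosen_size: int
    correlation_matrix: np.ndarray
    descriptor_names: tuple[str, ...]
    truncated_at: Optional[int] = None

    @property
    def chosen_model(self) -> LinearModel:
        return self.best_per_size[self.chosen_size][0]

    def size_table(self) -> list[dict]:
        """Per-size best statistics (the R²/R²cv/s²-vs-size curves)."""
        return [
            {
                "size": k,
                "r2": models[0].r2,
                "r2_cv": models[0].r2_cv,
                "s2": models[0].s2,
                "descriptors": list(models[0].descriptor_names),
            }
            for k, models in sorted(self.best_per_size.items())
        ]


def fit_ols(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None
) -> LinearModel:
    """OLS with R², F, per-coefficient t, and exact leave-one-out R²cv.

    R²cv uses the hat-matrix identity for LOO residuals,
    e_i / (1 − h_ii), which is algebraically identical to n refits.
    Raises on rank deficiency, identifying a dependent column.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("X row count must equal len(y)")
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} rows, got {n}")
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))

    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        # identify a column linearly dependent on its predecessors
        for j in range(1, p + 1):
            if np.linalg.matrix_rank(A[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"rank-deficient design: column {names[j - 1]!r} is linearly "
                    "dependent on the preceding columns"
                )
        raise ValueError("rank-deficient design")

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = n - p - 1
    XtX_inv = np.linalg.inv(A.T @ A)

    r2 = 1.0 - rss / ss_tot
    if dof > 0:
        s2 = rss / dof
        f_stat = (r2 / p) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = np.where(se > 0, beta / se, np.copysign(np.inf, beta))
        # exact LOO residuals via leverages
        h = np.einsum("ij,jk,ik->i", A, XtX_inv, A)
        loo_resid = resid / (1.0 - h)
        press = float(loo_resid @ loo_resid)
        r2_cv = 1.0 - press / ss_tot
    else:
        # saturated fit: residual statistics are undefined
        s2 = f_stat = r2_cv = np.nan
        t_all = np.full(p + 1, np.nan)

    return LinearModel(
        descriptor_names=names,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        r2=r2,
        r2_cv=r2_cv,
        s2=s2,
        f_stat=float(f_stat),
        t_stats=t_all[1:].copy(),
    )


def correlation_matrix(
    X: np.ndarray, names: Sequence[str] | None = None
) -> np.ndarray:
    """Pearson correlation matrix of descriptor columns (unit diagonal)."""
    X = np.atleast_2d(np.asarray(X, float))
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant column {names[j]!r}: correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def heuristic_search(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    max_size: int = 7,
    collinearity_max: float = 0.8,
    beam: int = 10,
    size_choice_delta: float = 0.02,
    chosen_size: int | None = None,
    f_prefilter: float = 1.0,
) -> SelectionTrace:
    """Beam forward selection of descriptor subsets of size 1…max_size.

    Candidate subsets must be pairwise-admissible (|r| < ``collinearity_max``
    between every pair of included descriptors).  Descriptors whose
    single-descriptor F falls below ``f_prefilter`` never enter the search.
    Ties in R² break toward the larger minimum |t|, then by name order.
    ``chosen_size`` overrides the automatic R²cv-gain rule.
    """
    X = matrix.values
    y = np.asarray(y, float)
    n, p = X.shape
    if n < max_size + 2:
        raise ValueError(f"need at least max_size+2={max_size + 2} compounds, got {n}")

    corr = correlation_matrix(X, matrix.names)

    def admissible(subset: tuple[int, ...], j: int) -> bool:
        return all(abs(corr[i, j]) < collinearity_max for i in subset)

    def fit_subset(subset: tuple[int, ...]) -> LinearModel:
        return fit_ols(X[:, subset], y, [matrix.names[i] for i in subset])

    def sort_key(item: tuple[tuple[int, ...], LinearModel]):
        subset, m = item
        return (-m.r2, -float(np.min(np.abs(m.t_stats))), tuple(m.descriptor_names))

    # size 1 with the F pre-filter
    singles = []
    for j in range(p):
        m = fit_subset((j,))
        if m.f_stat >= f_prefilter:
            singles.append(((j,), m))
    if not singles:
        raise ValueError("no descriptor passes the single-descriptor F pre-filter")
    singles.sort(key=sort_key)

    best_per_size: dict[int, list[LinearModel]] = {1: [m for _, m in singles[:beam]]}
    frontier = singles[:beam]
    truncated_at = None

    for size in range(2, max_size + 1):
        if n <= size + 1:
            truncated_at = size
            break
        seen: set[tuple[int, ...]] = set()
        candidates = []
        for subset, _ in frontier:
            for j in range(p):
                if j in subset or not admissible(subset, j):
                    continue
                new = tuple(sorted(subset + (j,)))
                if new in seen:
                    continue
                seen.add(new)
                candidates.append((new, fit_subset(new)))
        if not candidates:
            truncated_at = size
            break
        candidates.sort(key=sort_key)
        frontier = candidates[:beam]
        best_per_size[size] = [m for _, m in frontier]

    if chosen_size is None:
        sizes = sorted(best_per_size)
        chosen = sizes[-1]
        for prev, cur in zip(sizes, sizes[1:]):
            gain = best_per_size[cur][0].r2_cv - best_per_size[prev][0].r2_cv
            if gain < size_choice_delta:
                chosen = prev
                break
    else:
        if chosen_size not in best_per_size:
            raise ValueError(f"no model of size {chosen_size} in the trace")
        chosen = chosen_size

    return SelectionTrace(
        best_per_size=best_per_size,
        chosen_size=chosen,
        correlation_matrix=corr,
        descriptor_names=matrix.names,
        truncated_at=truncated_at,
    )


def exhaustive_best_subset(
    matrix: DescriptorMatrix, y: np.ndarray, size: int
) -> LinearModel:
    """Brute-force best subset of a given size by R² (test oracle)."""
    best = None
    for subset in itertools.combinations(range(matrix.shape[1]), size):
        m = fit_ols(matrix.values[:, subset], y, [matrix.names[i] for i in subset])
        key = (-m.r2, tuple(m.descriptor_names))
        if best is None or key < best[0]:
            best = (key, m)
    return best[1]
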