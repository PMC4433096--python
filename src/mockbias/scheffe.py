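"""Scheffé mixture-effect models.

Because mixture proportions are constrained to the simplex (sum to one), the
usual intercept-plus-main-effects polynomial is not identifiable; the Scheffé
parameterization drops the intercept and uses

    E(y) = sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_{i<j<k} b_ijk x_i x_j x_k

(the "special cubic" form when all three groups of terms are present).  Each
b_i is the expected response at the pure blend x_i = 1; the b_ij and b_ijk
are binary and ternary blending coefficients measuring departure from linear
blending — positive means synergistic (the co-occurring component inflates
the response), negative antagonistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError, SchemaError

ORDERS = ("linear", "quadratic", "special_cubic")

SIMPLEX_TOL = 1e-6


def scheffe_terms(p: int, order: str = "special_cubic") -> list[tuple[int, ...]]:
    """Index tuples of the Scheffé model terms for ``p`` components.

    Terms are ordered as all singletons, then all unordered pairs, then all
    unordered triples (each group in lexicographic order).
    """
    if order not in ORDERS:
        raise ValueError(f"unknown model order {order!r}")
    terms: list[tuple[int, ...]] = [(i,) for i in range(p)]
    if order in ("quadratic", "special_cubic"):
        terms += list(itertools.combinations(range(p), 2))
    if order == "special_cubic":
        terms += list(itertools.combinations(range(p), 3))
    return terms


def term_name(term: tuple[int, ...], names: list[str]) -> str:
    return ":".join(names[i] for i in term)


def build_design_matrix(
    points: np.ndarray | pd.DataFrame,
    order: str = "special_cubic",
    validate: bool = True,
) -> np.ndarray:
    """Model matrix of Scheffé terms evaluated at simplex points.

    Columns are x_i, then x_i x_j (i<j), then x_i x_j x_k (i<j<k); there is
    no intercept column.

    Raises
    ------
    SchemaError
        If ``validate`` and any row does not sum to one within tolerance.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if validate:
        sums = x.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > SIMPLEX_TOL)
        if bad.size:
            raise SchemaError(
                f"rows {bad[:5].tolist()} do not lie on the simplex "
                f"(sums {sums[bad[:5]].tolist()})"
            )
    terms = scheffe_terms(x.shape[1], order)
    cols = [np.prod(x[:, list(t)], axis=1) for t in terms]
    return np.column_stack(cols)


@dataclass
class ScheffeModel:
    """A fitted Scheffé mixture-effect model for one response.

    ``p_adjusted`` carries the Bonferroni-adjusted p-values for blending
    terms (multiplied by the number of blending terms, capped at 1); linear
    terms are not screened and keep their raw p-value.
    """

    taxon: str
    p_components: int
    order: str
    terms: list[tuple[int, ...]]
    term_names: list[str]
    coefs: np.ndarray
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    r_squared: float
    r_squared_uncentered: float
    n_obs: int
    component_names: list[str] = field(default_factory=list)

    def coef(self, term: tuple[int, ...]) -> float:
        return float(self.coefs[self.terms.index(tuple(sorted(term)))])

    def predict(self, points: np.ndarray | pd.DataFrame, validate: bool = True) -> np.ndarray:
        X = build_design_matrix(points, self.order, validate=validate)
        return X @ self.coefs

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "order": [len(t) for t in self.terms],
                "coef": self.coefs,
                "std_error": self.std_errors,
                "t": self.t_stats,
                "p": self.p_values,
                "p_bonferroni": self.p_adjusted,
            }
        )

    def to_dict(self) -> dict:
        d = {
            "taxon": self.taxon,
            "order": self.order,
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
            "r_squared_uncentered": self.r_squared_uncentered,
            "component_names": self.component_names,
            "terms": self.summary_frame().to_dict(orient="records"),
        }
        return d


def _blending_mask(terms: list[tuple[int, ...]]) -> np.ndarray:
    return np.array([len(t) > 1 for t in terms])


def fit_scheffe(
    X: np.ndarray,
    y: np.ndarray | pd.Series,
    terms: list[tuple[int, ...]] | None = None,
    taxon: str = "",
    component_names: list[str] | None = None,
    order: str = "special_cubic",
) -> ScheffeModel:
    """Ordinary least squares fit of a Scheffé model (no intercept).

    ``X`` is a model matrix from :func:`build_design_matrix`.  R² is reported
    about the response mean (1 - SSE/SST centered), with the uncentered
    variant carried alongside as a diagnostic.

    Raises
    ------
    ModelError
        If there are fewer rows than columns or the matrix is rank deficient
        (the error names the collinear columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if terms is None:
        # infer p from column count of a pure-order matrix
        terms = _infer_terms(k, order)
    names = component_names or [f"x{i + 1}" for i in range(max(max(t) for t in terms) + 1)]
    if n < k:
        raise ModelError(f"need at least {k} observations for {k} coefficients, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        dep = _dependent_columns(X)
        dep_names = [term_name(terms[j], names) for j in dep]
        raise ModelError(f"model matrix is rank deficient; collinear columns: {dep_names}")

    res = sm.OLS(y, X).fit()
    coefs = np.asarray(res.params, dtype=float)
    resid = y - X @ coefs
    sse = float(resid @ resid)
    sst_c = float(np.sum((y - y.mean()) ** 2))
    sst_u = float(y @ y)
    r2_c = 1.0 - sse / sst_c if sst_c > 0 else 1.0
    r2_u = 1.0 - sse / sst_u if sst_u > 0 else 1.0

    pvals = np.asarray(res.pvalues, dtype=float)
    mask = _blending_mask(terms)
    m = int(mask.sum())
    adj = pvals.copy()
    if m:
        adj[mask] = np.minimum(1.0, pvals[mask] * m)
    return ScheffeModel(
        taxon=taxon,
        p_components=len(names),
        order=order,
        terms=[tuple(t) for t in terms],
        term_names=[term_name(t, names) for t in terms],
        coefs=coefs,
        std_errors=np.asarray(res.bse, dtype=float),
        t_stats=np.asarray(res.tvalues, dtype=float),
        p_values=pvals,
        p_adjusted=adj,
        r_squared=max(min(r2_c, 1.0), 0.0),
        r_squared_uncentered=max(min(r2_u, 1.0), 0.0),
        n_obs=n,
        component_names=names,
    )


def _infer_terms(k: int, order: str) -> list[tuple[int, ...]]:
    from math import comb

    for p in range(1, 200):
        size = {
            "linear": p,
            "quadratic": p + comb(p, 2),
            "special_cubic": p + comb(p, 2) + comb(p, 3),
        }[order]
        if size == k:
            return scheffe_terms(p, order)
        if size > k:
            break
    raise ModelError(f"cannot infer component count from {k} columns for order {order!r}")


def _dependent_columns(X: np.ndarray) -> list[int]:
    """Indices of columns that are linear combinations of earlier ones."""
    dep = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(trial) > rank:
            kept = trial
            rank += 1
        else:
            dep.append(j)
    return dep


def fit_taxon_models(
    prescribed: pd.DataFrame,
    observed: pd.DataFrame,
    order: str = "special_cubic",
) -> dict[str, ScheffeModel]:
    """Fit one model per taxon: observed proportion on prescribed proportions.

    Rows are aligned on the shared index (run/sample id).
    """
    common = prescribed.index.intersection(observed.index)
    if len(common) == 0:
        raise ModelError("no shared samples between prescribed and observed tables")
    Xpts = prescribed.loc[common]
    X = build_design_matrix(Xpts.to_numpy(), order)
    terms = scheffe_terms(Xpts.shape[1], order)
    names = list(Xpts.columns)
    models = {}
    for taxon in observed.columns:
        models[taxon] = fit_scheffe(
            X,
            observed.loc[common, taxon].to_numpy(),
            terms=terms,
            taxon=taxon,
            component_names=names,
            order=order,
        )
    return models


def screen_blends(model: ScheffeModel, alpha: float = 0.05) -> pd.DataFrame:
    """Significant blending terms after Bonferroni adjustment.

    The adjustment multiplies each blending-term p-value by the number of
    blending terms in the model (linear terms are not part of the family).
    Returned terms have adjusted p < ``alpha`` and carry a direction label:
    synergistic for a positive coefficient, antagonistic for negative,
    ordered by decreasing significance.
    """
    frame = model.summary_frame()
    blends = frame[frame["order"] > 1].copy()
    sig = blends[blends["p_bonferroni"].notna() & (blends["p_bonferroni"] < alpha)].copy()
    sig["direction"] = np.where(sig["coef"] > 0, "synergistic", "antagonistic")
    sig = sig.sort_values(["p_bonferroni", "p"], kind="mergesort").reset_index(drop=True)
    return sig


def _simplex_lattice(n_parts: int, resolution: int) -> np.ndarray:
    """All compositions of ``resolution`` units into ``n_parts`` parts, as fractions."""
    if n_parts == 0:
        return np.zeros((1, 0))
    if n_parts == 1:
        return np.ones((1, 1))
    pts = []
    for combo in itertools.combinations(range(resolution + n_parts - 1), n_parts - 1):
        bars = (-1,) + combo + (resolution + n_parts - 1,)
        counts = [bars[i + 1] - bars[i] - 1 for i in range(n_parts)]
        pts.append(counts)
    return np.asarray(pts, dtype=float) / resolution


def blending_surface(
    model: ScheffeModel,
    i: int | str,
    j: int | str,
    grid_resolution: int = 21,
    lattice_step: float = 0.05,
) -> pd.DataFrame:
    """Expected-response contour grid over proportions of components i and j.

    At a grid point (x_i, x_j) with x_i + x_j <= 1 the remaining mass
    1 - x_i - x_j is spread over the other components; the surface value is
    the model prediction averaged uniformly over a simplex lattice (step
    ``lattice_step``) of those remaining components.  Along the hypotenuse
    x_i + x_j = 1 the value is exactly b_i x_i + b_j x_j + b_ij x_i x_j.

    Returns a long-format frame with columns ``xi``, ``xj``, ``value``.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    names = model.component_names
    ii = names.index(i) if isinstance(i, str) else int(i)
    jj = names.index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValueError("components i and j must differ")
    p = model.p_components
    others = [c for c in range(p) if c not in (ii, jj)]
    resolution = max(1, round(1.0 / lattice_step))
    lattice = _simplex_lattice(len(others), resolution)

    axis = np.linspace(0.0, 1.0, grid_resolution)
    rows = []
    for xi in axis:
        for xj in axis:
            rem = 1.0 - xi - xj
            if rem < -1e-12:
                continue
            rem = max(rem, 0.0)
            if others and rem > 0:
                pts = np.zeros((lattice.shape[0], p))
                pts[:, ii] = xi
                pts[:, jj] = xj
                pts[:, others] = lattice * rem
            else:
                pts = np.zeros((1, p))
                pts[:, ii] = xi
                pts[:, jj] = xj
                if others and rem > 0:  # pragma: no cover
                    pts[:, others] = rem / len(others)
            if abs(xi + xj + (rem if others else 0) - 1) > SIMPLEX_TOL and not others:
                continue
            vals = model.predict(pts, validate=False)
            rows.append((xi, xj, float(vals.mean())))
    return pd.DataFrame(rows, columns=["xi", "xj", "value"])
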