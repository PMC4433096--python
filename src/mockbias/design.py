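"""D-optimal mixture designs for Scheffé special cubic models.

A special cubic model in p components has p + C(p,2) + C(p,3) coefficients,
so a design must contain at least that many runs (63 for p = 7, 298 for
p = 12).  The classic support is the simplex-centroid subset of pure blends,
binary midpoints and ternary centroids; from a candidate set of such points
a D-optimal subset is chosen by Fedorov point exchange, maximizing the
determinant of the information matrix X'X of the special cubic model matrix.
The assembled design adds interior lack-of-fit points and exact replicate
runs (for a pure-error variance estimate), with run order randomized.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, MatchingError, SchemaError
from .scheffe import build_design_matrix

ROLES = ("support", "lack_of_fit", "replicate")

SIMPLEX_TOL = 1e-12


def special_cubic_size(p: int) -> int:
    """Number of coefficients (= minimum runs) of a special cubic model.

    Returns p + C(p,2) + C(p,3); for p < 3 the missing binomial terms are
    zero, so e.g. p = 1 gives 1.
    """
    if p < 1:
        raise DesignError(f"component count must be >= 1, got {p}")
    return p + comb(p, 2) + comb(p, 3)


def candidate_set(p: int, include_interior: bool = False) -> np.ndarray:
    """Candidate simplex points supporting a special cubic fit.

    The p pure blends, all C(p,2) binary midpoints, and all C(p,3) ternary
    centroids — exactly ``special_cubic_size(p)`` points.  With
    ``include_interior`` the p axial points (x_i = (p+1)/(2p), the rest
    1/(2p)) are appended, useful for enlarged candidate pools and
    lack-of-fit support.
    """
    if p < 2:
        raise DesignError(f"candidate set needs at least 2 components, got {p}")
    pts = list(np.eye(p))
    for i, j in combinations(range(p), 2):
        v = np.zeros(p)
        v[[i, j]] = 0.5
        pts.append(v)
    for i, j, k in combinations(range(p), 3):
        v = np.zeros(p)
        v[[i, j, k]] = 1.0 / 3.0
        pts.append(v)
    if include_interior:
        for i in range(p):
            v = np.full(p, 1.0 / (2.0 * p))
            v[i] = (p + 1.0) / (2.0 * p)
            pts.append(v)
    return np.asarray(pts)


def information_logdet(points: np.ndarray) -> float:
    """log det of X'X for the special cubic model matrix at ``points``."""
    X = build_design_matrix(points, "special_cubic", validate=False)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -np.inf


def select_d_optimal(
    candidates: np.ndarray,
    n_support: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Choose ``n_support`` candidate points by Fedorov point exchange.

    Starting from a random subset, repeatedly performs the single exchange
    (design point out, candidate in) that most increases det(X'X), until no
    exchange improves; the best of ``n_restarts`` seeded restarts is
    returned.  Ties in the exchange delta are broken by candidate index.
    Deterministic for a fixed seed.  When ``n_support`` equals the candidate
    count the full set is returned.

    Raises
    ------
    DesignError
        If ``n_support`` is below the special cubic parameter count (the
        model would be rank deficient).
    """
    candidates = np.asarray(candidates, dtype=float)
    n_cand, p = candidates.shape
    k = special_cubic_size(p)
    if n_support < k:
        raise DesignError(
            f"infeasible design: {n_support} runs cannot support the "
            f"{k}-parameter special cubic model in {p} components"
        )
    if n_support > n_cand:
        raise DesignError(f"requested {n_support} support points from {n_cand} candidates")
    if n_support == n_cand:
        return candidates.copy()

    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_logdet = -np.inf
    for _ in range(n_restarts):
        idx = np.sort(rng.choice(n_cand, size=n_support, replace=False))
        cur = information_logdet(candidates[idx])
        for _ in range(max_sweeps):
            improved = False
            pool = [c for c in range(n_cand) if c not in set(idx)]
            best_delta, best_pair = 0.0, None
            for pos in range(n_support):
                for c in pool:
                    trial = idx.copy()
                    trial[pos] = c
                    val = information_logdet(candidates[trial])
                    delta = val - cur
                    if delta > best_delta + 1e-12:
                        best_delta, best_pair = delta, (pos, c)
            if best_pair is not None:
                idx = idx.copy()
                idx[best_pair[0]] = best_pair[1]
                idx = np.sort(idx)
                cur = information_logdet(candidates[idx])
                improved = True
            if not improved:
                break
        if cur > best_logdet:
            best_logdet, best_idx = cur, idx
    if best_idx is None or not np.isfinite(best_logdet):
        raise DesignError("point exchange failed to find a non-singular design")
    return candidates[best_idx]


@dataclass
class MixtureDesign:
    """A runs × taxa table of prescribed proportions with run annotations.

    ``proportions`` is indexed by integer ``run_id``; ``role`` is one of
    support / lack_of_fit / replicate per run; ``replicate_of`` holds the
    run_id a replicate copies (NA otherwise).
    """

    proportions: pd.DataFrame
    role: pd.Series
    replicate_of: pd.Series

    def __post_init__(self) -> None:
        self.proportions.index.name = "run_id"
        self.replicate_of = self.replicate_of.astype("Int64")
        self.role.index.name = "run_id"
        self.replicate_of.index.name = "run_id"
        self.role.name = "role"
        self.replicate_of.name = "replicate_of"

    # -- basic accessors -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.proportions.columns)

    @property
    def n_runs(self) -> int:
        return len(self.proportions)

    @property
    def n_components(self) -> int:
        return self.proportions.shape[1]

    def treatment_ids(self) -> pd.Series:
        """Map each run to the run_id of its unique treatment combination."""
        base = pd.Series(self.proportions.index, index=self.proportions.index)
        filled = self.replicate_of.where(self.replicate_of.notna(), base)
        return filled.astype(int)

    @property
    def n_unique_treatments(self) -> int:
        return self.treatment_ids().nunique()

    def validate(self) -> None:
        vals = self.proportions.to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise DesignError("proportions must lie in [0, 1]")
        if np.any(np.abs(vals.sum(axis=1) - 1.0) > SIMPLEX_TOL):
            raise DesignError("every run's proportions must sum to 1 within 1e-12")
        bad = set(self.role) - set(ROLES)
        if bad:
            raise DesignError(f"unknown roles: {sorted(bad)}")
        for rid, ref in self.replicate_of.dropna().items():
            if int(ref) not in self.proportions.index:
                raise DesignError(f"replicate {rid} references missing run {ref}")
            if not np.array_equal(
                self.proportions.loc[rid].to_numpy(),
                self.proportions.loc[int(ref)].to_numpy(),
            ):
                raise DesignError(f"replicate {rid} differs from its source run {ref}")

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(",".join(frame.columns) + "\n")
            for _, row in frame.iterrows():
                cells = [str(row["run_id"]), str(row["role"]), str(row["replicate_of"])]
                cells += [f"{v:.17g}" for v in row[self.taxa]]
                fh.write(",".join(cells) + "\n")

    def to_frame(self) -> pd.DataFrame:
        frame = self.proportions.reset_index()
        frame.insert(1, "role", self.role.to_numpy())
        rep = self.replicate_of.astype(object).where(self.replicate_of.notna(), "")
        frame.insert(2, "replicate_of", rep.to_numpy())
        return frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "MixtureDesign":
        frame = pd.read_csv(path, dtype={"replicate_of": "Int64"}, float_precision="round_trip")
        for col in ("run_id", "role", "replicate_of"):
            if col not in frame.columns:
                raise SchemaError(f"{path}: design file missing column {col!r}")
        taxa = [c for c in frame.columns if c not in ("run_id", "role", "replicate_of")]
        if not taxa:
            raise SchemaError(f"{path}: design file has no taxon columns")
        props = frame.set_index("run_id")[taxa].astype(float)
        design = cls(
            proportions=props,
            role=frame.set_index("run_id")["role"],
            replicate_of=frame.set_index("run_id")["replicate_of"],
        )
        design.validate()
        return design


def _interior_lack_of_fit_points(
    p: int, n_points: int, existing: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Interior lattice points not already in the design.

    The first point is the overall centroid (all components at 1/p); further
    points are equal blends of a random subset of min(4, p) components,
    drawn until distinct from all existing rows.
    """
    pts: list[np.ndarray] = []
    have = {tuple(np.round(r, 12)) for r in existing}

    def try_add(v: np.ndarray) -> None:
        key = tuple(np.round(v, 12))
        if key not in have:
            have.add(key)
            pts.append(v)

    try_add(np.full(p, 1.0 / p))
    kk = min(4, p)
    attempts = 0
    while len(pts) < n_points:
        attempts += 1
        if attempts > 1000:
            raise DesignError("could not find enough unique lack-of-fit points")
        sub = rng.choice(p, size=kk, replace=False)
        v = np.zeros(p)
        v[sub] = 1.0 / kk
        try_add(v)
    return np.asarray(pts[:n_points])


def assemble_runs(
    support: np.ndarray,
    n_lack_of_fit: int,
    n_replicates: int,
    seed: int = 0,
    taxa: list[str] | None = None,
) -> MixtureDesign:
    """Assemble the full randomized design from its D-optimal support.

    Appends ``n_lack_of_fit`` additional unique interior treatment
    combinations and ``n_replicates`` exact copies of unique runs sampled
    uniformly without replacement, then randomizes run order (run_ids are
    assigned 1..n in randomized order).  The unique-treatment count is
    ``len(support) + n_lack_of_fit``.

    Raises
    ------
    DesignError
        On duplicate support rows or more replicates than unique runs.
    """
    support = np.asarray(support, dtype=float)
    n_sup, p = support.shape
    keys = {tuple(np.round(r, 12)) for r in support}
    if len(keys) != n_sup:
        raise DesignError("support rows must be unique treatment combinations")
    rng = np.random.default_rng(seed)

    lof = (
        _interior_lack_of_fit_points(p, n_lack_of_fit, support, rng)
        if n_lack_of_fit
        else np.zeros((0, p))
    )
    unique_rows = np.vstack([support, lof])
    roles = ["support"] * n_sup + ["lack_of_fit"] * len(lof)
    n_unique = len(unique_rows)
    if n_replicates > n_unique:
        raise DesignError(
            f"cannot replicate {n_replicates} runs out of {n_unique} unique runs"
        )
    rep_src = rng.choice(n_unique, size=n_replicates, replace=False)

    # entries: (proportions, role, source unique index or None)
    entries = [(unique_rows[i], roles[i], None) for i in range(n_unique)]
    entries += [(unique_rows[s], "replicate", int(s)) for s in rep_src]
    order = rng.permutation(len(entries))

    run_ids = np.arange(1, len(entries) + 1)
    new_id_of_unique: dict[int, int] = {}
    for rid, pos in zip(run_ids, order):
        if entries[pos][2] is None:
            new_id_of_unique[pos] = int(rid)
    rows, role_out, rep_out = [], [], []
    for rid, pos in zip(run_ids, order):
        props, role, src = entries[pos]
        rows.append(props)
        role_out.append(role)
        rep_out.append(new_id_of_unique[src] if src is not None else pd.NA)

    cols = taxa if taxa is not None else [f"x{i + 1}" for i in range(p)]
    design = MixtureDesign(
        proportions=pd.DataFrame(rows, index=pd.Index(run_ids, name="run_id"), columns=cols),
        role=pd.Series(role_out, index=run_ids),
        replicate_of=pd.Series(rep_out, index=run_ids, dtype="Int64"),
    )
    design.validate()
    return design


def build_design(
    p: int,
    n_support: int | None = None,
    n_lack_of_fit: int = 2,
    n_replicates: int = 15,
    seed: int = 0,
    taxa: list[str] | None = None,
) -> MixtureDesign:
    """One-call construction: candidates -> D-optimal support -> full design.

    Defaults mirror the seven-taxon study layout: the 63-point support plus
    2 lack-of-fit runs and 15 replicates, i.e. 80 runs with 65 unique
    treatment combinations.
    """
    if n_support is None:
        n_support = special_cubic_size(p)
    cands = candidate_set(p)
    support = select_d_optimal(cands, n_support, seed=seed)
    return assemble_runs(support, n_lack_of_fit, n_replicates, seed=seed, taxa=taxa)


def match_design(table: pd.DataFrame, design: MixtureDesign) -> pd.DataFrame:
    """Align a samples × taxa table to the design rows (by run_id index).

    Raises MatchingError when a sample has no design row or columns differ.
    """
    if list(table.columns) != design.taxa:
        raise MatchingError(
            f"taxon columns {list(table.columns)} do not match design taxa {design.taxa}"
        )
    missing = table.index.difference(design.proportions.index)
    if len(missing):
        raise MatchingError(f"samples not present in design: {list(missing[:5])}")
    return design.proportions.loc[table.index]
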