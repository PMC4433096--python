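"""Inverse scaling-factor models: predict true composition from observed.

For every mock sample and every taxon actually present (prescribed
proportion > 0), the scaling factor is the observed proportion divided by
the actual proportion.  One random-forest regression per taxon (500 trees,
two candidate split variables per node) maps the full vector of observed,
copy-number-adjusted proportions of a sample to that taxon's scaling
factor.  For a new sample the observed proportions are adjusted for copy
number, a factor is predicted for each taxon with nonzero counts, the
observed proportion is divided by the predicted observed/actual factor
(orientation configurable), and the result re-normalized to sum to one.

The predictors are the observed proportions — the only quantity available
for a clinical sample at prediction time — even though the factors are
defined against the actual proportions of the training mocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .bias import adjust_counts
from .design import MixtureDesign, match_design
from .errors import ConfigError, ModelError
from .taxa import TaxonMeta

ORIENTATIONS = ("obs_over_actual", "actual_over_obs")

#: predicted factors are clipped to this floor before division
FACTOR_FLOOR = 1e-6

DEFAULT_N_TREES = 500
DEFAULT_MAX_FEATURES = 2
MIN_OBSERVATIONS = 10


@dataclass
class ScalingObservations:
    """Training data for the inverse models.

    ``factors`` is tidy (sample_id, taxon, factor) with factors defined only
    where the actual proportion is positive; ``predictors`` holds each
    sample's full observed proportion vector and ``actual`` the prescribed
    proportions, both indexed by sample_id.
    """

    factors: pd.DataFrame
    predictors: pd.DataFrame
    actual: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.predictors.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.predictors.index

    def subset(self, sample_ids) -> "ScalingObservations":
        mask = self.factors["sample_id"].isin(sample_ids)
        return ScalingObservations(
            factors=self.factors[mask].reset_index(drop=True),
            predictors=self.predictors.loc[sample_ids],
            actual=self.actual.loc[sample_ids],
        )


def scaling_factors(observed: pd.DataFrame, design: MixtureDesign) -> ScalingObservations:
    """Observed / actual proportion per (sample, taxon) with actual > 0.

    Zero-actual entries are skipped silently (no factor is defined there).
    """
    prescribed = match_design(observed, design)
    rows = []
    for sid in observed.index:
        for taxon in observed.columns:
            actual = prescribed.loc[sid, taxon]
            if actual > 0:
                rows.append((sid, taxon, float(observed.loc[sid, taxon] / actual)))
    factors = pd.DataFrame(rows, columns=["sample_id", "taxon", "factor"])
    return ScalingObservations(
        factors=factors, predictors=observed.copy(), actual=prescribed.copy()
    )


@dataclass
class InverseModelSet:
    """One fitted regression forest per taxon plus training metadata."""

    models: dict[str, RandomForestRegressor]
    taxa: list[str]
    n_trees: int = DEFAULT_N_TREES
    max_features: int = DEFAULT_MAX_FEATURES
    seed: int = 0
    skipped: list[str] = field(default_factory=list)

    def predict_factor(self, taxon: str, predictors: np.ndarray) -> np.ndarray:
        if taxon not in self.models:
            raise ModelError(f"no inverse model for taxon {taxon!r}")
        return self.models[taxon].predict(np.atleast_2d(predictors))

    def oob_scores(self) -> dict[str, float]:
        return {
            t: float(m.oob_score_) for t, m in self.models.items() if hasattr(m, "oob_score_")
        }


def fit_inverse(
    scaling: ScalingObservations,
    n_trees: int = DEFAULT_N_TREES,
    max_features: int = DEFAULT_MAX_FEATURES,
    seed: int = 0,
    min_obs: int = MIN_OBSERVATIONS,
    oob: bool = True,
) -> InverseModelSet:
    """Fit the per-taxon scaling-factor forests.

    Taxa with fewer than ``min_obs`` factor observations are skipped with a
    warning.  Deterministic for a fixed seed.
    """
    models: dict[str, RandomForestRegressor] = {}
    skipped: list[str] = []
    for t_idx, taxon in enumerate(scaling.taxa):
        obs = scaling.factors[scaling.factors["taxon"] == taxon]
        if len(obs) < min_obs:
            warnings.warn(
                f"taxon {taxon!r} has only {len(obs)} scaling observations "
                f"(< {min_obs}); skipping"
            )
            skipped.append(taxon)
            continue
        X = scaling.predictors.loc[obs["sample_id"]].to_numpy()
        y = obs["factor"].to_numpy()
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=seed + t_idx,
            oob_score=oob,
            bootstrap=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            forest.fit(X, y)
        models[taxon] = forest
    return InverseModelSet(
        models=models,
        taxa=scaling.taxa,
        n_trees=n_trees,
        max_features=max_features,
        seed=seed,
        skipped=skipped,
    )


def correct_proportions(
    observed: pd.DataFrame,
    models: InverseModelSet,
    orientation: str = "obs_over_actual",
) -> pd.DataFrame:
    """Apply the inverse correction to (already adjusted) observed proportions.

    With the default ``obs_over_actual`` orientation the observed proportion
    is divided by the predicted observed/actual factor; with
    ``actual_over_obs`` it is multiplied by the prediction (the literal
    multiply-by-factor reading).  Predicted factors below a small positive
    floor are clipped before division.  Taxa with zero observed proportion
    receive zero; rows are re-normalized to sum to one.

    Raises
    ------
    ModelError
        A taxon with nonzero proportion but no fitted model.
    """
    if orientation not in ORIENTATIONS:
        raise ConfigError(f"unknown factor orientation {orientation!r}")
    out = np.zeros_like(observed.to_numpy(dtype=float))
    Xall = observed.to_numpy(dtype=float)
    for j, taxon in enumerate(observed.columns):
        nz = np.flatnonzero(Xall[:, j] > 0)
        if nz.size == 0:
            continue
        if taxon not in models.models:
            raise ModelError(
                f"taxon {taxon!r} has nonzero observations but no fitted inverse model"
            )
        factors = models.models[taxon].predict(Xall[nz])
        factors = np.maximum(factors, FACTOR_FLOOR)
        if orientation == "obs_over_actual":
            out[nz, j] = Xall[nz, j] / factors
        else:
            out[nz, j] = Xall[nz, j] * factors
    sums = out.sum(axis=1)
    if np.any(sums == 0):
        raise ModelError("a corrected sample has no positive proportions")
    out /= sums[:, None]
    return pd.DataFrame(out, index=observed.index, columns=observed.columns)


def correct_sample(
    observed_counts: pd.DataFrame,
    taxa: list[TaxonMeta],
    models: InverseModelSet,
    orientation: str = "obs_over_actual",
) -> pd.DataFrame:
    """Full correction of raw counts: copy-number adjust, predict, renormalize.

    ``observed_counts`` is samples × taxa; the result holds predicted true
    proportions summing to one per sample.
    """
    observed = adjust_counts(observed_counts, taxa, "cells")
    return correct_proportions(observed, models, orientation)


def cross_validate(
    scaling: ScalingObservations,
    k: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_features: int = DEFAULT_MAX_FEATURES,
    orientation: str = "obs_over_actual",
) -> pd.DataFrame:
    """k-fold cross-validated correction error, per taxon and fold.

    Folds partition *samples* (a sample's taxa stay together).  For each
    fold the forests are refit on the training samples and the held-out
    samples corrected; the per-taxon mean absolute error of corrected vs
    actual proportions is reported.  Returns a tidy frame
    (taxon, fold, mae, n).
    """
    ids = scaling.sample_ids
    n = len(ids)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > n:
        raise ConfigError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    rows = []
    for f, test_pos in enumerate(folds):
        test_ids = ids[np.sort(test_pos)]
        train_ids = ids.difference(test_ids)
        train = scaling.subset(train_ids)
        models = fit_inverse(
            train, n_trees=n_trees, max_features=max_features, seed=seed, oob=False
        )
        corrected = correct_proportions(
            scaling.predictors.loc[test_ids], models, orientation
        )
        err = (corrected - scaling.actual.loc[test_ids]).abs()
        for taxon in scaling.taxa:
            rows.append((taxon, f, float(err[taxon].mean()), len(test_ids)))
    return pd.DataFrame(rows, columns=["taxon", "fold", "mae", "n"])
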