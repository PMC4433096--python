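"""Count adjustment, bias computation, stage decomposition and significance.

Bias is the observed minus the prescribed proportion of a taxon in a mock
community; negative values mean the signal was suppressed, positive that it
was amplified.  Because the three experiments mix cells, DNA and PCR product
over the same design, pairwise comparisons isolate pipeline stages:

    total       = experiment 1 (cells)  - prescribed
    extraction  = experiment 1 (cells)  - experiment 2 (dna)
    pcr         = experiment 2 (dna)    - experiment 3 (pcr product)
    seq_class   = experiment 3 (pcr)    - prescribed

which telescope to the total per matched treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MixtureDesign, match_design
from .errors import ConfigError, MatchingError, SchemaError
from .taxa import TaxonMeta, taxa_frame

STAGES = ("total", "extraction", "pcr", "seq_class")


def adjust_counts(
    counts: pd.DataFrame, taxa: list[TaxonMeta], experiment: str
) -> pd.DataFrame:
    """Copy-number / genome-size adjust raw counts and normalize to proportions.

    cells : divide counts by 16S copy number (reads per cell).
    dna   : multiply by genome size and divide by copy number (reads per
            nanogram of input DNA).
    pcr   : no adjustment (amplicons are the input units already).

    Each sample row is then normalized to sum to one.

    Raises
    ------
    SchemaError
        Negative counts, a taxon without metadata, or an all-zero sample
        (its proportions would be undefined).
    """
    if experiment not in ("cells", "dna", "pcr"):
        raise ConfigError(f"unknown experiment {experiment!r}")
    meta = taxa_frame(taxa)
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise SchemaError(f"no metadata for taxa: {missing}")
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise SchemaError("counts must be nonnegative")
    cn = meta.loc[counts.columns, "copy_number"].to_numpy(dtype=float)
    gs = meta.loc[counts.columns, "genome_size"].to_numpy(dtype=float)
    if experiment == "cells":
        adj = vals / cn
    elif experiment == "dna":
        adj = vals * gs / cn
    else:
        adj = vals.copy()
    row_sums = adj.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise SchemaError(
            f"samples with all-zero counts have undefined proportions: "
            f"{list(counts.index[zero][:5])}"
        )
    props = pd.DataFrame(adj / row_sums[:, None], index=counts.index, columns=counts.columns)
    props.attrs["experiment"] = experiment
    return props


def compute_bias(observed: pd.DataFrame, design: MixtureDesign) -> pd.DataFrame:
    """Per-sample per-taxon bias: observed minus prescribed proportion.

    Samples are matched to design rows by run_id; the full frame is returned
    (biases sum to zero across taxa per sample).  Use
    :func:`summarize_bias` for present-taxa-only summaries.
    """
    prescribed = match_design(observed, design)
    return observed - prescribed


def summarize_bias(bias: pd.DataFrame, design: MixtureDesign) -> pd.DataFrame:
    """Median and IQR of bias per taxon, over samples containing the taxon.

    A taxon counts as present in a sample iff its prescribed proportion is
    positive, regardless of whether reads were observed.
    """
    prescribed = match_design(bias, design)
    rows = []
    for taxon in bias.columns:
        present = prescribed[taxon] > 0
        vals = bias.loc[present, taxon]
        q1, med, q3 = (
            (np.nan, np.nan, np.nan)
            if vals.empty
            else np.percentile(vals, [25, 50, 75])
        )
        rows.append((taxon, int(present.sum()), med, q1, q3))
    return pd.DataFrame(rows, columns=["taxon", "n_present", "median", "q1", "q3"])


def collapse_replicates(observed: pd.DataFrame, design: MixtureDesign) -> pd.DataFrame:
    """Average proportions within replicate groups; index becomes treatment id."""
    treatments = design.treatment_ids().loc[observed.index]
    out = observed.groupby(treatments.to_numpy()).mean()
    out.index.name = "treatment_id"
    return out


def stage_decomposition(
    exp1: pd.DataFrame,
    exp2: pd.DataFrame,
    exp3: pd.DataFrame,
    design: MixtureDesign,
) -> pd.DataFrame:
    """Decompose bias by pipeline stage across the three experiments.

    Experiments share the design's treatment combinations, not sample
    identities, so replicate runs are averaged within each experiment before
    differencing.  Returns a tidy frame with columns ``stage``,
    ``treatment_id``, ``taxon``, ``bias``; per matched treatment the
    extraction, pcr and seq_class rows sum to the total row.
    """
    collapsed = [collapse_replicates(e, design) for e in (exp1, exp2, exp3)]
    common = collapsed[0].index
    for c in collapsed[1:]:
        common = common.intersection(c.index)
    for label, c in zip(("exp1", "exp2", "exp3"), collapsed):
        extra = c.index.difference(common)
        if len(extra):
            raise MatchingError(
                f"treatments present in {label} but not in all experiments: {list(extra[:5])}"
            )
    e1, e2, e3 = (c.loc[common] for c in collapsed)
    prescribed = design.proportions.loc[common]

    stages = {
        "total": e1 - prescribed,
        "extraction": e1 - e2,
        "pcr": e2 - e3,
        "seq_class": e3 - prescribed,
    }
    tidy = []
    for stage, frame in stages.items():
        long = frame.stack().rename("bias").reset_index()
        long.columns = ["treatment_id", "taxon", "bias"]
        long.insert(0, "stage", stage)
        tidy.append(long)
    return pd.concat(tidy, ignore_index=True)


def stage_summary(decomp: pd.DataFrame, design: MixtureDesign) -> pd.DataFrame:
    """Median / IQR per (taxon, stage) over treatments containing the taxon."""
    prescribed = design.proportions
    treat_rows = prescribed.loc[sorted(decomp["treatment_id"].unique())]
    rows = []
    for (stage, taxon), grp in decomp.groupby(["stage", "taxon"], sort=False):
        present_ids = treat_rows.index[treat_rows[taxon] > 0]
        vals = grp.set_index("treatment_id").loc[
            grp["treatment_id"].isin(present_ids).to_numpy(), "bias"
        ] if len(present_ids) else pd.Series(dtype=float)
        sub = grp[grp["treatment_id"].isin(present_ids)]["bias"]
        q1, med, q3 = (
            (np.nan, np.nan, np.nan) if sub.empty else np.percentile(sub, [25, 50, 75])
        )
        rows.append((taxon, stage, len(sub), med, q1, q3, float(sub.abs().median()) if len(sub) else np.nan))
    return pd.DataFrame(
        rows, columns=["taxon", "stage", "n", "median", "q1", "q3", "median_abs"]
    )


def stage_median_bias(decomp: pd.DataFrame, design: MixtureDesign) -> dict[str, float]:
    """Overall signed median bias per stage, over present-taxon entries.

    Symmetric technical noise cancels in this summary, so it isolates
    systematic distortion: near zero for an unbiased pipeline regardless of
    replicate-level noise.
    """
    prescribed = design.proportions
    out = {}
    for stage, grp in decomp.groupby("stage", sort=False):
        present = [
            prescribed.loc[t, taxon] > 0
            for t, taxon in zip(grp["treatment_id"], grp["taxon"])
        ]
        vals = grp.loc[present, "bias"]
        out[str(stage)] = float(vals.median()) if len(vals) else float("nan")
    return out


def technical_variation(observed: pd.DataFrame, design: MixtureDesign) -> pd.Series:
    """Replicate median absolute error of observed proportions per taxon.

    For every replicated treatment, each member's absolute deviation from
    the replicate-group mean is collected; the median is taken per taxon
    over deviations from samples in which the taxon is present (prescribed
    proportion > 0).  With no replicated treatments a warning is issued and
    an all-NaN series returned.
    """
    treatments = design.treatment_ids().loc[observed.index]
    sizes = treatments.value_counts()
    replicated = sizes[sizes > 1].index
    if len(replicated) == 0:
        warnings.warn("design contains no replicated treatments; MAE undefined")
        return pd.Series(np.nan, index=observed.columns, name="mae")
    mae = {}
    prescribed = design.proportions
    for taxon in observed.columns:
        devs = []
        for t in replicated:
            members = treatments.index[treatments == t]
            if prescribed.loc[t, taxon] <= 0:
                continue
            vals = observed.loc[members, taxon].to_numpy()
            devs.extend(np.abs(vals - vals.mean()))
        mae[taxon] = float(np.median(devs)) if devs else np.nan
    return pd.Series(mae, name="mae")


@dataclass
class MahalanobisResult:
    """Bootstrap test of whether a mean bias vector differs from zero."""

    distance: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "distance": self.distance,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "n_boot": self.n_boot,
            "significant": self.significant,
        }


def _mahalanobis(diffs: np.ndarray) -> float:
    mean = diffs.mean(axis=0)
    if diffs.shape[0] < 2:
        return float("nan")
    cov = np.cov(diffs, rowvar=False)
    cov = np.atleast_2d(cov)
    # bias vectors over a full taxon set sum to zero, so the covariance is
    # singular by construction; fall back to the pseudo-inverse
    if np.linalg.cond(cov) > 1e10:
        inv = np.linalg.pinv(cov)
    else:
        inv = np.linalg.inv(cov)
    return float(np.sqrt(max(mean @ inv @ mean, 0.0)))


def mahalanobis_bootstrap(
    differences: pd.DataFrame | np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> MahalanobisResult:
    """Percentile-bootstrap CI for the Mahalanobis distance of mean bias.

    The distance of the mean difference vector from zero is computed under
    the sample covariance (pseudo-inverse when singular); samples are
    resampled with replacement ``n_boot`` times and the percentile interval
    at ``level`` taken.  The bias is flagged significant when zero lies
    outside the interval.

    Raises
    ------
    MatchingError
        Fewer than 2 matched samples.
    """
    diffs = np.atleast_2d(np.asarray(differences, dtype=float))
    n = diffs.shape[0]
    if n < 2:
        raise MatchingError(f"need at least 2 matched samples, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = _mahalanobis(diffs)
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = _mahalanobis(diffs[idx])
    boots = boots[np.isfinite(boots)]
    alpha = 1.0 - level
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    significant = not (lo <= 0.0 <= hi)
    return MahalanobisResult(
        distance=dist,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_boot=n_boot,
        significant=bool(significant),
    )
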