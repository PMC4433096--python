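"""Generative model for the three mock-community mixture experiments.

The three experiments mix prescribed proportions of cells, genomic DNA, and
PCR product from the same strains, so each passes through a nested subset of
the processing pipeline (extraction -> PCR -> sequencing/classification).
The simulator uses the smallest mechanism able to produce both per-taxon
main effects and pairwise blending effects: multiplicative per-taxon stage
efficiencies with first-order pairwise interaction modifiers,

    cells: w_i = x_i * c_i * e_i * (1 + sum_j g_ij x_j) * a_i * (1 + sum_j d_ij x_j) * s_i
    dna:   w_i = x_i * (c_i / G_i) * a_i * (1 + sum_j d_ij x_j) * s_i
    pcr:   w_i = x_i * s_i

with c_i the 16S copy number, G_i the genome size, e/a/s the extraction,
PCR and sequencing/classification efficiencies, and g/d the extraction and
PCR interaction matrices.  Read counts are Multinomial(depth, w/sum w) after
per-sample lognormal jitter on the weights (technical noise).  Bias from
non-viable cells is not separable from extraction bias and is folded into
e_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .errors import ConfigError, SimulationError
from .taxa import TaxonMeta

SCENARIOS = ("neutral", "default", "extraction_only", "pcr_only")
EXPERIMENTS = ("cells", "dna", "pcr")

#: reads per sample; about 3.9 million reads spread over 240 samples.
DEFAULT_DEPTH = 16_000
#: coefficient of variation of per-sample lognormal technical jitter,
#: sized so replicate median absolute error stays below 5%.
DEFAULT_NOISE_CV = 0.03


@dataclass
class BiasTruth:
    """Ground-truth bias parameters of the generative model.

    Efficiencies are strictly positive per-taxon factors; interaction
    matrices have zero diagonal and entries capped at 0.9/(p-1) in magnitude
    so that 1 + sum_j g_ij x_j stays positive on the whole simplex.
    """

    extraction_eff: np.ndarray
    pcr_eff: np.ndarray
    seq_eff: np.ndarray
    extraction_interaction: np.ndarray
    pcr_interaction: np.ndarray
    noise_cv: float = DEFAULT_NOISE_CV
    depth: int = DEFAULT_DEPTH
    seed: int = 0
    scenario: str = field(default="custom")

    def __post_init__(self) -> None:
        for name in ("extraction_eff", "pcr_eff", "seq_eff"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise SimulationError(f"{name} must be strictly positive")
        p = len(self.extraction_eff)
        for name in ("extraction_interaction", "pcr_interaction"):
            mat = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, mat)
            if mat.shape != (p, p):
                raise SimulationError(f"{name} must be {p}x{p}")
            if np.any(np.diag(mat) != 0):
                raise SimulationError(f"{name} must have zero diagonal")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if self.depth < 1:
            raise SimulationError("depth must be >= 1")

    @property
    def p(self) -> int:
        return len(self.extraction_eff)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "depth": self.depth,
            "noise_cv": self.noise_cv,
            "extraction_eff": self.extraction_eff.tolist(),
            "pcr_eff": self.pcr_eff.tolist(),
            "seq_eff": self.seq_eff.tolist(),
            "extraction_interaction": self.extraction_interaction.tolist(),
            "pcr_interaction": self.pcr_interaction.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BiasTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            extraction_eff=np.asarray(d["extraction_eff"]),
            pcr_eff=np.asarray(d["pcr_eff"]),
            seq_eff=np.asarray(d["seq_eff"]),
            extraction_interaction=np.asarray(d["extraction_interaction"]),
            pcr_interaction=np.asarray(d["pcr_interaction"]),
            noise_cv=float(d["noise_cv"]),
            depth=int(d["depth"]),
            seed=int(d["seed"]),
            scenario=str(d.get("scenario", "custom")),
        )


def _sparse_interactions(
    p: int, rng: np.random.Generator, density: float = 0.2, magnitude: float = 0.5
) -> np.ndarray:
    cap = min(magnitude, 0.9 / (p - 1))
    mat = np.zeros((p, p))
    mask = rng.random((p, p)) < density
    np.fill_diagonal(mask, False)
    mat[mask] = rng.uniform(-cap, cap, size=int(mask.sum()))
    return mat


def make_truth(
    p: int,
    scenario: str = "default",
    seed: int = 0,
    noise_cv: float = DEFAULT_NOISE_CV,
    depth: int = DEFAULT_DEPTH,
) -> BiasTruth:
    """Draw ground-truth bias parameters for a scenario.

    neutral
        All efficiencies 1, all interactions 0 (identity pipeline).
    default
        Lognormal extraction and PCR efficiencies (sd 0.5 on the log scale),
        near-identity sequencing factors (within ~5% of 1), and sparse
        interactions (20% of off-diagonal entries nonzero).
    extraction_only / pcr_only
        Only the named stage is biased; the others are identity.
    """
    if p < 2:
        raise ConfigError(f"need at least 2 components, got {p}")
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, SCENARIOS.index(scenario)]))
    ones = np.ones(p)
    zeros = np.zeros((p, p))
    ext = rng.lognormal(mean=0.0, sigma=0.5, size=p)
    pcr = rng.lognormal(mean=0.0, sigma=0.5, size=p)
    seq = rng.lognormal(mean=0.0, sigma=0.025, size=p)
    gamma = _sparse_interactions(p, rng)
    delta = _sparse_interactions(p, rng)
    if scenario == "neutral":
        ext, pcr, seq, gamma, delta = ones, ones.copy(), ones.copy(), zeros, zeros.copy()
    elif scenario == "extraction_only":
        pcr, seq, delta = ones, ones.copy(), zeros
    elif scenario == "pcr_only":
        ext, seq, gamma = ones, ones.copy(), zeros
    return BiasTruth(
        extraction_eff=ext,
        pcr_eff=pcr,
        seq_eff=seq,
        extraction_interaction=gamma,
        pcr_interaction=delta,
        noise_cv=noise_cv,
        depth=depth,
        seed=seed,
        scenario=scenario,
    )


def expected_weights(
    x: np.ndarray, truth: BiasTruth, taxa: list[TaxonMeta], experiment: str
) -> np.ndarray:
    """Noise-free template weights w_i for prescribed proportions ``x``.

    ``x`` may be a single simplex vector or a matrix of rows.  Dividing by
    the row sum gives the analytic expected observed proportions (exact up
    to the jitter and multinomial noise, which are mean-one and unbiased in
    the weight domain respectively).
    """
    if experiment not in EXPERIMENTS:
        raise ConfigError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p = truth.p
    if x.shape[1] != p or len(taxa) != p:
        raise SimulationError("design, truth and taxa dimensions disagree")
    cn = np.array([t.copy_number for t in taxa], dtype=float)
    gs = np.array([t.genome_size for t in taxa], dtype=float)
    ext_mod = 1.0 + x @ truth.extraction_interaction.T
    pcr_mod = 1.0 + x @ truth.pcr_interaction.T
    if np.any(ext_mod <= 0) or np.any(pcr_mod <= 0):
        raise SimulationError("interaction terms drove a weight negative")
    if experiment == "cells":
        w = x * cn * truth.extraction_eff * ext_mod * truth.pcr_eff * pcr_mod * truth.seq_eff
    elif experiment == "dna":
        w = x * (cn / gs) * truth.pcr_eff * pcr_mod * truth.seq_eff
    else:  # pcr product
        w = x * truth.seq_eff
    if np.any(w < 0):
        raise SimulationError("negative template weight")
    return w


def expected_proportions(
    x: np.ndarray, truth: BiasTruth, taxa: list[TaxonMeta], experiment: str
) -> np.ndarray:
    """Closed-form expected observed proportions w / sum(w)."""
    w = expected_weights(x, truth, taxa, experiment)
    return w / w.sum(axis=1, keepdims=True)


def _simulate_counts(
    x: np.ndarray,
    truth: BiasTruth,
    taxa: list[TaxonMeta],
    experiment: str,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if depth < 1:
        raise SimulationError(f"depth must be >= 1, got {depth}")
    w = expected_weights(x, truth, taxa, experiment)
    if truth.noise_cv > 0:
        sigma = np.sqrt(np.log1p(truth.noise_cv**2))
        jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=w.shape)
        w = w * jitter
    q = w / w.sum(axis=1, keepdims=True)
    counts = np.empty_like(q, dtype=np.int64)
    for s in range(q.shape[0]):
        counts[s] = rng.multinomial(depth, q[s])
    return counts


def simulate_experiment(
    design: MixtureDesign,
    truth: BiasTruth,
    taxa: list[TaxonMeta],
    experiment: str,
    depth: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one experiment's count table over all design runs.

    Each run (replicates included) receives independent jitter and an
    independent multinomial draw of ``depth`` reads.  The returned frame is
    indexed by run_id with taxon columns; rows sum exactly to ``depth``.
    Deterministic given (truth.seed, experiment) or an explicit ``seed``.
    """
    names = [t.name for t in taxa]
    if design.taxa != names:
        raise SimulationError(
            f"design columns {design.taxa} do not match taxa {names}"
        )
    depth = truth.depth if depth is None else depth
    base = truth.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base, 100 + EXPERIMENTS.index(experiment)]))
    counts = _simulate_counts(
        design.proportions.to_numpy(), truth, taxa, experiment, depth, rng
    )
    return pd.DataFrame(counts, index=design.proportions.index.copy(), columns=names)


def simulate_clinical(
    truth: BiasTruth,
    taxa: list[TaxonMeta],
    true_profiles: pd.DataFrame,
    depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate observed counts for samples with known true compositions.

    Applies the full cells-experiment mechanism (the whole pipeline) to each
    profile row.  Profiles must be nonnegative and sum to 1 per row.
    """
    prof = true_profiles.to_numpy(dtype=float)
    if np.any(prof < 0):
        raise SimulationError("true profiles must be nonnegative")
    if np.any(np.abs(prof.sum(axis=1) - 1.0) > 1e-9):
        raise SimulationError("true profile rows must sum to 1")
    depth = truth.depth if depth is None else depth
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    counts = _simulate_counts(prof, truth, taxa, "cells", depth, rng)
    return pd.DataFrame(
        counts, index=true_profiles.index.copy(), columns=[t.name for t in taxa]
    )


def random_profiles(
    n: int,
    taxa: list[TaxonMeta],
    seed: int = 0,
    min_taxa: int = 2,
    max_taxa: int = 4,
) -> pd.DataFrame:
    """Low-diversity community profiles for clinical-like test samples.

    Each sample contains a uniform-random subset of ``min_taxa``..``max_taxa``
    taxa with Dirichlet(1) proportions among them, mimicking the low richness
    typical of vaginal communities.
    """
    p = len(taxa)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    rows = np.zeros((n, p))
    for s in range(n):
        k = int(rng.integers(min_taxa, max_taxa + 1))
        sub = rng.choice(p, size=k, replace=False)
        rows[s, sub] = rng.dirichlet(np.ones(k))
    return pd.DataFrame(
        rows,
        index=pd.Index([f"clinical_{s + 1}" for s in range(n)], name="sample_id"),
        columns=[t.name for t in taxa],
    )
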