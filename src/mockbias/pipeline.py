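"""End-to-end orchestration: design -> simulate/ingest -> bias -> models -> inverse."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .bias import (
    adjust_counts,
    collapse_replicates,
    mahalanobis_bootstrap,
    stage_decomposition,
    stage_median_bias,
    stage_summary,
    technical_variation,
)
from .design import MixtureDesign, build_design, special_cubic_size
from .errors import ConfigError, MockbiasError
from .inverse import cross_validate, fit_inverse, scaling_factors
from .io import RunConfig, read_counts, write_counts
from .scheffe import fit_taxon_models, screen_blends
from .simulate import make_truth, simulate_experiment
from .taxa import read_taxa, vaginal_panel, write_taxa

log = logging.getLogger("mockbias")

EXPERIMENT_OF = {"exp1": "cells", "exp2": "dna", "exp3": "pcr"}


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: ok", name)
                return out
            except MockbiasError as exc:
                raise MockbiasError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full protocol and write a report bundle.

    Stages: load/construct design and taxa; simulate (or ingest) the three
    experiments; adjust counts; decompose bias by stage with replicate MAE
    and bootstrap Mahalanobis significance; fit per-taxon special cubic
    models and screen blending terms; fit inverse scaling-factor forests and
    cross-validate.  All artifacts carry the config hash and seeds; the
    machine-readable report is ``report.json`` in the output directory.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- inputs ----------------------------------------------------------
    for key in ("taxa_path", "design_path", "exp1_path", "exp2_path", "exp3_path"):
        path = config[key]
        if path is not None and not Path(path).exists():
            raise ConfigError(f"configured {key} does not exist: {path}")

    taxa = read_taxa(config.taxa_path) if config.taxa_path else vaginal_panel()
    names = [t.name for t in taxa]
    if config.design_path:
        design = MixtureDesign.from_csv(config.design_path)
    else:
        design = build_design(
            p=len(taxa),
            n_support=config.n_support or special_cubic_size(len(taxa)),
            n_lack_of_fit=config.n_lack_of_fit,
            n_replicates=config.n_replicates,
            seed=config.design_seed,
            taxa=names,
        )
        design.to_csv(out / "design.csv")
    write_taxa(taxa, out / "taxa.csv")

    # -- counts: ingest or simulate -------------------------------------
    count_paths = [config.exp1_path, config.exp2_path, config.exp3_path]
    counts = {}
    truth = None
    if all(count_paths):
        for label, path in zip(EXPERIMENT_OF, count_paths):
            counts[label] = read_counts(path)
    elif any(count_paths):
        raise ConfigError("provide all three experiment count tables or none")
    else:
        truth = make_truth(
            len(taxa),
            scenario=config.scenario,
            seed=config.truth_seed,
            noise_cv=config.noise_cv,
            depth=config.depth,
        )
        truth.to_json(out / "truth.json")
        for label, experiment in EXPERIMENT_OF.items():
            counts[label] = simulate_experiment(design, truth, taxa, experiment)
            write_counts(counts[label], out / f"{label}.tsv")

    # -- bias quantification ---------------------------------------------
    props = {
        label: adjust_counts(counts[label], taxa, experiment)
        for label, experiment in EXPERIMENT_OF.items()
    }
    decomp = stage_decomposition(props["exp1"], props["exp2"], props["exp3"], design)
    decomp.to_csv(out / "bias_tidy.tsv", sep="\t", index=False)
    summary = stage_summary(decomp, design)
    summary.to_csv(out / "bias_summary.tsv", sep="\t", index=False)
    mae = {label: technical_variation(props[label], design) for label in props}

    collapsed = {label: collapse_replicates(props[label], design) for label in props}
    prescribed = design.proportions.loc[collapsed["exp1"].index]
    pairs = {
        "total": collapsed["exp1"] - prescribed,
        "extraction": collapsed["exp1"] - collapsed["exp2"],
        "pcr": collapsed["exp2"] - collapsed["exp3"],
        "seq_class": collapsed["exp3"] - prescribed,
    }
    significance = {
        stage: mahalanobis_bootstrap(
            diff.to_numpy(), n_boot=config.n_boot, level=config.boot_level,
            seed=config.boot_seed,
        ).to_dict()
        for stage, diff in pairs.items()
    }

    # -- mixture effect models -------------------------------------------
    models = fit_taxon_models(design.proportions, props["exp1"])
    model_report = {}
    for taxon, model in models.items():
        sig = screen_blends(model, alpha=config.alpha)
        model_report[taxon] = {
            "r_squared": model.r_squared,
            "r_squared_uncentered": model.r_squared_uncentered,
            "n_significant_blends": int(len(sig)),
            "significant_blends": sig.to_dict(orient="records"),
        }
    (out / "models.json").write_text(json.dumps(model_report, indent=2))

    # -- inverse correction ----------------------------------------------
    scaling = scaling_factors(props["exp1"], design)
    inverse_models = fit_inverse(
        scaling,
        n_trees=config.n_trees,
        max_features=config.max_features,
        seed=config.forest_seed,
    )
    cv = cross_validate(
        scaling,
        k=config.cv_folds,
        seed=config.forest_seed,
        n_trees=config.n_trees,
        max_features=config.max_features,
        orientation=config.factor_orientation,
    )
    cv.to_csv(out / "cv_report.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "config_hash": config.hash(),
        "config": dict(config),
        "design": {
            "n_runs": design.n_runs,
            "n_unique_treatments": design.n_unique_treatments,
            "n_components": design.n_components,
        },
        "stage_median_abs_bias": {
            stage: float(
                summary.loc[summary["stage"] == stage, "median_abs"].median()
            )
            for stage in pairs
        },
        # worst per-taxon signed median bias per stage (robust to replicate noise)
        "stage_max_abs_median_bias": {
            stage: float(
                summary.loc[summary["stage"] == stage, "median"].abs().max()
            )
            for stage in pairs
        },
        # overall signed median per stage: symmetric noise cancels here
        "stage_median_bias": stage_median_bias(decomp, design),
        "replicate_mae": {label: mae[label].to_dict() for label in mae},
        "significance": significance,
        "models": {
            taxon: {
                k: v for k, v in rep.items() if k != "significant_blends"
            }
            for taxon, rep in model_report.items()
        },
        "inverse": {
            "oob_r2": inverse_models.oob_scores(),
            "skipped_taxa": inverse_models.skipped,
            "cv_mae_per_taxon": cv.groupby("taxon")["mae"].mean().to_dict(),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
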