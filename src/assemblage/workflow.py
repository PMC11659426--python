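"""End-to-end analysis: simulate or load a survey, collapse to each
requested taxonomic level, then run distance-decay Mantel tests,
stepwise environmental regression, co-occurrence null models, CV
profiles and core-biome curves, writing one summary per run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .dissimilarity import METRICS, geographic_distances, pairwise_dissimilarity
from .mantel import DegenerateMatrixError, mantel_test
from .mrm import PredictorSet, abs_diff_matrix, loso_cv_r2, stepwise_mrm
from .nullmodels import bonferroni_threshold, null_test
from .table import (
    CommunityTable,
    collapse_to_level,
    to_presence_absence,
    to_proportions,
)
from .variability import core_biome_curve, cv_profile

log = logging.getLogger("assemblage")

__all__ = ["RunConfig", "run_full_analysis"]

#: Pseudo-level meaning "analyze the table as-is, without collapsing".
FINEST = "asv"


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``input_dir`` (a directory in the layout written by
    :func:`assemblage.simulate.write_dataset`) or ``generator`` (a
    :class:`GeneratorConfig` to simulate from) must be given.
    """

    output_dir: str = "results/run"
    input_dir: str | None = None
    generator: simulate.GeneratorConfig | None = None
    levels: list[str] = field(
        default_factory=lambda: [FINEST, "genus", "family", "order", "class",
                                 "phylum"]
    )
    metrics: list[str] = field(default_factory=lambda: list(METRICS))
    n_perm: int = 1000
    n_null: int = 1000
    alpha: float = 0.05
    seed: int = 0


def _level_table(dataset: simulate.SyntheticDataset, level: str) -> CommunityTable:
    if level == FINEST:
        return dataset.table
    return collapse_to_level(dataset.table, dataset.taxonomy, level)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write summary.json plus TSV tables.

    Returns the summary dict.  Stage failures are recorded per stage
    (with the stage name) and do not abort the remaining stages.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.input_dir is not None:
        dataset = simulate.load_dataset(cfg.input_dir)
    elif cfg.generator is not None:
        dataset = simulate.generate(cfg.generator)
    else:
        raise ValueError("RunConfig needs input_dir or generator")
    table, n_dropped = dataset.table.drop_empty_taxa()
    log.info("loaded table %s; dropped %d empty taxa", table.shape, n_dropped)
    dataset = dataclasses.replace(dataset, table=table)

    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_of = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(("mantel", "mrm", "sim9", "it"), seeds)
    }

    geo = geographic_distances(dataset.coordinates)
    summary: dict = {
        "config": {
            "levels": cfg.levels,
            "metrics": cfg.metrics,
            "n_perm": cfg.n_perm,
            "n_null": cfg.n_null,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
            "stage_seeds": seed_of,
            "n_dropped_empty_taxa": n_dropped,
        },
        "mantel": [],
        "mrm": [],
        "null_models": [],
        "errors": [],
    }

    env_predictors = PredictorSet()
    for name in dataset.environment.columns:
        env_predictors[name] = abs_diff_matrix(
            dataset.environment[name].to_dict()
        )
    env_predictors["geographic_km"] = geo

    bonf_mantel = bonferroni_threshold(cfg.alpha, len(cfg.levels) * len(cfg.metrics))
    bonf_null = bonferroni_threshold(cfg.alpha, len(cfg.levels))

    for level in cfg.levels:
        try:
            lvl_table, lvl_dropped = _level_table(dataset, level).drop_empty_taxa()
        except Exception as exc:  # noqa: BLE001 - per-stage reporting
            summary["errors"].append({"stage": f"collapse:{level}",
                                      "error": str(exc)})
            continue
        log.info("level %s: %d taxa (%d empty dropped)",
                 level, lvl_table.shape[0], lvl_dropped)

        for metric in cfg.metrics:
            stage = f"mantel:{level}:{metric}"
            try:
                dm = pairwise_dissimilarity(lvl_table, metric)
                res = mantel_test(dm, geo, n_perm=cfg.n_perm,
                                  seed=seed_of["mantel"])
                summary["mantel"].append(
                    {
                        "level": level,
                        "metric": metric,
                        "rho": res.rho,
                        "p": res.p_one_sided,
                        "significant_bonferroni": res.p_one_sided < bonf_mantel,
                    }
                )
            except DegenerateMatrixError as exc:
                summary["errors"].append({"stage": stage, "error": str(exc)})
                continue
            except Exception as exc:  # noqa: BLE001
                summary["errors"].append({"stage": stage, "error": str(exc)})
                continue

            stage = f"mrm:{level}:{metric}"
            try:
                fit = stepwise_mrm(dm, env_predictors, alpha=cfg.alpha,
                                   n_perm=cfg.n_perm, seed=seed_of["mrm"])
                r2cv = (loso_cv_r2(dm, fit, env_predictors)
                        if fit.selected else None)
                summary["mrm"].append(
                    {
                        "level": level,
                        "metric": metric,
                        "selected": fit.selected,
                        "coefficients": fit.coefficients,
                        "r2": fit.r2,
                        "r2_cv": r2cv,
                        "step_p_values": fit.step_p_values,
                    }
                )
            except Exception as exc:  # noqa: BLE001
                summary["errors"].append({"stage": stage, "error": str(exc)})

        # CC and MA degenerate independently (e.g. a coarse level where
        # every taxon occupies every sample freezes the fixed-fixed
        # chain but leaves the abundance test intact)
        row = {"level": level}
        try:
            pa = to_presence_absence(lvl_table)
            cc = null_test("cc", pa, "sim9", n_null=cfg.n_null,
                           seed=seed_of["sim9"])
            row.update(
                cc_observed=cc.observed, cc_null_mean=cc.null_mean,
                cc_null_sd=cc.null_sd, cc_p_low=cc.p_low,
                cc_significant_bonferroni=cc.p_low < bonf_null,
            )
        except Exception as exc:  # noqa: BLE001
            summary["errors"].append({"stage": f"nullmodels:cc:{level}",
                                      "error": str(exc)})
        try:
            ma = null_test("ma", lvl_table, "it", n_null=cfg.n_null,
                           seed=seed_of["it"])
            row.update(
                ma_observed=ma.observed, ma_null_mean=ma.null_mean,
                ma_null_sd=ma.null_sd, ma_p_low=ma.p_low,
                ma_significant_bonferroni=ma.p_low < bonf_null,
            )
        except Exception as exc:  # noqa: BLE001
            summary["errors"].append({"stage": f"nullmodels:ma:{level}",
                                      "error": str(exc)})
        if len(row) > 1:
            summary["null_models"].append(row)

        try:
            props, _ = to_proportions(lvl_table)
            prof = cv_profile(props)
            prof.data.to_csv(out / f"cv_{level}.tsv", sep="\t",
                             index_label="taxon_id")
        except Exception as exc:  # noqa: BLE001
            summary["errors"].append({"stage": f"cv:{level}", "error": str(exc)})

    # functional CV profile and core-biome curve on the finest level
    try:
        cv_profile(dataset.functional).data.to_csv(
            out / "cv_gene_groups.tsv", sep="\t", index_label="group_id"
        )
    except Exception as exc:  # noqa: BLE001
        summary["errors"].append({"stage": "cv:gene_groups", "error": str(exc)})
    try:
        pa = to_presence_absence(dataset.table)
        curve = core_biome_curve(pa, method="exact")
        pd.DataFrame(
            {"n_samples": np.arange(1, len(curve) + 1), "expected_shared": curve}
        ).to_csv(out / "corebiome.tsv", sep="\t", index=False)
        summary["core_biome"] = {
            "mean_richness": float(curve[0]),
            "shared_by_two": float(curve[1]) if len(curve) > 1 else None,
            "strict_core": float(curve[-1]),
        }
    except Exception as exc:  # noqa: BLE001
        summary["errors"].append({"stage": "corebiome", "error": str(exc)})

    pd.DataFrame(summary["mantel"]).to_csv(out / "mantel.tsv", sep="\t",
                                           index=False)
    pd.DataFrame(
        [
            {**row, "selected": ",".join(row["selected"]),
             "coefficients": json.dumps(row["coefficients"]),
             "step_p_values": json.dumps(row["step_p_values"])}
            for row in summary["mrm"]
        ]
    ).to_csv(out / "mrm.tsv", sep="\t", index=False)
    pd.DataFrame(summary["null_models"]).to_csv(out / "nullmodels.tsv",
                                                sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
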