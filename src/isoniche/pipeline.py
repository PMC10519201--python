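"""End-to-end orchestration of the trophic-niche workflow.

A single structured config drives the full analysis: load or simulate the
isotope and diet tables, fit the hierarchical bivariate Student-t model,
fit per-group niche posteriors with Bayesian ellipse areas, compute the
directional overlap matrix, and run the diet classifiers.  All randomness
fans out from one root seed via a counter-based seed-sequence scheme, so a
config + seed pair fully determines the report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import read_diet_table, read_isotope_table, write_table
from .diet_classifier import (
    DEFAULT_GRID,
    ClassifierReport,
    shapley_importance,
    tune_and_evaluate_rf,
)
from .hier_model import (
    HierModelConfig,
    HierPosterior,
    effect_summary_table,
    fit_hier_mvst,
    pairwise_species_contrasts,
    species_mean_summary,
)
from .niche_ellipse import compare_areas, fit_bivariate_posterior, sea_b
from .niche_overlap import overlap_matrix
from .synthetic_data import (
    default_diet_spec,
    default_isotope_spec,
    generate_diet_dataset,
    generate_isotope_dataset,
)

logger = logging.getLogger(__name__)

STAGES = ("hier", "niche", "overlap", "classify")

#: Classification tasks mirroring the published analysis: the two-species
#: task plus the within-species sex/stage/season tasks.
DEFAULT_TASKS = [
    {"target": "species"},
    {"target": "season", "species": "H_dipterurus"},
    {"target": "sex", "species": "H_dipterurus"},
    {"target": "stage", "species": "H_dipterurus"},
    {"target": "season", "species": "N_entemedor"},
    {"target": "sex", "species": "N_entemedor"},
    {"target": "stage", "species": "N_entemedor"},
]


@dataclass
class ReportBundle:
    """Machine-readable result tables for one full run."""

    species_summary: pd.DataFrame | None
    species_contrasts: pd.DataFrame | None
    effect_summary: pd.DataFrame | None
    niche_areas: pd.DataFrame | None
    area_comparisons: pd.DataFrame | None
    overlaps: pd.DataFrame | None
    classifier_reports: list[ClassifierReport]
    prey_rankings: dict[str, pd.Series]
    diagnostics: pd.DataFrame | None
    provenance: dict

    def to_dict(self) -> dict:
        def df(d):
            return None if d is None else d.to_dict(orient="records")

        return {
            "schema_version": 1,
            "species_summary": df(self.species_summary),
            "species_contrasts": df(self.species_contrasts),
            "effect_summary": df(self.effect_summary),
            "niche_areas": df(self.niche_areas),
            "area_comparisons": df(self.area_comparisons),
            "overlaps": None
            if self.overlaps is None
            else self.overlaps.to_dict(orient="index"),
            "classifier_reports": [
                {
                    k: v
                    for k, v in dataclasses.asdict(r).items()
                    if k != "model_"
                }
                for r in self.classifier_reports
            ],
            "prey_rankings": {
                k: v.to_dict() for k, v in self.prey_rankings.items()
            },
            "diagnostics": None
            if self.diagnostics is None
            else self.diagnostics.reset_index().to_dict(orient="records"),
            "provenance": self.provenance,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report_bundle.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
        for name in (
            "species_summary",
            "species_contrasts",
            "effect_summary",
            "niche_areas",
            "area_comparisons",
        ):
            d = getattr(self, name)
            if d is not None:
                d.to_csv(out / f"{name}.csv", index=False)
        if self.overlaps is not None:
            self.overlaps.to_csv(out / "overlaps.csv")
        if self.diagnostics is not None:
            self.diagnostics.to_csv(out / "diagnostics.csv")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _get_isotope(config: dict, seed: int, out: Path | None) -> pd.DataFrame | None:
    block = config.get("isotope")
    if block is None:
        return None
    if "path" in block:
        return read_isotope_table(block["path"], block.get("column_map"))
    spec = default_isotope_spec(n_override=block.get("n_override"))
    df = generate_isotope_dataset(spec, seed)
    if out is not None:
        write_table(df, out / "isotope_data.csv")
    return df


def _get_diet(config: dict, seed: int, out: Path | None) -> pd.DataFrame | None:
    block = config.get("diet")
    if block is None:
        return None
    if "path" in block:
        return read_diet_table(block["path"], block.get("column_map"))
    spec = default_diet_spec(n_override=block.get("n_override"))
    df = generate_diet_dataset(spec, seed)
    if out is not None:
        write_table(df, out / "diet_data.csv")
    return df


def run_full_analysis(
    config: dict, out_dir: str | Path | None = None, seed: int | None = None
) -> ReportBundle:
    """Run the configured stages in dependency order and bundle the results.

    Any stage failure raises with the stage name; previously completed
    outputs are retained on disk next to a ``FAILED`` marker.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    root_seed = int(seed if seed is not None else config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    provenance = {
        "config_hash": cfg_hash,
        "seed": root_seed,
        "package_version": __version__,
        "stages": stages,
    }
    bundle = ReportBundle(
        species_summary=None,
        species_contrasts=None,
        effect_summary=None,
        niche_areas=None,
        area_comparisons=None,
        overlaps=None,
        classifier_reports=[],
        prey_rankings={},
        diagnostics=None,
        provenance=provenance,
    )
    try:
        isotope = _get_isotope(config, _stage_seed(root_seed, "simulate_isotope"), out)
        diet = _get_diet(config, _stage_seed(root_seed, "simulate_diet"), out)

        hier_post: HierPosterior | None = None
        if "hier" in stages:
            if isotope is None:
                raise RuntimeError("stage hier: no isotope input configured")
            hier_cfg = HierModelConfig(
                **config.get("hier", {}), seed=_stage_seed(root_seed, "hier")
            )
            logger.info("stage hier: fitting hierarchical model")
            hier_post = fit_hier_mvst(isotope, hier_cfg)
            force = not hier_post.converged
            bundle.species_summary = species_mean_summary(hier_post, force=force)
            bundle.species_contrasts = pairwise_species_contrasts(hier_post, force=force)
            bundle.effect_summary = effect_summary_table(hier_post, force=force)
            bundle.diagnostics = hier_post.diagnostics.assign(
                divergences=hier_post.divergences, converged=hier_post.converged
            )

        seas: dict[str, object] = {}
        if "niche" in stages or "overlap" in stages:
            if isotope is None:
                raise RuntimeError("stage niche: no isotope input configured")
            ncfg = config.get("niche", {})
            ndraw = int(ncfg.get("ndraw", 4000))
            nseed = _stage_seed(root_seed, "niche")
            posts = []
            for i, sp in enumerate(sorted(isotope["species"].unique())):
                xy = isotope.loc[
                    isotope["species"] == sp, ["d13C", "d15N"]
                ].to_numpy()
                posts.append(
                    fit_bivariate_posterior(
                        xy, ndraw=ndraw, seed=(nseed + i) % 2**31, label=sp
                    )
                )
            seas = {p.label: sea_b(p) for p in posts}
            bundle.niche_areas = pd.DataFrame(
                [
                    {
                        "group": lab,
                        "sea_b_mean": r.mean,
                        "hdi_lower": r.hdi95.lower,
                        "hdi_upper": r.hdi95.upper,
                        "n": p.n,
                    }
                    for (lab, r), p in zip(seas.items(), posts)
                ]
            )
            comps = []
            labs = list(seas)
            for i, a in enumerate(labs):
                for b in labs[i + 1 :]:
                    c = compare_areas(seas[a], seas[b], seed=nseed)
                    comps.append(
                        {
                            "group_a": a,
                            "group_b": b,
                            "mean_diff": c.mean_diff,
                            "hdi_lower": c.hdi95.lower,
                            "hdi_upper": c.hdi95.upper,
                            "p_a_greater": c.p_a_greater,
                        }
                    )
            bundle.area_comparisons = pd.DataFrame(comps)
            if "overlap" in stages:
                ocfg = config.get("overlap", {})
                max_draws = int(ocfg.get("ndraw", 1000))
                trimmed = [
                    type(p)(p.label, p.mu[:max_draws], p.sigma[:max_draws], p.n)
                    for p in posts
                ]
                bundle.overlaps = overlap_matrix(
                    trimmed,
                    conf=float(ocfg.get("conf", 0.95)),
                    nmc=int(ocfg.get("nmc", 10_000)),
                    seed=_stage_seed(root_seed, "overlap"),
                )

        if "classify" in stages:
            if diet is None:
                raise RuntimeError("stage classify: no diet input configured")
            ccfg = config.get("classify", {})
            grid = ccfg.get("grid") or DEFAULT_GRID
            tasks = ccfg.get("tasks") or DEFAULT_TASKS
            cseed = _stage_seed(root_seed, "classify")
            for t_i, task in enumerate(tasks):
                sub = diet
                label = task["target"]
                if "species" in task:
                    sub = diet[diet["species"] == task["species"]]
                    label = f"{task['species']}:{task['target']}"
                logger.info("stage classify: task %s", label)
                rep = tune_and_evaluate_rf(
                    sub, task["target"], grid=grid, seed=(cseed + t_i) % 2**31
                )
                rep.task = label
                bundle.classifier_reports.append(rep)
                if ccfg.get("shap", True):
                    imp = shapley_importance(
                        rep.model_,
                        sub.head(int(ccfg.get("shap_rows", 60))),
                        n_samples=int(ccfg.get("shap_samples", 24)),
                        seed=(cseed + 1000 + t_i) % 2**31,
                        background=sub,
                    )
                    bundle.prey_rankings[label] = imp.global_ranking()
    except Exception as exc:
        if out is not None:
            bundle.write(out)
            (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if out is not None:
        bundle.write(out)
    return bundle
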