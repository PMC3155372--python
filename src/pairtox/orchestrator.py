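"""End-to-end pipeline runner.

Wires the stages in order (dose_response -> categorize -> som_validate
-> discrimination -> pathway -> clinchem -> susceptible), hands each
stochastic stage its own seed derived from the master seed, and writes
the report tables plus a JSON run summary.  Stages communicate through
typed in-memory results as well as the on-disk TSVs, so each stage can
be re-run on a prior stage's outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pairtox import categorize as cat
from pairtox import clinchem as cc
from pairtox import discrimination as disc
from pairtox import io as ptio
from pairtox import pathway as pw
from pairtox import som_validate as som
from pairtox import susceptible as sus
from pairtox.dose_response import AnalysisConfig, analyze_genes
from pairtox.synthetic_data import SyntheticStudy

STAGES = ("dose_response", "som", "pathway")


def stage_seed(master: int, stage: str) -> int:
    """Independent, reproducible per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_all(study: SyntheticStudy, config: AnalysisConfig | None = None,
            out_dir: str | Path | None = None, seed: int = 0,
            som_config: som.SomConfig | None = None,
            pathway_permutations: int | None = None) -> dict:
    """Run every stage on a study and (optionally) write the report.

    Returns a dict with the per-stage results and a ``manifest``.
    """
    config = config or AnalysisConfig(seed=stage_seed(seed, "dose_response"))
    manifest = RunManifest(config=asdict(config), seed=seed)
    manifest.stage_seeds["dose_response"] = config.seed
    results: dict = {"manifest": manifest}

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as err:  # noqa: BLE001 - stage-named context
            raise StageError(stage, err) from err
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        return out

    ptio.reconcile(study.expression, study.metadata)

    def _markers():
        tested = analyze_genes(study.expression, study.metadata, config)
        return cat.categorize_all(tested, alpha=config.alpha)

    markers = timed("dose_response", _markers)
    results["markers"] = markers
    counts = cat.category_counts(markers["category"])
    candidates = markers.index[markers["category"] != "none"].tolist()

    def _som():
        if not candidates:
            return None
        sc = som_config or som.SomConfig(seed=stage_seed(seed, "som"))
        manifest.stage_seeds["som"] = sc.seed
        profiles = som.build_profiles(study.expression, study.metadata, candidates)
        model = som.train_som(profiles, sc)
        som.label_clusters(model, markers["category"])
        return {"model": model,
                "concordance": som.concordance(markers["category"], model)}

    results["som"] = timed("som", _som)

    def _performance():
        return disc.evaluate_all(study.expression, study.metadata,
                                 markers.loc[candidates, "category"])

    results["performance"] = timed("discrimination", _performance)
    results["performance_summary"] = disc.summarize_performance(results["performance"])

    def _pathways():
        if not study.gene_sets:
            return pd.DataFrame(columns=["set", "size", "categorized_genes", "p",
                                         "tol_specific", "significant"])
        pconf = pw.PathwayConfig(
            n_permutations=pathway_permutations or 2000,
            alpha=config.alpha, seed=stage_seed(seed, "pathway"))
        manifest.stage_seeds["pathway"] = pconf.seed
        cand_sets = pw.filter_candidate_sets(study.gene_sets, markers)
        return pw.analyze_sets(study.expression, study.metadata, cand_sets, pconf)

    results["pathways"] = timed("pathway", _pathways)

    def _clinchem():
        groups = study.groups
        summaries = []
        for analyte in study.clinchem.columns:
            res = cc.anova_from_raw(study.clinchem[analyte],
                                    groups.loc[study.clinchem.index])
            summaries.append({"analyte": analyte, "F": res.F,
                              "df_between": res.df_between,
                              "df_within": res.df_within, "p": res.p})
        return pd.DataFrame(summaries)

    results["clinchem"] = timed("clinchem", _clinchem)

    def _susceptible():
        return sus.analyze_susceptible(study.expression, study.clinchem,
                                       study.groups, markers["category"])

    results["susceptible"] = timed("susceptible", _susceptible)

    conc = results["som"]["concordance"] if results["som"] else None
    summary = ptio.RunSummary(
        config=asdict(config), seed=seed,
        n_genes=int(len(study.expression)),
        n_samples=int(study.expression.shape[1]),
        category_counts=markers["category"].value_counts().to_dict(),
        primary_counts=counts["primary"], ideal_counts=counts["ideal"],
        total_markers=counts["total"], total_ideal=counts["total_ideal"],
        concordance_pct=100 * conc["overall"] if conc else None,
        ideal_concordance_pct=(100 * conc["ideal"]
                               if conc and conc["n_total_ideal"] else None),
    )
    results["summary"] = summary

    if out_dir is not None:
        report = {
            "markers": markers.reset_index(),
            "performance": results["performance"],
            "pathways": results["pathways"],
            "clinchem": results["clinchem"],
            "susceptible": results["susceptible"]["flags"],
            "summary": summary,
        }
        paths = ptio.write_report(report, out_dir)
        manifest.outputs = {k: str(v) for k, v in paths.items()}
    return results
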