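"""End-to-end orchestration of the clonality analysis.

``run_full`` executes simulate -> filter -> differential methylation ->
pair discrimination -> clonality scoring -> clinical rules -> survival on
a simulated study (three matched cohorts plus normals) and on the
packaged in-print fixture tables, writing every result table under one
output directory.  Identical config and seed produce byte-identical
numeric tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import classify_cohort
from .clonality import (
    classify_pairs,
    concordance,
    count_adjacent_pairs,
    distance_group_stats,
    hierarchical_cluster,
    null_distribution,
    score_correlation,
    threshold_consistency,
)
from .discriminate import feature_curve
from .dmp import count_significant, differential_methylation, rank_dmps
from .io import (
    filter_complete_probes,
    load_fixture_tables,
    write_beta_matrix,
)
from .simulate import generate_cohort, study_configs
from .survival import cox_hazard_ratio, logrank_test, time_to_recurrence_comparison

log = logging.getLogger("methclonal")

__all__ = ["run_full", "run_fixture_analysis", "run_simulated_analysis"]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("fixtures")
def run_fixture_analysis(outdir: Path) -> dict:
    """Desk-scale analysis of the packaged printed tables.

    Reproduces the clonality-label bookkeeping: MS-column TR count,
    feasible threshold interval, method concordances, score correlation
    and time-to-recurrence comparisons.
    """
    fx = load_fixture_tables()
    pairs = fx.pairs
    ms = np.array([p.ms_score for p in pairs])
    pis = np.array([p.pis_score for p in pairs])
    ids = [p.pair_id for p in pairs]

    interval = threshold_consistency(ms, [p.label_ms for p in pairs])
    clinical = classify_cohort(fx.ptlr_clinical)
    conc_pis = concordance([p.label_ms for p in pairs], [p.label_pis for p in pairs], ids)
    conc_clin = concordance(
        [p.label_ms for p in pairs], list(clinical["label"]), ids
    )
    corr = score_correlation(ms, pis)
    ttr = time_to_recurrence_comparison(pairs)

    report = {
        "n_pairs": len(pairs),
        "ms_tr_count": sum(p.label_ms == "TR" for p in pairs),
        "tau_feasible": interval.feasible,
        "tau_interval_e4": [interval.lower * 1e4, interval.upper * 1e4],
        "ms_vs_pis_agree": conc_pis.n_agree,
        "ms_vs_pis_disagreements": conc_pis.disagreements,
        "ms_vs_clinical_agree": conc_clin.n_agree,
        "ms_vs_clinical_disagreements": conc_clin.disagreements,
        "score_correlation": corr,
    }
    outdir.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(outdir / "clinical_labels.csv", index=False)
    ttr.to_csv(outdir / "time_to_recurrence_tests.csv", index=False)
    (outdir / "fixture_report.json").write_text(json.dumps(report, indent=2))
    return report


@_stage("simulation")
def run_simulated_analysis(
    outdir: Path,
    seed: int,
    n_probes: int = 3_000,
    feature_grid: tuple[int, ...] = (22, 100),
    write_matrices: bool = False,
) -> dict:
    """Full pipeline on a simulated three-cohort study."""
    outdir.mkdir(parents=True, exist_ok=True)
    configs = study_configs(n_probes=n_probes, seed=seed)
    report: dict = {"seed": seed, "n_probes": n_probes}

    cohorts = {}
    for name, cfg in configs.items():
        data = generate_cohort(cfg)
        cohorts[name] = data
        tag = name.replace("/", "_")
        data.annotation.table.to_csv(outdir / f"{tag}_annotation.csv", index=False)
        data.truth.to_csv(outdir / f"{tag}_truth.csv", index=False)
        data.survival.to_csv(outdir / f"{tag}_survival.csv", index=False)
        if write_matrices:
            write_beta_matrix(data.beta, outdir / f"{tag}_beta.tsv")

    # differential methylation on the progression-signal cohort
    am = cohorts["PT/AM"]
    beta = filter_complete_probes(am.beta)
    dmp = differential_methylation(beta, am.annotation, "PT/AM")
    top = rank_dmps(dmp, 50)
    top.to_csv(outdir / "PT_AM_top_dmps.tsv", sep="\t", index=False)
    report["ptam_significant_dmps"] = count_significant(dmp)

    # pair discrimination feature curve on the same cohort
    curve = feature_curve(beta, am.annotation, "PT/AM", list(feature_grid), c_grid=(1.0,))
    curve.to_csv(outdir / "PT_AM_feature_curve.tsv", sep="\t", index=False)
    report["ptam_best_accuracy"] = float(curve["accuracy"].max())

    # clonality per cohort
    clon = {}
    for name, data in cohorts.items():
        tag = name.replace("/", "_")
        b = filter_complete_probes(data.beta)
        null = null_distribution(b, data.annotation, name)
        pd.DataFrame({"ms_score": null.scores}).to_csv(
            outdir / f"{tag}_null_scores.tsv", sep="\t", index=False
        )
        pairs = data.annotation.complete_pairs(name)
        vals = b.values
        from .clonality import ms_score

        scores = np.array(
            [ms_score(vals[p].to_numpy(), vals[r].to_numpy()) for _, p, r in pairs]
        )
        labels = classify_pairs(scores, null.tau)
        table = pd.DataFrame(
            {
                "pair_id": [pid for pid, _, _ in pairs],
                "ms_score_e4": scores * 1e4,
                "label_ms": labels,
                "truth": list(data.truth["label"]),
            }
        )
        table.to_csv(outdir / f"{tag}_ms_labels.tsv", sep="\t", index=False)
        dendro = hierarchical_cluster(b)
        (outdir / f"{tag}_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        adjacency = count_adjacent_pairs(dendro, data.annotation, name)
        _, dist_tests = distance_group_stats(b, data.annotation, name)
        dist_tests.to_csv(outdir / f"{tag}_distance_tests.tsv", sep="\t", index=False)
        clon[name] = {
            "tau_e4": null.tau * 1e4,
            "n_unrelated": null.n_unrelated,
            "tr_calls": labels.count("TR"),
            "adjacent_pairs": adjacency,
            "truth_tr": int((data.truth["label"] == "TR").sum()),
        }
    report["clonality"] = clon

    # survival on the PT/LR cohort truth groups
    lr = cohorts["PT/LR"].survival
    a = lr[lr["group"] == "TR"]
    b_ = lr[lr["group"] == "NP"]
    if len(a) >= 2 and len(b_) >= 2 and lr["event"].sum() >= 2:
        chi2, p = logrank_test(a, b_)
        report["survival_logrank"] = {"chi2": chi2, "p_value": p}
        try:
            cox = cox_hazard_ratio(lr)
            report["survival_cox_hr"] = cox.hazard_ratio()
        except (RuntimeError, ValueError) as exc:
            report["survival_cox_hr"] = None
            log.warning("Cox fit skipped: %s", exc)

    (outdir / "simulation_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_full(
    outdir: str | Path,
    seed: int = 0,
    n_probes: int = 3_000,
    feature_grid: tuple[int, ...] = (22, 100),
    write_matrices: bool = False,
) -> dict:
    """Run the fixture analysis and the simulated study; write all tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "seed": seed,
        "fixtures": run_fixture_analysis(outdir / "fixtures"),
        "simulation": run_simulated_analysis(
            outdir / "simulation",
            seed=seed,
            n_probes=n_probes,
            feature_grid=feature_grid,
            write_matrices=write_matrices,
        ),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("full run complete: %s", outdir)
    return report
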