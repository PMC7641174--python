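"""End-to-end orchestration: simulate -> score -> select -> train -> evaluate -> survival.

A run reproduces the three-cohort design: a training cohort (GO vs GH)
on which the feature panel is selected and the naive-Bayes model fitted
and cross-validated; a test cohort scored with the frozen model; and a
validation cohort of initially-GH patients (some of whom progress) used
for the progression confusion table and ophthalmopathy-free survival
comparison.  All stochastic stages derive their seeds from one master
seed and the run emits a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .chaos import DistanceParams
from .classify import (
    confusion_stats,
    evaluate,
    hcluster_features,
    loocv,
    nb_train,
    nb_predict,
    rf_importance_select,
    welch_filter,
)
from .io import RepertoireSample
from .simulate import Cohort, SimulationConfig, simulate_cohort, simulate_followup
from .survival import LogrankResult, km_estimate, logrank, records_to_frame, split_by_group
from .tcs import TCSConfig, TCSFeatureMatrix, build_feature_matrix, matrix_to_tsv, sample_tcs_vector


@dataclass
class RunConfig:
    """Everything one pipeline run needs; nested stage configs with defaults."""

    outdir: str | Path = "tcs_run"
    seed: int = 0
    # cohort sizes: (GO, GH, GH_to_GO)
    train_sizes: tuple[int, int, int] = (33, 37, 0)
    test_sizes: tuple[int, int, int] = (10, 20, 0)
    validation_sizes: tuple[int, int, int] = (0, 18, 17)
    clonotypes_per_sample: int = 20_000
    sim_overrides: dict = field(default_factory=dict)
    distance: DistanceParams = field(default_factory=DistanceParams)
    tcs: TCSConfig = field(default_factory=TCSConfig)
    welch_alpha: float = 0.05
    n_trees: int = 1000
    n_selected: int = 13
    threshold: float = 0.5

    def sim_config(self, sizes: tuple[int, int, int], seed_offset: int) -> SimulationConfig:
        n_go, n_gh, n_prog = sizes
        return SimulationConfig(
            n_GO=n_go,
            n_GH=n_gh,
            n_GH_to_GO=n_prog,
            clonotypes_per_sample=self.clonotypes_per_sample,
            master_seed=(self.seed * 7919 + seed_offset) % (2**31 - 1),
            **self.sim_overrides,
        )


def score_cohort(cohort: Cohort, config: RunConfig, universe=None) -> TCSFeatureMatrix:
    """TCS feature matrix of a simulated (or loaded) cohort."""
    vectors = {
        s.sample_id: sample_tcs_vector(s, config.distance, config.tcs) for s in cohort.samples
    }
    return build_feature_matrix(vectors, cohort.labels, universe=universe, config=config.tcs)


def score_samples(
    samples: list[RepertoireSample], labels: dict[str, str], config: RunConfig, universe=None
) -> TCSFeatureMatrix:
    vectors = {s.sample_id: sample_tcs_vector(s, config.distance, config.tcs) for s in samples}
    return build_feature_matrix(vectors, labels, universe=universe, config=config.tcs)


def _progression_label(label: str) -> str:
    return "GO" if label in ("GO", "GH_to_GO") else "GH"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow and write artifacts + manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result: dict[str, Any] = {}

    # --- cohorts (one study population: shared gene usage and signal V-Js) -
    from .simulate import cohort_context

    study_ctx = cohort_context(config.sim_config(config.train_sizes, 0))
    train = simulate_cohort(config.sim_config(config.train_sizes, 1), context=study_ctx)
    test = simulate_cohort(config.sim_config(config.test_sizes, 2), context=study_ctx)
    validation = simulate_cohort(config.sim_config(config.validation_sizes, 3), context=study_ctx)

    # --- TCS feature matrices (test/validation on the training universe) ---
    train_m = score_cohort(train, config)
    universe = train_m.vj_universe
    test_m = score_cohort(test, config, universe=universe)
    val_m = score_cohort(validation, config, universe=universe)
    matrix_to_tsv(train_m, outdir / "train_tcs.tsv")
    matrix_to_tsv(test_m, outdir / "test_tcs.tsv")
    matrix_to_tsv(val_m, outdir / "validation_tcs.tsv")

    # --- feature selection and model --------------------------------------
    welch, filtered = welch_filter(
        train_m.values, train_m.labels, alpha=config.welch_alpha, min_keep=config.n_selected
    )
    selection = rf_importance_select(
        train_m.values, train_m.labels, filtered,
        n_trees=config.n_trees, k=min(config.n_selected, len(filtered)), seed=config.seed,
    )
    model = nb_train(train_m.values[list(selection.selected)], train_m.labels)
    model.to_json(outdir / "model.json")
    result["n_universe"] = len(universe)
    result["n_filtered"] = len(filtered)
    result["selected_vjs"] = list(selection.selected)
    result["signal_vjs"] = list(train.signal_vjs)
    result["n_recovered"] = len(set(selection.selected) & set(train.signal_vjs))

    # --- training LOOCV and test evaluation -------------------------------
    cv = loocv(train_m.values, train_m.labels, selection.selected, threshold=config.threshold)
    test_eval = evaluate(model, test_m.values, test_m.labels, threshold=config.threshold)
    for name, ev in (("loocv", cv), ("test", test_eval)):
        result[f"{name}_auc"] = ev.auc
        result[f"{name}_sensitivity"] = ev.sensitivity
        result[f"{name}_specificity"] = ev.specificity
        ev.roc.to_csv(outdir / f"{name}_roc.tsv", sep="\t", index=False)

    order, cut = hcluster_features(train_m.values, selection.selected)
    pd.DataFrame({"sample_id": order}).assign(
        cluster=[cut[train_m.sample_ids.index(s)] for s in order]
    ).to_csv(outdir / "train_clustering.tsv", sep="\t", index=False)

    # --- validation: progression prediction + survival --------------------
    val_scores = nb_predict(model, val_m.values)
    predicted = ["predicted_GO" if s >= config.threshold else "predicted_GH" for s in val_scores]
    truth = [_progression_label(l) for l in val_m.labels]
    tp = sum(p == "predicted_GO" and t == "GO" for p, t in zip(predicted, truth))
    fp = sum(p == "predicted_GO" and t == "GH" for p, t in zip(predicted, truth))
    tn = sum(p == "predicted_GH" and t == "GH" for p, t in zip(predicted, truth))
    fn = sum(p == "predicted_GH" and t == "GO" for p, t in zip(predicted, truth))
    sens, spec = confusion_stats(tp, fp, tn, fn)
    result.update(
        validation_tp=tp, validation_fp=fp, validation_tn=tn, validation_fn=fn,
        validation_sensitivity=sens, validation_specificity=spec,
    )

    assignments = pd.DataFrame(
        {"sample_id": val_m.sample_ids, "label": val_m.labels.to_numpy(), "group": predicted}
    )
    records = simulate_followup(assignments, config.sim_config(config.validation_sizes, 3), seed=config.seed + 11)
    groups = split_by_group(records)
    records_to_frame(records).to_csv(outdir / "validation_followup.tsv", sep="\t", index=False)
    if len(groups) == 2 and any(r.event for r in records):
        a, b = (groups[g] for g in sorted(groups))
        lr: LogrankResult = logrank(a, b)
        result["logrank_chi2"] = lr.chi2
        result["logrank_p"] = lr.p
        for g, recs in groups.items():
            km_estimate(recs).to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
    progression_times = [r.time for r in records if r.event]
    result["n_progression_events"] = len(progression_times)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "config_hash": hashlib.sha256(json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "results": {k: v for k, v in result.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return result


def recovery_experiment(
    seed: int,
    train_sizes: tuple[int, int, int] = (33, 37, 0),
    test_sizes: tuple[int, int, int] = (10, 20, 0),
    clonotypes_per_sample: int = 5000,
    subsample_cap: int = 2000,
    n_trees: int = 1000,
    k: int = 13,
) -> dict[str, Any]:
    """Planted-signal recovery: simulate train/test cohorts from one study
    population, run the selection + naive-Bayes workflow, and report LOOCV
    AUC, held-out test AUC and how many of the planted signal V-Js the
    selection recovered."""
    from .simulate import cohort_context

    config = RunConfig(
        seed=seed,
        train_sizes=train_sizes,
        test_sizes=test_sizes,
        clonotypes_per_sample=clonotypes_per_sample,
        distance=DistanceParams(subsample_cap=subsample_cap),
        n_trees=n_trees,
        n_selected=k,
    )
    ctx = cohort_context(config.sim_config(train_sizes, 0))
    train = simulate_cohort(config.sim_config(train_sizes, 1), context=ctx)
    test = simulate_cohort(config.sim_config(test_sizes, 2), context=ctx)
    train_m = score_cohort(train, config)
    test_m = score_cohort(test, config, universe=train_m.vj_universe)
    _, filtered = welch_filter(train_m.values, train_m.labels, min_keep=k)
    selection = rf_importance_select(
        train_m.values, train_m.labels, filtered, n_trees=n_trees, k=k, seed=seed
    )
    cv = loocv(train_m.values, train_m.labels, selection.selected)
    model = nb_train(train_m.values[list(selection.selected)], train_m.labels)
    test_eval = evaluate(model, test_m.values, test_m.labels)
    return {
        "n_train": len(train.samples),
        "n_test": len(test.samples),
        "loocv_auc": cv.auc,
        "test_auc": test_eval.auc,
        "selected": list(selection.selected),
        "signal_vjs": list(ctx.signal_vjs),
        "n_recovered": len(set(selection.selected) & set(ctx.signal_vjs)),
    }


def permutation_null_experiment(
    seed: int,
    n_per_class: int = 100,
    clonotypes_per_sample: int = 2000,
    n_perm: int = 20,
    subsample_cap: int = 2000,
) -> list[float]:
    """Chance-level calibration: LOOCV AUCs on label-permuted null cohorts.

    The cohort is simulated without any planted class effect (zero
    penetrance) and the feature panel is fixed a priori (the designated
    signal V-Js), so each permuted AUC is an unbiased draw from the
    chance distribution.  Permuting a cohort that does carry planted
    signal instead leaves the panel features strongly mutually
    correlated, and random label imbalance over that one latent factor
    widens the AUC spread well beyond the Mann-Whitney null."""
    from .classify import permutation_null_aucs
    from .simulate import SimulationConfig

    sim = SimulationConfig(
        n_GO=n_per_class,
        n_GH=n_per_class,
        clonotypes_per_sample=clonotypes_per_sample,
        effect_penetrance=0.0,
        master_seed=seed,
    )
    cohort = simulate_cohort(sim)
    config = RunConfig(seed=seed, distance=DistanceParams(subsample_cap=subsample_cap))
    matrix = score_cohort(cohort, config)
    panel = [vj for vj in cohort.signal_vjs if vj in matrix.vj_universe]
    return permutation_null_aucs(
        matrix.values, matrix.labels, panel, n_perm=n_perm, seed=seed
    )


def progression_split_experiment(seed: int, n_gh: int = 18, n_progressor: int = 17) -> dict[str, Any]:
    """Follow-up simulation for a validation-style cohort split by
    progression status; returns the log-rank comparison."""
    from .simulate import SimulationConfig

    assignments = pd.DataFrame(
        {
            "sample_id": [f"v{i}" for i in range(n_progressor + n_gh)],
            "label": ["GH_to_GO"] * n_progressor + ["GH"] * n_gh,
            "group": ["predicted_GO"] * n_progressor + ["predicted_GH"] * n_gh,
        }
    )
    records = simulate_followup(assignments, SimulationConfig(master_seed=seed), seed=seed)
    groups = split_by_group(records)
    lr = logrank(groups["predicted_GO"], groups["predicted_GH"])
    times = [r.time for r in records if r.event]
    return {"chi2": lr.chi2, "p": lr.p, "n_events": len(times), "event_times": times}


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj
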