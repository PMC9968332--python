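"""End-to-end experiment orchestration.

One experiment = simulate (or ingest) a matched cohort, then for each of
``n_repeats`` seeded replicates: stratified train/holdout split, per-level
degenerate-gene filtering, normalization of every (method, titration
level) cell, supervised evaluation on both platform-pure holdouts, and
PCA projection-reconstruction scoring.  Undefined cells (TDM at 100%
RNA-seq, QN (CN) at 0/100%) are skipped with a logged reason; partial
failures are recorded per cell and the run continues.

Outputs are long-format TSV tables (one metric row per cell) plus a JSON
manifest recording the config echo and every derived seed, sufficient to
reproduce any single cell in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .data import (ExpressionMatrix, LabelTable, MatchedPairSet,
                   filter_degenerate_genes, intersect_genes)
from .reconstruction import fit_pca, project_reconstruct, repredict
from .simulate import SyntheticConfig, generate
from .supervised import (MetricsRecord, cohen_kappa, delta_kappa,
                         one_vs_all_metrics, predict_labels, predict_scores,
                         summarize, train_classifier)
from .titration import (LEVELS, METHODS, MethodUnavailable, TitrationPlan,
                        audit_bundle, make_bundle, make_plan,
                        rnaseq_filter_subsets)

logger = logging.getLogger("xplatnorm")


@dataclass
class RunConfig:
    """Configuration of one full repeated experiment."""

    methods: Sequence[str] = METHODS
    levels: Sequence[int] = LEVELS
    classifiers: Sequence[str] = ("lasso", "svm", "rf")
    tasks: Sequence[str] = ("subtype",)
    n_repeats: int = 10
    master_seed: int = 0
    n_components: int = 50
    simulation: Optional[SyntheticConfig] = None
    array_path: Optional[str] = None
    rnaseq_path: Optional[str] = None
    labels_path: Optional[str] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.simulation is None and not (
                self.array_path and self.rnaseq_path and self.labels_path):
            self.simulation = SyntheticConfig()


def build_matched_pair(array: ExpressionMatrix, rnaseq: ExpressionMatrix,
                       patient_ids: Optional[Sequence[str]] = None,
                       ) -> MatchedPairSet:
    """Pair two ingested matrices by patient.

    Columns may be patient ids directly (identical on both platforms) or
    platform-suffixed sample ids ``<patient>.A`` / ``<patient>.R``.
    """
    if set(array.samples) == set(rnaseq.samples):
        mapping = {p: (p, p) for p in array.samples}
    else:
        strip = lambda s, suf: s[:-len(suf)] if s.endswith(suf) else s
        arr_p = {strip(s, ".A"): s for s in array.samples}
        seq_p = {strip(s, ".R"): s for s in rnaseq.samples}
        if set(arr_p) != set(seq_p):
            raise ValueError("cannot match array and RNA-seq samples by patient")
        mapping = {p: (arr_p[p], seq_p[p]) for p in arr_p}
    if patient_ids is None:
        patient_ids = sorted(mapping)
    return intersect_genes(array, rnaseq, mapping, patient_ids)


def evaluate_bundle(bundle, plan: TitrationPlan, labels: LabelTable,
                    classifiers: Sequence[str], tasks: Sequence[str],
                    repeat: int, seed: int,
                    n_components: int = 50,
                    do_reconstruction: bool = True,
                    ) -> Tuple[List[MetricsRecord], List[dict]]:
    """Score one normalized cell: classifiers on both holdouts, plus PCA
    reconstruction MASE and re-prediction kappa."""
    records: List[MetricsRecord] = []
    recon_rows: List[dict] = []
    train_y = labels.subtypes_of(list(bundle.train.columns))
    holdouts = [("array", bundle.array_holdout)]
    if bundle.rnaseq_holdout is not None:
        holdouts.append(("rnaseq", bundle.rnaseq_holdout))
    hold_y = labels.subtypes_of(plan.holdout_patients)

    subtype_models: Dict[str, object] = {}
    if "subtype" in tasks:
        for family in classifiers:
            model = train_classifier(bundle.train, train_y, family, seed)
            subtype_models[family] = model
            for platform, frame in holdouts:
                pred = predict_labels(model, frame)
                classes, scores = predict_scores(model, frame)
                auc, sens, spec = one_vs_all_metrics(hold_y, classes, scores,
                                                     pred)
                records.append(MetricsRecord(
                    classifier=family, method=bundle.method,
                    level=bundle.level, holdout_platform=platform,
                    task="subtype", kappa=cohen_kappa(hold_y, pred).kappa,
                    auc=auc, sensitivity=sens, specificity=spec,
                    repeat=repeat, seed=seed))

    if "mutation" in tasks and labels.mutation:
        for gene, calls in labels.mutation.items():
            tr_p = [p for p in bundle.train.columns if p in calls]
            ho_p = [p for p in plan.holdout_patients if p in calls]
            if len(tr_p) < 10 or len(ho_p) < 2:
                continue
            mut_tr = np.asarray([calls[p] for p in tr_p])
            mut_ho = np.asarray([calls[p] for p in ho_p])
            if len(np.unique(mut_tr)) < 2 or len(np.unique(mut_ho)) < 2:
                continue
            sub_tr = labels.subtypes_of(tr_p)
            for family in classifiers:
                for platform, frame in holdouts:
                    delta, k_true, _ = delta_kappa(
                        bundle.train[tr_p], frame[ho_p], mut_tr, mut_ho,
                        sub_tr, family, null_seed=seed + 7919, cv_seed=seed)
                    records.append(MetricsRecord(
                        classifier=family, method=bundle.method,
                        level=bundle.level, holdout_platform=platform,
                        task="mutation", kappa=k_true, delta_kappa=delta,
                        auc=float("nan"), sensitivity=float("nan"),
                        specificity=float("nan"), repeat=repeat, seed=seed))

    if do_reconstruction:
        model = fit_pca(bundle.train, n_components)
        for platform, frame in holdouts:
            result = project_reconstruct(frame, model)
            row = dict(method=bundle.method, level=bundle.level,
                       holdout_platform=platform, repeat=repeat, seed=seed,
                       median_mase=float(result.mase.median(skipna=True)),
                       n_constant_genes=result.n_constant_genes,
                       n_components=model.n_components)
            for family, clf in subtype_models.items():
                row[f"recon_kappa_{family}"] = repredict(
                    result.reconstructed, clf, hold_y)
            recon_rows.append(row)
    return records, recon_rows


def run_experiment(config: RunConfig) -> dict:
    """Run the full repeated titration experiment.

    Returns a dict with the metrics table, reconstruction table, summary
    table, manifest, and logged skips; writes them under
    ``config.out_dir`` when set.
    """
    records: List[MetricsRecord] = []
    recon_rows: List[dict] = []
    skips: List[dict] = []
    repeat_seeds = [config.master_seed + r for r in range(config.n_repeats)]

    for repeat, seed in enumerate(repeat_seeds):
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=seed)
            pair, labels = generate(sim)
        else:
            from .data import read_expression_matrix, read_label_table
            array = read_expression_matrix(config.array_path, "array")
            rnaseq = read_expression_matrix(config.rnaseq_path, "rnaseq")
            labels = read_label_table(config.labels_path)
            pair = build_matched_pair(array, rnaseq, labels.patient_ids)
        plan = make_plan(pair, labels, seed, levels=config.levels)
        filtered = filter_degenerate_genes(pair,
                                           rnaseq_filter_subsets(pair, plan))
        for method in config.methods:
            for level in config.levels:
                try:
                    bundle = make_bundle(filtered, plan, level, method)
                except MethodUnavailable as exc:
                    logger.info("skip repeat=%d method=%s level=%d: %s",
                                repeat, method, level, exc)
                    skips.append(dict(repeat=repeat, method=method,
                                      level=level, reason=str(exc)))
                    continue
                except Exception as exc:  # partial failure: record, continue
                    logger.warning("cell failed repeat=%d method=%s "
                                   "level=%d: %s", repeat, method, level, exc)
                    skips.append(dict(repeat=repeat, method=method,
                                      level=level, reason=f"error: {exc}"))
                    continue
                audit_bundle(bundle, filtered, plan)
                recs, recon = evaluate_bundle(
                    bundle, plan, labels, config.classifiers, config.tasks,
                    repeat, seed, config.n_components)
                records.extend(recs)
                recon_rows.extend(recon)

    metrics = pd.DataFrame([r.as_dict() for r in records])
    recon = pd.DataFrame(recon_rows)
    summaries = summarize(records) if records else pd.DataFrame()
    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "repeat_seeds": repeat_seeds,
        "methods": list(config.methods),
        "levels": list(config.levels),
        "classifiers": list(config.classifiers),
        "tasks": list(config.tasks),
        "n_repeats": config.n_repeats,
        "n_components": config.n_components,
        "simulation": (dataclasses.asdict(config.simulation)
                       if config.simulation is not None else None),
        "inputs": {"array": config.array_path, "rnaseq": config.rnaseq_path,
                   "labels": config.labels_path},
        "skips": skips,
        "nested_titration": True,
    }
    result = {"metrics": metrics, "reconstruction": recon,
              "summaries": summaries, "manifest": manifest, "skips": skips}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        recon.to_csv(out / "recon_metrics.tsv", sep="\t", index=False)
        summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result
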