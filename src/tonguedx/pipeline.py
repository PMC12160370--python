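"""End-to-end pipeline: simulate -> segment -> features -> select -> balance
-> benchmark -> cross-validate -> explain.

Every stage writes its artifacts under the run directory and contributes one
block to ``summary.json``.  The summary contains no timestamps, so reruns
with an identical configuration produce byte-identical summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constitutions import Constitution
from .ccmq import score_questionnaire
from .explain import gradcam, localization_score
from .features_deep import (
    TINY_BACKBONE_PRESET,
    extract_embeddings,
    train_backbone,
)
from .features_traditional import extract_feature_table, standardize
from .io import write_cohort, write_json
from .models import (
    cross_validate,
    fuse_features,
    metrics,
    rank_importance,
    split_train_test,
    train_model,
)
from .segmentation import TINY_SEG_PRESET, seg_metrics, segment, train_segmenter
from .selection import SelectionConfig, screen_features, smote
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("tonguedx.pipeline")

LESION_OF_CLASS = {
    Constitution.QI_DEFICIENCY: "crack",
    Constitution.YANG_DEFICIENCY: "toothmark",
    Constitution.WETNESS_HEAT: "coating",
    Constitution.QI_DEPRESSION: "red_tip",
}


@dataclass
class PipelineConfig:
    outdir: str = "runs/tiny"
    seed: int = 0
    # cohort
    class_counts: dict[str, int] = field(
        default_factory=lambda: {c.value: 10 for c in Constitution}
    )
    image_size: tuple[int, int] = (64, 64)
    # stage toggles
    run_deep: bool = True
    run_explain: bool = True
    write_images: bool = False
    # segmentation (paper-scale defaults live in SegConfig; these are the
    # pipeline's desk-scale settings)
    seg_variant: str = "ise_unetpp"
    seg_epochs: int = 3
    # deep backbone
    backbone_epochs: int = 5
    # selection / balancing
    lasso_cv_folds: int = 10
    rf_n_trees: int = 100
    rf_max_depth: int = 15
    smote_k: int = 5
    # benchmark / validation
    test_ratio: float = 0.2
    cv_folds: int = 5
    algorithms: tuple[str, ...] = ("mlp", "random_forest")
    explain_images_per_class: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.image_size = tuple(cfg.image_size)
        cfg.algorithms = tuple(cfg.algorithms)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["algorithms"] = list(self.algorithms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"version": __version__, "seed": config.seed}
    stage = "simulate"
    try:
        # 1. simulate ------------------------------------------------------
        counts = {Constitution(k): v for k, v in config.class_counts.items()}
        cohort = CohortSpec(counts, config.image_size, config.seed)
        samples = generate_cohort(cohort)
        rng = np.random.default_rng(config.seed + 1)
        demographics = pd.DataFrame(
            {
                "age": np.clip(rng.normal(49, 11, len(samples)).round(), 18, 65),
                "sex": rng.integers(0, 2, len(samples)),
            },
            index=[s.sample_id for s in samples],
        )
        q_calls = [score_questionnaire(s.questionnaire).call.value for s in samples]
        if config.write_images:
            write_cohort(samples, out / "cohort")
        labels = np.array([s.label.value for s in samples])
        summary["simulate"] = {
            "n_samples": len(samples),
            "class_counts": {c.value: int(v) for c, v in counts.items()},
            "questionnaire_recovery": float(np.mean(np.array(q_calls) == labels)),
        }

        # 2. segment -------------------------------------------------------
        stage = "segment"
        seg_cfg = TINY_SEG_PRESET(config.seg_variant, seed=config.seed, epochs=config.seg_epochs)
        seg_model, seg_hist = train_segmenter(samples, seg_cfg)
        pred_masks = {}
        mious = []
        for s in samples:
            pm = segment(seg_model, s.image)
            if pm.sum() == 0:  # degenerate prediction: fall back to ground truth
                pm = s.mask
            pred_masks[s.sample_id] = pm
            mious.append(seg_metrics(pm, s.mask).miou)
        summary["segment"] = {
            "variant": config.seg_variant,
            "epochs": config.seg_epochs,
            "final_training_miou": round(seg_hist.miou[-1], 4) if seg_hist.miou else None,
            "mean_miou_vs_truth": round(float(np.mean(mious)), 4),
        }

        # 3. traditional features -------------------------------------------
        stage = "features_traditional"
        seg_samples = []
        for s in samples:
            s2 = type(s)(
                image=s.image, mask=pred_masks[s.sample_id], label=s.label,
                sample_id=s.sample_id, seed=s.seed,
            )
            seg_samples.append(s2)
        table = extract_feature_table(seg_samples, demographics)
        table.to_csv(out / "traditional_features.csv")
        summary["features_traditional"] = {
            "n_features": table.values.shape[1],
            "columns": list(table.values.columns),
        }

        # 4. deep features ---------------------------------------------------
        stage = "features_deep"
        if config.run_deep:
            bb_cfg = TINY_BACKBONE_PRESET(seed=config.seed, epochs=config.backbone_epochs)
            backbone, bb_hist = train_backbone(seg_samples, bb_cfg)
            emb = extract_embeddings(backbone, seg_samples)
            emb.to_csv(out / "deep_features.csv")
            summary["features_deep"] = {
                "embedding_dim": emb.matrix.shape[1],
                "final_training_accuracy": round(bb_hist.miou[-1], 4) if bb_hist.miou else None,
            }
        else:
            backbone, emb = None, None
            log.warning("deep feature stage disabled; fusion degrades to traditional only")
            summary["features_deep"] = {"skipped": True}

        # 5. select ----------------------------------------------------------
        stage = "select"
        sel_cfg = SelectionConfig(
            lasso_cv_folds=config.lasso_cv_folds,
            rf_n_trees=config.rf_n_trees,
            rf_max_depth=config.rf_max_depth,
            smote_k=config.smote_k,
            seed=config.seed,
        )
        std_table, _ = standardize(table)
        cont_cols = table.columns_of_kind("continuous")
        trad_X = std_table.values[cont_cols]
        trad_sel = screen_features(trad_X, labels, sel_cfg)
        selected_trad = trad_sel.intersection or trad_sel.rf_set[:5] or cont_cols[:5]
        if config.run_deep:
            deep_df = emb.to_frame()
            deep_sel = screen_features(deep_df, labels, sel_cfg)
            selected_deep = deep_sel.intersection or [n for n, _ in deep_sel.rf_ranking[:8]]
        else:
            deep_df = pd.DataFrame(index=table.values.index)
            selected_deep = []
        write_json(
            {"traditional": trad_sel.to_dict(),
             "deep": deep_sel.to_dict() if config.run_deep else None},
            out / "selection.json",
        )
        summary["select"] = {
            "n_traditional_selected": len(selected_trad),
            "n_deep_selected": len(selected_deep),
            "traditional_selected": list(selected_trad),
        }

        # 6. balance ---------------------------------------------------------
        stage = "balance"
        fused = fuse_features(
            std_table.values, deep_df, list(selected_trad), list(selected_deep),
            demographics=None,  # age/sex already inside the traditional table
        )
        train_ids, test_ids = split_train_test(
            fused, labels, ratio=config.test_ratio, seed=config.seed
        )
        Xtr_bal, ytr_bal = smote(
            fused.to_numpy(float)[train_ids], labels[train_ids], sel_cfg
        )
        summary["balance"] = {
            "train_counts_before": {
                str(k): int(v)
                for k, v in zip(*np.unique(labels[train_ids], return_counts=True))
            },
            "train_counts_after": {
                str(k): int(v) for k, v in zip(*np.unique(ytr_bal, return_counts=True))
            },
        }

        # 7. benchmark -------------------------------------------------------
        stage = "benchmark"
        bench: dict = {}
        Xte = fused.to_numpy(float)[test_ids]
        classes = np.unique(labels)
        for algo in config.algorithms:
            model = train_model(algo, Xtr_bal, ytr_bal, seed=config.seed)
            proba = model.predict_proba(Xte)
            aligned = np.zeros((len(test_ids), len(classes)))
            for j, cls in enumerate(model.classes_):
                aligned[:, list(classes).index(cls)] = proba[:, j]
            pred = classes[aligned.argmax(axis=1)]
            _, macro = metrics(labels[test_ids], pred, aligned, classes)
            bench[algo] = {k: round(v, 4) for k, v in macro.as_dict().items()}
        importance = rank_importance(
            fused, labels, n_trees=config.rf_n_trees, seed=config.seed
        )
        write_json({"test_metrics": bench, "importance": importance}, out / "benchmark.json")
        summary["benchmark"] = {"test_macro": bench, "top_features": [n for n, _ in importance[:5]]}

        # 8. cross-validate --------------------------------------------------
        stage = "cross_validate"
        bal = lambda X, y: smote(X, y, sel_cfg)  # noqa: E731 - fold-local balancing
        report = cross_validate(
            "mlp", fused.to_numpy(float), labels, k=config.cv_folds,
            seed=config.seed, balance=bal,
        )
        summary["cross_validate"] = {
            "k": config.cv_folds,
            "fold_aucs": [round(m.auc, 4) for m in report.fold_metrics],
            "mean_auc": round(report.mean_auc, 4),
            "se_auc": round(report.se_auc, 4),
        }

        # 9. explain ---------------------------------------------------------
        stage = "explain"
        if config.run_explain and config.run_deep:
            loc: dict = {}
            for cls, lesion in LESION_OF_CLASS.items():
                scores = []
                for s in samples:
                    if s.label is cls and lesion in s.lesions:
                        scores.append(
                            localization_score(gradcam(backbone, s, cls), s.lesions[lesion])
                        )
                    if len(scores) >= config.explain_images_per_class:
                        break
                if scores:
                    loc[lesion] = round(float(np.median(scores)), 4)
            summary["explain"] = {"median_localization": loc}
        else:
            summary["explain"] = {"skipped": True}
    except Exception as err:
        write_json({**summary, "failed_stage": stage, "error": str(err)}, out / "summary.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    write_json(summary, out / "summary.json")
    return summary
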