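#!/usr/bin/env python
"""Stage 5: the cross-validated classification experiment grid.

    python analysis/05_classification_experiments.py
        [--features results/features.csv] [--out results/classification]
        [--seed 0] [--full-grid]

By default runs the headline arms (univariate selection and all-features
PCA, AdaBoost, both tasks); ``--full-grid`` sweeps all five classifiers,
three feature sets, both reductions and the three oversampling modes.
Writes one JSON report per arm plus a ``summary.csv``.
"""

import argparse
import dataclasses
import itertools
import json
from pathlib import Path

import pandas as pd

from pedmri.classify import ExperimentConfig, train_and_evaluate


def default_arms(seed: int) -> list[ExperimentConfig]:
    return [
        ExperimentConfig(task=task, reduction=red, classifier="adaboost",
                         seed=seed)
        for task in ("type", "grade") for red in ("univariate", "pca")
    ]


def full_grid(seed: int) -> list[ExperimentConfig]:
    arms = []
    for task, fs, red, clf, ov in itertools.product(
        ("type", "grade"), ("all", "roi", "wb"), ("univariate", "pca"),
        ("adaboost", "random_forest", "svm", "knn", "neural_net"),
        ("none", "replicate", "smote"),
    ):
        arms.append(ExperimentConfig(task=task, feature_set=fs, reduction=red,
                                     classifier=clf, oversampling=ov,
                                     seed=seed))
    return arms


def arm_name(cfg: ExperimentConfig) -> str:
    return "_".join([cfg.task, cfg.feature_set, cfg.reduction,
                     cfg.classifier, cfg.oversampling])


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path,
                        default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/classification"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--full-grid", action="store_true")
    args = parser.parse_args()

    table = pd.read_csv(args.features, index_col="subject_id")
    arms = full_grid(args.seed) if args.full_grid else default_arms(args.seed)
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for cfg in arms:
        name = arm_name(cfg)
        report = train_and_evaluate(table, cfg)
        payload = {
            "config": dataclasses.asdict(cfg),
            "bar": report.bar,
            "f_stat": report.f_stat,
            "precision_macro": report.precision_macro,
            "per_class": report.per_class,
            "confusion": report.confusion.to_dict(),
            "fold_details": report.fold_details,
        }
        (args.out / f"{name}.json").write_text(json.dumps(payload, indent=2,
                                                          default=str) + "\n")
        rows.append({"arm": name, "task": cfg.task, "bar": report.bar,
                     "f_stat": report.f_stat,
                     "precision_macro": report.precision_macro})
        print(f"{name}: BAR = {report.bar:.1f}%, F = {report.f_stat:.2f}")
    summary = pd.DataFrame(rows).sort_values(["task", "bar"],
                                             ascending=[True, False])
    summary.to_csv(args.out / "summary.csv", index=False)
    print(f"summary: {args.out / 'summary.csv'}")


if __name__ == "__main__":
    main()
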