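#!/usr/bin/env python
"""Stage 6: two-feature perturbation analysis around the ADC ROI mean.

    python analysis/06_perturbation.py [--features results/features.csv]
        [--out results/perturbation.csv] [--task grade] [--seed 0]

Pairs every other feature of the chosen family with the base feature, runs
the cross-validated classifier on each pair and ranks partners by
between-group average precision.
"""

import argparse
from pathlib import Path

import pandas as pd

from pedmri.classify import ExperimentConfig, perturbation_analysis


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path,
                        default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/perturbation.csv"))
    parser.add_argument("--task", choices=["grade", "type"], default="grade")
    parser.add_argument("--family", choices=["roi", "wb"], default="roi")
    parser.add_argument("--base-feature", default="ADC_ROI_mean")
    parser.add_argument("--classifier", default="adaboost")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    table = pd.read_csv(args.features, index_col="subject_id")
    cfg = ExperimentConfig(task=args.task, classifier=args.classifier,
                           reduction="none", seed=args.seed)
    ranking = perturbation_analysis(table, cfg, base_feature=args.base_feature,
                                    family=args.family)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    ranking.to_csv(args.out)
    print(ranking.head(10).to_string())
    print(f"perturbation ranking: {args.out}")


if __name__ == "__main__":
    main()
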