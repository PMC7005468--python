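#!/usr/bin/env python
"""Stage 1: simulate the phantom cohort and write volumes + manifest.

    python analysis/01_simulate_cohort.py [--config cohort.yaml]
        [--out results/cohort] [--seed N]

The default configuration is a desk-scale cohort (22/17/10 subjects on a
24x24x16 grid).  Pass ``--small`` for a quick 3/3/3 run on a 12x12x10 grid.
All downstream stages read only the manifest this stage writes.
"""

import argparse
import dataclasses
from pathlib import Path

from pedmri.io import config_hash, save_cohort_config, save_subject, write_manifest
from pedmri.synthetic import CohortConfig, iter_cohort

SMALL = dict(n_per_class=(3, 3, 3), grid_shape=(12, 12, 10),
             voxel_size_mm=(3.0, 3.0, 3.0))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=None,
                        help="Cohort YAML; defaults are used when omitted.")
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--small", action="store_true",
                        help="Quick 3/3/3 cohort on a small grid.")
    args = parser.parse_args()

    if args.config is not None:
        from pedmri.io import load_cohort_config
        cfg = load_cohort_config(args.config)
    else:
        cfg = CohortConfig(**SMALL) if args.small else CohortConfig()
    if args.seed is not None:
        cfg = dataclasses.replace(cfg, seed=args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    save_cohort_config(cfg, args.out / "cohort.yaml")
    tag = f"pedmri cfg={config_hash(cfg)} seed={cfg.seed}"

    rows = []
    for subject in iter_cohort(cfg):
        rows.append(save_subject(subject, args.out / "volumes", descrip=tag))
        print(f"wrote {subject.subject_id} ({subject.label})")
    write_manifest(rows, args.out / "manifest.csv")
    print(f"manifest: {args.out / 'manifest.csv'} ({len(rows)} subjects)")


if __name__ == "__main__":
    main()
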