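#!/usr/bin/env python
"""Stage 2: quantify every subject in a cohort manifest.

    python analysis/02_quantify_maps.py [--manifest results/cohort/manifest.csv]
        [--out results/maps]

Writes per-subject ADC, UCBV, K2 and CCBV maps (NAWM-normalised) plus the
QC mask, and a ``maps_manifest.csv`` pointing at them.
"""

import argparse
from pathlib import Path

import pandas as pd

from pedmri.io import load_manifest, load_subject, quantify_to_maps, write_volume

MAP_NAMES = ["ADC", "UCBV", "K2", "CCBV", "qc"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--manifest", type=Path,
                        default=Path("results/cohort/manifest.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/maps"))
    args = parser.parse_args()

    manifest = load_manifest(args.manifest)
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for _, row in manifest.iterrows():
        subject = load_subject(row)
        maps = quantify_to_maps(subject)
        out_row = {"subject_id": subject.subject_id, "label": subject.label}
        for name in MAP_NAMES:
            p = args.out / f"{subject.subject_id}_{name}.nii.gz"
            write_volume(maps[name].astype(float), p, subject.voxel_size_mm)
            out_row[name] = str(p)
        rows.append(out_row)
        print(f"quantified {subject.subject_id}")
    pd.DataFrame(rows).to_csv(args.out / "maps_manifest.csv", index=False)
    print(f"maps manifest: {args.out / 'maps_manifest.csv'}")


if __name__ == "__main__":
    main()
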