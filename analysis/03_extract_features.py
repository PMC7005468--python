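#!/usr/bin/env python
"""Stage 3: build the subjects x 33-features table from quantified maps.

    python analysis/03_extract_features.py
        [--manifest results/cohort/manifest.csv]
        [--maps results/maps/maps_manifest.csv]
        [--out results/features.csv]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pedmri.features import build_feature_table, feature_schema
from pedmri.io import load_manifest, read_volume


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--manifest", type=Path,
                        default=Path("results/cohort/manifest.csv"))
    parser.add_argument("--maps", type=Path,
                        default=Path("results/maps/maps_manifest.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = parser.parse_args()

    manifest = load_manifest(args.manifest).set_index("subject_id")
    maps_manifest = pd.read_csv(args.maps).set_index("subject_id")

    subject_maps, subject_masks, labels = {}, {}, {}
    for sid, mrow in maps_manifest.iterrows():
        crow = manifest.loc[sid]
        subject_maps[sid] = {m: read_volume(mrow[m])
                             for m in ("ADC", "UCBV", "K2", "CCBV")}
        subject_masks[sid] = {
            "roi": read_volume(crow["roi_mask"]) > 0.5,
            "brain": read_volume(crow["brain_mask"]) > 0.5,
            "qc": read_volume(mrow["qc"]) > 0.5,
        }
        labels[sid] = mrow["label"]
    voxel = (float(manifest["voxel_x_mm"].iloc[0]),
             float(manifest["voxel_y_mm"].iloc[0]),
             float(manifest["voxel_z_mm"].iloc[0]))

    table = build_feature_table(subject_maps, subject_masks, labels, voxel)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out)
    args.out.with_suffix(".meta.json").write_text(
        json.dumps(feature_schema(), indent=2) + "\n"
    )
    print(f"features: {args.out} ({len(table)} subjects x "
          f"{table.shape[1] - 2} features)")


if __name__ == "__main__":
    main()
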