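#!/usr/bin/env python
"""Extract texture features from textured phantom volumes.

Builds two-VOI phantoms whose regions carry different sinusoidal textures,
runs the full extraction (resample → discretize → GLCM/GLRL/NGTDM/first
order in 3D and 2.5D), and screens the features for an A-vs-B difference.
Shows that the extractor recovers a known generative texture contrast.
Writes results/phantom_features.csv and results/phantom_screening.csv.
"""

from pathlib import Path

import pandas as pd

from radkinetics import screening, synthetic, textures

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = []
    for seed in range(12):
        spec = synthetic.PhantomSpec(
            grid_shape=(32, 32, 12),
            texture_a=(100.0, 40.0, 4.0),
            texture_b=(100.0, 40.0, 9.0),
            mask_radius_mm=7.0,
            seed=seed,
        )
        vol, mask_a, mask_b = synthetic.generate_textured_phantom(spec)
        for mask, label in ((mask_a, "ORN"), (mask_b, "Control")):
            records.append(
                {
                    "voi_id": f"S{seed}_{label}",
                    "patient_id": f"S{seed}",
                    "label": label,
                    "timepoint_month": 0,
                    "volume": vol,
                    "mask": mask,
                }
            )
    cfg = textures.ExtractionConfig(n_levels=16, nid_neighborhoods=(3, 5))
    table = textures.extract_feature_table(records, cfg, required_months=(0,))
    table.to_csv(OUT / "phantom_features.csv", index=False)

    feats = [
        f
        for f in screening.feature_columns(table)
        if table[f].notna().all() and table[f].std() > 0
    ]
    screen = screening.mann_whitney_screen(table, features=feats)
    screen.sort_values("p").to_csv(OUT / "phantom_screening.csv", index=False)
    top = screen.sort_values("p").head(5)
    n_sig = int(screen["significant"].sum())
    print(f"extracted {len(feats)} usable features from {len(table)} VOIs")
    print(f"{n_sig} features separate the two texture classes at p < 0.05; top 5:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
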