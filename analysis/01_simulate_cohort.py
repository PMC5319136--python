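#!/usr/bin/env python
"""Simulate the study cohort: 10 subjects, paired CT scans ~1 year apart.

Generates the synthetic two-time-point cohort (growth factor 1.15 in
subchondral density, 4% between-subject jitter, 5 HU image noise) and
writes a per-scan inventory plus one example scan as NIfTI so the raw
substrate can be inspected with standard viewers.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from ctoam.synthetic import default_spec, generate_cohort
from ctoam.volume import save_nifti

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20170220

def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = replace(default_spec(), noise_sd=5.0)
    cohort = generate_cohort(10, 1.15, spec, seed=SEED)

    rows = []
    for subj in cohort.subjects:
        for tp, scan in (("t1", subj.t1), ("t2", subj.t2)):
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "timepoint": tp,
                    "jitter_scale": round(subj.scale, 4),
                    "density_scale": round(
                        subj.scale * (1.15 if tp == "t2" else 1.0), 4
                    ),
                    "bone_voxels": int(scan.mask.data.sum()),
                    "hu_min": round(float(scan.volume.voxels.min()), 1),
                    "hu_max": round(float(scan.volume.voxels.max()), 1),
                }
            )
    inv = pd.DataFrame(rows)
    inv.to_csv(OUT / "cohort_inventory.csv", index=False)

    example = cohort.subjects[0].t1
    scratch = Path(__file__).resolve().parent.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    save_nifti(scratch / "S01_t1_volume.nii.gz", example.volume.voxels, example.volume.spacing)
    save_nifti(scratch / "S01_t1_mask.nii.gz", example.mask.data.astype("uint8"),
               example.volume.spacing)

    print(f"simulated {len(cohort.subjects)} subjects x 2 time points")
    print(inv.to_string(index=False))
    print(f"inventory -> {OUT/'cohort_inventory.csv'}; example NIfTI -> scratch/")


if __name__ == "__main__":
    main()
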