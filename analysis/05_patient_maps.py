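#!/usr/bin/env python
"""Map and feature assembly for one synthetic patient.

Runs the full chain (envelope, B-scan, speckle, attenuation, H-scan, texture)
on a single simulated tumor acquisition and verifies the structural counts:
87 parametric maps, 174 regional features, the amplitude/frequency domain
split, and the perturbation-replicate table used by the ICC stability stage.
Writes results/05_patient_features.csv and results/05_map_summary.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from usradiomics.features import (
    assemble_maps,
    feature_schema,
    perturbation_replicates,
    regionize,
)
from usradiomics.speckle import SpeckleWindowSpec
from usradiomics.synth import CohortSpec, PhantomSpec, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
warnings.simplefilter("ignore")

ph = PhantomSpec(depth_extent_cm=1.5, lateral_extent_cm=1.2, focus_depth_cm=1.0)
spec = CohortSpec(n_per_group=1, timepoints=("pre",), phantom=ph,
                  tumor_radius_mm=(4.5, 5.5), seed=505)
pid, tp, label, frame, masks, truth = next(iter(simulate_cohort(spec)))
maps, masks_iso = assemble_maps(frame, masks,
                                speckle_spec=SpeckleWindowSpec(overlap=0.9))
row = regionize(maps, masks_iso)
reps = perturbation_replicates(maps, masks_iso, pixel_mm=frame.line_pitch * 1e3,
                               rng=np.random.default_rng(5))

schema = feature_schema()
summary = pd.DataFrame({
    "quantity": ["parametric_maps", "regional_features", "frequency_domain_maps",
                 "amplitude_domain_maps", "tumor_features", "peri_tumor_features",
                 "icc_replicates"],
    "count": [len(maps), row.size,
              sum(1 for c in schema if c.domain == "frequency") // 2,
              sum(1 for c in schema if c.domain == "amplitude") // 2,
              sum(1 for c in schema if c.region == "tumor"),
              sum(1 for c in schema if c.region == "peri_tumor"),
              len(reps)],
})
row.rename("value").to_csv(OUT / "05_patient_features.csv")
summary.to_csv(OUT / "05_map_summary.csv", index=False)
print(summary.to_string(index=False))
print(f"\nPatient {pid} ({tp}, label {label}): the simulated tumor has larger "
      f"scatterer footprints than background, and its H-scan mean is "
      f"correspondingly lower ({row['hscan_freq|tumor']:.2f} MHz in-tumor vs "
      f"{row['hscan_freq|peri_tumor']:.2f} MHz in the ring); Nakagami shape "
      f"m = {row['nak_m|tumor']:.2f} (tumor) vs {row['nak_m|peri_tumor']:.2f} "
      f"(ring) reflects the sparser in-tumor scattering.")
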