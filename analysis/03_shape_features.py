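#!/usr/bin/env python
"""Condition the FTV masks and extract the 17 3D shape features.

Each raw FTV mask is resampled to 1 mm isotropic voxels, closed with a
5 mm ball, anti-aliased, and stripped of components of 100 voxels or
fewer; the 17 shape features and their T1/T0 ratios are then computed
from the cleaned masks. Degenerate T1 masks yield missing feature
vectors, which downstream imputation fills.
"""

from pathlib import Path

import pandas as pd

from ftvmorph.config import PipelineConfig
from ftvmorph.pipeline import exam_shape_features
from ftvmorph.shape import shape_ratios
from ftvmorph.synthetic import CohortConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
N, SEED = 120, 7


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig(n_patients=N, seed=SEED)
    bundle = simulate_cohort(CohortConfig(n_patients=N, seed=SEED))
    rows = []
    n_missing = 0
    for (e0, e1) in bundle.exams:
        _, f0, _ = exam_shape_features(e0, cfg)
        _, f1, _ = exam_shape_features(e1, cfg)
        n_missing += int(f1.missing)
        row = {"patient_id": e0.patient_id}
        row.update({f"{k}_t0": v for k, v in f0.to_dict().items()})
        row.update({f"{k}_t1": v for k, v in f1.to_dict().items()})
        row.update({f"{k}_ratio": v for k, v in shape_ratios(f0, f1).items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "shape_features.csv", index=False)
    savr = df["surface_area_to_volume_ratio_ratio"].dropna()
    print(f"extracted 51 shape variables for {N} patients "
          f"({n_missing} degenerate T1 masks -> missing vectors)")
    print(f"SA:V T1/T0 ratio: median {savr.median():.2f} "
          f"[{savr.quantile(0.25):.2f}, {savr.quantile(0.75):.2f}]")


if __name__ == "__main__":
    main()
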