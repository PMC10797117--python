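#!/usr/bin/env python
"""Generate one synthetic subject and summarize its ground truth.

Builds the digital lung phantom on both acquisition grids (2D UTE, 3D DCE),
verifies the designed defect fraction, and records the ground-truth observed
T1 per echo time in normal and defect lung.  Writes
results/01_phantom_summary.json; image volumes go to scratch/ (they are
regenerated on demand and not part of the tracked results).
"""

import json
from pathlib import Path

import numpy as np

from lungt1dce import phantom as ph
from lungt1dce.pipeline import RunConfig, make_subject, save_subject, run_subject

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

def main():
    cfg = RunConfig(snr=20.0, seed=SEED)
    subject = make_subject(cfg, seed=SEED, subject_id=0,
                           params=ph.PhantomParams(defect_fraction=0.20))
    truth = subject.truth
    summary = {
        "seed": SEED,
        "designed_defect_fraction": 0.20,
        "achieved_defect_fraction_3d": truth.achieved_defect_fraction(),
        "n_lung_voxels_3d": int(truth.lung_mask.sum()),
        "n_slices": len(subject.slices),
        "dce_frames": subject.dce_series.n_frames,
        "dce_dt_s": subject.dce_series.dt_s,
    }
    for sl in subject.slices:
        ut = sl.truth
        key = f"slice_z{sl.z_mm:+.0f}mm"
        summary[key] = {
            "n_lung_voxels": int(ut.lung_mask.sum()),
            "defect_fraction": ut.achieved_defect_fraction(),
        }
        for te in cfg.te_list_us:
            t1, valid = ph.observed_t1(ut, te)
            normal = ut.lung_mask & ~ut.defect_mask & valid
            summary[key][f"true_t1_te{te:.0f}us_normal_median_ms"] = float(
                np.median(t1[normal]))
            summary[key][f"true_t1_te{te:.0f}us_defect_median_ms"] = float(
                np.median(t1[ut.defect_mask & valid]))
    out = ROOT / "results" / "01_phantom_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(json.dumps(summary, indent=2, sort_keys=True))
    print("\nGround-truth observed T1 rises with TE (blood compartment "
          "dominates at long TE) and is uniformly shorter inside defects.")
    # full NIfTI bundle for inspection, outside the tracked results
    result = run_subject(cfg, subject)
    save_subject(result, subject, cfg, ROOT / "scratch" / "subject_example")
    print(f"NIfTI bundle written under {ROOT / 'scratch' / 'subject_example'}")


if __name__ == "__main__":
    main()
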