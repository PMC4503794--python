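#!/usr/bin/env python
"""Group-level analysis of the 20-subject map-level cohort.

Builds the full-size phantom, simulates the 20-subject two-session kf map
cohort with the injected left-insula effect, derives the Monte Carlo
cluster-extent threshold, runs the paired-t cluster analysis (vaccine >
placebo) and the ROI small-volume FWE tests, and writes the cluster table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from qmtpipe.group_inference import (
    monte_carlo_cluster_threshold,
    paired_cluster_analysis,
    roi_fwe_smallvolume,
    roi_mean_change,
)
from qmtpipe.synthetic_cohort import (
    CohortSpec,
    PhantomSpec,
    build_phantom,
    simulate_kf_map_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20260921


def main() -> None:
    phantom = build_phantom(PhantomSpec(), seed=SEED)
    cohort = CohortSpec(seed=SEED)
    mask = phantom.brain_mask
    placebo, vaccine, dkf = simulate_kf_map_cohort(phantom, cohort, seed=SEED + 1)

    mc = monte_carlo_cluster_threshold(
        mask, fwhm_mm=8.0, voxel_mm=3.0, p_voxel=0.001, n_iter=1000,
        alpha=0.05, seed=SEED + 2, df=cohort.n_subjects - 1,
    )
    print(
        f"Monte Carlo cluster-extent threshold (1000 iterations, p_voxel=.001, "
        f"alpha=.05, df-matched): k* = {mc.k_star} voxels"
    )

    stat, clusters, surviving = paired_cluster_analysis(
        vaccine, placebo, mask, 8.0, 3.0, mc, 0.001
    )
    rows = [
        dict(
            label=c.label, extent=c.extent, peak_t=round(c.peak_t, 3),
            x_mm=c.peak_mm[0], y_mm=c.peak_mm[1], z_mm=c.peak_mm[2],
            corrected_p=round(c.corrected_p, 5),
            survives=c.extent >= mc.k_star,
        )
        for c in clusters
    ]
    table = pd.DataFrame(
        rows, columns=["label", "extent", "peak_t", "x_mm", "y_mm", "z_mm",
                       "corrected_p", "survives"],
    )
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "cluster_table.tsv", sep="\t", index=False)
    print("\nClusters (vaccine > placebo, cluster-forming p < .001):")
    print(table.to_string(index=False) if len(table) else "  none")

    print("\nROI small-volume FWE (sign-flip permutation, max |t|):")
    roi_rows = []
    for name, roi in phantom.rois.items():
        peak, peak_t, p = roi_fwe_smallvolume(
            vaccine, placebo, roi, n_perm=2048, seed=SEED + 3
        )
        means = roi_mean_change(vaccine - placebo, roi)
        roi_rows.append(
            dict(roi=name, peak_t=round(peak_t, 3), fwe_p=round(p, 4),
                 mean_delta_kf=round(float(means.mean()), 4))
        )
        print(
            f"  {name:16s} peak t = {peak_t:6.2f}, FWE p = {p:.4f}, "
            f"mean delta-kf = {means.mean():.3f} s^-1"
        )
    pd.DataFrame(roi_rows).to_csv(RESULTS / "roi_fwe.tsv", sep="\t", index=False)
    print(
        f"\nGenerative effect: delta-kf mean {cohort.delta_kf_mean} s^-1 in "
        f"insula_L only; realized cohort mean {dkf.mean():.3f} s^-1"
    )


if __name__ == "__main__":
    sys.exit(main())
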