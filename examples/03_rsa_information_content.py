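"""Representational similarity analysis of semantic and quality coding.

Simulates 8 participants with the default planted structure -- semantic
gain rising with quality (0.2/0.5/0.9) in low-level visual areas,
constant (0.8) in high-level areas -- and quantifies per-ROI semantic
information content (correlation of the ROI RDM with the ideal one-hot
semantic RDM) within each quality condition, plus Welch's ANOVA across
qualities.
"""

import vqmvpa as v

config = v.DesignConfig(
    n_participants=8, n_runs=4, trials_per_block=9, block_total_s=50.0,
    images_per_cell=4, seed=3,
)
rois = ("calcarine", "superior_occipital", "middle_occipital", "fusiform")
params = v.SimulationParams(
    voxels_per_unilateral_roi=30, n_reliable_voxels=15, roi_names=rois, seed=3
)

reps = v.extract_representations(
    v.simulate_betas(v.generate_design(config), params), k=10
)
table = v.information_content_table(reps)

print(f"{'ROI':<22}{'low':>7}{'neutral':>9}{'high':>7}"
      f"{'Welch F':>9}{'p':>9}  quality-info")
for roi in rois:
    res, _ = v.compare_across_quality(table, roi)
    sem = table[(table["roi"] == roi) & (table["label_type"] == "semantic")
                & (table["quality"] != "all")]
    m = sem.groupby("quality")["r"].mean()
    qinfo = table[(table["roi"] == roi)
                  & (table["label_type"] == "quality")]["r"].mean()
    print(f"{roi:<22}{m['low']:>7.3f}{m['neutral']:>9.3f}{m['high']:>7.3f}"
          f"{res.f:>9.2f}{res.p:>9.4f}  {qinfo:>6.3f}")

# Low-level areas (calcarine, superior occipital) show semantic content
# rising steeply with image quality and a significant Welch ANOVA;
# high-level areas (middle occipital, fusiform) hold it constant.  The
# whole-RDM quality information content stays low everywhere: no single
# area explicitly encodes quality.
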