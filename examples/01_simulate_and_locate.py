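"""Generate a synthetic two-group cohort and localize the source voxels.

Builds a cohort with a known dysfunctional subcircuit (weaker cross-ROI
coupling in patients), runs the reversal coarse-grained localization, and
compares the recovered source masks against the planted ground truth.
"""

from dataclasses import replace

from rcga import CohortSpec, generate_cohort, locate_sources
from rcga.pipeline import cohort_matrices, preprocess_matrices

# a lighter cohort than the 39/37 default keeps this demo quick
spec = replace(CohortSpec(), n_patients=12, n_controls=12)
cohort = generate_cohort(spec, seed=42)
pre = preprocess_matrices(cohort_matrices(cohort), spec.tr)

links = [(l.roi_a, l.roi_b) for l in spec.links]
coords = {roi: cohort.data[cohort.subject_ids[0]][roi].voxel_coords for roi in pre}
located = locate_sources(
    pre, cohort.labels, links, alpha=0.05, theta=0.15,
    coords=coords, affine=cohort.affine,
)

for roi, res in located.items():
    truth = cohort.truth[roi]
    rec = res.mask.values
    jaccard = (rec & truth).sum() / (rec | truth).sum()
    print(f"\n{roi}: {res.mask.source_count} source voxels "
          f"(truth {truth.sum()}), Jaccard {jaccard:.2f}")
    print(res.clusters[["cluster_id", "size", "peak_x_mm", "peak_y_mm",
                        "peak_z_mm", "peak_intensity"]].to_string(index=False))

# Each ROI's table lists its 18-connected source clusters: the peak row is
# the voxel whose links to the other region differ most often between
# groups (peak_intensity = fraction of significantly altered links).
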