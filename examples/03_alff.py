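"""Amplitude of low-frequency fluctuation: ROI-mean vs source-mean series.

ALFF is the band-averaged (0.01-0.08 Hz) square-root power of a cleaned
BOLD series. Coherent source voxels reinforce each other in the source
mean, while the whole-ROI mean buries them among non-informative voxels,
so the source-mean ALFF is larger for nearly every subject.
"""

from dataclasses import replace

from rcga import CohortSpec, alff_group_compare, alff_table, generate_cohort, locate_sources
from rcga.pipeline import cohort_matrices, preprocess_matrices

spec = replace(CohortSpec(), n_patients=12, n_controls=12)
cohort = generate_cohort(spec, seed=42)
pre = preprocess_matrices(cohort_matrices(cohort), spec.tr)
links = [(l.roi_a, l.roi_b) for l in spec.links]
located = locate_sources(pre, cohort.labels, links, theta=0.15)
masks = {roi: res.mask.values for roi, res in located.items()}

table = alff_table(pre, cohort.labels, cohort.subject_ids, spec.tr, masks=masks)
summary = table.groupby(["roi", "mode", "group"])["alff"].mean().round(3)
print(summary.to_string())

frac = (
    table.pivot_table(index=["roi", "subject_id"], columns="mode", values="alff")
    .eval("voxel > roi").mean()
)
print(f"\nsource-mean ALFF exceeds ROI-mean ALFF for {frac:.0%} of subject-ROIs")

roi_alff = table.query("roi == 'regionB' and mode == 'voxel'")
t, p = alff_group_compare(
    roi_alff.query("group == 'patient'")["alff"].to_numpy(),
    roi_alff.query("group == 'control'")["alff"].to_numpy(),
)
print(f"regionB voxel-wise ALFF, patients vs controls: t = {t:.2f}, p = {p:.3f}")
# The negative t reflects the generator: controls' stronger cross-ROI
# coupling adds in-band power to their source voxels, so patient ALFF is
# lower — and the effect is far clearer on source-mean than ROI-mean series.
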