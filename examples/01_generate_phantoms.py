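"""Generate a synthetic NCCT cohort and inspect its ground truth.

Builds a 10-subject phantom cohort with subtle (-8 HU) lesions and prints
the manifest: which subjects had lesions inserted, where, and the true
ASPECTS that follows. Same seed -> bit-identical cohort.
"""

from autoaspects import PhantomSpec, generate_cohort

cohort = generate_cohort(10, stroke_prevalence=0.622,
                         spec=PhantomSpec(lesion_delta_hu=-8.0), seed=42)
print(cohort.manifest[["subject_id", "is_stroke", "hemisphere", "n_regions",
                       "true_reported", "true_category"]].to_string(index=False))
sub = next(s for s in cohort.subjects if s.lesion_regions)
print(f"\n{sub.subject_id}: lesions in {[str(r) for r in sub.lesion_regions]}")
print(f"volume shape {sub.volume.shape}, spacing {sub.volume.spacing} mm,"
      f" HU range [{sub.volume.voxels.min():.0f}, {sub.volume.voxels.max():.0f}]")
# true_reported is 10 minus the affected-region count of the worse hemisphere;
# "<6" marks the subjects that would fail the thrombectomy cutoff.
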