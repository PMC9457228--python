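"""Two-step training on a small cohort, then per-subject ASPECTS.

Pre-trains the slice encoder on hemisphere slices (with the ipsilateral
exclusion rule), fine-tunes the full region classifier, and scores every
subject. Short epochs and strong lesion contrast keep this to about a
minute; see scripts/acceptance.py for the full verification experiment.
"""

from autoaspects import (PhantomSpec, TrainConfig, generate_cohort, run_evaluate,
                         run_predict, train_two_step)

cohort = generate_cohort(20, stroke_prevalence=0.7,
                         spec=PhantomSpec(lesion_delta_hu=-30.0), seed=7)
model, pre_log, fin_log = train_two_step(
    cohort, TrainConfig(epochs=3, seed=0), TrainConfig(epochs=12, seed=0))
print("pre-training tail:\n", pre_log.tail(1).to_string(index=False))
print("fine-tuning tail:\n", fin_log.tail(1).to_string(index=False))

results = run_predict(model, cohort)
print(results[["subject_id", "left_score", "right_score",
               "reported_score", "category"]].head(5).to_string(index=False))
report = run_evaluate(results, cohort)
print("\npooled metrics over all 20 territories:")
print(report["pooled"].round(3).to_string())
# Sensitivity/specificity here are on the training cohort itself -- an
# optimistic smoke check; held-out numbers come from the experiments module.
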