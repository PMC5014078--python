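"""Transfer prognostic models across groups and test prediction-error
shifts with permutation family-wise control.

Models are selected and trained on the reference group only (group-a
predictions by leave-one-out cross-validation, group-b predictions in a
single pass).  A positive t means the models overestimate group-b
scores.  Shuffling group labels 500 times yields a corrected per-task
alpha controlling the family-wise error over all tasks.
"""

from lesionprog import generate_cohort, pipeline
from lesionprog.selection import select_features
from lesionprog.simulate import SimulationConfig
from lesionprog.transfer import (
    errors_by_task,
    permutation_familywise_threshold,
    shift_tests,
    transfer_predict,
)

cohort = generate_cohort(
    SimulationConfig(
        n_group_a=120, n_group_b=33, n_regions=30, n_tasks=6,
        lambda_sensitivity=1.5, noise_sd=3.0, noise_shared_sd=0.0, seed=21,
    )
)
table_a, table_b, scores_a, scores_b = pipeline.split_tables(cohort)

models = {t: select_features(table_a, scores_a[t], task=t) for t in cohort.tasks}
records = transfer_predict(models, table_a, scores_a, table_b, scores_b)
null = permutation_familywise_threshold(
    errors_by_task(records), cohort.demographics["group"], n_perm=500, seed=22
)
table = shift_tests(records, corrected_alpha=null.corrected_alpha)

print(f"corrected per-task alpha: {null.corrected_alpha:.4f} "
      f"(nominal 0.05 over {len(cohort.tasks)} tasks)")
print(table[["task", "mean_error_a", "mean_error_b", "t", "p", "significant"]]
      .round(3).to_string(index=False))
print("\nGroup-a errors centre near zero (cross-validated, unbiased); the "
      "positive group-b means and t values show the reference-trained models "
      "systematically overestimate the transfer group, as expected when its "
      "scores are more sensitive to the same lesions.")
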