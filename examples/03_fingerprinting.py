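"""Cross-session subject identification from lead-matrix features.

Each synthetic subject has a persistent phase template; each run perturbs
it slightly.  A 1-nearest-neighbor classifier under the cosine metric,
trained on one session and tested on the other (both directions), asks:
is the lead matrix a stable, subject-specific fingerprint?
"""

from cyclicity import CohortSpec, cohort_features, gen_cohort
from cyclicity.stability import knn_session_identification

spec = CohortSpec(
    n_group_a=15, n_group_b=32, n_channels=33, n_samples=300,
    subject_jitter=0.5,          # persistent per-subject phase offsets (rad)
    ordering_jitter_a=0.05,      # small per-run wobble
    ordering_jitter_b=0.05,
    seed=9,
)
features = cohort_features(gen_cohort(spec))
result = knn_session_identification(features)

n = len(result.subjects)
perfect = sum(1 for v in result.per_subject_correct.values() if v == 4)
print(f"subjects: {n}, runs tested: {int(result.confusion.sum())}")
print(f"identification accuracy: {result.overall_accuracy:.1%} "
      f"(chance would be 1/{n} = {1 / n:.1%})")
print(f"subjects classified perfectly (4/4 runs): {perfect}")
# Accuracy far above chance means the lead matrix captures stable
# individual traits across sessions, not just run-level noise.
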