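"""Score the 12-item JAWS questionnaire and derive reference labels.

Shows both scorings (reverse-coded total and the positive/negative
subscales), the positivity ratio, and the two-means dichotomisation.
"""

import numpy as np

from edaffect import SynthConfig, positivity_ratio, reference_labels, score_jaws, simulate_cohort

cohort = simulate_cohort(SynthConfig(seed=1))
scores = [score_jaws(r) for r in cohort.responses]

mean_total = np.mean([s.total for s in scores])
mean_pos = np.mean([s.pos for s in scores])
mean_neg = np.mean([s.neg for s in scores])
print(f"cohort means: total {mean_total:.2f}, pos {mean_pos:.2f}, "
      f"neg {mean_neg:.2f}")
print(f"identity check: pos + 36 - neg = {mean_pos + 36 - mean_neg:.2f}")
print(f"positivity ratio (mean_pos / mean_neg): "
      f"{positivity_ratio(mean_pos, mean_neg):.2f}")

labels, threshold = reference_labels(
    [s.total for s in scores], [s.participant_id for s in scores]
)
n_high = sum(labels.labels.values())
print(f"two-means split of totals: threshold {threshold:.1f}, "
      f"{n_high} high vs {len(labels) - n_high} low")
# A ratio near 3:1 is the classical flourishing benchmark; values below it
# indicate negative affect carries real weight in the cohort.
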