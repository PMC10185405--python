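"""Screen ortholog candidates for architecture outliers.

Simulates an ortholog group: several species' orthologs derive from one
ancestral architecture with mild divergence, one candidate with heavy
feature loss. Each protein's mean bidirectional score against the
reference is computed; a candidate more than two standard deviations below
the group mean is flagged as architecturally diverged — the screen used to
spot functionally diverged orthologs or faulty gene models.
"""

from archsim import (
    PerturbationSpec,
    bidirectional_mean,
    flag_outliers,
    perturb,
    random_architecture,
)

reference = random_architecture(
    n_layers=2, n_types=5, n_instances=8, length=420, seed=11
)
group = [
    perturb(reference, PerturbationSpec(p_loss=0.05, shift_sd=0.01, seed=s))
    for s in range(6)
]
broken = perturb(reference, PerturbationSpec(p_loss=0.4, shift_sd=0.05, seed=7))

group_scores = [bidirectional_mean(reference, g) for g in group]
candidate_score = bidirectional_mean(reference, broken)

print("group mean bidirectional FAS scores:")
for i, s in enumerate(group_scores):
    print(f"  ortholog {i}: {s:.4f}")
print(f"candidate: {candidate_score:.4f}")
print(f"flagged as outlier (mean - 2*SD rule): "
      f"{flag_outliers(group_scores, candidate_score)}")
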