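"""Prospective follow-up layer: symptom prevalences and per-symptom ANOVA.

Nineteen former patients carry binary indicators for 12 symptoms in four
allergic-disorder domains; each symptom splits the cohort into yes/no and a
one-way ANOVA asks whether the mean polygenic score differs between the
groups.
"""

from prspipe import (
    simulate_followup_phenotypes,
    simulate_score_cohort,
    summarize_phenotypes,
    symptom_association,
)
from prspipe.scoring import ScoreSet

scores, _ = simulate_score_cohort(0.41, 19, 1, seed=7)
cases = ScoreSet(sample_ids=scores.sample_ids[:19], raw_score=scores.raw_score[:19],
                 trait_label="asthma", threshold=0.001, n_snps_included=25)
phen = simulate_followup_phenotypes(cases, seed=7)

print(summarize_phenotypes(phen).to_string(index=False))
print()
for r in symptom_association(cases, phen):
    if r.status != "ok":
        print(f"{r.symptom:<24} untestable (all subjects on one side)")
        continue
    print(f"{r.symptom:<24} yes={r.n_yes:<3d} no={r.n_no:<3d} "
          f"mean PRS yes/no = {r.mean_prs_yes:+.2f}/{r.mean_prs_no:+.2f}  "
          f"F={r.f_stat:.2f} p={r.p_value:.3f}")

# Asthma-domain symptoms are simulated with a +1 log-odds-per-SD loading on
# the score, so their symptom-positive groups tend to show higher mean PRS;
# the other domains are null.
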