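"""Score a synthetic cohort and stratify it into adherence groups.

Generates a study-scale cohort (513 respondents), encodes the 28
questionnaire items into 32 binary indicators, sums the adherence score
(0-28) and splits respondents at the score quartiles.
"""

from medlifenet import (
    default_instrument,
    encode_cohort,
    group_percentages,
    score_matrix,
    stratify_quartiles,
)
from medlifenet.simulate import SimulationConfig, generate_structured

instrument = default_instrument()
cohort = generate_structured(SimulationConfig(seed=1))
X = encode_cohort(instrument, cohort.records)
scores = score_matrix(instrument, X)
groups = stratify_quartiles(scores)
counts = {g: groups.count(g) for g in ("low", "intermediate", "high")}

print(f"respondents: {X.n}, indicators: {len(X.indicator_ids)}")
print(f"score mean {scores.mean():.1f}, sd {scores.std(ddof=1):.1f}, "
      f"range {scores.min()}-{scores.max()}")
print(f"group counts: {counts}")
print(f"group shares: {group_percentages(counts)}")
print()
print("Respondents strictly below the first score quartile form the low-"
      "adherence group, those strictly above the third the high-adherence "
      "group; the shares are rounded so they total 100%.")
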