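"""Contrast the low- and high-adherence extremes indicator by indicator.

Each indicator's 2x2 table (group x indicator) gets a Fisher exact p-value,
Bonferroni correction, and a log odds ratio with a 95% Woolf interval
(Haldane-Anscombe corrected when a cell is zero). Significant rows are the
behaviours that distinguish the two lifestyle extremes.
"""

from medlifenet import (
    default_instrument,
    encode_cohort,
    enrich,
    score_matrix,
    stratify_quartiles,
)
from medlifenet.enrichment import enrichment_frame
from medlifenet.simulate import SimulationConfig, generate_structured

instrument = default_instrument()
cohort = generate_structured(SimulationConfig(seed=5, trait_effect=0.8))
X = encode_cohort(instrument, cohort.records)
groups = stratify_quartiles(score_matrix(instrument, X))

high = [i for i, g in enumerate(groups) if g == "high"]
low = [i for i, g in enumerate(groups) if g == "low"]
results = enrich(high, low, X, group_label="high")

df = enrichment_frame(results)
sig = df[df.significant].sort_values("log_or", ascending=False)
print(f"high-adherence group n={len(high)}, low n={len(low)}")
print(f"significant indicators after correction: {len(sig)} of {len(df)}\n")
print(sig[["indicator", "log_or", "ci_low", "ci_high", "p_adj", "direction"]]
      .head(12).to_string(index=False))
print()
print("Positive log OR: the behaviour is over-represented among high "
      "adherents; an infinite log OR means the contrast group had no such "
      "respondents, and only the estimable interval bound is reported.")
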