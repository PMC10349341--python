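"""Per-drug statistics: industry comparison and designation strata.

Builds per-drug per-phase cost profiles from the attribution ledger, pairs
them with industry benchmarks, and runs the paired-t and Mann-Whitney
comparisons the report tables are built from.
"""

from trialspend import (GeneratorConfig, InflationIndex, build_ledger,
                        classify_corpus, designation_comparisons, generate,
                        industry_comparison, per_drug_profiles)

corpus, _ = generate(GeneratorConfig(seed=42))
index = InflationIndex.from_frame(corpus.inflation, 2018)
ledger = build_ledger(classify_corpus(corpus), corpus, index)
profiles = per_drug_profiles(ledger.drug_phase_totals(),
                             corpus.industry_costs, corpus.drugs)

print(f"funded drugs with profiles: {len(profiles)}; "
      f"paired with industry benchmarks: {int(profiles.industry_total.notna().sum())}")
print()
print("Paired public-vs-industry comparison (M$, base year 2018):")
cols = ["phase", "n_drugs", "nih_mean", "industry_mean", "nih_pct_of_industry",
        "mean_difference", "p_value"]
print(industry_comparison(profiles)[cols].round(2).to_string(index=False))
print()
print("Designation strata (per-drug development totals, Mann-Whitney):")
table3 = designation_comparisons(profiles)
print(table3[["designation", "n_yes", "n_no", "median_yes", "median_no",
              "p_value"]].round(3).to_string(index=False))
# nih_pct_of_industry is the public mean as a percent of the industry mean;
# mean_difference is industry minus public spending per drug, so positive
# values mean industry outspends the public funder in that phase.
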