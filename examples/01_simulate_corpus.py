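"""Generate a synthetic publication/funding corpus with ground truth.

Builds the nine input tables (publications, project links, project periods
and yearly costs, trial registry, drug/target lexicon, industry benchmarks,
inflation index) under the default study conditions and prints the true
deduplicated funding totals per research category.
"""

from trialspend import GeneratorConfig, generate

corpus, truth = generate(GeneratorConfig(seed=42))

print(f"publications: {len(corpus.publications)}")
print(f"publication->project links: {len(corpus.links)}")
print(f"projects: {len(corpus.projects)}, registry entries: {len(corpus.registry)}")
print()
print("True deduplicated totals (base-year M$):")
print(truth.category_totals.to_string(index=False))
print()
print(f"drugs with funded development project-years: {len(truth.drug_totals)}"
      f" of {len(corpus.drugs)}")
# Each category row counts every (project, fiscal-year) funding key once, no
# matter how many publications reach it; 'development' is the subset of
# applied research reporting phased clinical trials.
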