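"""Measure trial-detector sensitivity/specificity under injected noise.

Corrupts the trial signal at known false-positive/false-negative rates,
labels a 400-publication validation sample, and recovers the detector's
operating point together with inter-reader agreement (Cohen's kappa).
"""

import numpy as np

from trialspend import GeneratorConfig, generate, inject_noise, validation_metrics
from trialspend.term_search import detect_clinical_trial

corpus, truth = generate(GeneratorConfig(seed=42))
noisy, flips = inject_noise(corpus, fp_rate=0.08, fn_rate=0.07, seed=1)
print(f"flipped publications: {len(flips)} "
      f"({(flips.flip == 'fn').sum()} signal removed, "
      f"{(flips.flip == 'fp').sum()} signal added)")

pubs = {p.pmid: p for p in noisy.publications.itertuples()}
applied = truth.publications[truth.publications.category == "applied"]
sample = applied.sample(400, random_state=1)
predicted = np.array([detect_clinical_trial(pubs[p]) for p in sample.pmid])

# two simulated readers: reader 2 mislabels 3% of items
rng = np.random.default_rng(2)
reader1 = sample.is_trial.to_numpy()
reader2 = np.where(rng.random(400) < 0.03, ~reader1, reader1)

m = validation_metrics(predicted, reader1, reader2)
print(f"labeled sample: {m.n_labeled} consensus items of 400")
print(f"sensitivity: {m.sensitivity:.3f}  (expected ~{1 - 0.07:.2f})")
print(f"specificity: {m.specificity:.3f}  (expected ~{1 - 0.08:.2f})")
print(f"inter-reader kappa: {m.kappa:.3f}")
# Sensitivity/specificity are measured against the readers' consensus labels;
# with noise rates fn/fp the detector's expected operating point is
# (1-fn, 1-fp).
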