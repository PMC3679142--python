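"""Cross-validate the combined-kernel classifier on synthetic data.

Generates the default synthetic study conditions (40 planted heterodimers,
20 larger complexes whose internal pairs are hard negatives, weak background
edges, repeated domain compositions across most heterodimers), then compares
the features-only baseline (alpha = 0) with the combined kernel (alpha = 0.6).
"""

import numpy as np

import hetdimer as hd

data = hd.generate(hd.SyntheticConfig(seed=0))
examples = hd.build_dataset(data.catalog, data.network)
labels = np.array([ex.label for ex in examples])
pairs = [ex.pair for ex in examples]
print(f"dataset: {(labels == 1).sum()} positives, {(labels == -1).sum()} negatives")

features = hd.feature_matrix(data.network, data.domains, pairs)
indicator = hd.kdc_gram(pairs, data.domains)
cv = hd.CVConfig(n_folds=10, seed=0)

for alpha in (0.0, 0.6):
    config = hd.TrainingConfig(c_plus=1.0, c_minus=1.0,
                               kernel=hd.KernelConfig(alpha=alpha))
    result = hd.cross_validate(features, labels, indicator, config, cv)
    print(f"alpha={alpha:.1f}:  precision={result.precision:.3f}  "
          f"recall={result.recall:.3f}  F={result.fmeasure:.3f}")

print("\nThe F gain at alpha=0.6 is the contribution of the domain-composition"
      "\nkernel: ambiguous positives are rescued by class-mates with identical"
      "\ndomain architecture.")
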