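"""Train the box classifier and measure sensitivity/specificity.

Synthesizes a promoter dataset, makes a 9:1 stratified split, trains the
network on the (heavily imbalanced) training partition and reports
held-out true-positive and true-negative rates at the 0.5 score cutoff.
"""

import sig70scan as s

data = s.synthesize_dataset(s.SyntheticConfig(n_positive=170, n_negative=16000, seed=1))
split = s.stratified_split(data, test_fraction=0.1, seed=1)
print(f"train: {split.train.positives_count}+{split.train.negatives_count}   "
      f"test: {split.test.positives_count}+{split.test.negatives_count}")

model = s.train(s.build_network(s.NetworkConfig(seed=1)), split.train)
print(f"trained {model.n_parameters} parameters over {len(model.training_log)} epochs")

m = s.evaluate(model, split.test)
print(f"held-out sensitivity {m.sensitivity:.3f}  specificity {m.specificity:.3f}")
print(f"consensus TTGACA/TATAAT scores {model.score(s.CONSENSUS_PAIR):.4f}")
print("\nSensitivity is the fraction of true promoters recovered; specificity the")
print("fraction of background correctly rejected, both at a 0.5 score cutoff.")
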