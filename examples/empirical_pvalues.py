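"""Monte-Carlo p-values for classifier scores.

Builds a null distribution of scores on random 12-mers and converts scores
into empirical tail probabilities: the chance a random sequence scores at
least as high.
"""

import numpy as np

import sig70scan as s

data = s.synthesize_dataset(s.SyntheticConfig(seed=2))
model = s.train(s.build_network(s.NetworkConfig(seed=2)), data)

null = s.build_null(model, sample_size=100_000, seed=3)
print(f"null sample: {null.sample_size} random 12-mers; "
      f"minimum resolvable p = {null.min_resolvable_p:g}")

for label, kmer in [
    ("consensus      ", "TTGACATATAAT"),
    ("one mismatch   ", "TTGACCTATAAT"),
    ("random GC-rich ", "GCGCGGCCGGCG"),
]:
    score = model.score(kmer)
    p = s.p_value(null, score)
    shown = f"{p:.2e}" if p > 0 else f"< {null.min_resolvable_p:g}"
    print(f"{label} {kmer}  score {score:.4f}  p {shown}")

print("\nA p of 2e-4 (the genome-scan default cutoff) means a random 12-mer")
print("matches this score level once in five thousand draws.")
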