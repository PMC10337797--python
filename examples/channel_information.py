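"""Entropy and mutual information basics on the rating scale.

Builds a few tiny distributions and channels, prints their information
content in bits, and checks a noisy binary channel against its closed form.
"""

import math

from ratecap import (
    ContingencyTable,
    DiscreteDistribution,
    entropy_bits,
    mi_uniform_input,
    mutual_information_bits,
)

# A uniform choice among k alternatives carries log2(k) bits: the classic
# benchmarks for one-dimensional absolute judgment.
for k in (4, 6, 150):
    h = entropy_bits(DiscreteDistribution.uniform(range(k)))
    print(f"uniform over {k:3d} categories: H = {h:.3f} bits")

# A rater who always distinguishes two stimuli transmits 1 bit per rating;
# one who answers at random transmits none.
perfect = ContingencyTable([[5, 0], [0, 5]])
random_ = ContingencyTable([[3, 3], [3, 3]])
print(f"noiseless binary rater:  I = {mutual_information_bits(perfect):.3f} bits")
print(f"coin-flipping rater:     I = {mutual_information_bits(random_):.3f} bits")

# A binary symmetric channel that flips 10% of responses: the uniform-input
# MI has the closed form 1 - H2(0.1).
p = 0.1
h2 = -p * math.log2(p) - (1 - p) * math.log2(1 - p)
mi = mi_uniform_input([[1 - p, p], [p, 1 - p]])
print(f"10%-flip binary channel: I = {mi:.4f} bits (closed form {1 - h2:.4f})")
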