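"""Virtual-screening metrics: enrichment factor and BEDROC.

Builds a 100-compound screen with 10 actives, ranks them three ways
(perfect, random, inverted) and prints EF at 1% / 10% and BEDROC at
alpha = 80.5, the early-recognition setting that weights roughly the top 2%.
"""

import numpy as np

from cpifuse import RankedScreen, enrichment_factor, bedroc

rng = np.random.default_rng(0)
N, n = 100, 10
is_active = np.zeros(N, dtype=bool)
is_active[:n] = True

orders = {
    "perfect": np.arange(N, 0, -1, dtype=float),
    "random": rng.permutation(N).astype(float),
    "inverted": np.arange(N, dtype=float),
}
for name, scores in orders.items():
    s = RankedScreen(scores, is_active)
    ef10 = enrichment_factor(s, 0.10)
    ef1 = enrichment_factor(s, 0.01)
    b = bedroc(s, alpha=80.5)
    print(f"{name:9s} EF@1% {ef1:5.1f}  EF@10% {ef10:5.2f}  "
          f"BEDROC(80.5) {b:.3f}")
# A perfect ranking reaches the EF ceiling min(1/f, N/n) and BEDROC ~= 1;
# random ranking gives EF ~= 1 and BEDROC near the random baseline.
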