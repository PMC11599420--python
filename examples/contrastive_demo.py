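"""InfoNCE behaviour at a glance.

Shows the (N+1)-way classification structure: uniform similarity gives
ln(N+1), a dominant positive drives the loss to zero, and the temperature
sharpens or flattens the contrast.
"""

import numpy as np

from constructs import info_nce

rng = np.random.default_rng(0)
d = 64


def unit(v):
    return v / np.linalg.norm(v)


v = unit(np.ones(d))
for n in (1, 7, 255):
    print(f"uniform logits, N={n:3d}:  loss = {info_nce(v, v, [v] * n, 0.07):.4f}"
          f"   (ln(N+1) = {np.log(n + 1):.4f})")

s = unit(rng.standard_normal(d))
negs = [unit(rng.standard_normal(d)) for _ in range(255)]
for tau in (1.0, 0.07):
    aligned = info_nce(s, s, negs, tau)
    misaligned = info_nce(s, unit(rng.standard_normal(d)), negs, tau)
    print(f"tau={tau:4.2f}: aligned positive {aligned:8.4f}   "
          f"random positive {misaligned:8.4f}")
print("lower temperature -> sharper discrimination between matched and "
      "mismatched patches")
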