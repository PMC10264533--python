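"""LBA building blocks: densities, choice probabilities, simulation.

A two-accumulator LBA describes one speeded binary decision. Here we
evaluate its closed-form defective densities and check them against a
quick simulation.
"""

import numpy as np

from lbacomp import LBAParams, defective_density, simulate_trials
from lbacomp.lba import response_probability

params = LBAParams(b=0.95, A=0.30, v_correct=1.35, v_error=0.25, s_v=1.0, t0=0.45)

p_correct = response_probability(params, "correct")
print(f"P(correct response)      = {p_correct:.4f}")
print(f"density at rt=1.0s (hit) = {defective_density(1.0, 'correct', params):.4f}")

correct, rt = simulate_trials(params, 50_000, np.random.default_rng(0))
print(f"simulated accuracy       = {correct.mean():.4f}")
print(f"simulated median RT      = {np.median(rt):.3f} s")

# The simulated accuracy should match the quadrature probability to ~0.004
# (3 binomial SEs at n=50,000); the median RT reflects threshold/rate/t0.
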