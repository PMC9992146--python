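"""Classical fingerprinting: dictionary generation and dot-product matching.

Simulates a small (f_s x k_sw) dictionary, corrupts one of its rows with
noise, and matches it back by maximum cosine similarity.  The matched grid
point is the brute-force quantification every neural quantifier in this
package is benchmarked against.
"""

import numpy as np

from cestmrf import (ParameterGrid, PoolParameters, TissueParameters,
                     dot_product_match, generate_dictionary,
                     generate_pseudorandom_schedule)

tissue = TissueParameters(
    water=PoolParameters(t1=2.5, t2=0.8),
    solute=PoolParameters(t1=1.0, t2=0.04, chemical_shift=3.0,
                          exchange_rate=400.0, volume_fraction=1.35e-3))
schedule = generate_pseudorandom_schedule(30, "cest_3ppm", seed=7)

grid = ParameterGrid(axes={
    "volume_fraction": list(np.linspace(1e-4, 3.5e-3, 21)),
    "exchange_rate": list(np.linspace(20, 1400, 21))})
dictionary = generate_dictionary(grid, schedule, tissue)
print(f"dictionary: {dictionary.grid.size} entries x M={dictionary.m}")

rng = np.random.default_rng(0)
true_index = 150
noisy = dictionary.trajectories[true_index] + rng.normal(0, 1e-3, 30)
estimates, idx = dot_product_match(noisy[None], dictionary)

pts = grid.points()
print("true  f_s=%.2e  k_sw=%6.1f Hz" % tuple(pts[true_index]))
print("match f_s=%.2e  k_sw=%6.1f Hz  (grid index %d)"
      % (estimates["volume_fraction"][0], estimates["exchange_rate"][0],
         idx[0]))
print("a perfect match returns the generating grid point; small noise may "
      "move it by one grid step")
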