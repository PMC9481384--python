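"""One stochastic succession run: 30 species competing for 10 substrates.

Draws a random community from the reference parameter intervals, runs 100
days of succession under moderate parameter disturbance, and prints the
statistics the study design tracks: how many species persist, the
Gini-Simpson diversity of the final community, and correlation summaries
of the daily relative-abundance series.
"""

import numpy as np

from midsim.community_gen import sample_community
from midsim.ecostats import (correlation_summary, count_coexisting,
                             relative_abundance, simpson_index)
from midsim.integrator import SimConfig, simulate
from midsim.noise import DisturbanceSpec

community = sample_community(M=30, m=10, rng=np.random.default_rng(103))
disturbance = DisturbanceSpec(psd1=5, psd2=5, psd3=5, psd4=5, psd5=5)
traj = simulate(community, disturbance, SimConfig(seed=1))

n = count_coexisting(traj)
P, _ = relative_abundance(traj.X[-1])
summary = correlation_summary(traj, species=5)

print(f"species persisting above 0.1% relative abundance : {n}")
print(f"final Gini-Simpson diversity                     : "
      f"{simpson_index(P):.3f}")
print(f"mean |autocorrelation| (lags 1-10, top-5 species): "
      f"{summary['mean_abs_autocorr_overall']:.3f}")
if not summary["cross_empty"]:
    print(f"mean of max |cross-correlation| per species pair : "
          f"{summary['max_abs_crosscorr_overall']:.3f}")
# A small persisting count with low diversity is the competitive-exclusion
# signature; the correlation summaries quantify how smooth/trending
# (values near 1) or noise-dominated (values near 0) the series are.
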