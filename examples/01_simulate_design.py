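"""Enumerate the factorial design and simulate the whole experiment.

The default design crosses 2 ciliate species x 3 clonal strains x 3
temperatures x 3 atrazine levels, with 5 dilutions of a log-phase
source culture, 3 replicate assays and 3 sampling time points. Every
sample row carries the observed density (counted cells in 810 uL) and
the sample-level trait moments downstream stages consume.
"""

from strainlink.config import DesignConfig
from strainlink.synthetic.design import design_counts
from strainlink.synthetic.generate import simulate_experiment

config = DesignConfig()
counts = design_counts(config)
print("design:", counts)
# conditions=54 curves, assays=162, picture_series=2430: one density-
# dependence curve per condition, 15 points each (5 dilutions x 3 reps)

samples = simulate_experiment(config, seed=1)
print(f"\nsimulated {len(samples)} samples; first rows:")
cols = ["sample_id", "time_point", "true_density", "density", "speed_mean", "size_mean"]
print(samples[cols].head(6).to_string(index=False))
# density is the noisy counted estimate of true_density (cells/mL)
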