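"""Coverage overdispersion and repeat-driven pile-up.

Samples per-tag read counts from the Gamma-Poisson coverage model, recovers
the dispersion parameter by method of moments, and shows how repeat tags
dominate the high-coverage tail of a simulated run.
"""

import numpy as np

from rrsnp import (SimConfig, fit_gamma_overdispersion, make_parent_genomes,
                   sample_tag_counts, simulate_tag_reads)

rng = np.random.default_rng(42)

# pure model: mean 10 reads/tag, Gamma shape 1 (variance/mean = 11)
counts = sample_tag_counts(rng, 10_000, mean=10.0, shape=1.0)
fit = fit_gamma_overdispersion(counts)
print(f"simulated shape 1.0 -> recovered {fit.shape:.3f} "
      f"(mean {fit.mean:.2f}, var/mean {fit.var_mean_ratio:.1f})")

# in context: a simulated run where repetitive tags draw 10x the mean
config = SimConfig(genome_length=300_000, seed=42)
genomes = make_parent_genomes(config)
_, records = simulate_tag_reads(genomes, "CviRI", (70, 200), config)
rep = np.array([r.read_count for r in records if r.repetitive])
nonrep = np.array([r.read_count for r in records if not r.repetitive])
print(f"repetitive tags   : n={rep.size:5d}  mean coverage {rep.mean():7.1f}")
print(f"non-repetitive    : n={nonrep.size:5d}  mean coverage {nonrep.mean():7.1f}")
hi = [r for r in records if r.read_count > 200]
print(f"tags with >200 reads: {len(hi)}, of which "
      f"{100 * sum(r.repetitive for r in hi) / max(1, len(hi)):.0f}% repetitive")
print(
    "\nThe var/mean ratio far above 1 is the overdispersion signature; the\n"
    ">200-read class being dominated by repetitive tags reproduces the\n"
    "repeat-driven coverage bias that motivates the repeat filters."
)
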