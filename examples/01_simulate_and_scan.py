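"""Simulate a biparental cross with one planted QTL and map it.

A 144-segregant haploid panel (16 chromosomes x 100 cM, 30 markers each)
carries an additive QTL on chromosome V explaining ~25% of phenotypic
variance in glucose doubling time.  We estimate the genetic map, run a
Haley-Knott genome scan with a 1000-permutation genome-wide null, and print
the called peak.
"""

from plasticqtl import (
    PlantedEffect,
    SimulationConfig,
    call_peaks,
    effect_for_variance,
    estimate_map,
    permute_threshold,
    simulate_cross,
)

effect = effect_for_variance(0.25, noise_sd=1.0)   # allele-mean difference
cfg = SimulationConfig(
    environments=["glucose"],
    parameters=["doubling_time"],
    planted_effects=[PlantedEffect("additive", ((5, 50.0),),
                                   {"glucose": effect})],
    seed=1,
)
d = simulate_cross(cfg)
gmap = estimate_map(d.genotypes)
print(f"panel: {d.genotypes.n_segregants} segregants, "
      f"{d.genotypes.n_markers} markers, map {gmap.total_length_cm():.0f} cM")

res = permute_threshold(d, gmap, "doubling_time", "glucose",
                        n_perm=1000, seed=2)
print(f"genome-wide max LOD = {res.max_lod:.2f} "
      f"(5% permutation threshold ~ {sorted(res.perm_null)[-50]:.2f})")

for c in call_peaks(res, d, p_max=0.05):
    print(f"QTL {c.locus}: LOD {c.lod:.2f}, p = {c.p_value}, "
          f"S-Y effect {c.effect:+.2f} +/- {c.effect_se:.2f}, "
          f"{100 * c.variance_explained:.0f}% variance explained")
# The call should sit on chromosome V near 125 kb (50 cM at 2.5 kb/cM): the
# planted allele-mean difference is recovered within its standard error.
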