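"""Targeted two- and three-locus epistasis scan.

Genome-wide pairwise scans are underpowered at ~144 segregants, so the scan
is restricted to a candidate marker set.  Here a two-locus interaction
(chrIII x chrVIII, 15% of maxOD variance in sucrose) plus a pure three-way
term anchored at chrII are planted; candidates are the planted markers plus
one decoy per chromosome, mimicking the collated peaks of relaxed
single-environment scans.  P-values come from a permutation null of the
maximum interaction LOD over the whole tested set.
"""

import numpy as np

from plasticqtl import (
    PlantedEffect,
    SimulationConfig,
    candidate_set_from_markers,
    effect_for_variance,
    estimate_map,
    scan_pairs,
    scan_triples,
    simulate_cross,
)

e2 = effect_for_variance(0.15, noise_sd=1.0, order=2)
e3 = effect_for_variance(0.12, noise_sd=1.0, order=3)
cfg = SimulationConfig(
    environments=["sucrose"], parameters=["maxOD"],
    planted_effects=[
        PlantedEffect("epistatic2", ((3, 30.0), (8, 70.0)), {"sucrose": e2},
                      parameter="maxOD"),
        PlantedEffect("epistatic3", ((2, 60.0), (3, 30.0), (8, 70.0)),
                      {"sucrose": e3}, parameter="maxOD"),
    ],
    seed=5,
)
d = simulate_cross(cfg)
gmap = estimate_map(d.genotypes)


def marker_near(chrom, cm):
    sub = d.genotypes.markers[d.genotypes.markers["chromosome"] == chrom]
    return sub["id"].iloc[int(np.argmin(np.abs(sub["position_cm"] - cm)))]


planted = [marker_near(3, 30.0), marker_near(8, 70.0)]
anchor = marker_near(2, 60.0)
decoys = [marker_near(c, 50.0) for c in range(1, 17)
          if marker_near(c, 50.0) not in planted + [anchor]]
cands = candidate_set_from_markers(d, gmap, planted + decoys)
print(f"candidate set: {len(cands)} markers -> "
      f"{len(cands) * (len(cands) - 1) // 2} pairs tested")

pairs = scan_pairs(d, gmap, cands, "maxOD", "sucrose", n_perm=1000, seed=9,
                   p_max=0.2)
for c in pairs:
    print(f"pair {c.locus}: interaction LOD {c.interaction_lod:.2f}, "
          f"set-max p = {c.p_value}")

triples = scan_triples(d, gmap, [anchor], pairs, "maxOD", "sucrose",
                       n_perm=1000, seed=11, p_max=0.2)
for c in triples:
    print(f"triple {c.locus}: three-way LOD {c.interaction_lod:.2f} "
          f"(full-vs-additive {c.secondary_lod:.2f}), p = {c.p_value}")
    print("  genotype-class means (S/Y words in locus order):")
    for cls, (mean, se, n) in c.class_means.items():
        print(f"    {cls}: {mean:+.2f} +/- {se:.2f} (n={n})")
# The three-way LOD compares the full model against all pairwise terms, so a
# significant value means the pair interaction itself depends on the anchor
# genotype - interaction plasticity across genetic backgrounds.
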