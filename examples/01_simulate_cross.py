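"""Simulate a RAD-seq family cross with a planted XY sex chromosome.

The design mirrors a lab cross: 28 sons and 27 daughters, ten 30-Mb
chromosomes with ~1 RAD locus per 30 kb, and a sex-determination region
on LG5 (6.8-20.3 Mb) where recombination is fully suppressed in the
father.  Ten percent of SD-region loci are Y-limited (present only on
the Y haplotype), ten percent are deleted from the Y.
"""

from radsexmap import CrossDesign, simulate_cross

design = CrossDesign(seed=1)
sim = simulate_cross(design)

print(f"offspring: {design.n_sons} sons + {design.n_daughters} daughters")
print(f"simulated loci: {len(sim.depths)}, SNPs emitted: {sim.genotypes.n_sites}")
print("planted locus classes:", sim.truth.loci["true_class"].value_counts().to_dict())

# Y-limited loci carry no genotype rows (a diploid caller never sees them)
# but they do carry depth: near depth_mean/2 in sons, near zero in daughters.
ylim = sim.truth.loci.query("true_class == 'Y_LIMITED'")["locus_id"]
sons = [s for s in sim.depths.columns if s.startswith("son")]
daus = [s for s in sim.depths.columns if s.startswith("dau")]
print(
    f"Y-limited mean depth: sons {sim.depths.loc[ylim, sons].values.mean():.1f}, "
    f"daughters {sim.depths.loc[ylim, daus].values.mean():.2f} "
    "(hemizygous dose vs contamination floor)"
)
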