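"""Chromosome-level inference: enrichment, Manhattan table, SD region.

Per chromosome, a two-sided Fisher exact test asks whether male-only
coverage loci are over-represented; sliding-window density of the most
significant association SNPs localizes the sex-determination region.
"""

from radsexmap import (
    CrossDesign,
    assoc_scan,
    call_sd_region,
    chrom_enrichment,
    classify_table,
    manhattan_table,
    sex_means,
    simulate_cross,
)

sim = simulate_cross(CrossDesign(seed=1))
records = assoc_scan(sim.genotypes)
means = sex_means(sim.depths, sim.genotypes.individuals)
classes = classify_table(means, placement=sim.placement)

enrich = chrom_enrichment(classes, "MALE_ONLY")
print("male-only enrichment, top 3 chromosomes:")
print(enrich.head(3).to_string(index=False))

man = manhattan_table(records)
peak = man.loc[man["neglog10_p"].idxmax()]
print(f"\nManhattan peak: {peak['chrom']}:{int(peak['pos'])} -log10 p = {peak['neglog10_p']:.1f}")

region = call_sd_region(records, alpha=0.001, window_mb=2.0, min_hits=3)
print(
    f"called SD region: {region.chrom}:{region.start/1e6:.1f}-{region.end/1e6:.1f} Mb "
    f"({region.n_hits} significant SNPs, {region.density:.1f}/Mb)"
)
print(f"planted SD region: {sim.design.sd_chrom_label}:"
      f"{sim.design.sd_region[0]/1e6:.1f}-{sim.design.sd_region[1]/1e6:.1f} Mb")
print(
    "\nThe enrichment p-value and the window call converge on the planted "
    "chromosome; the called interval overlaps the planted one but its "
    "bounds wobble with where the significant SNPs happen to cluster, "
    "since partially linked flanking SNPs also reach significance."
)
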