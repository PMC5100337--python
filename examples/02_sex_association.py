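"""Between-sex association: F_ST and Fisher exact test per SNP.

Sons and daughters are treated as two populations; a SNP tightly linked
to the sex-determining locus shows a large allele-frequency difference
between them and a tiny exact-test p-value.
"""

from radsexmap import CrossDesign, assoc_scan, simulate_cross, top_sites

sim = simulate_cross(CrossDesign(seed=1))
records = assoc_scan(sim.genotypes, gate_alpha=0.05)

sig = records[records["fisher_p"] < 0.001]
print(f"SNPs scored: {len(records)}; with p < 0.001: {len(sig)}")
print("significant SNPs per chromosome:", sig["chrom"].value_counts().to_dict())

print("\nfive most significant sites (rank by exact-test p):")
cols = ["site_id", "chrom", "pos", "fst", "fisher_p"]
print(top_sites(records, n=5)[cols].to_string(index=False))
print(
    "\nAll top hits sit on the planted sex chromosome "
    f"({sim.design.sd_chrom_label}). F_ST plateaus near 1/3, the maximum "
    "for an XY-informative site in a single cross: sons are all Aa and "
    "daughters all AA, so the sexes still share the X-borne allele."
)
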