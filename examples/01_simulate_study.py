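"""Generate a synthetic capture-genotyping study.

Draws candidate SNP sites from four source databases with distinct MAF
spectra, Hardy-Weinberg genotypes, and per-region capture depths with
realistic non-uniformity, then prints the study's headline dimensions.
"""

from gbtspanel import SimSpec, simulate_depths, simulate_genotypes, simulate_sites

spec = SimSpec(n_samples=50, seed=1)
sites = simulate_sites(spec)
genotypes = simulate_genotypes(sites, spec.n_samples, spec.missing_rate, seed=2)
depths = simulate_depths(list(sites["site_id"]), spec.n_samples, spec.depth, seed=3)

print(f"candidate sites: {len(sites)}")
print(sites["source_db"].value_counts().to_string())
print(f"genotype matrix: {genotypes.n_samples} samples x {genotypes.n_sites} sites")
print(f"missing calls: {(genotypes.calls < 0).mean() * 100:.2f}%")
print(f"mean region depth: {depths.depth.mean():.1f}X")
# Each database mimics a real SNP source: db4's Beta law concentrates its
# allele frequencies near 0, so most of its sites will be near-monomorphic.
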