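"""Diversity statistics: MAF, PIC, Ao, Ae, Ho, He and attribution tables.

PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2 measures a site's
informativeness for linkage analysis; for a balanced biallelic SNP it
peaks at 0.375.
"""

from gbtspanel import (
    SimSpec, database_attribution, diversity_table, pic, simulate_genotypes,
    simulate_sites, summarize_marker_set,
)
from gbtspanel.site_selection import compute_maf_all

print(f"PIC of a 50/50 biallelic site: {pic([0.5, 0.5])}")

spec = SimSpec(n_samples=100, seed=9)
sites = simulate_sites(spec)
gm = simulate_genotypes(sites, spec.n_samples, 0.0, seed=10)

div = diversity_table(gm)
print(summarize_marker_set(div).to_string(index=False))

with_maf = gm.sites.assign(maf=compute_maf_all(gm))
print(database_attribution(with_maf).to_string(index=False))
# The attribution table mirrors how each source database contributes
# polymorphic (MAF > 0.05) sites to the panel.
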