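"""Capture-probe design against a toy reference.

110 bp windows overlapping each target site are tiled every 10 bp and
filtered on GC content (30-70%) and exact two-strand homology count
(< 3 for background sites, < 5 for trait loci); up to 2 or 3 survivors
closest to 50% GC are kept.
"""

from gbtspanel import CandidateSite, design_probes, simulate_reference

reference = simulate_reference({"chrA": 50_000}, seed=13)

background = CandidateSite("bg1", "chrA", 25_000, "A", "G")
trait = CandidateSite("tr1", "chrA", 30_000, "A", "G",
                      source_db="trait", is_trait_marker=True)

for site in (background, trait):
    probes = design_probes(site, reference)
    kind = "trait" if site.is_trait_marker else "background"
    print(f"{site.site_id} ({kind}): {len(probes)} probe(s)")
    for p in probes:
        print(f"  {p.probe_id}: {p.chrom}:{p.start}-{p.end} "
              f"GC={p.gc_fraction:.2f} homology={p.homology_count}")
# A homology count of 1 means the probe occurs exactly once in the
# genome (its own locus) on either strand.
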