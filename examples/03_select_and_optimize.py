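"""Background-site selection at 40X and five-criterion panel optimization.

Sites failing missing rate < 0.1, site uniformity > 0.25 or target rate
> 0.5 (at simulated 40X) are discarded; discarded sites with MAF > 0.05
form a reinsertion pool the optimizer uses to close chromosome gaps and
raise the polymorphic shares under a < 1% reinsertion budget.
"""

from gbtspanel import (
    SimSpec, compute_site_qc, downsample_depth, optimize, select_background,
    simulate_depths, simulate_genotypes, simulate_optimizer_fixture, simulate_sites,
)

spec = SimSpec(n_samples=60, seed=4)
sites = simulate_sites(spec)
gm = simulate_genotypes(sites, spec.n_samples, spec.missing_rate, seed=5)
dm = simulate_depths(list(sites["site_id"]), spec.n_samples, spec.depth, seed=6)
dm40 = downsample_depth(dm, nominal_depth=40, seed=7)

qc = compute_site_qc(gm, dm40)
selected, discarded = select_background(qc, sites=gm.sites)
print(f"selected {len(selected)} high-confidence sites, discarded {len(discarded)}")
print("discard reasons:", discarded["failed"].value_counts().to_dict())

# optimization demo on a deliberately feasible fixture
sel, disc, trait, cfg = simulate_optimizer_fixture(seed=0)
panel = optimize(sel, disc, trait, cfg)
print("optimizer report:", panel.report["criteria"])
print(f"reinserted {panel.report['reinserted_count']} sites "
      f"(budget {panel.report['budget']}); panel accounting: {panel.accounting}")
# 'criteria' flags gap / budget / maf05_share / top_bin_share; unmet
# criteria are reported rather than forced.
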