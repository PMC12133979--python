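"""Synthetic-data generation for end-to-end testing of the panel pipeline.

The generator emulates the statistical structure the analysis assumes:

* twelve chromosomes with the SL2.40 tomato assembly lengths (scaled down
  by a configurable factor for desk-scale runs),
* four candidate-site source databases with distinct minor-allele-frequency
  spectra, each database drawing its true alternate-allele frequency from a
  Beta law (database 4 concentrated near zero, mimicking its very low
  polymorphic share),
* Hardy-Weinberg genotypes from the true frequencies with independent
  per-call missingness,
* per-region capture depth with log-normal region multipliers (capture
  non-uniformity), an off-target read fraction and a duplicate fraction,
* trait-marker loci with known resistant/susceptible alleles and a planted
  per-sample resistance truth, so caller recovery is checkable end to end.

Everything is driven by ``numpy.random.Generator``; identical spec + seed
gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import SITE_COLUMNS, GenotypeMatrix, DepthMatrix
from .errors import CapacityError, ParameterError, ValidationError
from .trait_markers import TraitMarkerDef, TraitSite

#: SL2.40 tomato chromosome lengths in Mbp.
SL240_CHROM_LENGTHS_MBP: dict[str, float] = {
    "SL2.40ch01": 90.30,
    "SL2.40ch02": 49.92,
    "SL2.40ch03": 64.84,
    "SL2.40ch04": 64.06,
    "SL2.40ch05": 65.02,
    "SL2.40ch06": 46.04,
    "SL2.40ch07": 65.27,
    "SL2.40ch08": 63.03,
    "SL2.40ch09": 67.66,
    "SL2.40ch10": 64.83,
    "SL2.40ch11": 53.39,
    "SL2.40ch12": 65.49,
}

#: Published candidate-site counts of the four source databases.
DEFAULT_DB_COUNTS: dict[str, int] = {
    "db1": 8744, "db2": 680, "db3": 1248, "db4": 1552,
}

#: Beta(a, b) laws for the true alternate-allele frequency per database,
#: calibrated via the Beta CDF so each database's expected MAF > 0.05 share
#: matches its real-source counterpart (about 68%, 54%, 90% and 1.4%):
#: db1/db2 moderately polymorphic, db3 strongly, db4 almost monomorphic.
DEFAULT_DB_BETA: dict[str, tuple[float, float]] = {
    "db1": (0.46, 1.5),
    "db2": (0.31, 1.5),
    "db3": (0.92, 1.3),
    "db4": (0.009, 3.0),
}

_BASES = np.array(list("ACGT"))


@dataclass
class DepthModel:
    """Capture-depth model: Poisson depths around log-normal region multipliers."""

    mean_depth: float = 100.0
    sigma: float = 0.7
    off_target_fraction: float = 0.30
    duplicate_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if not 0.0 <= self.off_target_fraction < 1.0:
            raise ParameterError("off_target_fraction must be in [0, 1)")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ParameterError("duplicate_fraction must be in [0, 1]")


@dataclass
class SimSpec:
    """Full configuration of a synthetic study."""

    n_samples: int = 136
    chrom_lengths_mbp: dict[str, float] = field(
        default_factory=lambda: dict(SL240_CHROM_LENGTHS_MBP)
    )
    chrom_scale: float = 0.01
    db_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DB_COUNTS))
    db_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DB_BETA)
    )
    missing_rate: float = 0.01
    depth: DepthModel = field(default_factory=DepthModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must be in [0, 1]")
        if self.chrom_scale <= 0:
            raise ValidationError("chrom_scale must be positive")
        if any(c < 0 for c in self.db_counts.values()):
            raise ValidationError("database site counts must be >= 0")

    def chrom_lengths_bp(self) -> dict[str, int]:
        return {
            c: max(1, int(round(mbp * 1e6 * self.chrom_scale)))
            for c, mbp in self.chrom_lengths_mbp.items()
        }


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions uniform on [1, length]."""
    if n > length:
        raise CapacityError(f"requested {n} sites on a {length} bp chromosome")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(1, length + 1, size=n - len(chosen))
        chosen.update(int(x) for x in draw)
    return np.sort(np.fromiter(chosen, dtype=np.int64))


def _allocate(counts_total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of counts_total across weights."""
    raw = counts_total * weights / weights.sum()
    alloc = np.floor(raw).astype(int)
    rem = counts_total - alloc.sum()
    order = np.argsort(-(raw - alloc))
    alloc[order[:rem]] += 1
    return alloc


def simulate_sites(spec: SimSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw candidate sites for each source database.

    Returns the canonical site table with one extra column,
    ``true_alt_freq`` — the population alternate-allele frequency each
    site's genotypes will be drawn from.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lengths = spec.chrom_lengths_bp()
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    rows = []
    for db in sorted(spec.db_counts):
        total = spec.db_counts[db]
        if total == 0:
            continue
        a, b = spec.db_beta[db]
        alloc = _allocate(total, weights)
        k = 0
        for chrom, n_chrom in zip(chroms, alloc):
            positions = _sample_positions(rng, lengths[chrom], n_chrom)
            freqs = rng.beta(a, b, size=n_chrom)
            ref_idx = rng.integers(0, 4, size=n_chrom)
            alt_idx = (ref_idx + rng.integers(1, 4, size=n_chrom)) % 4
            for pos, p, ri, ai in zip(positions, freqs, ref_idx, alt_idx):
                rows.append((
                    f"{db}_s{k:06d}", chrom, int(pos),
                    _BASES[ri], _BASES[ai], "SNP", db, False, float(p),
                ))
                k += 1
    df = pd.DataFrame(rows, columns=[*SITE_COLUMNS, "true_alt_freq"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_genotypes(
    sites: pd.DataFrame,
    n_samples: int,
    missing_rate: float,
    seed: int,
    *,
    founder_mixture: bool = False,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes from each site's ``true_alt_freq``.

    Missingness is independent per (sample, site) at ``missing_rate``.
    With ``founder_mixture`` each sample inherits one allele from a single
    shared founder haplotype, giving half-sibling-like relatedness for
    qualitative demonstrations (the HWE calibration properties no longer
    hold in that mode).
    """
    if "true_alt_freq" not in sites.columns:
        raise ValidationError("sites must carry a true_alt_freq column")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValidationError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = sites["true_alt_freq"].to_numpy(dtype=float)
    n_sites = len(sites)
    if founder_mixture:
        founder = rng.binomial(1, p)  # one shared parental haplotype
        calls = founder[None, :] + rng.binomial(1, p, size=(n_samples, n_sites))
    else:
        calls = rng.binomial(2, p, size=(n_samples, n_sites))
    calls = calls.astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(size=calls.shape) < missing_rate] = -1
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=samples,
        sites=sites[list(SITE_COLUMNS)].reset_index(drop=True),
        calls=calls,
    )


def simulate_depths(
    regions,
    n_samples: int,
    model: DepthModel,
    seed: int,
    *,
    sample_prefix: str = "S",
) -> DepthMatrix:
    """Per-region Poisson depths with log-normal capture multipliers.

    ``depth(s, r) ~ Poisson(mean_depth * m_r)`` with ``m_r ~
    LogNormal(0, sigma^2)`` drawn once per region; per-sample totals are
    derived so that ``on_target_reads`` is the row sum, ``total_reads``
    back-solves the off-target fraction, and duplicates are a fixed share
    of the total.
    """
    regions = list(regions)
    rng = np.random.default_rng(seed)
    multipliers = rng.lognormal(0.0, model.sigma, size=len(regions))
    lam = model.mean_depth * multipliers
    depth = rng.poisson(lam, size=(n_samples, len(regions))).astype(np.int64)
    on_target = depth.sum(axis=1)
    total = np.round(on_target / (1.0 - model.off_target_fraction)).astype(np.int64)
    total = np.maximum(total, on_target)
    duplicates = np.round(model.duplicate_fraction * total).astype(np.int64)
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    totals = pd.DataFrame(
        {
            "total_reads": total,
            "on_target_reads": on_target,
            "duplicate_reads": duplicates,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return DepthMatrix(samples=samples, regions=regions, depth=depth, totals=totals)


# ---------------------------------------------------------------------------
# Trait-marker truth fixtures
# ---------------------------------------------------------------------------

_STATUSES = np.array(["resistant", "heterozygous", "susceptible"])


def simulate_trait_truth(
    n_genes: int,
    sites_per_gene: int,
    n_samples: int,
    seed: int,
    *,
    missing_rate: float = 0.0,
    status_probs: tuple[float, float, float] = (0.4, 0.3, 0.3),
):
    """Plant a known resistance status per (sample, gene) and emit
    genotypes consistent with it.

    Genes with one site use the single-point determination form, genes
    with several sites the haplotype form.  The reference allele plays the
    susceptible role and the alternate allele the resistant role at every
    constituent site.  Returns ``(defs, genotypes, truth)`` where *truth*
    is a samples x genes DataFrame of planted statuses.
    """
    if sites_per_gene < 1:
        raise ValidationError("sites_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(SL240_CHROM_LENGTHS_MBP)
    defs: list[TraitMarkerDef] = []
    site_rows = []
    for g in range(n_genes):
        gene = f"TG{g + 1:02d}"
        sites = []
        for k in range(sites_per_gene):
            site_id = f"{gene}_m{k + 1}"
            chrom = chroms[(g * sites_per_gene + k) % len(chroms)]
            pos = 1000 * (g * sites_per_gene + k + 1)
            site_rows.append((site_id, chrom, pos, "A", "G", "SNP", "trait", True))
            sites.append(TraitSite(site_id=site_id, resistant_allele="G", susceptible_allele="A"))
        form = "single_point" if sites_per_gene == 1 else "haplotype"
        defs.append(TraitMarkerDef(
            gene=gene, disease=f"disease{g + 1:02d}", sites=sites, form=form,
        ))
    sites_df = pd.DataFrame(site_rows, columns=list(SITE_COLUMNS))

    truth = rng.choice(_STATUSES, size=(n_samples, n_genes), p=list(status_probs))
    calls = np.empty((n_samples, n_genes * sites_per_gene), dtype=np.int8)
    for g in range(n_genes):
        cols = slice(g * sites_per_gene, (g + 1) * sites_per_gene)
        for i in range(n_samples):
            status = truth[i, g]
            if status == "resistant":
                states = np.full(sites_per_gene, 2, dtype=np.int8)
            elif status == "heterozygous":
                # at least one heterozygous site, the rest homozygous resistant
                states = np.where(rng.random(sites_per_gene) < 0.5, 1, 2).astype(np.int8)
                if not (states == 1).any():
                    states[0] = 1
            else:
                # at least one homozygous-susceptible site, the rest arbitrary
                states = rng.integers(0, 3, size=sites_per_gene).astype(np.int8)
                if not (states == 0).any():
                    states[0] = 0
            calls[i, cols] = states
    if missing_rate > 0:
        calls[rng.random(size=calls.shape) < missing_rate] = -1
    samples = [f"S{i:04d}" for i in range(n_samples)]
    gm = GenotypeMatrix(samples=samples, sites=sites_df, calls=calls)
    truth_df = pd.DataFrame(truth, index=samples, columns=[d.gene for d in defs])
    return defs, gm, truth_df


# ---------------------------------------------------------------------------
# Optimizer fixture
# ---------------------------------------------------------------------------

def simulate_optimizer_fixture(
    n_selected: int = 2000,
    n_discarded: int = 500,
    n_trait: int = 40,
    seed: int = 0,
    chrom_scale: float = 0.01,
):
    """A feasible panel-optimization problem on 12 scaled chromosomes.

    Eleven chromosomes receive densely, evenly spaced selected sites whose
    mean adjacent gap already satisfies the scaled 0.3 Mbp constraint; the
    last chromosome is deliberately sparse (mean gap just above the
    threshold) and the discarded pool contains polymorphic sites inside its
    span, so gap repair succeeds within the 1% reinsertion budget.  MAF
    values are drawn so that the MAF > 0.05 background share and the
    top-class share already exceed their floors.

    Returns ``(selected, discarded, trait, config)`` — three site tables
    with a ``maf`` column and the matching :class:`RunConfig`.
    """
    rng = np.random.default_rng(seed)
    lengths = {
        c: int(round(mbp * 1e6 * chrom_scale))
        for c, mbp in SL240_CHROM_LENGTHS_MBP.items()
    }
    chroms = list(lengths)
    max_gap = 300_000.0 * chrom_scale  # scaled 0.3 Mbp constraint

    dense_chroms = chroms[:-1]
    sparse_chrom = chroms[-1]
    n_sparse = 60
    n_dense = n_selected - n_sparse
    weights = np.array([lengths[c] for c in dense_chroms], dtype=float)
    alloc = _allocate(n_dense, weights)

    def _maf_mix(rng, n, share_le05=0.38, share_top=0.21):
        """MAF vector with the given spectrum shares, shuffled."""
        n_low = int(round(share_le05 * n))
        n_top = int(round(share_top * n))
        n_mid = n - n_low - n_top
        vals = np.concatenate([
            rng.uniform(0.0, 0.05, n_low),
            rng.uniform(0.06, 0.40, n_mid),
            rng.uniform(0.41, 0.50, n_top),
        ])
        rng.shuffle(vals)
        return vals

    rows = []
    k = 0
    spacing = 0.8 * max_gap
    spans: dict[str, int] = {}
    for chrom, n_chrom in zip(dense_chroms, alloc):
        # even spacing at 80% of the gap ceiling, anchored at the start
        positions = (1 + spacing * np.arange(n_chrom)).astype(np.int64)
        if positions[-1] > lengths[chrom]:
            raise CapacityError(f"dense layout exceeds {chrom} length")
        spans[chrom] = int(positions[-1])
        for pos in positions:
            rows.append((f"sel_{k:05d}", chrom, int(pos)))
            k += 1
    # sparse chromosome: mean gap ~17% above the ceiling
    sparse_spacing = 1.17 * max_gap
    positions = (1 + sparse_spacing * np.arange(n_sparse)).astype(np.int64)
    sparse_span = (int(positions[0]), int(positions[-1]))
    spans[sparse_chrom] = int(positions[-1])
    for pos in positions:
        rows.append((f"sel_{k:05d}", sparse_chrom, int(pos)))
        k += 1
    selected = pd.DataFrame(rows, columns=["site_id", "chrom", "pos"])
    selected["ref_allele"] = "A"
    selected["alt_allele"] = "G"
    selected["variant_class"] = "SNP"
    selected["source_db"] = rng.choice(["db1", "db2", "db3", "db4"], size=len(selected),
                                       p=[0.75, 0.05, 0.07, 0.13])
    selected["is_trait_marker"] = False
    selected["maf"] = _maf_mix(rng, len(selected))

    # discarded pool: polymorphic sites inside the sparse span plus filler
    n_in_span = 60
    pool_pos = rng.integers(sparse_span[0] + 1, sparse_span[1], size=n_in_span)
    rows = [
        (f"disc_{i:05d}", sparse_chrom, int(p)) for i, p in enumerate(np.unique(pool_pos))
    ]
    n_filler = n_discarded - len(rows)
    filler_chrom = rng.choice(dense_chroms, size=n_filler)
    filler_pos = np.array([rng.integers(1, lengths[c] + 1) for c in filler_chrom])
    rows += [
        (f"disc_f{i:05d}", c, int(p)) for i, (c, p) in enumerate(zip(filler_chrom, filler_pos))
    ]
    discarded = pd.DataFrame(rows, columns=["site_id", "chrom", "pos"])
    discarded["ref_allele"] = "A"
    discarded["alt_allele"] = "G"
    discarded["variant_class"] = "SNP"
    discarded["source_db"] = "db1"
    discarded["is_trait_marker"] = False
    # pool sites polymorphic, filler mostly monomorphic
    maf = rng.uniform(0.0, 0.05, size=len(discarded))
    in_span = discarded["chrom"].eq(sparse_chrom).to_numpy()
    maf[in_span] = rng.uniform(0.10, 0.50, size=in_span.sum())
    high = rng.random(len(discarded)) < 0.3
    maf[high & ~in_span] = rng.uniform(0.06, 0.50, size=(high & ~in_span).sum())
    discarded["maf"] = maf

    # trait sites inside the selected spans so they never open new gaps
    trait_rows = []
    for i in range(n_trait):
        chrom = chroms[i % len(chroms)]
        trait_rows.append((f"tsm_{i:03d}", chrom, int(rng.integers(1, spans[chrom] + 1))))
    trait = pd.DataFrame(trait_rows, columns=["site_id", "chrom", "pos"])
    trait["ref_allele"] = "A"
    trait["alt_allele"] = "G"
    trait["variant_class"] = "SNP"
    trait["source_db"] = "trait"
    trait["is_trait_marker"] = True
    trait["maf"] = _maf_mix(rng, n_trait)

    config = RunConfig(max_mean_gap_bp=max_gap)
    return selected, discarded, trait, config


# ---------------------------------------------------------------------------
# Toy reference sequence
# ---------------------------------------------------------------------------

def simulate_reference(chrom_lengths: dict[str, int], seed: int) -> dict[str, str]:
    """Uniform-random reference sequences for probe design demos."""
    rng = np.random.default_rng(seed)
    return {
        chrom: "".join(_BASES[rng.integers(0, 4, size=length)])
        for chrom, length in chrom_lengths.items()
    }
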