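"""Trait-specific resistance-marker definitions and per-sample gene calls.

A gene's status is determined either from a single diagnostic site
("single-point form") or jointly from several linked sites ("haplotype
form").  Per site the diploid call is classified as

    R  homozygous for the resistant allele,
    H  heterozygous resistant/susceptible,
    S  homozygous for the susceptible allele,
    M  missing,

and the haplotype rule maps the site states to a gene status: any missing
site makes the call a ``no_call``; otherwise one homozygous-susceptible
site is decisive (``susceptible``); otherwise any heterozygous site gives
``heterozygous``; a gene is called ``resistant`` only when every site is
homozygous resistant.  Inter-laboratory agreement per gene is compared
against a 90% confirmation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import DefinitionError, ValidationError

STATUSES = ("resistant", "heterozygous", "susceptible", "no_call")

#: Default agreement threshold above which a gene's presence is confirmed.
CONFIRMATION_THRESHOLD = 0.90


@dataclass(frozen=True)
class TraitSite:
    site_id: str
    resistant_allele: str
    susceptible_allele: str

    def __post_init__(self) -> None:
        if self.resistant_allele == self.susceptible_allele:
            raise ValidationError(
                f"{self.site_id}: resistant and susceptible alleles must differ"
            )


@dataclass(frozen=True)
class TraitMarkerDef:
    gene: str
    disease: str
    sites: tuple
    form: str  # "single_point" | "haplotype"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.form not in ("single_point", "haplotype"):
            raise ValidationError(f"{self.gene}: unknown form {self.form!r}")
        if self.form == "single_point" and len(self.sites) != 1:
            raise ValidationError(f"{self.gene}: single-point form requires exactly 1 site")
        if self.form == "haplotype" and len(self.sites) < 2:
            raise ValidationError(f"{self.gene}: haplotype form requires >= 2 sites")


@dataclass(frozen=True)
class GeneCall:
    sample_id: str
    gene: str
    status: str
    evidence: tuple  # ((site_id, state), ...)


def _site_state(code: int, site: TraitSite, ref: str, alt: str) -> str:
    """Classify one coded diploid call against the definition's alleles."""
    if code < 0:
        return "M"
    alleles = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt)}[int(code)]
    r, s = site.resistant_allele, site.susceptible_allele
    known = {r, s}
    if not set(alleles) <= known:
        raise DefinitionError(
            f"site {site.site_id}: genotype allele outside "
            f"the defined resistant/susceptible pair {sorted(known)}"
        )
    n_resistant = sum(a == r for a in alleles)
    return {2: "R", 1: "H", 0: "S"}[n_resistant]


def combine_states(states) -> str:
    """Gene status from per-site states (order-invariant)."""
    states = list(states)
    if not states:
        raise ValidationError("cannot combine an empty state list")
    if "M" in states:
        return "no_call"
    if "S" in states:
        return "susceptible"
    if "H" in states:
        return "heterozygous"
    return "resistant"


def call_gene(gm: GenotypeMatrix, tdef: TraitMarkerDef, sample: str) -> GeneCall:
    """Call one gene's resistance status for one sample."""
    try:
        i = gm.samples.index(sample)
    except ValueError:
        raise ValidationError(f"sample {sample!r} absent from genotype matrix") from None
    evidence = []
    meta = gm.sites.set_index("site_id")
    for tsite in tdef.sites:
        if tsite.site_id not in meta.index:
            raise DefinitionError(
                f"gene {tdef.gene}: definition site {tsite.site_id!r} "
                "absent from the genotype matrix"
            )
        row = meta.loc[tsite.site_id]
        code = int(gm.site_column(tsite.site_id)[i])
        evidence.append((tsite.site_id, _site_state(code, tsite, row.ref_allele, row.alt_allele)))
    status = combine_states(state for _, state in evidence)
    return GeneCall(sample_id=sample, gene=tdef.gene, status=status, evidence=tuple(evidence))


def call_gene_all(gm: GenotypeMatrix, tdef: TraitMarkerDef) -> pd.Series:
    """Vectorized per-sample status for one gene (index = sample ids)."""
    meta = gm.sites.set_index("site_id")
    state_codes = np.empty((gm.n_samples, len(tdef.sites)), dtype="<U1")
    for k, tsite in enumerate(tdef.sites):
        if tsite.site_id not in meta.index:
            raise DefinitionError(
                f"gene {tdef.gene}: definition site {tsite.site_id!r} "
                "absent from the genotype matrix"
            )
        row = meta.loc[tsite.site_id]
        col = gm.site_column(tsite.site_id)
        for i in range(gm.n_samples):
            state_codes[i, k] = _site_state(int(col[i]), tsite, row.ref_allele, row.alt_allele)
    statuses = [combine_states(state_codes[i]) for i in range(gm.n_samples)]
    return pd.Series(statuses, index=gm.samples, name=tdef.gene)


def screen_population(gm: GenotypeMatrix, defs) -> pd.DataFrame:
    """Per-gene counts and fractions of each status over all samples.

    Genes keep the order of ``defs``.  Fractions sum to 1 per gene.
    """
    rows = []
    for tdef in defs:
        statuses = call_gene_all(gm, tdef)
        counts = statuses.value_counts()
        row = {"gene": tdef.gene, "disease": tdef.disease, "form": tdef.form,
               "n_samples": gm.n_samples}
        for status in STATUSES:
            c = int(counts.get(status, 0))
            row[f"n_{status}"] = c
            row[f"frac_{status}"] = c / gm.n_samples
        rows.append(row)
    return pd.DataFrame(rows)


def concordance(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    threshold: float = CONFIRMATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene agreement between two call sets (samples x genes tables).

    Sample pairs where either side is ``no_call`` are excluded from the
    denominator and reported in ``n_excluded``.  A gene is confirmed when
    the agreement rate reaches the threshold; with no comparable pairs the
    agreement is undefined (NaN) and the gene is not confirmed.
    """
    if list(calls_a.index) != list(calls_b.index):
        raise ValidationError("call sets must cover the same samples, in order")
    if list(calls_a.columns) != list(calls_b.columns):
        raise ValidationError("call sets must cover the same genes, in order")
    rows = []
    for gene in calls_a.columns:
        a, b = calls_a[gene], calls_b[gene]
        comparable = (a != "no_call") & (b != "no_call")
        n_comp = int(comparable.sum())
        n_excluded = len(a) - n_comp
        if n_comp == 0:
            agreement = float("nan")
            confirmed = False
        else:
            agreement = float((a[comparable] == b[comparable]).mean())
            confirmed = agreement >= threshold
        rows.append({
            "gene": gene, "n_compared": n_comp, "n_excluded": n_excluded,
            "agreement": agreement, "confirmed": confirmed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Definition-table I/O (one TSV row per constituent site)
# ---------------------------------------------------------------------------

DEF_COLUMNS = ["gene", "disease", "form", "site_id", "resistant_allele", "susceptible_allele"]


def write_trait_defs(defs, path) -> None:
    rows = [
        (d.gene, d.disease, d.form, s.site_id, s.resistant_allele, s.susceptible_allele)
        for d in defs for s in d.sites
    ]
    pd.DataFrame(rows, columns=DEF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trait_defs(path) -> list[TraitMarkerDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != DEF_COLUMNS:
        raise ValidationError(f"{path}: unexpected trait-definition columns {list(df.columns)}")
    defs = []
    for (gene, disease, form), grp in df.groupby(["gene", "disease", "form"], sort=False):
        sites = [
            TraitSite(site_id=r.site_id, resistant_allele=r.resistant_allele,
                      susceptible_allele=r.susceptible_allele)
            for r in grp.itertuples(index=False)
        ]
        defs.append(TraitMarkerDef(gene=gene, disease=disease, sites=sites, form=form))
    return defs
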