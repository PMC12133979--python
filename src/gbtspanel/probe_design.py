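"""Capture-probe design against a reference sequence.

For each target site, 110 bp candidate windows overlapping the site are
tiled at a fixed stride and filtered on GC content (30-70%, inclusive) and
on the homology count: the number of exact full-length occurrences of the
probe or its reverse complement anywhere in the reference (overlaps
counted; a unique probe scores 1, its own locus).  Background sites accept
counts < 3 and keep up to 2 probes; trait-specific sites accept counts < 5
and keep up to 3.  Survivors closest to 50% GC win, ties broken by the
smaller start coordinate.  An empty result is a legal, reported outcome —
some loci simply cannot host a compliant probe.

Homology here is exact-match, not alignment-based: the count semantics are
implementable, deterministic and oracle-verifiable, and the thresholds
keep their published meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .core import DNA_ALPHABET, CandidateSite
from .errors import GbtsPanelError, ValidationError

#: Tiling stride (bp) between candidate window starts.
CANDIDATE_STRIDE = 10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Probe:
    probe_id: str
    site_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    sequence: str
    gc_fraction: float
    homology_count: int


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length; ambiguity codes are rejected."""
    if not sequence:
        raise ValidationError("empty sequence")
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise ValidationError(f"unsupported characters in sequence: {sorted(bad)}")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _count_overlapping(needle: str, haystack: str) -> int:
    count = start = 0
    while True:
        hit = haystack.find(needle, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1


def homology_count(probe_sequence: str, reference: dict[str, str] | str) -> int:
    """Exact occurrences of the probe or its reverse complement across all
    reference sequences, counting overlaps.

    The probe's own source locus is one occurrence, so a genome-unique
    probe scores 1.  A palindromic probe is not double-counted.
    """
    if isinstance(reference, str):
        reference = {"ref": reference}
    if not reference or all(not s for s in reference.values()):
        raise ValidationError("empty reference")
    rc = reverse_complement(probe_sequence)
    total = 0
    for seq in reference.values():
        total += _count_overlapping(probe_sequence, seq)
        if rc != probe_sequence:
            total += _count_overlapping(rc, seq)
    return total


def design_probes(
    site: CandidateSite,
    reference: dict[str, str],
    config: RunConfig | None = None,
) -> list[Probe]:
    """Design up to 2 (background) or 3 (trait) compliant probes for a site."""
    config = config or RunConfig()
    if site.chrom not in reference:
        raise GbtsPanelError(f"chromosome {site.chrom!r} absent from reference")
    chrom_seq = reference[site.chrom]
    length = config.probe_length
    if site.pos > len(chrom_seq):
        raise ValidationError(
            f"{site.site_id}: position {site.pos} beyond {site.chrom} length {len(chrom_seq)}"
        )
    if site.is_trait_marker:
        homology_limit = config.homology_max_trait
        cap = config.max_probes_trait
    else:
        homology_limit = config.homology_max_background
        cap = config.max_probes_background

    # every window of `length` bp containing the site, tiled at the stride
    first_start = max(1, site.pos - length + 1)
    last_start = min(site.pos, len(chrom_seq) - length + 1)
    candidates = []
    for start in range(first_start, last_start + 1, CANDIDATE_STRIDE):
        seq = chrom_seq[start - 1: start - 1 + length]
        if len(seq) < length or set(seq) - DNA_ALPHABET:
            continue
        gc = gc_fraction(seq)
        if not config.gc_min <= gc <= config.gc_max:
            continue
        hom = homology_count(seq, reference)
        if hom >= homology_limit:
            continue
        candidates.append((abs(gc - 0.5), start, seq, gc, hom))

    candidates.sort(key=lambda c: (c[0], c[1]))
    probes = []
    for k, (_, start, seq, gc, hom) in enumerate(candidates[:cap]):
        probes.append(Probe(
            probe_id=f"{site.site_id}_p{k + 1}",
            site_id=site.site_id,
            chrom=site.chrom,
            start=start,
            end=start + length - 1,
            sequence=seq,
            gc_fraction=gc,
            homology_count=hom,
        ))
    return probes
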