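"""miRNA seed-region matching against 3'UTR sequences.

The seed region is the 5' portion of the mature miRNA that nucleates
binding. Three nested seed definitions are used (positions are 1-based on
the mature miRNA, 5'->3'):

* 6-mer: nucleotides 2-7,
* 7-mer: nucleotides 2-8 (the "7mer-m8" site),
* 8-mer: nucleotides 1-8.

A candidate site is an exact Watson-Crick occurrence of the DNA reverse
complement of a seed on the UTR plus strand (U -> T). Because the seeds
nest, an 8-mer site at UTR position p implies a 7-mer site at p and a
6-mer site at p + 1; scanning collapses these to the single longest match
per locus. ``N`` never matches. Positions are 1-based and fully closed.

An association between a dysregulated gene and a dysregulated miRNA is
called a *candidate direct* interaction when the pair has at least one
seed match and a negative regression slope (miRNA up, mRNA down —
consistent with binding-mediated repression); significant associations
without a seed match or with a positive slope are *candidate indirect*
(feedback / feed-forward regulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import SequenceRecord, ValidationError

__all__ = [
    "SeedSet",
    "SeedMatch",
    "InteractionCall",
    "extract_seeds",
    "scan_utr",
    "scan_many",
    "classify_interactions",
]

_RC = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}


def _revcomp_to_dna(rna: str) -> str:
    return "".join(_RC[c] for c in reversed(rna))


@dataclass(frozen=True)
class SeedSet:
    """The nested 6/7/8-nt seeds of one miRNA and their DNA site strings."""

    mirna: str
    seeds: dict[int, str]  # length -> RNA seed
    sites: dict[int, str]  # length -> DNA reverse-complement site


@dataclass(frozen=True)
class SeedMatch:
    mirna: str
    target: str
    seed_length: int
    position: int  # 1-based start of the site on the UTR plus strand
    site: str
    source: str = ""  # optional originating FASTA label


@dataclass(frozen=True)
class InteractionCall:
    gene: str
    mirna: str
    has_seed_match: bool
    beta_sign: str  # "negative" | "positive"
    call: str  # "candidate_direct" | "candidate_indirect"


def extract_seeds(mirna: SequenceRecord) -> SeedSet:
    """Extract the 6/7/8-nt seeds (nt 2-7, 2-8, 1-8) and their DNA sites."""
    if mirna.alphabet != "rna":
        raise ValidationError(f"miRNA {mirna.id!r} must be an RNA sequence")
    if len(mirna) < 8:
        raise ValidationError(
            f"miRNA {mirna.id!r} is {len(mirna)} nt; need >= 8 for seed extraction"
        )
    s = mirna.seq
    seeds = {6: s[1:7], 7: s[1:8], 8: s[0:8]}
    sites = {k: _revcomp_to_dna(v) for k, v in seeds.items()}
    return SeedSet(mirna.id, seeds, sites)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence starts, overlapping occurrences included."""
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return out
        out.append(i)
        start = i + 1


def scan_utr(utr: SequenceRecord, seedset: SeedSet, source: str = "") -> list[SeedMatch]:
    """All seed-site occurrences on a UTR, longest match kept per locus.

    Site geometry: the 7-mer site is the first 7 nt of the 8-mer site and
    the 6-mer site is its last 7..2 nt, so an 8-mer hit at 0-based offset p
    subsumes the 7-mer hit at p and the 6-mer hit at p + 1, and a 7-mer
    hit at p subsumes the 6-mer hit at p + 1. Subsumed shorter matches are
    suppressed; everything else is reported (overlaps included).
    """
    if utr.alphabet != "dna":
        raise ValidationError(f"UTR {utr.id!r} must be a DNA sequence")
    hits = {L: _find_all(utr.seq, seedset.sites[L]) for L in (6, 7, 8)}
    eight = set(hits[8])
    seven = [p for p in hits[7] if p not in eight]
    covered_by_longer = eight | set(seven)
    six = [p for p in hits[6] if (p - 1) not in covered_by_longer]
    matches = [
        SeedMatch(seedset.mirna, utr.id, 8, p + 1, seedset.sites[8], source)
        for p in sorted(eight)
    ]
    matches += [
        SeedMatch(seedset.mirna, utr.id, 7, p + 1, seedset.sites[7], source)
        for p in sorted(seven)
    ]
    matches += [
        SeedMatch(seedset.mirna, utr.id, 6, p + 1, seedset.sites[6], source)
        for p in sorted(six)
    ]
    return sorted(matches, key=lambda m: (m.position, -m.seed_length))


def scan_many(
    utrs: Sequence[SequenceRecord],
    mirnas: Sequence[SequenceRecord],
    source: str = "",
) -> list[SeedMatch]:
    """Scan every UTR against every miRNA."""
    seedsets = [extract_seeds(m) for m in mirnas]
    out: list[SeedMatch] = []
    for utr in utrs:
        for ss in seedsets:
            out.extend(scan_utr(utr, ss, source))
    return out


def classify_interactions(
    assoc: Iterable,  # AssociationResult-like: gene, mirna, beta, significant
    matches: Iterable[SeedMatch],
) -> list[InteractionCall]:
    """Call each significant association candidate direct or indirect.

    candidate_direct  = seed match present and beta < 0;
    candidate_indirect = significant association without a seed match, or
    with a positive beta. One call per significant pair.
    """
    matched = {(m.target, m.mirna) for m in matches}
    calls = []
    for a in assoc:
        if not getattr(a, "significant", True):
            continue
        has = (a.gene, a.mirna) in matched
        neg = a.beta < 0
        call = "candidate_direct" if (has and neg) else "candidate_indirect"
        calls.append(
            InteractionCall(a.gene, a.mirna, has, "negative" if neg else "positive", call)
        )
    return calls
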