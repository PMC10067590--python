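"""CAPS marker discovery: restriction digestion and diagnostic enzymes.

A CAPS (cleaved amplified polymorphic sequence) marker is a sequence variant
that creates or destroys a restriction site, so that digesting the two
alleles of a PCR product gives different fragment patterns on a gel.  This
module digests linear allele sequences in silico with IUPAC-aware Type II
enzyme specs and reports the enzymes whose fragment patterns differ between
two alleles.

Conventions
-----------
* Amplicons are linear PCR products; only linear digestion is modelled.
* Recognition sites are matched on the plus strand; a non-palindromic site is
  additionally matched as its reverse complement, with the cut position
  mapped back to plus-strand coordinates.  Overlapping sites are all counted.
* Ambiguity handling is conservative: a site matches only where the template
  code is *contained* in the site code at every position (an R in the
  template does not satisfy a G in the site, because the enzyme might not
  cut), so reported patterns are guaranteed cuts.
* Reports carry ``n_enzymes_tested``: the bundled enzyme table is a common
  subset, not a full commercial catalogue, so diagnostic counts are only
  comparable between runs using the same table.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from .io_formats import IUPAC_BITS, EnzymeSpec, reverse_complement


@dataclass(frozen=True)
class DigestPattern:
    """Fragment lengths (sorted) from digesting one linear sequence."""

    enzyme: str
    fragment_lengths: tuple[int, ...]
    n_sites: int

    def __post_init__(self) -> None:
        if len(self.fragment_lengths) != self.n_sites + 1:
            raise ValueError("linear digest must yield n_sites + 1 fragments")


@dataclass(frozen=True)
class DiagnosticEnzyme:
    enzyme: str
    pattern_a: DigestPattern
    pattern_b: DigestPattern
    max_fragment_diff: int  # resolvability metric, see find_diagnostic_enzymes


@dataclass(frozen=True)
class DiagnosticReport:
    locus: str
    allele_a: str
    allele_b: str
    diagnostic_enzymes: tuple[DiagnosticEnzyme, ...]
    n_enzymes_tested: int


@lru_cache(maxsize=512)
def _site_regex(site: str) -> "re.Pattern[str]":
    """Lookahead regex matching every start where the template code is
    contained in the site code at all positions (overlaps included)."""
    classes = []
    for code in site:
        mask = IUPAC_BITS[code]
        chars = "".join(c for c, m in IUPAC_BITS.items() if m & ~mask == 0)
        classes.append(f"[{chars}]")
    return re.compile("(?=" + "".join(classes) + ")")


def _scan_one_strand(sequence: str, site: str) -> list[int]:
    """Start positions where the template is contained in the site pattern."""
    return [m.start() for m in _site_regex(site).finditer(sequence)]


def find_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """All cut positions (plus-strand coordinates) of ``enzyme`` in a linear
    sequence.

    For a plus-strand site match at ``s`` the top strand is cut at
    ``s + cut_top``.  For a match of the reverse-complemented site (enzyme
    bound to the minus strand) the plus strand is the enzyme's bottom strand,
    cut at ``s + len(site) - cut_bottom``.  Cuts at identical positions from
    both orientations are merged.
    """
    cuts: set[int] = set()
    n = len(sequence)
    for s in _scan_one_strand(sequence, enzyme.site):
        cuts.add(s + enzyme.cut_top)
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.site)
        for s in _scan_one_strand(sequence, rc):
            cuts.add(s + len(enzyme.site) - enzyme.cut_bottom)
    return sorted(c for c in cuts if 0 < c < n)


def digest(sequence: str, enzyme: EnzymeSpec) -> DigestPattern:
    """Fragment pattern of one linear digest; fragment lengths sum to the
    sequence length."""
    cuts = find_sites(sequence, enzyme)
    bounds = [0] + cuts + [len(sequence)]
    fragments = tuple(
        sorted(b - a for a, b in zip(bounds, bounds[1:]))
    )
    return DigestPattern(
        enzyme=enzyme.name, fragment_lengths=fragments, n_sites=len(cuts)
    )


def _resolvability(pat_a: DigestPattern, pat_b: DigestPattern) -> int:
    """How easily a gel separates the two patterns: the smallest distance
    from any fragment unique to one pattern to the nearest fragment of the
    other (larger = easier to see)."""
    ca, cb = Counter(pat_a.fragment_lengths), Counter(pat_b.fragment_lengths)
    unique_a = list((ca - cb).elements())
    unique_b = list((cb - ca).elements())
    diffs = []
    for frag in unique_a:
        others = pat_b.fragment_lengths
        diffs.append(min((abs(frag - o) for o in others), default=frag))
    for frag in unique_b:
        others = pat_a.fragment_lengths
        diffs.append(min((abs(frag - o) for o in others), default=frag))
    return min(diffs) if diffs else 0


def find_diagnostic_enzymes(
    allele_a: str,
    allele_b: str,
    enzymes: Sequence[EnzymeSpec],
    locus: str = "",
    id_a: str = "allele_a",
    id_b: str = "allele_b",
) -> DiagnosticReport:
    """Enzymes whose fragment patterns differ (as multisets) between alleles.

    Diagnostic enzymes are ranked by the resolvability metric, largest
    first, so the most gel-practical marker comes first.
    """
    diagnostics: list[DiagnosticEnzyme] = []
    for enz in enzymes:
        pa = digest(allele_a, enz)
        pb = digest(allele_b, enz)
        if Counter(pa.fragment_lengths) != Counter(pb.fragment_lengths):
            diagnostics.append(
                DiagnosticEnzyme(
                    enzyme=enz.name,
                    pattern_a=pa,
                    pattern_b=pb,
                    max_fragment_diff=_resolvability(pa, pb),
                )
            )
    diagnostics.sort(key=lambda d: (-d.max_fragment_diff, d.enzyme))
    return DiagnosticReport(
        locus=locus,
        allele_a=id_a,
        allele_b=id_b,
        diagnostic_enzymes=tuple(diagnostics),
        n_enzymes_tested=len(enzymes),
    )
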