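"""Mismatch-tolerant in-silico PCR and amplification-call classification.

Given a primer pair and a template genome, this module finds every binding
site for each primer within a mismatch budget (ungapped, substitutions only),
pairs convergent forward/reverse sites into predicted amplicons within a
product-size window, and classifies each primer-set x genome-set combination:

* ``perfect``  - both primers bind with 0 mismatches
* ``strong``   - at most 2 mismatches on the worse primer
* ``weak``     - 3-5 mismatches on the worse primer

A combination's overall call is then ``single_perfect`` / ``single_strong`` /
``single_weak`` when exactly one product is predicted, ``multiple_targets``
when more than one, and ``no_match`` when none.  The 3-mismatch case is
grouped with the weak class so that the perfect/strong/weak partition is
total (the strong class is 1-2 mismatches, the weak class 3-5).

Matching is IUPAC-aware: a primer base matches a template ambiguity code iff
the base belongs to the code's set, so ``N`` in the template matches (and is
counted as a match).  Circular templates are scanned across the origin, and
amplicons may wrap the origin.  Product lengths are end-to-end, both primers
included, following the usual in-silico PCR convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    IUPAC_BITS,
    GenomeRecord,
    PrimerRole,
    PrimerSet,
    reverse_complement,
)

# 3'-terminal window (in primer bases) over which 3' mismatches are counted.
THREE_PRIME_WINDOW = 5


class Strand(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"


class MatchClass(str, enum.Enum):
    PERFECT = "perfect"
    STRONG = "strong"
    WEAK = "weak"


class CallSummary(str, enum.Enum):
    SINGLE_PERFECT = "single_perfect"
    SINGLE_STRONG = "single_strong"
    SINGLE_WEAK = "single_weak"
    MULTIPLE_TARGETS = "multiple_targets"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class PcrConfig:
    """Scan parameters.

    ``max_mm`` is the per-primer mismatch budget (the weak class tops out at
    5); ``min_len``/``max_len`` bound the predicted product size end-to-end.
    The defaults admit both short introns (~550 nt products) and the largest
    products seen in practice (> 4 kb split-intron alleles).
    """

    max_mm: int = 5
    min_len: int = 100
    max_len: int = 6000

    def __post_init__(self) -> None:
        if not 0 <= self.max_mm <= 5:
            raise ValueError("max_mm must be in 0..5")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")


@dataclass(frozen=True)
class PrimerHit:
    """One ungapped primer binding site on the forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the plus strand; for circular
    templates ``end`` may exceed the record length, meaning the site wraps the
    origin.  ``three_prime_mismatches`` counts mismatches within the 5
    3'-most primer bases (reported, never used to veto a hit).
    """

    record_id: str
    strand: Strand
    start: int
    end: int
    mismatches: int
    three_prime_mismatches: int
    which: str  # "forward_primer" | "reverse_primer"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("bad hit coordinates")
        if self.three_prime_mismatches > self.mismatches:
            raise ValueError("3' mismatches cannot exceed total mismatches")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product (end-to-end, primers included)."""

    record_id: str
    locus: str
    start: int
    end: int
    length: int
    wraps_origin: bool
    fwd_hit: PrimerHit
    rev_hit: PrimerHit
    match_class: MatchClass

    @property
    def max_primer_mismatches(self) -> int:
        return max(self.fwd_hit.mismatches, self.rev_hit.mismatches)


@dataclass(frozen=True)
class AmplificationCall:
    """Classification of one primer set x genome set combination."""

    locus: str
    genome_set_id: str
    amplicons: tuple[Amplicon, ...]
    summary: CallSummary


# --------------------------------------------------------------------------
# Primer-site scanning


def _bit_array(seq: str) -> np.ndarray:
    """Map a sequence to its IUPAC bitmask array (uint8)."""
    lut = np.zeros(256, dtype=np.uint8)
    for code, bits in IUPAC_BITS.items():
        lut[ord(code)] = bits
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr


def _window_mismatches(primer: str, template_bits: np.ndarray) -> np.ndarray:
    """Mismatch counts of `primer` against every window of the template.

    Returns an int array of length ``len(template) - len(primer) + 1``; entry
    ``i`` is the number of primer positions whose base is not contained in the
    template's IUPAC code at window ``[i, i+m)``.
    """
    m = len(primer)
    n = len(template_bits)
    if m > n:
        raise ValueError("primer longer than template")
    primer_bits = _bit_array(primer)
    n_win = n - m + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mism += (template_bits[j : j + n_win] & primer_bits[j]) == 0
    return mism


def _window_mismatch_matrix(primer: str, template_bits: np.ndarray) -> np.ndarray:
    """Boolean per-position mismatch matrix (n_windows x primer_len)."""
    m = len(primer)
    n = len(template_bits)
    primer_bits = _bit_array(primer)
    n_win = n - m + 1
    out = np.empty((n_win, m), dtype=bool)
    for j in range(m):
        out[:, j] = (template_bits[j : j + n_win] & primer_bits[j]) == 0
    return out


def find_primer_sites(
    primer: str,
    genome: GenomeRecord,
    max_mm: int = 2,
    which: str = "forward_primer",
) -> list[PrimerHit]:
    """Find all binding sites of ``primer`` on both strands of ``genome``.

    A plus-strand hit is a window matching the primer as given; a minus-strand
    hit is a window matching the primer's reverse complement (i.e. the primer
    anneals to the minus strand).  Circular genomes are scanned across the
    origin; wrap-spanning hits keep ``start`` within the sequence and carry
    ``end > len(genome)``.
    """
    m = len(primer)
    n = len(genome)
    if m > n:
        raise ValueError(
            f"primer length {m} exceeds genome {genome.id} length {n}"
        )
    template = genome.sequence
    if genome.is_circular and n >= m:
        template = template + template[: m - 1]
    tbits = _bit_array(template)

    hits: list[PrimerHit] = []
    for strand, query in ((Strand.PLUS, primer),
                          (Strand.MINUS, reverse_complement(primer))):
        mat = _window_mismatch_matrix(query, tbits)
        totals = mat.sum(axis=1)
        # 3'-most primer bases sit at the window's right edge on the plus
        # strand and at its left edge on the minus strand.
        w = min(THREE_PRIME_WINDOW, m)
        if strand is Strand.PLUS:
            three = mat[:, m - w :].sum(axis=1)
        else:
            three = mat[:, :w].sum(axis=1)
        for i in np.flatnonzero(totals <= max_mm):
            start = int(i)
            if start >= n:  # duplicate of a wrap-extended window
                continue
            hits.append(
                PrimerHit(
                    record_id=genome.id,
                    strand=strand,
                    start=start,
                    end=start + m,
                    mismatches=int(totals[i]),
                    three_prime_mismatches=int(three[i]),
                    which=which,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand.value))
    return hits


# --------------------------------------------------------------------------
# Amplicon pairing and classification


def _classify_pair(mm_fwd: int, mm_rev: int) -> MatchClass:
    worst = max(mm_fwd, mm_rev)
    if worst == 0:
        return MatchClass.PERFECT
    if worst <= 2:
        return MatchClass.STRONG
    return MatchClass.WEAK


def pair_amplicons(
    fwd_hits: Sequence[PrimerHit],
    rev_hits: Sequence[PrimerHit],
    min_len: int,
    max_len: int,
    topology_length: int | None = None,
    locus: str = "",
) -> list[Amplicon]:
    """Pair convergent hits into predicted amplicons.

    A product is formed by a plus-strand forward-primer hit and a
    minus-strand reverse-primer hit (the primers point toward each other)
    whose end-to-end length falls in ``[min_len, max_len]``.  Lengths include
    both primers.  ``topology_length`` is the record length for circular
    templates (enables origin-wrapping products) and ``None`` for linear.
    """
    amplicons: list[Amplicon] = []
    for f in fwd_hits:
        if f.strand is not Strand.PLUS:
            continue
        for r in rev_hits:
            if r.strand is not Strand.MINUS:
                continue
            if f.record_id != r.record_id:
                continue
            length = r.end - f.start
            wraps = False
            if topology_length is not None and length <= 0:
                length += topology_length
                wraps = True
            if length <= 0:
                continue
            if wraps and length >= topology_length:
                continue  # degenerate: would span the whole circle
            if not min_len <= length <= max_len:
                continue
            amplicons.append(
                Amplicon(
                    record_id=f.record_id,
                    locus=locus,
                    start=f.start,
                    end=f.start + length,
                    length=length,
                    wraps_origin=wraps or f.end > (topology_length or f.end)
                    or r.end > (topology_length or r.end),
                    fwd_hit=f,
                    rev_hit=r,
                    match_class=_classify_pair(f.mismatches, r.mismatches),
                )
            )
    amplicons.sort(key=lambda a: (a.record_id, a.start, a.length))
    return amplicons


def classify_call(
    amplicons: Sequence[Amplicon], locus: str, genome_set_id: str
) -> AmplificationCall:
    """Summarize the amplicons of one primer-set x genome-set combination."""
    if len(amplicons) == 0:
        summary = CallSummary.NO_MATCH
    elif len(amplicons) > 1:
        summary = CallSummary.MULTIPLE_TARGETS
    else:
        summary = {
            MatchClass.PERFECT: CallSummary.SINGLE_PERFECT,
            MatchClass.STRONG: CallSummary.SINGLE_STRONG,
            MatchClass.WEAK: CallSummary.SINGLE_WEAK,
        }[amplicons[0].match_class]
    return AmplificationCall(
        locus=locus,
        genome_set_id=genome_set_id,
        amplicons=tuple(amplicons),
        summary=summary,
    )


def predict_amplicons(
    primer_set: PrimerSet,
    genome: GenomeRecord,
    config: PcrConfig = PcrConfig(),
) -> list[Amplicon]:
    """All predicted products of one primer pair on one template record.

    Products run forward-primer -> reverse-primer in either template
    orientation: the forward primer may bind the plus strand with the reverse
    primer downstream on the minus strand, or the mirror arrangement (the
    amplicon then sits on the other strand); both orientations are scanned.
    """
    fwd = find_primer_sites(primer_set.forward, genome, config.max_mm,
                            which="forward_primer")
    rev = find_primer_sites(primer_set.reverse, genome, config.max_mm,
                            which="reverse_primer")
    circ = len(genome) if genome.is_circular else None
    amps = pair_amplicons(
        fwd, rev, config.min_len, config.max_len, circ, locus=primer_set.locus
    )
    # Mirror orientation: reverse primer on the plus strand upstream of the
    # forward primer on the minus strand.
    amps += pair_amplicons(
        rev, fwd, config.min_len, config.max_len, circ, locus=primer_set.locus
    )
    # De-duplicate products that are their own mirror (possible only when the
    # two primers hit identical windows).
    seen: set[tuple] = set()
    unique = []
    for a in sorted(amps, key=lambda a: (a.start, a.length)):
        key = (a.record_id, a.start % (circ or a.start + 1), a.length)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


def scan_genome_set(
    genome_sets: Mapping[str, Sequence[GenomeRecord]],
    primers: Sequence[PrimerSet],
    config: PcrConfig = PcrConfig(),
) -> list[AmplificationCall]:
    """One :class:`AmplificationCall` per (amplification primer set, genome set).

    A genome set may hold several records (e.g. a multi-chromosome assembly);
    hits are pooled across its records before classification.
    """
    amp_primers = [p for p in primers if p.role is PrimerRole.AMPLIFICATION]
    calls: list[AmplificationCall] = []
    for set_id, records in genome_sets.items():
        if len(records) == 0:
            raise ValueError(f"genome set {set_id!r} is empty")
        for ps in amp_primers:
            amplicons: list[Amplicon] = []
            for rec in records:
                if len(rec) <= max(len(ps.forward), len(ps.reverse)):
                    continue
                amplicons.extend(predict_amplicons(ps, rec, config))
            calls.append(classify_call(amplicons, ps.locus, set_id))
    return calls


def extract_amplicon_sequence(genome: GenomeRecord, amplicon: Amplicon) -> str:
    """The template sequence of a predicted product, 5'->3' on the plus strand."""
    n = len(genome)
    if amplicon.end <= n:
        return genome.sequence[amplicon.start : amplicon.end]
    if not genome.is_circular:
        raise ValueError("amplicon overruns a linear record")
    return genome.sequence[amplicon.start :] + genome.sequence[: amplicon.end - n]


def calls_to_table(calls: Sequence[AmplificationCall]) -> "pd.DataFrame":
    """Flat report: one row per call (lengths/classes comma-joined)."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "locus": c.locus,
                "genome_set": c.genome_set_id,
                "summary": c.summary.value,
                "n_products": len(c.amplicons),
                "lengths": ",".join(str(a.length) for a in c.amplicons),
                "classes": ",".join(a.match_class.value for a in c.amplicons),
                "fwd_mismatches": ",".join(
                    str(a.fwd_hit.mismatches) for a in c.amplicons
                ),
                "rev_mismatches": ",".join(
                    str(a.rev_hit.mismatches) for a in c.amplicons
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "genome_set", "summary", "n_products",
            "lengths", "classes", "fwd_mismatches", "rev_mismatches",
        ],
    )
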