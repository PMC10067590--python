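"""SNP/indel calling, divergence statistics (K0, I) and allele typing.

Definitions
-----------
SNP site
    A gap-free alignment column whose two bases are unambiguous (A/C/G/T)
    and differ.  C/T and G/A pairs are flagged (``is_ct_like``) because such
    differences can be erased at the RNA level by plant-mitochondrial C-to-U
    editing; the flag is reported, never interpreted.
indel event
    One *maximal* run of gap columns in one sequence; a 4-nt gap is one event
    of length 4 regardless of length.
K0
    Corrected nucleotide substitutions per site, computed on the alignment
    with all gap columns removed.  Columns containing N are excluded from
    both the site and the substitution count.  Corrections: Jukes-Cantor
    (default) or Kimura 2-parameter; ``none`` returns the raw proportion p.
I
    Indel events per site: the number of indel events divided by the number
    of aligned, gap-stripped (and N-free) sites.

Allele typing groups identical amplicon sequences per locus; allele 1 is the
longest allele, and a configurable gel-resolvability threshold (default 8 nt,
roughly what acrylamide gels resolve for ~1 kb products) marks which allele
pairs are distinguishable by electrophoresis alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .pairwise_align import AlignmentParams, PairwiseAlignment, align_pair, strip_gap_columns

GEL_RESOLUTION_NT = 8

Correction = Literal["jc69", "k2p", "none"]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class SnpSite:
    """A single-nucleotide difference between two aligned sequences."""

    column: int      # 1-based alignment column
    offset_a: int    # 1-based position in ungapped sequence a
    offset_b: int
    base_a: str
    base_b: str
    is_ct_like: bool

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise ValueError("SNP bases must differ")
        if self.base_a not in "ACGT" or self.base_b not in "ACGT":
            raise ValueError("SNP bases must be unambiguous A/C/G/T")


@dataclass(frozen=True)
class IndelEvent:
    """One maximal gap run; ``bearer`` names the sequence carrying the
    insertion (i.e. the other sequence has the gap)."""

    column_start: int  # 1-based first gap column
    length: int
    bearer: str  # "a_has_insertion" | "b_has_insertion"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class DivergenceStats:
    n_sites: int        # gap-stripped, N-free column count
    n_subs: int
    p: float
    K0: float
    n_indel_events: int
    I: float
    correction: str = "jc69"


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample standard deviation of K0 and I over pairs."""

    label: str
    pair_ids: tuple[tuple[str, str], ...]
    mean_K0: float
    sd_K0: float
    mean_I: float
    sd_I: float
    n_pairs: int


@dataclass(frozen=True)
class AlleleCall:
    locus: str
    entry: str
    allele_index: int  # 1 = longest allele at this locus
    length: int
    distinguishing_features: tuple = ()


# --------------------------------------------------------------------------
# Polymorphism calling


def call_polymorphisms(
    alignment: PairwiseAlignment,
) -> tuple[list[SnpSite], list[IndelEvent]]:
    """SNP sites and maximal-gap-run indel events, in coordinate order."""
    snps: list[SnpSite] = []
    indels: list[IndelEvent] = []
    pos_a = pos_b = 0
    run_start = 0
    run_len = 0
    run_bearer = ""

    def flush_run() -> None:
        nonlocal run_len
        if run_len:
            indels.append(
                IndelEvent(column_start=run_start, length=run_len,
                           bearer=run_bearer)
            )
            run_len = 0

    for col, (x, y) in enumerate(
        zip(alignment.aligned_a, alignment.aligned_b), start=1
    ):
        if x == "-" or y == "-":
            bearer = "b_has_insertion" if x == "-" else "a_has_insertion"
            if run_len and bearer == run_bearer:
                run_len += 1
            else:
                flush_run()
                run_start, run_len, run_bearer = col, 1, bearer
            if x != "-":
                pos_a += 1
            if y != "-":
                pos_b += 1
            continue
        flush_run()
        pos_a += 1
        pos_b += 1
        if x != y and x in "ACGT" and y in "ACGT":
            snps.append(
                SnpSite(
                    column=col,
                    offset_a=pos_a,
                    offset_b=pos_b,
                    base_a=x,
                    base_b=y,
                    is_ct_like=frozenset((x, y)) in _TRANSITIONS,
                )
            )
    flush_run()
    return snps, indels


# --------------------------------------------------------------------------
# Divergence statistics


def jc69(p: float) -> float:
    """Jukes-Cantor correction; undefined for p >= 0.75."""
    if p >= 0.75:
        raise ValueError(f"JC69 distance undefined for p={p:.4f} >= 0.75")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition (P) and transversion (Q)
    proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ValueError(f"K2P distance undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def compute_divergence(
    alignment: PairwiseAlignment,
    correction: Correction = "jc69",
) -> DivergenceStats:
    """K0 and I for one pairwise alignment.

    Substitutions are counted on gap-stripped columns; columns containing N
    (in either sequence) are excluded from both numerator and denominator.
    I = indel events / the same site count.
    """
    snps, indels = call_polymorphisms(alignment)
    stripped, _removed = strip_gap_columns(alignment)
    n_sites = sum(
        1
        for x, y in zip(stripped.aligned_a, stripped.aligned_b)
        if x != "N" and y != "N"
    )
    if n_sites < 1:
        raise ValueError("no N-free, gap-free columns to compute divergence on")
    n_subs = len(snps)
    p = n_subs / n_sites
    if correction == "jc69":
        K0 = jc69(p)
    elif correction == "k2p":
        n_ts = sum(1 for s in snps if frozenset((s.base_a, s.base_b)) in _TRANSITIONS)
        K0 = k2p(n_ts / n_sites, (n_subs - n_ts) / n_sites)
    elif correction == "none":
        K0 = p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return DivergenceStats(
        n_sites=n_sites,
        n_subs=n_subs,
        p=p,
        K0=K0,
        n_indel_events=len(indels),
        I=len(indels) / n_sites,
        correction=correction,
    )


def divergence_between(
    seq_a: str,
    seq_b: str,
    correction: Correction = "jc69",
    params: AlignmentParams = AlignmentParams(),
    id_a: str = "a",
    id_b: str = "b",
) -> DivergenceStats:
    """Convenience: align two sequences, then compute K0 and I."""
    return compute_divergence(
        align_pair(seq_a, seq_b, params, id_a=id_a, id_b=id_b), correction
    )


def summarize_group(
    stats: Sequence[DivergenceStats],
    label: str,
    pair_ids: Sequence[tuple[str, str]] | None = None,
) -> GroupSummary:
    """Arithmetic mean and sample (n-1) standard deviation of K0 and I."""
    if len(stats) == 0:
        raise ValueError("cannot summarize an empty group")
    k0 = np.array([s.K0 for s in stats], dtype=float)
    ii = np.array([s.I for s in stats], dtype=float)
    sd = (lambda v: float(np.std(v, ddof=1))) if len(stats) > 1 else (lambda v: 0.0)
    return GroupSummary(
        label=label,
        pair_ids=tuple(pair_ids or ()),
        mean_K0=float(k0.mean()),
        sd_K0=sd(k0),
        mean_I=float(ii.mean()),
        sd_I=sd(ii),
        n_pairs=len(stats),
    )


# --------------------------------------------------------------------------
# Allele discrimination tables


def build_discrimination_table(
    entries: Sequence[tuple[str, str, str]],
    params: AlignmentParams = AlignmentParams(),
    gel_threshold: int = GEL_RESOLUTION_NT,
) -> list[AlleleCall]:
    """Group (entry, locus, sequence) triples into alleles per locus.

    Entries with byte-identical sequences share an allele.  Alleles are
    numbered by decreasing length (ties broken lexicographically for
    determinism).  Each call carries the SNP/indel features distinguishing
    its allele from allele 1, from a pairwise alignment.
    """
    by_locus: dict[str, list[tuple[str, str]]] = {}
    for entry, locus, seq in entries:
        by_locus.setdefault(locus, []).append((entry, seq))

    calls: list[AlleleCall] = []
    for locus, members in by_locus.items():
        if len(members) < 2:
            raise ValueError(f"locus {locus!r} needs >= 2 entries to compare")
        alleles = sorted({seq for _, seq in members},
                         key=lambda s: (-len(s), s))
        features: dict[int, tuple] = {1: ()}
        for idx, allele in enumerate(alleles[1:], start=2):
            aln = align_pair(alleles[0], allele, params,
                             id_a=f"{locus}.allele1", id_b=f"{locus}.allele{idx}")
            snps, indels = call_polymorphisms(aln)
            features[idx] = tuple(snps) + tuple(indels)
        index_of = {allele: i + 1 for i, allele in enumerate(alleles)}
        for entry, seq in members:
            idx = index_of[seq]
            calls.append(
                AlleleCall(
                    locus=locus,
                    entry=entry,
                    allele_index=idx,
                    length=len(seq),
                    distinguishing_features=features[idx],
                )
            )
    calls.sort(key=lambda c: (c.locus, c.allele_index, c.entry))
    return calls


def gel_resolvable_pairs(
    calls: Sequence[AlleleCall], gel_threshold: int = GEL_RESOLUTION_NT
) -> list[dict]:
    """Allele pairs per locus with their length difference and whether a gel
    could resolve it (|dL| >= threshold)."""
    out: list[dict] = []
    by_locus: dict[str, dict[int, int]] = {}
    for c in calls:
        by_locus.setdefault(c.locus, {})[c.allele_index] = c.length
    for locus, lengths in sorted(by_locus.items()):
        idxs = sorted(lengths)
        for i, a in enumerate(idxs):
            for b in idxs[i + 1 :]:
                diff = abs(lengths[a] - lengths[b])
                out.append(
                    {
                        "locus": locus,
                        "allele_a": a,
                        "allele_b": b,
                        "length_diff": diff,
                        "gel_resolvable": diff >= gel_threshold,
                    }
                )
    return out
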