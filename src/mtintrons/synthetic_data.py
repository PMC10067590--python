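"""Synthetic mitochondrial genomes and intron panels with truth-logged variation.

Real templates for this kind of marker work are multi-hundred-kb organelle
genomes and Sanger-sequenced amplicons.  This module generates miniature
stand-ins that preserve the features the pipeline cares about:

* conserved exon anchors flanking variable introns, with exact primer
  binding sites (the amplicon is forward-primer + intron + reverse-primer);
* congener-scale variation: rare SNPs and short (1-10 nt) indels inside
  introns, exon anchors left untouched;
* inter-genus-scale variation (an order of magnitude more substitutions);
* optional large insertions (a split-intron mimic);
* controlled primer-site mismatch injection; linear or circular topology.

Every mutation is logged in a :class:`TruthRecord`; replaying the record
onto the ancestor reproduces the derived sequence byte-for-byte, so
downstream calls can be checked against planted truth exactly.

All randomness flows from one :func:`numpy.random.default_rng` stream keyed
by ``SimConfig.seed``: a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    GenomeRecord,
    PrimerRole,
    PrimerSet,
    Topology,
    reverse_complement,
)
from .insilico_pcr import Strand, _window_mismatches, _bit_array

_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Rates are per intron site.  ``n_snps``/``n_indels`` override the rates
    with exact per-locus counts (useful for planting a precise contrast).
    ``indel_length_weights`` is a categorical distribution over 1-10 nt,
    the dominant indel class in plant mitochondrial introns; a rare large
    insertion can be added via ``large_insertion_length``/``_prob``.
    """

    seed: int = 0
    n_loci: int = 3
    exon_anchor_length: int = 60
    intron_length_range: tuple[int, int] = (800, 1400)
    intron_lengths: Mapping[str, int] | None = None
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    n_snps: int | None = None
    n_indels: int | None = None
    indel_length_weights: tuple[float, ...] = (1.0,) * 10  # lengths 1..10
    large_insertion_length: int | None = None
    large_insertion_prob: float = 0.0
    primer_mm_injection: int = 0
    topology: Topology = Topology.LINEAR
    genome_padding: int = 500
    min_event_spacing: int = 25
    edge_buffer: int = 30
    mutate_exons: bool = False

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate, self.large_insertion_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.intron_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad intron_length_range")


def congener_config(seed: int = 0, **overrides) -> SimConfig:
    """Divergence preset at the within-genus scale (K0 ~ 0.001)."""
    cfg = SimConfig(seed=seed, snp_rate=0.001, indel_rate=0.0002)
    return replace(cfg, **overrides) if overrides else cfg


def inter_genus_config(seed: int = 0, **overrides) -> SimConfig:
    """Divergence preset at the between-genera scale (K0 ~ 0.03-0.05)."""
    cfg = SimConfig(seed=seed, snp_rate=0.04, indel_rate=0.003)
    return replace(cfg, **overrides) if overrides else cfg


# --------------------------------------------------------------------------
# Truth records


@dataclass(frozen=True)
class PlantedSnp:
    position: int  # 0-based within the ancestor intron
    ref: str
    alt: str


@dataclass(frozen=True)
class PlantedIndel:
    position: int   # 0-based within the ancestor intron
    length: int
    kind: str       # "insertion" (relative to ancestor) | "deletion"
    inserted: str = ""  # inserted bases, for exact replay

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "insertion" and len(self.inserted) != self.length:
            raise ValueError("insertion must carry its bases")


@dataclass(frozen=True)
class PrimerEdit:
    locus: str
    which: str              # "forward" | "reverse"
    positions: tuple[int, ...]  # 0-based within the primer site window


@dataclass(frozen=True)
class LocusLayout:
    """Ancestor coordinates of one planted locus (0-based half-open)."""

    locus: str
    amplicon_start: int
    amplicon_end: int
    intron_start: int
    intron_end: int


@dataclass(frozen=True)
class TruthRecord:
    genome_id: str
    ancestor_id: str
    snps: Mapping[str, tuple[PlantedSnp, ...]]
    indels: Mapping[str, tuple[PlantedIndel, ...]]
    primer_edits: tuple[PrimerEdit, ...] = ()

    def n_snps(self, locus: str) -> int:
        return len(self.snps.get(locus, ()))

    def n_indels(self, locus: str) -> int:
        return len(self.indels.get(locus, ()))


# --------------------------------------------------------------------------
# Random sequence primitives


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_sequence(
    seq: str,
    rng: np.random.Generator,
    n_snps: int = 0,
    n_indels: int = 0,
    indel_length_weights: Sequence[float] = (1.0,) * 10,
    large_insertion_length: int | None = None,
    min_spacing: int = 25,
    edge_buffer: int = 30,
) -> tuple[str, list[PlantedSnp], list[PlantedIndel]]:
    """Plant exact numbers of SNPs and indel events into ``seq``.

    Events are placed at mutually separated positions (``min_spacing``) away
    from the sequence ends (``edge_buffer``) so each maximal gap run in a
    later alignment corresponds to exactly one planted event.  A large
    insertion, when requested, counts as one of the ``n_indels`` events.
    Returns the mutated sequence plus the truth lists (ancestor coordinates).
    """
    L = len(seq)
    n_events = n_snps + n_indels
    if n_events == 0:
        return seq, [], []
    lo, hi = edge_buffer, L - edge_buffer
    if hi - lo < n_events * max(min_spacing, 1):
        raise ValueError(
            f"sequence of length {L} too short for {n_events} events "
            f"with spacing {min_spacing}"
        )
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_events:
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - p) >= min_spacing for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 10000 * n_events:
            raise RuntimeError("could not place events; relax spacing")
    rng.shuffle(positions)
    snp_pos = sorted(positions[:n_snps])
    indel_pos = sorted(positions[n_snps : n_snps + n_indels])

    snps: list[PlantedSnp] = []
    for p in snp_pos:
        ref = seq[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append(PlantedSnp(position=p, ref=ref, alt=alt))

    weights = np.asarray(indel_length_weights, dtype=float)
    weights = weights / weights.sum()
    indels: list[PlantedIndel] = []
    large_slot = (
        int(rng.integers(0, n_indels))
        if (large_insertion_length and n_indels) else -1
    )
    for k, p in enumerate(indel_pos):
        if k == large_slot:
            length = int(large_insertion_length)
            kind = "insertion"
        else:
            length = int(rng.choice(np.arange(1, len(weights) + 1), p=weights))
            kind = "insertion" if rng.random() < 0.5 else "deletion"
        inserted = random_dna(rng, length) if kind == "insertion" else ""
        indels.append(
            PlantedIndel(position=p, length=length, kind=kind, inserted=inserted)
        )

    return apply_mutations(seq, snps, indels), snps, indels


def apply_mutations(
    seq: str, snps: Sequence[PlantedSnp], indels: Sequence[PlantedIndel]
) -> str:
    """Replay planted mutations onto an ancestor sequence (exact)."""
    out = list(seq)
    for s in snps:
        if out[s.position] != s.ref:
            raise ValueError(f"truth mismatch at {s.position}: "
                             f"expected {s.ref}, found {out[s.position]}")
        out[s.position] = s.alt
    # apply indels right-to-left so earlier coordinates stay valid
    for ind in sorted(indels, key=lambda i: -i.position):
        if ind.kind == "deletion":
            del out[ind.position : ind.position + ind.length]
        else:
            out[ind.position : ind.position] = list(ind.inserted)
    return "".join(out)


# --------------------------------------------------------------------------
# Ancestor genomes


def _select_loci(primers: Sequence[PrimerSet], n_loci: int) -> list[PrimerSet]:
    amp = [p for p in primers if p.role is PrimerRole.AMPLIFICATION]
    if n_loci > len(amp):
        raise ValueError(f"only {len(amp)} amplification primer sets available")
    return amp[:n_loci]


def generate_ancestor(
    primers: Sequence[PrimerSet],
    config: SimConfig,
    genome_id: str = "ancestor",
    rng: np.random.Generator | None = None,
    sanitize_max_mm: int = 5,
) -> tuple[GenomeRecord, dict[str, LocusLayout]]:
    """Build a genome with one cassette per locus.

    Cassette layout: exon anchor + forward-primer site + intron +
    reverse-complemented reverse-primer site + exon anchor, embedded in
    random intergenic filler.  After assembly the genome is *sanitized*:
    every spurious window within ``sanitize_max_mm`` mismatches of an
    amplification primer (outside the planted sites) is shuffled away, so a
    scan finds exactly the planted sites.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loci = _select_loci(primers, config.n_loci)

    pieces: list[str] = [random_dna(rng, config.genome_padding)]
    layouts: dict[str, LocusLayout] = {}
    pos = len(pieces[0])
    protected: list[tuple[int, int]] = []
    for ps in loci:
        anchor5 = random_dna(rng, config.exon_anchor_length)
        anchor3 = random_dna(rng, config.exon_anchor_length)
        if config.intron_lengths and ps.locus in config.intron_lengths:
            intron_len = int(config.intron_lengths[ps.locus])
        else:
            lo, hi = config.intron_length_range
            intron_len = int(rng.integers(lo, hi + 1))
        intron = random_dna(rng, intron_len)
        rev_site = reverse_complement(ps.reverse)

        amplicon_start = pos + len(anchor5)
        intron_start = amplicon_start + len(ps.forward)
        intron_end = intron_start + intron_len
        amplicon_end = intron_end + len(ps.reverse)
        layouts[ps.locus] = LocusLayout(
            locus=ps.locus,
            amplicon_start=amplicon_start,
            amplicon_end=amplicon_end,
            intron_start=intron_start,
            intron_end=intron_end,
        )
        protected.append((amplicon_start, intron_start))
        protected.append((intron_end, amplicon_end))

        cassette = anchor5 + ps.forward + intron + rev_site + anchor3
        pieces.append(cassette)
        pos += len(cassette)
        filler = random_dna(rng, config.genome_padding)
        pieces.append(filler)
        pos += len(filler)

    sequence = sanitize_planted_sites(
        "".join(pieces), loci, protected, rng, max_mm=sanitize_max_mm
    )
    record = GenomeRecord(
        id=genome_id, sequence=sequence, topology=config.topology,
        description="synthetic",
    )
    return record, layouts


def sanitize_planted_sites(
    sequence: str,
    primer_sets: Sequence[PrimerSet],
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    max_mm: int = 5,
    max_rounds: int = 30,
) -> str:
    """Remove chance primer-binding windows from a synthetic sequence.

    Scans every amplification primer on both strands; any window within
    ``max_mm`` mismatches that does not exactly coincide with a protected
    (planted) interval gets its mutable positions re-randomized.  Iterates
    until the scan is clean; raises if two planted sites conflict so that no
    clean assignment exists.
    """
    seq = list(sequence)
    protected_set = {(a, b) for a, b in protected}
    immutable = np.zeros(len(sequence), dtype=bool)
    for a, b in protected:
        immutable[a:b] = True

    for _ in range(max_rounds):
        dirty = False
        tbits = _bit_array("".join(seq))
        for ps in primer_sets:
            for primer in (ps.forward, ps.reverse):
                m = len(primer)
                for query in (primer, reverse_complement(primer)):
                    mism = _window_mismatches(query, tbits)
                    for i in np.flatnonzero(mism <= max_mm):
                        start = int(i)
                        if (start, start + m) in protected_set:
                            continue
                        window = [
                            j for j in range(start, start + m) if not immutable[j]
                        ]
                        if not window:
                            raise RuntimeError(
                                "planted primer sites conflict; cannot sanitize"
                            )
                        for j in rng.choice(
                            window, size=min(len(window), max_mm + 2),
                            replace=False,
                        ):
                            seq[j] = str(rng.choice(list("ACGT")))
                        dirty = True
        if not dirty:
            return "".join(seq)
    raise RuntimeError("sanitization did not converge; planted sites conflict")


# --------------------------------------------------------------------------
# Derived relatives


def derive_relative(
    ancestor: GenomeRecord,
    layouts: Mapping[str, LocusLayout],
    primers: Sequence[PrimerSet],
    config: SimConfig,
    genome_id: str = "relative",
    rng: np.random.Generator | None = None,
) -> tuple[GenomeRecord, TruthRecord]:
    """Mutate the ancestor's introns (and optionally primer sites).

    SNPs and indels are planted inside introns only, at ``snp_rate`` /
    ``indel_rate`` per site (or at the exact ``n_snps``/``n_indels`` counts);
    exon anchors and filler are untouched unless ``mutate_exons`` is set,
    which keeps the events recoverable from amplicon alignments.  Primer
    sites are edited only when ``primer_mm_injection`` > 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seq = ancestor.sequence
    snps: dict[str, tuple[PlantedSnp, ...]] = {}
    indels: dict[str, tuple[PlantedIndel, ...]] = {}
    edits: list[PrimerEdit] = []
    by_locus = {p.locus: p for p in primers if p.role is PrimerRole.AMPLIFICATION}

    # process loci right-to-left so earlier layout coordinates stay valid
    new_seq = seq
    for locus in sorted(layouts, key=lambda l: -layouts[l].intron_start):
        lay = layouts[locus]
        intron = seq[lay.intron_start : lay.intron_end]
        L = len(intron)
        n_snps = (
            config.n_snps if config.n_snps is not None
            else int(rng.binomial(L, config.snp_rate))
        )
        n_indels = (
            config.n_indels if config.n_indels is not None
            else int(rng.binomial(L, config.indel_rate))
        )
        large = None
        if config.large_insertion_length and rng.random() < config.large_insertion_prob:
            large = config.large_insertion_length
            n_indels = max(n_indels, 1)
        mutated, locus_snps, locus_indels = mutate_sequence(
            intron,
            rng,
            n_snps=n_snps,
            n_indels=n_indels,
            indel_length_weights=config.indel_length_weights,
            large_insertion_length=large,
            min_spacing=config.min_event_spacing,
            edge_buffer=config.edge_buffer,
        ) if (n_snps or n_indels) else (intron, [], [])
        snps[locus] = tuple(locus_snps)
        indels[locus] = tuple(locus_indels)
        new_seq = (
            new_seq[: lay.intron_start] + mutated + new_seq[lay.intron_end :]
        )

        if config.primer_mm_injection > 0 and locus in by_locus:
            ps = by_locus[locus]
            delta = len(mutated) - L  # intron length change shifts the 3' site
            for which, start, plen in (
                ("forward", lay.amplicon_start, len(ps.forward)),
                ("reverse", lay.intron_end + delta, len(ps.reverse)),
            ):
                positions = tuple(
                    sorted(
                        int(p)
                        for p in rng.choice(
                            plen, size=config.primer_mm_injection, replace=False
                        )
                    )
                )
                site = list(new_seq[start : start + plen])
                for p in positions:
                    site[p] = str(rng.choice([b for b in "ACGT" if b != site[p]]))
                new_seq = new_seq[:start] + "".join(site) + new_seq[start + plen :]
                edits.append(PrimerEdit(locus=locus, which=which, positions=positions))

    truth = TruthRecord(
        genome_id=genome_id,
        ancestor_id=ancestor.id,
        snps=snps,
        indels=indels,
        primer_edits=tuple(edits),
    )
    record = GenomeRecord(
        id=genome_id, sequence=new_seq, topology=ancestor.topology,
        description="synthetic relative of " + ancestor.id,
    )
    return record, truth


def replay_truth(
    ancestor: GenomeRecord,
    layouts: Mapping[str, LocusLayout],
    truth: TruthRecord,
) -> str:
    """Reconstruct a derived genome sequence from ancestor + truth record.

    Only intron mutations are replayed (primer edits are not part of the
    replay contract); with ``primer_mm_injection = 0`` the result equals the
    derived genome byte-for-byte.
    """
    seq = ancestor.sequence
    for locus in sorted(layouts, key=lambda l: -layouts[l].intron_start):
        lay = layouts[locus]
        intron = ancestor.sequence[lay.intron_start : lay.intron_end]
        mutated = apply_mutations(
            intron, truth.snps.get(locus, ()), truth.indels.get(locus, ())
        )
        seq = seq[: lay.intron_start] + mutated + seq[lay.intron_end :]
    return seq
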