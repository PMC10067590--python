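"""Synthetic reference panels for end-to-end evaluation (no downloads).

Real evaluations of this marker set run against deposited mitochondrial
genome assemblies and Sanger-sequenced intron amplicons.  Those records are
large binary downloads, so this module builds *synthetic stand-ins* whose
planted structure matches the published study conditions:

* :func:`survey_panel` - an 11 genome-set x 11 intron-locus in-silico PCR
  survey with a fixed class mixture (79 perfect-primer single products, 18
  single products at 1-2 mismatches, 1 weak single, 19 multi-target cells
  and 2 no-match cells = 121 combinations) and per-cell product lengths
  taken from published in-silico predictions for these marker loci.
* :func:`congener_intron_panel` - amplicon panels for the three sequenced
  introns (ccmFci1, nad5i4, nad7i1) across five congener pairs/trios plus
  three mutually diverged dicot genera, with planted within-genus contrasts
  (e.g. the Cynodon-like nad5i4 pair: 3 SNPs + one 4-nt indel; the
  Cenchrus-like ccmFci1 pair: one 4-nt indel, no SNPs) and between-genus
  divergence planted at the published K0 scale.
* :func:`split_intron_pair` - a split-intron mimic: two amplicons sharing
  632 5' and 133 3' nucleotides around a 3353-nt insertion.

Every builder is deterministic in its seed.  These are synthetic sequences:
they reproduce the *structure* of the real comparisons (event counts, match
classes, product lengths, divergence scale), not the actual nucleotides of
any accession.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomeRecord, PrimerSet, load_bundled_primers, reverse_complement
from .insilico_pcr import CallSummary
from .synthetic_data import (
    PlantedIndel,
    PlantedSnp,
    apply_mutations,
    mutate_sequence,
    random_dna,
    sanitize_planted_sites,
)

LOCI = (
    "ccmFci1", "nad1i2", "nad2i1", "nad2i4", "nad4i1", "nad4i3",
    "nad5i1", "nad5i4", "nad7i1", "nad7i2", "nad7i3",
)

# --------------------------------------------------------------------------
# Survey panel: 11 genome sets x 11 loci.
#
# Cell grammar: int -> single perfect product of that end-to-end length;
# ("s", L) -> single product with 1-2 primer mismatches; ("w", L) -> single
# weak product (4 mismatches per primer); ("m", [(L, mm), ...]) -> multiple
# targets; None -> no match.  Lengths for clean single-product cells follow
# the published predictions for these genome sets; multi-target cell lengths
# are representative.

_SURVEY: dict[str, dict[str, object]] = {
    "allium_cms_like": dict(zip(LOCI, (
        1142, 588, 1576, 1621, 1336, 1988, 903, 1266, 1382, 958, 1301))),
    "allium_normal_like": dict(zip(LOCI, (
        1142, 596, 1576, 1611, 1336, 1988, 903, 1266, 1410, 958, 1301))),
    "cocos_like": dict(zip(LOCI, (
        1080, 624, ("m", [(1313, 0), (2067, 4)]), 1552, 1358, 2368,
        916, 1072, 924, 1579, 1056))),
    "magnolia_b_like": dict(zip(LOCI, (
        ("m", [(1133, 0), (1112, 4)]), 626, 1433,
        ("m", [(1569, 0), (1332, 4)]), 1380, 2391, 891, 1400, 925,
        ("m", [(1532, 0), (1210, 4), (890, 5)]), 1059))),
    "magnolia_o_like": dict(zip(LOCI, (
        1151, 632, 1451, ("m", [(1584, 0), (1100, 4), (700, 5)]),
        1380, 2437, 901, 1430, ("m", [(938, 0), (1490, 4)]),
        ("m", [(1563, 0), (433, 4)]), 1079))),
    "silene_conica_like": dict(zip(LOCI, (
        ("m", [(1055, 4), (1105, 5)]),
        ("m", [(900, 4), (1200, 5), (1500, 4)]),
        1028, ("m", [(1273, 4), (3712, 5)]), ("w", 3165), 1674, 894,
        ("m", [(1162, 4), (2659, 5)]),
        ("m", [(1534, 0), (800, 4), (1100, 5)]),
        ("m", [(565, 4), (1245, 5)]), ("m", [(837, 4), (2254, 5)])))),
    "silene_latifolia_like": dict(zip(LOCI, (
        1067, 655, 1131, 1405, 1500, 1951, 906, 1136, 1003, 800, 1173))),
    "silene_noctiflora_like": dict(zip(LOCI, (
        None, ("m", [(700, 4), (1000, 5)]),
        ("m", [(1058, 4), (1123, 4), (2491, 5)]),
        ("m", [(1400, 4), (900, 5)]),
        ("m", [(1546, 0), (1000, 4), (700, 5)]),
        707, 920, 1151, 889, ("m", [(653, 0), (900, 4), (1200, 5)]), None))),
    "silene_vulgaris_like": dict(zip(LOCI, (
        1067, 672, 1136, 1409, 1484, 1975, 924, 1146, 989, 798, 1169))),
    # the 18 single products at 1-2 primer mismatches are planted in the two
    # seagrass-like sets (the survey reports only the total, not which cells)
    "zostera_japonica_like": dict(zip(LOCI, (
        ("s", 1621), ("s", 552), ("s", 1454), ("s", 1808), ("s", 1264),
        ("s", 1456), ("s", 993), ("s", 1311), ("s", 1283), ("s", 788),
        ("s", 2011)))),
    "zostera_marina_like": dict(zip(LOCI, (
        ("s", 1937), ("s", 549), ("m", [(1515, 0), (2640, 4)]), ("s", 2128),
        ("s", 1224), ("s", 1456), ("s", 999), ("s", 1260),
        ("m", [(1283, 0), (1505, 4)]), 788, 2287))),
}

# genome sets assembled as two records, emulating multi-contig assemblies
_MULTI_RECORD_SETS = ("silene_conica_like", "silene_noctiflora_like")

_ANCHOR = 60
_INTER_LOCUS_FILLER = 400
_SAME_LOCUS_FILLER = 6100  # > max product size: copies never cross-pair


@dataclass(frozen=True)
class ExpectedCall:
    summary: CallSummary
    lengths: tuple[int, ...]  # asserted only for clean single-product cells


def _inject(site: str, n_mm: int, rng: np.random.Generator) -> str:
    out = list(site)
    for p in rng.choice(len(site), size=n_mm, replace=False):
        out[p] = str(rng.choice([b for b in "ACGT" if b != out[p]]))
    return "".join(out)


def _cassette(
    ps: PrimerSet, length: int, mm: int, rng: np.random.Generator
) -> tuple[str, int, int]:
    """(cassette sequence, fwd-site offset, rev-site offset) with the planted
    product of the requested end-to-end length and per-primer mismatches."""
    intron_len = length - len(ps.forward) - len(ps.reverse)
    if intron_len < 1:
        raise ValueError(f"{ps.locus}: product length {length} too short")
    fwd_site = _inject(ps.forward, mm, rng) if mm else ps.forward
    rev_site = reverse_complement(ps.reverse)
    rev_site = _inject(rev_site, mm, rng) if mm else rev_site
    anchor5 = random_dna(rng, _ANCHOR)
    anchor3 = random_dna(rng, _ANCHOR)
    intron = random_dna(rng, intron_len)
    cassette = anchor5 + fwd_site + intron + rev_site + anchor3
    fwd_off = len(anchor5)
    rev_off = fwd_off + len(fwd_site) + intron_len
    return cassette, fwd_off, rev_off


def _cell_products(cell) -> list[tuple[int, int]]:
    """Normalize a cell spec to [(length, per-primer mismatches), ...]."""
    if cell is None:
        return []
    if isinstance(cell, int):
        return [(cell, 0)]
    tag = cell[0]
    if tag == "s":
        return [(cell[1], 1)]  # 1 mismatch per primer: the strong class
    if tag == "w":
        return [(cell[1], 4)]
    if tag == "m":
        return list(cell[1])
    raise ValueError(f"bad cell spec {cell!r}")


def expected_survey_calls() -> dict[tuple[str, str], ExpectedCall]:
    """The truth table of the survey panel: per (genome set, locus) the
    expected call summary, with exact product lengths for single cells."""
    expected: dict[tuple[str, str], ExpectedCall] = {}
    for set_id, row in _SURVEY.items():
        for locus in LOCI:
            products = _cell_products(row[locus])
            if not products:
                summary = CallSummary.NO_MATCH
            elif len(products) > 1:
                summary = CallSummary.MULTIPLE_TARGETS
            else:
                mm = products[0][1]
                summary = (
                    CallSummary.SINGLE_PERFECT if mm == 0
                    else CallSummary.SINGLE_STRONG if mm <= 2
                    else CallSummary.SINGLE_WEAK
                )
            expected[(set_id, locus)] = ExpectedCall(
                summary=summary,
                lengths=tuple(sorted(length for length, _ in products)),
            )
    return expected


def survey_panel(
    seed: int, primers: Sequence[PrimerSet] | None = None
) -> tuple[dict[str, list[GenomeRecord]], dict[tuple[str, str], ExpectedCall]]:
    """Build the 121-combination synthetic survey panel.

    Returns (genome sets, expected calls).  Each genome set is a synthetic
    linear sequence carrying one planted cassette per predicted product;
    chance primer-binding windows are sanitized away so a scan at up to 5
    mismatches finds exactly the planted sites.
    """
    if primers is None:
        primers = load_bundled_primers()
    by_locus = {p.locus: p for p in primers if p.role.value == "amplification"}
    rng = np.random.default_rng(seed)
    amp_primers = [by_locus[l] for l in LOCI]

    genome_sets: dict[str, list[GenomeRecord]] = {}
    for set_id, row in _SURVEY.items():
        pieces: list[str] = [random_dna(rng, _INTER_LOCUS_FILLER)]
        protected: list[tuple[int, int]] = []
        spans: list[tuple[int, int]] = []  # planted amplicon intervals
        pos = len(pieces[0])
        for locus in LOCI:
            ps = by_locus[locus]
            products = _cell_products(row[locus])
            for k, (length, mm) in enumerate(products):
                if k > 0:
                    gap = random_dna(rng, _SAME_LOCUS_FILLER)
                    pieces.append(gap)
                    pos += len(gap)
                cassette, fwd_off, rev_off = _cassette(ps, length, mm, rng)
                protected.append((pos + fwd_off, pos + fwd_off + len(ps.forward)))
                protected.append((pos + rev_off, pos + rev_off + len(ps.reverse)))
                spans.append((pos + fwd_off, pos + rev_off + len(ps.reverse)))
                pieces.append(cassette)
                pos += len(cassette)
            filler = random_dna(rng, _INTER_LOCUS_FILLER)
            pieces.append(filler)
            pos += len(filler)
        sequence = sanitize_planted_sites(
            "".join(pieces), amp_primers, protected, rng, max_mm=5
        )
        if set_id in _MULTI_RECORD_SETS:
            # split into a 2-contig set at the inter-cassette gap nearest the
            # middle, never inside a planted amplicon
            mid = len(sequence) // 2
            gaps = [
                (a_end + b_start) // 2
                for (_, a_end), (b_start, _) in zip(spans, spans[1:])
            ]
            cut = min(gaps, key=lambda g: abs(g - mid))
            genome_sets[set_id] = [
                GenomeRecord(id=f"{set_id}.1", sequence=sequence[:cut],
                             description="synthetic"),
                GenomeRecord(id=f"{set_id}.2", sequence=sequence[cut:],
                             description="synthetic"),
            ]
        else:
            genome_sets[set_id] = [
                GenomeRecord(id=set_id, sequence=sequence,
                             description="synthetic")
            ]
    return genome_sets, expected_survey_calls()


# --------------------------------------------------------------------------
# Congener amplicon panels for the three sequenced introns


def _k0_to_p(k0: float) -> float:
    """Invert the Jukes-Cantor correction."""
    return 0.75 * (1.0 - math.exp(-4.0 * k0 / 3.0))


# published amplicon lengths for the sequenced alleles (root lengths)
_ROOT_AMPLICON_LENGTH = {"ccmFci1": 955, "nad5i4": 929, "nad7i1": 901}
# published between-dicot-genera divergence scale per locus
_BETWEEN_GENUS_K0 = {"ccmFci1": 0.036, "nad5i4": 0.046, "nad7i1": 0.028}
_BETWEEN_GENUS_I = {"ccmFci1": 0.005, "nad5i4": 0.008, "nad7i1": 0.007}

WITHIN_GENUS_PAIRS = (
    ("citrus_maxima", "citrus_reticulata"),
    ("citrus_maxima", "citrus_medica"),
    ("citrus_medica", "citrus_reticulata"),
    ("cynodon_dactylon", "cynodon_transvaalensis"),
    ("cenchrus_americanus", "cenchrus_purpureus"),
    ("solanum_lycopersicum", "solanum_pennellii"),
    ("vaccinium_corymbosum", "vaccinium_virgatum"),
)
BETWEEN_GENUS_PAIRS = (
    ("citrus_maxima", "solanum_lycopersicum"),
    ("citrus_maxima", "vaccinium_corymbosum"),
    ("solanum_lycopersicum", "vaccinium_corymbosum"),
)

_FOUR_NT = (0, 0, 0, 1.0, 0, 0, 0, 0, 0, 0)  # indel length fixed at 4


def congener_intron_panel(
    seed: int, primers: Sequence[PrimerSet] | None = None
) -> dict[str, dict[str, str]]:
    """Amplicon sequences per locus for a synthetic congener panel.

    Returns ``{locus: {entry: amplicon sequence}}`` for the three sequenced
    introns.  Planted structure:

    * genus roots for citrus/solanum/vaccinium mutually diverged at the
      published between-dicot-genera K0 scale (plus a few short indels);
      cynodon/cenchrus descend from an independent root;
    * within genera: the ccmFci1 of the cenchrus-like pair differs by one
      4-nt indel only; the nad5i4 of the cynodon-like pair differs by 3 SNPs
      plus one 4-nt indel; the vaccinium-like pair by one nad5i4 SNP; the
      citrus-like trio by 1-2 nad5i4 SNPs and one nad7i1 SNP; the
      solanum-like pair is monomorphic.  ccmFci1 carries no within-genus
      SNPs anywhere, matching its observed total conservation.
    """
    if primers is None:
        primers = load_bundled_primers()
    by_locus = {p.locus: p for p in primers if p.role.value == "amplification"}
    rng = np.random.default_rng(seed)

    panel: dict[str, dict[str, str]] = {}
    for locus in ("ccmFci1", "nad5i4", "nad7i1"):
        ps = by_locus[locus]
        L_int = _ROOT_AMPLICON_LENGTH[locus] - len(ps.forward) - len(ps.reverse)
        root = random_dna(rng, L_int)

        # between-genus divergence: each genus root gets half the pairwise
        # substitution load so any two differ by ~p* sites
        p_star = _k0_to_p(_BETWEEN_GENUS_K0[locus])
        n_branch_snps = round(p_star * L_int / 2)
        n_branch_indels = max(1, round(_BETWEEN_GENUS_I[locus] * L_int / 2))
        genus_root: dict[str, str] = {}
        for genus in ("citrus", "solanum", "vaccinium"):
            mutated, _, _ = mutate_sequence(
                root, rng, n_snps=n_branch_snps, n_indels=n_branch_indels,
                min_spacing=12, edge_buffer=25,
            )
            genus_root[genus] = mutated
        # monocot genera descend from their own root (divergence from the
        # dicots is irrelevant to the group statistics computed here)
        monocot = random_dna(rng, L_int)
        for genus in ("cynodon", "cenchrus"):
            mutated, _, _ = mutate_sequence(
                monocot, rng, n_snps=n_branch_snps, n_indels=1,
                min_spacing=12, edge_buffer=25,
            )
            genus_root[genus] = mutated

        def derive(base: str, n_snps: int = 0, n_indels: int = 0) -> str:
            if n_snps == 0 and n_indels == 0:
                return base
            mutated, _, _ = mutate_sequence(
                base, rng, n_snps=n_snps, n_indels=n_indels,
                indel_length_weights=_FOUR_NT, min_spacing=30, edge_buffer=30,
            )
            return mutated

        entries: dict[str, str] = {}
        if locus == "ccmFci1":
            entries["citrus_maxima"] = genus_root["citrus"]
            entries["citrus_reticulata"] = genus_root["citrus"]
            entries["citrus_medica"] = genus_root["citrus"]
            entries["cynodon_dactylon"] = genus_root["cynodon"]
            entries["cynodon_transvaalensis"] = genus_root["cynodon"]
            entries["cenchrus_americanus"] = genus_root["cenchrus"]
            entries["cenchrus_purpureus"] = derive(
                genus_root["cenchrus"], n_indels=1)  # the 4-nt indel
            entries["solanum_lycopersicum"] = genus_root["solanum"]
            entries["solanum_pennellii"] = genus_root["solanum"]
            entries["vaccinium_corymbosum"] = genus_root["vaccinium"]
            entries["vaccinium_virgatum"] = genus_root["vaccinium"]
        elif locus == "nad5i4":
            entries["citrus_maxima"] = genus_root["citrus"]
            entries["citrus_reticulata"] = derive(genus_root["citrus"], n_snps=1)
            entries["citrus_medica"] = derive(genus_root["citrus"], n_snps=1)
            entries["cynodon_dactylon"] = genus_root["cynodon"]
            entries["cynodon_transvaalensis"] = derive(
                genus_root["cynodon"], n_snps=3, n_indels=1)
            entries["cenchrus_americanus"] = genus_root["cenchrus"]
            entries["cenchrus_purpureus"] = genus_root["cenchrus"]
            entries["solanum_lycopersicum"] = genus_root["solanum"]
            entries["solanum_pennellii"] = genus_root["solanum"]
            entries["vaccinium_corymbosum"] = genus_root["vaccinium"]
            entries["vaccinium_virgatum"] = derive(
                genus_root["vaccinium"], n_snps=1)
        else:  # nad7i1
            entries["citrus_maxima"] = genus_root["citrus"]
            entries["citrus_reticulata"] = derive(genus_root["citrus"], n_snps=1)
            entries["citrus_medica"] = genus_root["citrus"]
            entries["cynodon_dactylon"] = genus_root["cynodon"]
            entries["cynodon_transvaalensis"] = genus_root["cynodon"]
            entries["cenchrus_americanus"] = genus_root["cenchrus"]
            entries["cenchrus_purpureus"] = derive(
                genus_root["cenchrus"], n_snps=1, n_indels=1)
            entries["solanum_lycopersicum"] = genus_root["solanum"]
            entries["solanum_pennellii"] = genus_root["solanum"]
            entries["vaccinium_corymbosum"] = genus_root["vaccinium"]
            entries["vaccinium_virgatum"] = genus_root["vaccinium"]

        rev_site = reverse_complement(ps.reverse)
        panel[locus] = {
            entry: ps.forward + intron + rev_site
            for entry, intron in entries.items()
        }
    return panel


def split_intron_pair(seed: int) -> tuple[str, str]:
    """A split-intron mimic: (short allele, long allele).

    The two synthetic amplicons share 632 5' nucleotides and 133 3'
    nucleotides; the long allele carries a 3353-nt insertion between them.
    """
    rng = np.random.default_rng(seed)
    five = random_dna(rng, 632)
    three = random_dna(rng, 133)
    insertion = random_dna(rng, 3353)
    return five + three, five + insertion + three
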