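"""End-to-end orchestration: scan -> type -> divergence -> caps.

One :class:`RunConfig` drives the whole run; every stage is a pure function
of (inputs, config), all reports are TSV with a machine-readable JSON twin,
and a manifest records the config checksum plus a checksum per report so a
re-run from the same config can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .caps import find_diagnostic_enzymes
from .insilico_pcr import (
    AmplificationCall,
    CallSummary,
    PcrConfig,
    calls_to_table,
    extract_amplicon_sequence,
    scan_genome_set,
)
from .io_formats import (
    GenomeRecord,
    load_bundled_enzymes,
    load_bundled_primers,
    read_enzyme_table,
    read_fasta,
    read_primer_table,
)
from .polymorphism import (
    build_discrimination_table,
    call_polymorphisms,
    divergence_between,
    gel_resolvable_pairs,
    summarize_group,
)
from .pairwise_align import AlignmentParams, align_pair

logger = logging.getLogger(__name__)

REPORT_NAMES = (
    "calls.tsv", "alleles.tsv", "polymorphisms.tsv",
    "divergence.tsv", "caps.tsv",
)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending input."""


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for one pipeline run.

    ``genomes`` maps genome-set ids to lists of FASTA paths (every record in
    those files belongs to the set).  ``pairs`` optionally names the
    divergence comparisons as (entry_a, entry_b, group) triples over genome
    set ids; by default all within-locus entry pairs form one group per
    locus.
    """

    genomes: dict[str, list[str]] = field(default_factory=dict)
    primers: str | None = None   # TSV path; None = bundled marker set
    enzymes: str | None = None   # TSV path; None = bundled enzyme table
    out_dir: str = "mtintrons_run"
    max_mm: int = 5
    min_len: int = 100
    max_len: int = 6000
    correction: str = "jc69"
    gel_threshold: int = 8
    pairs: list[tuple[str, str, str]] | None = None
    log_level: str = "INFO"
    seed: int = 0

    def checksum(self) -> str:
        """Digest of the analysis-relevant parameters (where outputs go and
        how chatty the log is do not affect results)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "pairs" in raw and raw["pairs"] is not None:
        raw["pairs"] = [tuple(p) for p in raw["pairs"]]
    return RunConfig(**raw)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_report(df: pd.DataFrame, path: Path, config_checksum: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_checksum}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run scan -> type -> divergence -> caps and write the report bundle.

    Returns the manifest dict.  Any stage failure raises :class:`StageError`
    naming the stage and the offending input.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_sum = config.checksum()

    # ---- inputs -----------------------------------------------------
    if not config.genomes:
        raise StageError("scan: no genome sets configured")
    primers = (
        read_primer_table(config.primers) if config.primers
        else load_bundled_primers()
    )
    if not primers:
        raise StageError(f"scan: primer table {config.primers!r} is empty")
    enzymes = (
        read_enzyme_table(config.enzymes) if config.enzymes
        else load_bundled_enzymes()
    )
    genome_sets: dict[str, list[GenomeRecord]] = {}
    records_by_set: dict[str, dict[str, GenomeRecord]] = {}
    for set_id, paths in config.genomes.items():
        records: list[GenomeRecord] = []
        for p in paths:
            try:
                records.extend(read_fasta(p))
            except Exception as exc:
                raise StageError(f"scan: cannot read genome FASTA {p}: {exc}")
        if not records:
            raise StageError(f"scan: genome set {set_id!r} has no records")
        genome_sets[set_id] = records
        records_by_set[set_id] = {r.id: r for r in records}

    # ---- stage 1: scan ----------------------------------------------
    pcr = PcrConfig(max_mm=config.max_mm, min_len=config.min_len,
                    max_len=config.max_len)
    calls = scan_genome_set(genome_sets, primers, pcr)
    _write_report(calls_to_table(calls), out / "calls.tsv", cfg_sum)
    logger.info("scan: %d calls written", len(calls))

    # ---- amplicon extraction for downstream stages ------------------
    # single-product calls yield one amplicon sequence per (locus, set)
    amplicons: dict[str, dict[str, str]] = {}
    for call in calls:
        if call.summary in (CallSummary.SINGLE_PERFECT,
                            CallSummary.SINGLE_STRONG,
                            CallSummary.SINGLE_WEAK):
            amp = call.amplicons[0]
            rec = records_by_set[call.genome_set_id][amp.record_id]
            amplicons.setdefault(call.locus, {})[call.genome_set_id] = (
                extract_amplicon_sequence(rec, amp)
            )

    # ---- stage 2: type (alleles + polymorphisms) --------------------
    allele_rows: list[dict] = []
    poly_rows: list[dict] = []
    params = AlignmentParams()
    for locus, entries in sorted(amplicons.items()):
        if len(entries) < 2:
            continue
        triples = [(entry, locus, seq) for entry, seq in sorted(entries.items())]
        calls_a = build_discrimination_table(triples, params, config.gel_threshold)
        for c in calls_a:
            allele_rows.append(
                {"locus": c.locus, "entry": c.entry,
                 "allele": c.allele_index, "length": c.length}
            )
        names = [t[0] for t in triples]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                aln = align_pair(entries[a], entries[b], params,
                                 id_a=a, id_b=b)
                snps, indels = call_polymorphisms(aln)
                for s in snps:
                    poly_rows.append(
                        {"locus": locus, "entry_a": a, "entry_b": b,
                         "type": "snp", "column": s.column,
                         "detail": f"{s.base_a}/{s.base_b}",
                         "length": 1, "ct_like": s.is_ct_like}
                    )
                for ind in indels:
                    poly_rows.append(
                        {"locus": locus, "entry_a": a, "entry_b": b,
                         "type": "indel", "column": ind.column_start,
                         "detail": ind.bearer, "length": ind.length,
                         "ct_like": False}
                    )
    _write_report(
        pd.DataFrame(allele_rows,
                     columns=["locus", "entry", "allele", "length"]),
        out / "alleles.tsv", cfg_sum,
    )
    _write_report(
        pd.DataFrame(poly_rows,
                     columns=["locus", "entry_a", "entry_b", "type",
                              "column", "detail", "length", "ct_like"]),
        out / "polymorphisms.tsv", cfg_sum,
    )

    # ---- stage 3: divergence ----------------------------------------
    div_rows: list[dict] = []
    group_stats: dict[tuple[str, str], list] = {}
    for locus, entries in sorted(amplicons.items()):
        if config.pairs:
            todo = [
                (a, b, grp) for a, b, grp in config.pairs
                if a in entries and b in entries
            ]
        else:
            names = sorted(entries)
            todo = [
                (a, b, locus)
                for i, a in enumerate(names) for b in names[i + 1 :]
            ]
        for a, b, grp in todo:
            stats = divergence_between(
                entries[a], entries[b], config.correction, params,
                id_a=a, id_b=b,
            )
            div_rows.append(
                {"locus": locus, "entry_a": a, "entry_b": b, "group": grp,
                 "n_sites": stats.n_sites, "n_subs": stats.n_subs,
                 "p": round(stats.p, 6), "K0": round(stats.K0, 6),
                 "n_indel_events": stats.n_indel_events,
                 "I": round(stats.I, 6)}
            )
            group_stats.setdefault((locus, grp), []).append(stats)
    for (locus, grp), stats in sorted(group_stats.items()):
        summ = summarize_group(stats, grp)
        div_rows.append(
            {"locus": locus, "entry_a": "mean±sd", "entry_b": f"n={summ.n_pairs}",
             "group": grp, "n_sites": "", "n_subs": "",
             "p": "", "K0": f"{summ.mean_K0:.4f}±{summ.sd_K0:.4f}",
             "n_indel_events": "",
             "I": f"{summ.mean_I:.4f}±{summ.sd_I:.4f}"}
        )
    _write_report(
        pd.DataFrame(div_rows,
                     columns=["locus", "entry_a", "entry_b", "group",
                              "n_sites", "n_subs", "p", "K0",
                              "n_indel_events", "I"]),
        out / "divergence.tsv", cfg_sum,
    )

    # ---- stage 4: caps ----------------------------------------------
    caps_rows: list[dict] = []
    for locus, entries in sorted(amplicons.items()):
        uniq: dict[str, str] = {}
        for entry, seq in sorted(entries.items()):
            uniq.setdefault(seq, entry)
        alleles = sorted(uniq, key=lambda s: (-len(s), s))
        for i, sa in enumerate(alleles):
            for sb in alleles[i + 1 :]:
                report = find_diagnostic_enzymes(
                    sa, sb, enzymes, locus=locus,
                    id_a=uniq[sa], id_b=uniq[sb],
                )
                for d in report.diagnostic_enzymes:
                    caps_rows.append(
                        {"locus": locus, "allele_a": report.allele_a,
                         "allele_b": report.allele_b, "enzyme": d.enzyme,
                         "pattern_a": ",".join(map(str, d.pattern_a.fragment_lengths)),
                         "pattern_b": ",".join(map(str, d.pattern_b.fragment_lengths)),
                         "max_fragment_diff": d.max_fragment_diff,
                         "n_enzymes_tested": report.n_enzymes_tested}
                    )
    _write_report(
        pd.DataFrame(caps_rows,
                     columns=["locus", "allele_a", "allele_b", "enzyme",
                              "pattern_a", "pattern_b", "max_fragment_diff",
                              "n_enzymes_tested"]),
        out / "caps.tsv", cfg_sum,
    )

    # ---- manifest ---------------------------------------------------
    manifest = {
        "package": "mtintrons",
        "version": __version__,
        "config_sha256": cfg_sum,
        "config": dataclasses.asdict(config),
        "reports": {
            name: _sha256_file(out / name) for name in REPORT_NAMES
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return manifest
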