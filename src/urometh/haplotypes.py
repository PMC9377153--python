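"""Haplotype extraction from aligned bisulfite amplicon reads.

A methylation haplotype is the per-fragment methylation frequency
mf = (methylated CpGs) / (covered CpGs), rounded half-away-from-zero to one
decimal, so haplotypes live on the 11 bins {0.0, 0.1, ..., 1.0}.  Reads are
assigned to amplicons by overlap, pass per-read QC, and are aggregated into
per-(sample, amplicon) haplotype counts and relative prevalences.

Read-level QC (a read is removed if any rule fails, first failing rule is
reported):

1. conversion rate (converted / covered non-CpG cytosines) < 99%;
2. >= 2 unconverted non-CpG cytosines;
3. strand-conversion inconsistency (C->T and G->A evidence both above 5%);
4. MAPQ < 30.

A read with no covered non-CpG cytosine passes rule 1 vacuously.  Reads
covering no CpG, or fewer than half of the amplicon's CpGs, are excluded
with their own reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from ._stats import round_half_up
from .simulate import BINS

__all__ = [
    "AmpliconDef",
    "BisulfiteRead",
    "QCParams",
    "amplicons_from_bed",
    "parse_sam",
    "qc_filter_read",
    "read_methylation_frequency",
    "build_haplotype_table",
]


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon interval with its reference CpG context (0-based, half-open)."""

    name: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    strand: str = "+"

    def __post_init__(self):
        if not all(self.start <= p < self.end for p in self.cpg_positions):
            raise ValueError(f"amplicon {self.name}: CpG positions outside interval")


@dataclass
class BisulfiteRead:
    """Per-read methylation calls and conversion bookkeeping."""

    name: str
    amplicon: str
    mapq: int
    cpg_calls: list  # 1 = methylated, 0 = unmethylated, None = missing
    noncpg_c_covered: int = 0
    noncpg_c_unconverted: int = 0
    g_covered: int = 0
    ga_converted: int = 0

    def __post_init__(self):
        if self.noncpg_c_unconverted > self.noncpg_c_covered:
            raise ValueError("unconverted count exceeds covered count")

    @property
    def conversion_rate(self) -> float:
        """Fraction of covered non-CpG cytosines that converted; NaN if none covered."""
        if self.noncpg_c_covered == 0:
            return float("nan")
        return 1.0 - self.noncpg_c_unconverted / self.noncpg_c_covered

    @property
    def both_strand_converted(self) -> bool:
        """C->T and G->A conversion evidence both above 5% on one fragment."""
        ct = (self.noncpg_c_covered - self.noncpg_c_unconverted)
        ct_rate = ct / self.noncpg_c_covered if self.noncpg_c_covered else 0.0
        ga_rate = self.ga_converted / self.g_covered if self.g_covered else 0.0
        return ct_rate > 0.05 and ga_rate > 0.05


@dataclass(frozen=True)
class QCParams:
    min_conversion: float = 0.99
    min_mapq: int = 30
    max_unconverted: int = 2      # >= this many unconverted non-CpG C -> discard
    min_cpg_fraction: float = 0.5  # of the amplicon's CpGs a read must cover


def amplicons_from_bed(bed_path, fasta_path) -> list[AmpliconDef]:
    """Load amplicon intervals from BED and locate CpG sites in the reference."""
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    amplicons = []
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"], usecols=range(4))
    for row in bed.itertuples():
        seq = str(fasta[row.chrom][row.start:row.end])
        cpg = tuple(row.start + i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
        amplicons.append(AmpliconDef(str(row.name), str(row.chrom),
                                     int(row.start), int(row.end), cpg))
    names = [a.name for a in amplicons]
    if len(set(names)) != len(names):
        raise ValueError("amplicon names must be unique")
    return amplicons


def _collapse_mates(reads: list[BisulfiteRead]) -> BisulfiteRead:
    """Collapse overlapping mates of one fragment: union of CpG calls
    (first non-missing wins), summed conversion counts, min MAPQ."""
    if len(reads) == 1:
        return reads[0]
    first = reads[0]
    calls = list(first.cpg_calls)
    for other in reads[1:]:
        for i, c in enumerate(other.cpg_calls):
            if calls[i] is None:
                calls[i] = c
    return BisulfiteRead(
        name=first.name,
        amplicon=first.amplicon,
        mapq=min(r.mapq for r in reads),
        cpg_calls=calls,
        noncpg_c_covered=sum(r.noncpg_c_covered for r in reads),
        noncpg_c_unconverted=sum(r.noncpg_c_unconverted for r in reads),
        g_covered=sum(r.g_covered for r in reads),
        ga_converted=sum(r.ga_converted for r in reads),
    )


def parse_sam(sam_path, amplicons: list[AmpliconDef], fasta_path) -> list[BisulfiteRead]:
    """Parse aligned reads into BisulfiteRead records.

    Reads are assigned to the amplicon whose interval overlaps the alignment
    (amplicon contigs or genomic coordinates both work); fragments with the
    same query name are collapsed before haplotyping.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    by_chrom: dict[str, list[AmpliconDef]] = {}
    for amp in amplicons:
        by_chrom.setdefault(amp.chrom, []).append(amp)
    fragments: dict[tuple[str, str], list[BisulfiteRead]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            candidates = by_chrom.get(aln.reference_name, [])
            amp = next((a for a in candidates
                        if aln.reference_start < a.end and aln.reference_end > a.start),
                       None)
            if amp is None:
                continue
            ref = str(fasta[amp.chrom][:])
            cpg_set = {p: i for i, p in enumerate(amp.cpg_positions)}
            calls: list = [None] * len(amp.cpg_positions)
            ncc = ncu = gc = gac = 0
            qseq = aln.query_sequence
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if rpos >= len(ref):
                    continue
                rbase = ref[rpos]
                qbase = qseq[qpos]
                if rbase == "C":
                    if rpos in cpg_set:
                        if qbase == "C":
                            calls[cpg_set[rpos]] = 1
                        elif qbase == "T":
                            calls[cpg_set[rpos]] = 0
                    else:
                        ncc += 1
                        if qbase == "C":
                            ncu += 1
                elif rbase == "G":
                    gc += 1
                    if qbase == "A":
                        gac += 1
            rec = BisulfiteRead(
                name=aln.query_name, amplicon=amp.name,
                mapq=int(aln.mapping_quality), cpg_calls=calls,
                noncpg_c_covered=ncc, noncpg_c_unconverted=ncu,
                g_covered=gc, ga_converted=gac,
            )
            fragments.setdefault((aln.query_name, amp.name), []).append(rec)
    return [_collapse_mates(v) for v in fragments.values()]


def qc_filter_read(read: BisulfiteRead, min_conversion: float = 0.99,
                   min_mapq: int = 30, max_unconverted: int = 2):
    """Apply read-level QC.  Returns (keep, reason); reason is the first
    failing rule in order: conversion, unconverted_count, strand, mapq."""
    rate = read.conversion_rate
    if not np.isnan(rate) and rate < min_conversion:
        return False, "conversion"
    if read.noncpg_c_unconverted >= max_unconverted:
        return False, "unconverted_count"
    if read.both_strand_converted:
        return False, "strand"
    if read.mapq < min_mapq:
        return False, "mapq"
    return True, "pass"


def read_methylation_frequency(read: BisulfiteRead) -> float | None:
    """Haplotype bin of a read: rounded (methylated / covered) CpG ratio.

    Returns None when the read covers no CpG.
    """
    covered = [c for c in read.cpg_calls if c is not None]
    if not covered:
        return None
    return float(round_half_up(sum(covered) / len(covered)))


def build_haplotype_table(reads: list[BisulfiteRead], amplicons: list[AmpliconDef],
                          sample_id: str, qc: QCParams = QCParams()):
    """Aggregate QC-passing reads into a per-amplicon haplotype table.

    Returns (table, qc_summary).  ``table`` is long format with columns
    sample, amplicon, bin, count, prevalence; amplicons with zero passing
    reads are absent (missing, not zero-filled).  ``qc_summary`` counts
    reads per (amplicon, reason).
    """
    n_cpg = {a.name: len(a.cpg_positions) for a in amplicons}
    counts: dict[tuple[str, float], int] = {}
    qc_rows: dict[tuple[str, str], int] = {}

    def bump(amp, reason):
        qc_rows[(amp, reason)] = qc_rows.get((amp, reason), 0) + 1

    for read in reads:
        if read.amplicon not in n_cpg:
            bump(read.amplicon, "unknown_amplicon")
            continue
        keep, reason = qc_filter_read(read, qc.min_conversion, qc.min_mapq,
                                      qc.max_unconverted)
        if not keep:
            bump(read.amplicon, reason)
            continue
        covered = [c for c in read.cpg_calls if c is not None]
        if not covered:
            bump(read.amplicon, "no_cpg")
            continue
        if len(covered) < qc.min_cpg_fraction * n_cpg[read.amplicon]:
            bump(read.amplicon, "low_cpg_coverage")
            continue
        b = read_methylation_frequency(read)
        counts[(read.amplicon, b)] = counts.get((read.amplicon, b), 0) + 1
        bump(read.amplicon, "pass")

    totals: dict[str, int] = {}
    for (amp, _), n in counts.items():
        totals[amp] = totals.get(amp, 0) + n
    rows = [
        {"sample": sample_id, "amplicon": amp, "bin": b, "count": n,
         "prevalence": n / totals[amp]}
        for (amp, b), n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["sample", "amplicon", "bin", "count", "prevalence"])
    qc_summary = pd.DataFrame(
        [{"sample": sample_id, "amplicon": amp, "reason": reason, "n_reads": n}
         for (amp, reason), n in sorted(qc_rows.items())]
    )
    return table, qc_summary


def prevalence_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long haplotype table to samples x (amplicon, bin) prevalences.

    Bins unobserved in a sample are 0 where the amplicon was covered, NaN
    where the whole amplicon is missing for that sample.
    """
    samples = table["sample"].unique()
    amplicons = sorted(table["amplicon"].unique())
    cols = pd.MultiIndex.from_product([amplicons, list(BINS)],
                                      names=["amplicon", "bin"])
    wide = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample"), columns=cols)
    pivot = table.pivot_table(index="sample", columns=["amplicon", "bin"],
                              values="prevalence", aggfunc="first")
    covered = table.groupby(["sample", "amplicon"]).size()
    for sample, amp in covered.index:
        wide.loc[sample, amp] = 0.0
    wide.update(pivot)
    return wide
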