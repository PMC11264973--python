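"""SNP-site loading, heterozygous-site filtering, SNP windows and allele
partitioning of alignments.

Coordinates are 0-based half-open internally; VCF (1-based) is converted on
input and positions are converted back at output boundaries only.

The retention filter follows the published rule for RT-stop probing data:
a heterozygous SNP is retained iff it has at least ``min_total_reads``
SNP-spanning reads with a called allele (default 10) and at least
``min_allele_reads`` reads for *each* of the two alleles (default 2).
"Total" here counts spanning reads carrying the ref or alt allele, not raw
window coverage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .errors import (
    ContigMismatchError,
    EmptyInputError,
    InputFormatError,
)

TREATED = "treated"
CONTROL = "control"
ARMS = (TREATED, CONTROL)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNPSite:
    """A biallelic single-nucleotide variant (0-based position)."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position for {self.id}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt for {self.id}")
        for b in (self.ref_allele, self.alt_allele):
            if b not in _BASES:
                raise ValueError(f"non-SNV allele {b!r} for {self.id}")


@dataclass
class HetSNPObservation:
    """Per-allele spanning-read counts for one SNP, with retention status."""

    site: SNPSite
    ref_reads: int
    alt_reads: int
    other_reads: int
    retained: bool


@dataclass(frozen=True)
class SNPWindow:
    """The interval spanned by all SNP-spanning reads (0-based half-open).

    The window length N is the universe over which reactivity profiles and
    all downstream statistics are computed.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    snp_offset: int = 0

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("empty SNP window")
        if not (0 <= self.snp_offset < self.end - self.start):
            raise ValueError("snp_offset outside window")

    @property
    def N(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadObs:
    """A minimal view of one aligned read.

    ``stop_pos`` is the genomic position of the inferred RT-stop event: the
    base immediately upstream (in transcript orientation) of the alignment
    start — ``reference_start - 1`` for forward reads, ``reference_end`` for
    reverse reads.  ``blocks`` are the aligned reference blocks (gapless for
    unspliced reads) that contribute background coverage.
    """

    start: int
    end: int
    stop_pos: int
    blocks: tuple
    snp_base: str | None = None  # base carried at the SNP; None if not spanning


@dataclass
class FilterConfig:
    """Read- and site-level filters for allele counting."""

    min_total_reads: int = 10
    min_allele_reads: int = 2
    min_mapq: int = 20
    min_baseq: int = 13
    count_discarded_in_total: bool = True


@dataclass
class AllelePartition:
    """Window-overlapping reads split by allele and arm.

    Non-spanning reads are shared by both alleles.  Spanning reads carrying a
    third base (or a deletion) at the SNP are discarded from the allele sets
    but still counted in ``r_total``.
    """

    ref_spanning: dict = field(default_factory=lambda: {a: [] for a in ARMS})
    alt_spanning: dict = field(default_factory=lambda: {a: [] for a in ARMS})
    nonspanning: dict = field(default_factory=lambda: {a: [] for a in ARMS})
    discarded: dict = field(default_factory=lambda: {a: [] for a in ARMS})

    @property
    def r_d(self) -> int:
        """Number of SNP-spanning reads with a called allele, both arms."""
        return sum(len(self.ref_spanning[a]) + len(self.alt_spanning[a]) for a in ARMS)

    @property
    def r_total(self) -> int:
        """Total reads overlapping the window, both arms."""
        n = self.r_d + sum(len(self.nonspanning[a]) for a in ARMS)
        n += sum(len(self.discarded[a]) for a in ARMS)
        return n

    def n_overlapping(self, arm: str) -> int:
        return (
            len(self.ref_spanning[arm])
            + len(self.alt_spanning[arm])
            + len(self.nonspanning[arm])
            + len(self.discarded[arm])
        )


def retained(ref_reads: int, alt_reads: int, cfg: FilterConfig | None = None) -> bool:
    """Site retention rule: total spanning >= 10 and each allele >= 2."""
    cfg = cfg or FilterConfig()
    return (
        ref_reads + alt_reads >= cfg.min_total_reads
        and ref_reads >= cfg.min_allele_reads
        and alt_reads >= cfg.min_allele_reads
    )


# ---------------------------------------------------------------------------
# SNP file loading


def _load_vcf(path: str) -> list[SNPSite]:
    sites = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.ref is None or rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if ref not in _BASES or alt not in _BASES:
                continue
            sites.append(
                SNPSite(rec.chrom, rec.pos - 1, rec.id or f"{rec.chrom}:{rec.pos}", ref, alt)
            )
    return sites


def _load_tsv(path: str) -> list[SNPSite]:
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise InputFormatError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            chrom, pos_s, snp_id, ref, alt = parts[:5]
            try:
                pos = int(pos_s)
            except ValueError as e:
                raise InputFormatError(f"{path}:{ln}: bad position {pos_s!r}") from e
            ref, alt = ref.upper(), alt.upper()
            if ref not in _BASES or alt not in _BASES or ref == alt:
                continue  # indel / multi-allelic / malformed record: skip
            sites.append(SNPSite(chrom, pos - 1, snp_id, ref, alt))
    return sites


def load_snp_sites(path: str) -> list[SNPSite]:
    """Load biallelic SNVs from a VCF (plain or bgzipped) or a 5-column TSV.

    TSV columns are ``chrom, pos (1-based), id, ref, alt`` (dbSNP-style).
    Records are deduplicated by (chrom, pos, id) and sorted by (chrom, pos).
    """
    if not os.path.exists(path):
        raise InputFormatError(f"SNP file not found: {path}")
    lower = path.lower()
    if lower.endswith((".vcf", ".vcf.gz", ".bcf")):
        try:
            sites = _load_vcf(path)
        except (ValueError, OSError) as e:
            raise InputFormatError(f"cannot parse VCF {path}: {e}") from e
    else:
        sites = _load_tsv(path)
    seen: set = set()
    uniq = []
    for s in sites:
        key = (s.chrom, s.pos, s.id)
        if key in seen:
            continue
        seen.add(key)
        uniq.append(s)
    if not uniq:
        raise EmptyInputError(f"no usable biallelic SNV records in {path}")
    uniq.sort(key=lambda s: (s.chrom, s.pos, s.id))
    return uniq


# ---------------------------------------------------------------------------
# Read collection


def _read_to_obs(aln: pysam.AlignedSegment, snp_pos: int | None, min_baseq: int) -> ReadObs:
    blocks = tuple(aln.get_blocks())
    if aln.is_reverse:
        stop = aln.reference_end  # upstream base in transcript orientation
    else:
        stop = aln.reference_start - 1
    snp_base = None
    if snp_pos is not None and aln.reference_start <= snp_pos < aln.reference_end:
        qpos = None
        for q, r in aln.get_aligned_pairs(matches_only=True):
            if r == snp_pos:
                qpos = q
                break
        if qpos is not None:
            base = aln.query_sequence[qpos].upper()
            qual = aln.query_qualities[qpos] if aln.query_qualities is not None else 255
            if qual >= min_baseq:
                snp_base = base
            else:
                snp_base = "N"  # low base quality: uncallable, discard from alleles
        else:
            snp_base = "-"  # deletion at the SNP base
    return ReadObs(aln.reference_start, aln.reference_end, stop, blocks, snp_base)


def _usable(aln: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        aln.is_unmapped
        or aln.is_secondary
        or aln.is_supplementary
        or aln.is_duplicate
        or aln.is_qcfail
        or aln.mapping_quality < min_mapq
    )


def fetch_reads(
    handles: Sequence[pysam.AlignmentFile],
    chrom: str,
    start: int,
    end: int,
    cfg: FilterConfig,
    snp_pos: int | None = None,
) -> list[ReadObs]:
    """Collect usable reads overlapping [start, end) from pooled handles."""
    out = []
    for h in handles:
        if chrom not in h.references:
            raise ContigMismatchError(f"contig {chrom!r} absent from {h.filename!r}")
        for aln in h.fetch(chrom, max(0, start), end):
            if _usable(aln, cfg.min_mapq):
                out.append(_read_to_obs(aln, snp_pos, cfg.min_baseq))
    return out


def observe_snp(
    site: SNPSite,
    treated: Sequence[pysam.AlignmentFile],
    control: Sequence[pysam.AlignmentFile],
    cfg: FilterConfig | None = None,
) -> HetSNPObservation:
    """Count SNP-spanning reads per allele (pooled arms) and set retention."""
    cfg = cfg or FilterConfig()
    reads = fetch_reads(
        list(treated) + list(control), site.chrom, site.pos, site.pos + 1, cfg, site.pos
    )
    ref = alt = other = 0
    for r in reads:
        if r.snp_base == site.ref_allele:
            ref += 1
        elif r.snp_base == site.alt_allele:
            alt += 1
        elif r.snp_base is not None:
            other += 1
    return HetSNPObservation(site, ref, alt, other, retained(ref, alt, cfg))


def define_window(
    site: SNPSite,
    treated: Sequence[pysam.AlignmentFile],
    control: Sequence[pysam.AlignmentFile],
    cfg: FilterConfig | None = None,
    strand: str = "+",
) -> SNPWindow:
    """Envelope of all SNP-spanning reads (treated and control pooled)."""
    cfg = cfg or FilterConfig()
    reads = fetch_reads(
        list(treated) + list(control), site.chrom, site.pos, site.pos + 1, cfg, site.pos
    )
    spanning = [r for r in reads if r.snp_base is not None]
    if not spanning:
        raise InsufficientSpanning(site)
    start = min(r.start for r in spanning)
    end = max(r.end for r in spanning)
    return SNPWindow(site.chrom, start, end, strand, site.pos - start)


class InsufficientSpanning(ValueError):
    def __init__(self, site: SNPSite):
        super().__init__(f"no SNP-spanning reads at {site.id}")
        self.site = site


def partition_reads(
    window: SNPWindow,
    site: SNPSite,
    treated: Sequence[pysam.AlignmentFile],
    control: Sequence[pysam.AlignmentFile],
    cfg: FilterConfig | None = None,
) -> AllelePartition:
    """Assign every window-overlapping read to ref/alt/nonspanning/discarded."""
    cfg = cfg or FilterConfig()
    part = AllelePartition()
    for arm, handles in ((TREATED, treated), (CONTROL, control)):
        reads = fetch_reads(handles, window.chrom, window.start, window.end, cfg, site.pos)
        for r in reads:
            if r.snp_base is None:
                part.nonspanning[arm].append(r)
            elif r.snp_base == site.ref_allele:
                part.ref_spanning[arm].append(r)
            elif r.snp_base == site.alt_allele:
                part.alt_spanning[arm].append(r)
            else:
                part.discarded[arm].append(r)
    return part


def collapse_identical(reads: Iterable[ReadObs]) -> list[ReadObs]:
    """Optional identical-read collapse (off by default; input is assumed
    already PCR-deduplicated upstream)."""
    seen: set = set()
    out = []
    for r in reads:
        key = (r.start, r.end, r.blocks, r.snp_base)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out
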