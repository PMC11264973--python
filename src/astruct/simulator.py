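"""Synthetic RT-stop structure-probing datasets with ground-truth labels.

The benchmark design: each synthetic transcript carries one heterozygous SNP
at its midpoint and a paired/unpaired mask per allele.  Non-ASRS transcripts
give both alleles the same unpaired-base set; ASRS transcripts give the two
alleles different unpaired-base sets.  Reads are sampled per transcript with
Poisson-distributed counts at configurable depth tiers, split 1:1 between
alleles, in two sample arms: control reads start uniformly, while a fraction
``stop_rate`` of treated reads instead start one base downstream of an
unpaired base of their allele (an RT-stop event), with the artificial stop
intervention spread evenly across that allele's unpaired bases.

Reads are emitted as genuine coordinate-sorted, indexed BAM alignments over
a synthetic reference FASTA, so the whole alignment-facing pipeline is
exercised rather than bypassed.  By default masks come from a self-contained
stochastic stem-loop tiler; externally computed dot-bracket structures can
be supplied instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from sklearn.metrics import roc_auc_score

from .errors import EmptyInputError, InputFormatError

_NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Benchmark generator settings.

    depth_tiers are mean reads per transcript per arm (pooled over the
    pseudo-replicates); they are a desk-scale stand-in for genome-wide
    sequencing depths.  stop_rate is the probability that a treated read
    carries an artificial RT-stop intervention at an unpaired base.
    """

    n_transcripts: int = 200
    transcript_length: int = 500
    asrs_fraction: float = 0.5
    depth_tiers: tuple = (250, 500, 1000)
    stop_rate: float = 1.0
    read_length: int = 50
    allele_ratio: float = 0.5
    unpaired_fraction: float = 0.5
    min_asrs_hamming: int = 10
    asrs_neighborhood: int = 50
    n_replicates: int = 2
    exact_split: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.asrs_fraction <= 1.0):
            raise ValueError("asrs_fraction must be in [0, 1]")
        tiers = tuple(self.depth_tiers)
        if not tiers or any(t <= 0 for t in tiers) or list(tiers) != sorted(set(tiers)):
            raise ValueError("depth_tiers must be positive and strictly increasing")
        if not (0.0 < self.stop_rate <= 1.0):
            raise ValueError("stop_rate must be in (0, 1]")
        if self.transcript_length < 2 * self.read_length:
            raise ValueError("transcript must be at least twice the read length")


@dataclass
class SimTranscript:
    """One synthetic transcript with its per-allele structure masks.

    Masks are True at *paired* bases; the unpaired (reactive) set is the
    complement.  is_asrs marks a genuine allele-specific structure event.
    """

    id: str
    sequence: str
    paired_mask_ref: np.ndarray
    paired_mask_alt: np.ndarray
    snp_pos: int
    ref_allele: str
    alt_allele: str
    is_asrs: bool

    def __post_init__(self):
        L = len(self.sequence)
        if len(self.paired_mask_ref) != L or len(self.paired_mask_alt) != L:
            raise ValueError("mask length != sequence length")
        same = bool(np.array_equal(self.paired_mask_ref, self.paired_mask_alt))
        if self.is_asrs == same:
            raise ValueError("is_asrs label inconsistent with masks")


def dotbracket_to_mask(structure: str) -> np.ndarray:
    """Convert a dot-bracket string to a paired-base mask (True = paired)."""
    mask = np.zeros(len(structure), dtype=bool)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
            mask[i] = True
        elif c == ")":
            if not stack:
                raise InputFormatError("unbalanced dot-bracket: unmatched ')'")
            stack.pop()
            mask[i] = True
        elif c != ".":
            raise InputFormatError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise InputFormatError("unbalanced dot-bracket: unmatched '('")
    return mask


def sample_structure(
    length: int,
    rng: np.random.Generator | int | None = None,
    unpaired_fraction: float = 0.5,
    dot_bracket: str | None = None,
) -> np.ndarray:
    """Sample a paired/unpaired mask from a stochastic stem-loop tiler, or
    convert an externally supplied dot-bracket structure.

    The tiler lays down alternating stem (paired) and loop (unpaired)
    segments of geometric-ish random length, matching RNA's blocky
    helix/loop architecture, with the expected unpaired fraction given by
    ``unpaired_fraction``.
    """
    if dot_bracket is not None:
        return dotbracket_to_mask(dot_bracket)
    if length < 20:
        raise ValueError("structures shorter than 20 nt are not supported")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mask = np.zeros(length, dtype=bool)
    i = 0
    while i < length:
        seg = int(rng.integers(3, 9))  # helix/loop segments of 3-8 nt
        paired = rng.random() < (1.0 - unpaired_fraction)
        mask[i : i + seg] = paired
        i += seg
    return mask


def derive_alt_structure(
    mask_ref: np.ndarray,
    is_asrs: bool,
    rng: np.random.Generator | int | None = None,
    snp_pos: int | None = None,
    min_hamming: int = 10,
    neighborhood: int = 50,
    unpaired_fraction: float = 0.5,
) -> np.ndarray:
    """Alt-allele mask: identical for non-ASRS; an independently sampled
    mask differing from the ref mask in at least ``min_hamming`` bases
    within +/- ``neighborhood`` of the SNP for ASRS transcripts."""
    mask_ref = np.asarray(mask_ref, dtype=bool)
    if not is_asrs:
        return mask_ref.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = mask_ref.size
    if snp_pos is None:
        snp_pos = L // 2
    lo, hi = max(0, snp_pos - neighborhood), min(L, snp_pos + neighborhood + 1)
    for _ in range(100):
        mask_alt = sample_structure(L, rng, unpaired_fraction)
        if int(np.sum(mask_ref[lo:hi] != mask_alt[lo:hi])) >= min_hamming:
            return mask_alt
    # pathologically similar draws: force flips nearest the SNP
    mask_alt = mask_ref.copy()
    order = np.argsort(np.abs(np.arange(lo, hi) - snp_pos))
    mask_alt[np.arange(lo, hi)[order[:min_hamming]]] ^= True
    return mask_alt


def make_transcript(tid: str, cfg: SimConfig, rng: np.random.Generator, is_asrs: bool) -> SimTranscript:
    L = cfg.transcript_length
    seq = "".join(rng.choice(_NT, size=L))
    snp_pos = L // 2
    ref_allele = seq[snp_pos]
    alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_allele]))
    mask_ref = sample_structure(L, rng, cfg.unpaired_fraction)
    mask_alt = derive_alt_structure(
        mask_ref,
        is_asrs,
        rng,
        snp_pos,
        cfg.min_asrs_hamming,
        cfg.asrs_neighborhood,
        cfg.unpaired_fraction,
    )
    return SimTranscript(tid, seq, mask_ref, mask_alt, snp_pos, ref_allele, alt_allele, is_asrs)


def make_transcripts(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[SimTranscript]:
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_transcripts
    if cfg.exact_split:
        n_asrs = int(round(cfg.asrs_fraction * n))
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=n_asrs, replace=False)] = True
    else:
        labels = rng.random(n) < cfg.asrs_fraction
    return [make_transcript(f"tx{i:05d}", cfg, rng, bool(labels[i])) for i in range(n)]


def simulate_reads(
    transcript: SimTranscript,
    cfg: SimConfig,
    tier: int,
    rng: np.random.Generator | int | None = None,
) -> list[tuple]:
    """Sample reads for one transcript at one depth tier.

    Returns tuples (arm, replicate, allele, start, sequence).  Read counts
    per arm/replicate are Poisson(tier / n_replicates); each read's allele
    is Bernoulli(allele_ratio); treated reads carry the artificial stop
    intervention with probability stop_rate, starting one base 3' of a
    uniformly chosen unpaired base of their allele.
    """
    if tier <= 0:
        raise EmptyInputError("tier budget must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L, rl = cfg.transcript_length, cfg.read_length
    max_start = L - rl
    unpaired = {
        "ref": np.flatnonzero(~transcript.paired_mask_ref),
        "alt": np.flatnonzero(~transcript.paired_mask_alt),
    }
    # eligible stop bases: the read starting at u+1 must fit on the transcript
    eligible = {a: u[u + 1 <= max_start] for a, u in unpaired.items()}
    seq_by_allele = {}
    for allele, base in (("ref", transcript.ref_allele), ("alt", transcript.alt_allele)):
        s = list(transcript.sequence)
        s[transcript.snp_pos] = base
        seq_by_allele[allele] = "".join(s)
    reads = []
    for arm in ("treated", "control"):
        for rep in range(1, cfg.n_replicates + 1):
            n_reads = rng.poisson(tier / cfg.n_replicates)
            alleles = np.where(rng.random(n_reads) < cfg.allele_ratio, "ref", "alt")
            starts = rng.integers(0, max_start + 1, size=n_reads)
            if arm == "treated":
                # even intervention: equal stop probability per unpaired
                # base, drawn independently per read -- reads stay
                # exchangeable, which a balanced (round-robin) allocation
                # would not be, silently biasing the permutation null
                stop_mask = rng.random(n_reads) < cfg.stop_rate
                for allele in ("ref", "alt"):
                    elig = eligible[allele]
                    idx = np.flatnonzero(stop_mask & (alleles == allele))
                    if not elig.size or not idx.size:
                        continue
                    starts[idx] = rng.choice(elig, size=idx.size, replace=True) + 1
            for i in range(n_reads):
                st = int(starts[i])
                reads.append((arm, rep, alleles[i], st, seq_by_allele[alleles[i]][st : st + rl]))
    return reads


# ---------------------------------------------------------------------------
# Dataset writing


def _write_fasta(path: str, transcripts: list[SimTranscript]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")
    pysam.faidx(path)


def _write_vcf(path: str, transcripts: list[SimTranscript]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for t in transcripts:
            fh.write(f"##contig=<ID={t.id},length={len(t.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in transcripts:
            fh.write(
                f"{t.id}\t{t.snp_pos + 1}\tsnp_{t.id}\t{t.ref_allele}\t{t.alt_allele}\t.\t.\t.\n"
            )


def write_manifest(path: str, transcripts: list[SimTranscript]) -> None:
    rows = [
        {
            "transcript_id": t.id,
            "snp_id": f"snp_{t.id}",
            "snp_pos": t.snp_pos,
            "ref": t.ref_allele,
            "alt": t.alt_allele,
            "is_asrs": int(t.is_asrs),
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "is_asrs"}
    if not required <= set(df.columns):
        raise InputFormatError(f"manifest missing columns {required - set(df.columns)}")
    return df


def _write_bam(path: str, transcripts: list[SimTranscript], records: list[tuple]) -> None:
    """records: (ref_id_index, qname, start, sequence), pre-sorted."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": t.id, "LN": len(t.sequence)} for t in transcripts],
    }
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rid, qname, start, seq in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = rid
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    pysam.index(path)


def write_dataset(out_dir: str, cfg: SimConfig) -> dict:
    """Generate the full benchmark: reference FASTA, SNP VCF, truth manifest
    and, per depth tier, 2x treated + 2x control coordinate-sorted BAMs.

    One master seed; per-(transcript, tier) child RNGs are derived
    deterministically so any transcript is re-simulable in isolation.
    Returns a dict of the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    transcripts = make_transcripts(cfg, np.random.default_rng(master.spawn(1)[0]))
    fasta = os.path.join(out_dir, "ref.fa")
    vcf = os.path.join(out_dir, "snps.vcf")
    manifest = os.path.join(out_dir, "manifest.tsv")
    _write_fasta(fasta, transcripts)
    _write_vcf(vcf, transcripts)
    write_manifest(manifest, transcripts)
    paths = {"fasta": fasta, "vcf": vcf, "manifest": manifest, "tiers": {}}
    for ti, tier in enumerate(cfg.depth_tiers):
        tier_dir = os.path.join(out_dir, f"tier_{tier}")
        os.makedirs(tier_dir, exist_ok=True)
        per_file: dict = {}
        serial = 0
        for tx_i, t in enumerate(transcripts):
            child = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1 + ti, tx_i))
            )
            for arm, rep, allele, start, seq in simulate_reads(t, cfg, tier, child):
                qname = f"{t.id}:{arm}{rep}:{allele}:{serial}"
                serial += 1
                per_file.setdefault((arm, rep), []).append((tx_i, qname, start, seq))
        tier_paths = {}
        for (arm, rep), recs in sorted(per_file.items()):
            recs.sort(key=lambda r: (r[0], r[2]))
            path = os.path.join(tier_dir, f"{arm}_rep{rep}.bam")
            _write_bam(path, transcripts, recs)
            tier_paths.setdefault(arm, []).append(path)
        paths["tiers"][tier] = tier_paths
    return paths


def evaluate_auc(calls: pd.DataFrame, truth: pd.DataFrame, score_col: str = "astruct_score") -> float:
    """ROC AUC of the AStruct score against the ground-truth ASRS labels
    (rank / Mann-Whitney formulation, ties handled by midranks)."""
    merged = calls.merge(truth[["snp_id", "is_asrs"]], on="snp_id", how="inner")
    if merged.empty:
        raise EmptyInputError("no calls joinable to the truth manifest")
    y = merged["is_asrs"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: truth labels contain a single class")
    return float(roc_auc_score(y, merged[score_col].to_numpy()))
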