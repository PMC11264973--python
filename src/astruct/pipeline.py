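"""End-to-end orchestration: SNP list + BAMs -> per-SNP ASRS call table."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy.stats import false_discovery_control

from . import __version__
from .alignment_io import (
    FilterConfig,
    InsufficientSpanning,
    define_window,
    load_snp_sites,
    observe_snp,
    partition_reads,
)
from .asrs import call_site
from .errors import ContigMismatchError, EmptyResultError
from .reactivity import ReactivityConfig

CALL_COLUMNS = [
    "chrom",
    "pos",
    "snp_id",
    "ref",
    "alt",
    "ref_reads",
    "alt_reads",
    "r_d",
    "r_total",
    "window_start",
    "window_end",
    "N",
    "pcc",
    "esdc",
    "p_value",
    "astruct_score",
    "group",
    "bh_fdr",
]


@dataclass
class RunConfig:
    """Everything one `astruct call` run needs."""

    treated: list
    control: list
    snps: str
    out_dir: str
    fasta: str | None = None
    n_perm: int = 1000
    seed: int = 0
    per_base: bool = False
    export_profiles: bool = False
    filters: FilterConfig = field(default_factory=FilterConfig)
    reactivity: ReactivityConfig = field(default_factory=ReactivityConfig)

    def validate(self):
        for p in list(self.treated) + list(self.control) + [self.snps]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        if self.fasta and not os.path.exists(self.fasta):
            raise FileNotFoundError(self.fasta)


def _header_lines(cfg: RunConfig) -> list[str]:
    f, r = cfg.filters, cfg.reactivity
    return [
        f"# astruct v{__version__}",
        f"# seed={cfg.seed} n_perm={cfg.n_perm}",
        f"# treated={','.join(map(str, cfg.treated))}",
        f"# control={','.join(map(str, cfg.control))}",
        f"# snps={cfg.snps}",
        f"# min_total_reads={f.min_total_reads} min_allele_reads={f.min_allele_reads}"
        f" min_mapq={f.min_mapq} min_baseq={f.min_baseq}",
        f"# s_factor={r.s_factor} quantiles=({r.norm_quantile_lo},{r.norm_quantile_hi})",
        "# coordinates: pos and window_start 1-based inclusive; window_end inclusive",
    ]


def run_call(cfg: RunConfig, log=print) -> tuple[pd.DataFrame, dict]:
    """Run the full caller; returns (calls table, stage-count stats).

    Per-site RNG streams are derived from the master seed and the site's
    rank in the sorted SNP list, so reruns with the same inputs and seed are
    byte-identical.
    """
    cfg.validate()
    sites = load_snp_sites(cfg.snps)
    treated = [pysam.AlignmentFile(p) for p in cfg.treated]
    control = [pysam.AlignmentFile(p) for p in cfg.control]
    ref_fasta = None
    if cfg.fasta:
        from pyfaidx import Fasta

        ref_fasta = Fasta(cfg.fasta)
    stats = {
        "sites_seen": len(sites),
        "sites_on_contigs": 0,
        "ref_mismatch": 0,
        "heterozygous": 0,
        "retained": 0,
        "called": 0,
    }
    rows = []
    per_base_rows = []
    calls = []
    try:
        for idx, site in enumerate(sites):
            try:
                obs = observe_snp(site, treated, control, cfg.filters)
            except ContigMismatchError:
                continue
            stats["sites_on_contigs"] += 1
            if ref_fasta is not None:
                try:
                    base = str(ref_fasta[site.chrom][site.pos]).upper()
                except (KeyError, IndexError):
                    base = None
                if base is not None and base != site.ref_allele:
                    stats["ref_mismatch"] += 1
                    continue
            if obs.ref_reads > 0 and obs.alt_reads > 0:
                stats["heterozygous"] += 1
            if not obs.retained:
                continue
            stats["retained"] += 1
            try:
                window = define_window(site, treated, control, cfg.filters)
            except InsufficientSpanning:
                continue
            partition = partition_reads(window, site, treated, control, cfg.filters)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx,))
            )
            call = call_site(
                obs,
                window,
                partition,
                cfg.reactivity,
                n_perm=cfg.n_perm,
                rng=rng,
                per_base=cfg.per_base,
            )
            stats["called"] += 1
            calls.append(call)
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos + 1,
                    "snp_id": site.id,
                    "ref": site.ref_allele,
                    "alt": site.alt_allele,
                    "ref_reads": obs.ref_reads,
                    "alt_reads": obs.alt_reads,
                    "r_d": call.r_d,
                    "r_total": call.r_total,
                    "window_start": window.start + 1,
                    "window_end": window.end,
                    "N": window.N,
                    "pcc": call.pcc,
                    "esdc": call.esdc,
                    "p_value": call.p_value,
                    "astruct_score": call.astruct_score,
                    "group": call.group,
                }
            )
            if cfg.per_base and call.strucdiff is not None:
                for i in range(window.N):
                    per_base_rows.append(
                        {
                            "snp_id": site.id,
                            "window_pos": i,
                            "es_ref": call.profile_ref.scores[i],
                            "es_alt": call.profile_alt.scores[i],
                            "strucdiff": call.strucdiff[i],
                            "strucdiff_p": (
                                call.strucdiff_p[i] if call.strucdiff_p is not None else np.nan
                            ),
                        }
                    )
    finally:
        for h in treated + control:
            h.close()
    if stats["sites_on_contigs"] == 0:
        raise ContigMismatchError(
            "no SNP contig matches the alignment headers; wrong SNP file or reference?"
        )
    log(
        "astruct call: {sites_seen} sites seen, {sites_on_contigs} on alignment contigs, "
        "{heterozygous} heterozygous, {retained} retained, {called} called".format(**stats)
    )
    df = pd.DataFrame(rows, columns=[c for c in CALL_COLUMNS if c != "bh_fdr"])
    # convenience column beyond the published method, which reports raw P
    if not df.empty:
        df["bh_fdr"] = false_discovery_control(df["p_value"], method="bh")
    else:
        df["bh_fdr"] = []
    os.makedirs(cfg.out_dir, exist_ok=True)
    out_path = os.path.join(cfg.out_dir, "astruct_calls.tsv")
    write_calls(out_path, df, cfg)
    if cfg.per_base:
        pb = pd.DataFrame(
            per_base_rows,
            columns=["snp_id", "window_pos", "es_ref", "es_alt", "strucdiff", "strucdiff_p"],
        )
        pb_path = os.path.join(cfg.out_dir, "astruct_per_base.tsv")
        with open(pb_path, "w") as fh:
            fh.write("\n".join(_header_lines(cfg)) + "\n")
            pb.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    if cfg.export_profiles:
        from .reactivity import write_bedgraph

        prof_dir = os.path.join(cfg.out_dir, "profiles")
        os.makedirs(prof_dir, exist_ok=True)
        for call in calls:
            for prof in (call.profile_ref, call.profile_alt):
                write_bedgraph(
                    prof,
                    os.path.join(prof_dir, f"{call.site.id}_{prof.allele}.bedgraph"),
                    name=call.site.id,
                )
    if df.empty:
        raise EmptyResultError("zero retained SNPs: nothing to call")
    return df, stats


def write_calls(path: str, df: pd.DataFrame, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(cfg)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_calls(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
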