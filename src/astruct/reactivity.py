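"""Per-allele, per-base reactivity (structure) scores from RT-stop counts.

The scoring follows the icSHAPE-pipe lineage, restricted to one SNP window:

1. count RT-stop events R_i (the base immediately upstream of each read
   start) and background coverage B_i (every aligned base) over the window;
2. divide R and B by their within-window 95th-percentile order statistic
   (nearest-rank convention, 1-based index ceil(q*N));
3. background-subtracted enrichment ES_i = (R_i^T - s * R_i^C) / B_i^C using
   the treated (NAI-N3) stop signal and the control (DMSO) stop/coverage;
4. affinely rescale ES into [0, 1] between its 5th and 95th within-window
   order statistics, clamping outside values.

Bases with zero raw control coverage carry no information and are reported
missing (NaN); Eq-4 order statistics are taken over non-missing bases only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import AllelePartition, ReadObs, SNPWindow, ARMS, TREATED, CONTROL
from .errors import EmptyProfileError


@dataclass
class ReactivityConfig:
    """Tunables of the reactivity transform.

    s_factor: weight of the control stop signal subtracted from the treated
        stop signal (the predefined background-subtraction factor).
    norm_quantile_hi / norm_quantile_lo: the order-statistic quantiles used
        for normalization and unit scaling.
    background_pseudocount: floor applied to the *normalized* control
        background before division, so the ratio is always defined.  Bases
        with zero raw coverage are marked missing regardless.
    """

    s_factor: float = 0.25
    norm_quantile_hi: float = 0.95
    norm_quantile_lo: float = 0.05
    background_pseudocount: float = 1e-6

    def __post_init__(self):
        if not (0 < self.norm_quantile_lo < self.norm_quantile_hi < 1):
            raise ValueError("require 0 < lo < hi < 1 quantiles")
        if self.s_factor < 0:
            raise ValueError("s_factor must be >= 0")


@dataclass
class StopProfile:
    """Raw per-base RT-stop counts and background coverage for one allele/arm."""

    window: SNPWindow
    stops: np.ndarray
    background: np.ndarray
    arm: str = TREATED
    allele: str = "ref"

    def __post_init__(self):
        n = self.window.N
        if len(self.stops) != n or len(self.background) != n:
            raise ValueError("profile vectors must have window length")


@dataclass
class ReactivityProfile:
    """Unit-interval structure scores for one allele (NaN = missing)."""

    window: SNPWindow
    scores: np.ndarray
    allele: str = "ref"
    degenerate: bool = False


def nearest_rank(values: Sequence[float], q: float) -> float:
    """Nearest-rank order statistic: sorted 1-based index ceil(q * n)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty vector has no percentiles")
    idx = min(max(math.ceil(q * n), 1), n) - 1
    return float(v[idx])


def normalize_percentile(values: np.ndarray, q: float = 0.95) -> tuple[np.ndarray, bool]:
    """Divide by the nearest-rank q-th percentile.

    Returns (normalized vector, degenerate flag); a zero normalizer leaves
    the vector unchanged and sets the flag.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("normalize_percentile requires nonnegative input")
    factor = nearest_rank(values, q)
    if factor == 0:
        return values.copy(), True
    return values / factor, False


def enrichment_scores(
    treated_stops: np.ndarray,
    control_stops: np.ndarray,
    control_background: np.ndarray,
    cfg: ReactivityConfig | None = None,
    raw_control_background: np.ndarray | None = None,
) -> np.ndarray:
    """Background-subtracted enrichment, NaN where the control has no coverage.

    Inputs are the already percentile-normalized vectors; the optional raw
    (pre-normalization) control coverage determines missingness.
    """
    cfg = cfg or ReactivityConfig()
    r_t = np.asarray(treated_stops, dtype=float)
    r_c = np.asarray(control_stops, dtype=float)
    b_c = np.asarray(control_background, dtype=float)
    if not (r_t.shape == r_c.shape == b_c.shape):
        raise ValueError("enrichment inputs must share length")
    denom = np.maximum(b_c, cfg.background_pseudocount)
    es = (r_t - cfg.s_factor * r_c) / denom
    raw = b_c if raw_control_background is None else np.asarray(raw_control_background)
    es[raw == 0] = np.nan
    return es


def scale_unit(raw_es: np.ndarray, cfg: ReactivityConfig | None = None) -> tuple[np.ndarray, bool]:
    """Rescale enrichment scores into [0, 1] between their 5th and 95th
    within-window order statistics; missing values propagate.

    Returns (scores, degenerate flag); when the two order statistics
    coincide all non-missing values map to 0 and the flag is set.
    """
    cfg = cfg or ReactivityConfig()
    es = np.asarray(raw_es, dtype=float)
    finite = es[~np.isnan(es)]
    if finite.size == 0:
        raise EmptyProfileError("all bases missing; no profile to scale")
    lo = nearest_rank(finite, cfg.norm_quantile_lo)
    hi = nearest_rank(finite, cfg.norm_quantile_hi)
    out = np.full_like(es, np.nan)
    mask = ~np.isnan(es)
    if hi == lo:
        out[mask] = 0.0
        return out, True
    out[mask] = np.clip((es[mask] - lo) / (hi - lo), 0.0, 1.0)
    return out, False


def count_stops_and_background(reads: Iterable[ReadObs], window: SNPWindow) -> StopProfile:
    """Accumulate RT-stop and background counts over the window.

    The stop base is the one immediately upstream of the read start in
    transcript orientation; stops falling outside the window are dropped
    (the window is the declared universe of the scoring equations).
    """
    n = window.N
    stops = np.zeros(n, dtype=float)
    background = np.zeros(n, dtype=float)
    for r in reads:
        sp = r.stop_pos - window.start
        if 0 <= sp < n:
            stops[sp] += 1
        for bs, be in r.blocks:
            lo = max(bs, window.start) - window.start
            hi = min(be, window.end) - window.start
            if hi > lo:
                background[lo:hi] += 1
    return StopProfile(window, stops, background)


def profile_from_counts(
    treated_stops: np.ndarray,
    control_stops: np.ndarray,
    control_background: np.ndarray,
    cfg: ReactivityConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """Run normalize -> enrichment -> unit scaling on raw count vectors."""
    cfg = cfg or ReactivityConfig()
    q = cfg.norm_quantile_hi
    r_t, _ = normalize_percentile(treated_stops, q)
    r_c, _ = normalize_percentile(control_stops, q)
    b_c, _ = normalize_percentile(control_background, q)
    es = enrichment_scores(r_t, r_c, b_c, cfg, raw_control_background=control_background)
    return scale_unit(es, cfg)


def allele_reactivity(
    window: SNPWindow,
    partition: AllelePartition,
    cfg: ReactivityConfig | None = None,
) -> tuple[ReactivityProfile, ReactivityProfile]:
    """Per-allele profiles: each allele uses its spanning reads plus the
    shared non-spanning reads, in both sample arms independently."""
    cfg = cfg or ReactivityConfig()
    profiles = []
    for allele, spanning in (("ref", partition.ref_spanning), ("alt", partition.alt_spanning)):
        counts = {}
        for arm in ARMS:
            reads = list(spanning[arm]) + list(partition.nonspanning[arm])
            counts[arm] = count_stops_and_background(reads, window)
        scores, degenerate = profile_from_counts(
            counts[TREATED].stops,
            counts[CONTROL].stops,
            counts[CONTROL].background,
            cfg,
        )
        profiles.append(ReactivityProfile(window, scores, allele, degenerate))
    return profiles[0], profiles[1]


# ---------------------------------------------------------------------------
# Optional per-base exports


def write_bedgraph(profile: ReactivityProfile, path: str, name: str = "reactivity") -> None:
    w = profile.window
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}_{profile.allele}"\n')
        for i, s in enumerate(profile.scores):
            if not np.isnan(s):
                fh.write(f"{w.chrom}\t{w.start + i}\t{w.start + i + 1}\t{s:.6g}\n")


def profiles_long_table(snp_id, window, stop_profiles, es_by_allele):
    """Long-format per-base rows: (snp_id, window_pos, allele, raw_stop,
    raw_bg, es) for TSV export."""
    rows = []
    for allele, es in es_by_allele.items():
        sp = stop_profiles[allele]
        for i in range(window.N):
            rows.append(
                {
                    "snp_id": snp_id,
                    "window_pos": i,
                    "allele": allele,
                    "raw_stop": sp[TREATED].stops[i],
                    "raw_bg": sp[CONTROL].background[i],
                    "es": es[i],
                }
            )
    return rows
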