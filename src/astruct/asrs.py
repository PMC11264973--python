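"""Allelic structure-difference statistics.

For each retained heterozygous SNP the two allele reactivity profiles are
compared by:

* eSDC = (1 - pCC) * sqrt(N), where pCC is the Pearson correlation of the
  two profiles over jointly non-missing bases and N the window length — the
  experimental structural disruption coefficient.  Larger eSDC means more
  allelic structure difference.
* a one-sided permutation P value: SNP-spanning reads are repeatedly
  reassigned to pseudo-alleles at an expected 1:1 ratio (pseudo-ref count
  drawn Poisson with mean R_d/2, truncated to the valid range), the full
  reactivity transform is recomputed per permutation, and P is the add-one
  tail probability of a null eSDC at least as large as observed.
* the composite AStruct score = -log10(P) * eSDC * (1 - log10(R_d / R)),
  where R_d / R is the fraction of window reads that span the SNP; shared
  non-spanning reads dilute allelic contrast, and the third factor (>= 1)
  compensates.
* per-base StrucDiff: the width-5 sliding mean of |ES_alt - ES_ref| centred
  on each base, with a per-base permutation P value reusing the same
  permutation replicates.

Scores group into Low (score = 0), Medium (0 < score <= 1) and
High (score > 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import (
    ARMS,
    AllelePartition,
    HetSNPObservation,
    SNPSite,
    SNPWindow,
)
from .errors import InsufficientDataError
from .reactivity import (
    ReactivityConfig,
    ReactivityProfile,
    count_stops_and_background,
    profile_from_counts,
)

GROUP_LOW = "Low"
GROUP_MEDIUM = "Medium"
GROUP_HIGH = "High"

STRUCDIFF_HALFWIDTH = 2  # +/- 2 neighbourhood, fixed divisor 5


@dataclass
class NullDistribution:
    """Permutation null of eSDC values."""

    esdc_values: np.ndarray
    n_perm: int
    seed: int | None = None
    n_degenerate: int = 0

    def __post_init__(self):
        if len(self.esdc_values) != self.n_perm:
            raise ValueError("null length != n_perm")


@dataclass
class ASRSCall:
    """Full per-SNP result."""

    site: SNPSite
    window: SNPWindow
    pcc: float
    esdc: float
    p_value: float
    astruct_score: float
    group: str
    r_d: int
    r_total: int
    ref_reads: int = 0
    alt_reads: int = 0
    degenerate: bool = False
    strucdiff: np.ndarray | None = None
    strucdiff_p: np.ndarray | None = None
    profile_ref: ReactivityProfile | None = None
    profile_alt: ReactivityProfile | None = None
    null: NullDistribution | None = field(default=None, repr=False)


def esdc(profile_ref: ReactivityProfile, profile_alt: ReactivityProfile) -> tuple[float, float]:
    """Pearson correlation and eSDC = (1 - pCC) * sqrt(N).

    Zero-variance profiles over the shared support make the correlation
    undefined; the call is then degenerate and eSDC is 0 (pcc returned NaN).
    """
    if profile_ref.window != profile_alt.window:
        raise ValueError("profiles computed over different windows")
    a = np.asarray(profile_ref.scores, dtype=float)
    b = np.asarray(profile_alt.scores, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} jointly non-missing bases (need >= 3)"
        )
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 0.0
    pcc = float(np.corrcoef(x, y)[0, 1])
    n = profile_ref.window.N
    return pcc, (1.0 - pcc) * math.sqrt(n)


def p_value(observed_esdc: float, null: NullDistribution) -> float:
    """Add-one one-sided permutation P: (1 + #{null >= obs}) / (1 + n_perm)."""
    if null.n_perm < 1:
        raise ValueError("empty null distribution")
    b = int(np.sum(np.asarray(null.esdc_values) >= observed_esdc))
    return (1 + b) / (1 + null.n_perm)


def astruct_score(p: float, esdc_value: float, r_d: int, r_total: int) -> float:
    """Composite score -log10(P) * eSDC * (1 - log10(R_d / R))."""
    if not (0 < p <= 1):
        raise ValueError("P must be in (0, 1]")
    if not (0 < r_d <= r_total):
        raise ValueError("require 0 < r_d <= r_total")
    return (-math.log10(p)) * esdc_value * (1.0 - math.log10(r_d / r_total))


def classify_group(score: float) -> str:
    """Low (0), Medium (0, 1], High (1, inf)."""
    if score < 0:
        raise ValueError("AStruct score cannot be negative")
    if score == 0:
        return GROUP_LOW
    if score <= 1:
        return GROUP_MEDIUM
    return GROUP_HIGH


def strucdiff_track(ref_scores: np.ndarray, alt_scores: np.ndarray) -> np.ndarray:
    """Width-5 sliding mean of |ES_alt - ES_ref|, NaN where the +/-2
    neighbourhood is incomplete or contains a missing base."""
    a = np.asarray(ref_scores, dtype=float)
    b = np.asarray(alt_scores, dtype=float)
    n = a.size
    w = 2 * STRUCDIFF_HALFWIDTH + 1
    out = np.full(n, np.nan)
    if n < w:
        return out
    d = np.abs(b - a)
    bad = np.isnan(d)  # any missing base in the window invalidates the mean
    badsum = np.convolve(bad.astype(float), np.ones(w), mode="valid")
    vals = np.convolve(np.where(bad, 0.0, d), np.ones(w), mode="valid") / w
    vals[badsum > 0] = np.nan
    out[STRUCDIFF_HALFWIDTH : n - STRUCDIFF_HALFWIDTH] = vals
    return out


def strucdiff(
    profile_ref: ReactivityProfile,
    profile_alt: ReactivityProfile,
    null_tracks: np.ndarray | None = None,
    n_perm: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-base StrucDiff and, given permutation tracks, add-one P values."""
    if profile_ref.window != profile_alt.window:
        raise ValueError("profiles computed over different windows")
    obs = strucdiff_track(profile_ref.scores, profile_alt.scores)
    if null_tracks is None:
        return obs, None
    null_tracks = np.asarray(null_tracks, dtype=float)
    m = null_tracks.shape[0] if n_perm is None else n_perm
    with np.errstate(invalid="ignore"):
        exceed = np.nansum(null_tracks >= obs[None, :], axis=0)
    pvals = (1.0 + exceed) / (1.0 + m)
    pvals[np.isnan(obs)] = np.nan
    return obs, pvals


# ---------------------------------------------------------------------------
# Permutation engine


class ProfilePairEngine:
    """Recomputes the full reactivity transform for arbitrary assignments of
    the SNP-spanning reads to two pseudo-alleles.

    Read geometry is frozen into arrays once; each evaluation only re-bins
    stop/background counts for the chosen assignment and reruns the scoring
    equations, so the observed call and every permutation go through exactly
    the same code path.
    """

    def __init__(self, window: SNPWindow, partition: AllelePartition, cfg: ReactivityConfig):
        self.window = window
        self.cfg = cfg
        self.n = window.N
        self.arm_spanning = {}
        self.obs_ref_mask = {}
        self.nonspan_counts = {}
        for arm in ARMS:
            ref = list(partition.ref_spanning[arm])
            alt = list(partition.alt_spanning[arm])
            reads = ref + alt
            stop_idx = np.array(
                [r.stop_pos - window.start for r in reads], dtype=np.int64
            ).reshape(-1)
            in_win = (stop_idx >= 0) & (stop_idx < self.n)
            blocks = [
                [
                    (max(bs, window.start) - window.start, min(be, window.end) - window.start)
                    for bs, be in r.blocks
                    if min(be, window.end) > max(bs, window.start)
                ]
                for r in reads
            ]
            self.arm_spanning[arm] = (stop_idx, in_win, blocks)
            self.obs_ref_mask[arm] = np.array(
                [True] * len(ref) + [False] * len(alt), dtype=bool
            )
            ns = count_stops_and_background(partition.nonspanning[arm], window)
            self.nonspan_counts[arm] = (ns.stops, ns.background)

    def n_spanning(self, arm: str) -> int:
        return self.arm_spanning[arm][0].size

    def _counts(self, arm: str, sel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        stop_idx, in_win, blocks = self.arm_spanning[arm]
        ns_stops, ns_bg = self.nonspan_counts[arm]
        use = sel & in_win
        stops = ns_stops + np.bincount(stop_idx[use], minlength=self.n).astype(float)
        delta = np.zeros(self.n + 1)
        for i in np.flatnonzero(sel):
            for lo, hi in blocks[i]:
                delta[lo] += 1
                delta[hi] -= 1
        bg = ns_bg + np.cumsum(delta[: self.n])
        return stops, bg

    def profiles(self, ref_mask: dict) -> tuple[ReactivityProfile, ReactivityProfile]:
        out = []
        for allele in ("ref", "alt"):
            stops_by_arm = {}
            bg_by_arm = {}
            for arm in ARMS:
                sel = ref_mask[arm] if allele == "ref" else ~ref_mask[arm]
                stops_by_arm[arm], bg_by_arm[arm] = self._counts(arm, sel)
            scores, degenerate = profile_from_counts(
                stops_by_arm["treated"], stops_by_arm["control"], bg_by_arm["control"], self.cfg
            )
            out.append(ReactivityProfile(self.window, scores, allele, degenerate))
        return out[0], out[1]

    def observed_profiles(self) -> tuple[ReactivityProfile, ReactivityProfile]:
        return self.profiles(self.obs_ref_mask)

    def random_assignment(self, rng: np.random.Generator, max_redraw: int = 100):
        """Poisson 1:1 pseudo-allele assignment of the spanning reads.

        The pseudo-ref and pseudo-alt read counts are modelled as
        independent Poisson variables with equal means; conditioning on the
        observed spanning-read total makes the pseudo-ref count
        Binomial(m, 1/2), i.e. each spanning read flips a fair coin.  This
        matches the sampling variance of a genuine 1:1 allele split, so the
        null is calibrated.  Assignments leaving either pseudo-allele with
        zero spanning reads overall are redrawn (up to ``max_redraw``);
        returns None if that fails, which the caller records as a
        degenerate (eSDC 0) permutation.
        """
        for _ in range(max_redraw):
            masks = {}
            n_ref_total = n_alt_total = 0
            for arm in ARMS:
                m = self.n_spanning(arm)
                mask = rng.random(m) < 0.5
                masks[arm] = mask
                n_ref_total += int(mask.sum())
                n_alt_total += m - int(mask.sum())
            if n_ref_total > 0 and n_alt_total > 0:
                return masks
        return None


def permutation_null(
    window: SNPWindow,
    partition: AllelePartition,
    cfg: ReactivityConfig | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    engine: ProfilePairEngine | None = None,
    collect_tracks: bool = False,
) -> tuple[NullDistribution, np.ndarray | None]:
    """Permutation null of eSDC (and optionally per-permutation StrucDiff
    tracks) by Poisson 1:1 reassignment of the SNP-spanning reads.

    Non-spanning reads stay shared; the reactivity transform is recomputed
    from raw counts in every permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or ReactivityConfig()
    if engine is None:
        engine = ProfilePairEngine(window, partition, cfg)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = np.zeros(n_perm)
    tracks = np.full((n_perm, window.N), np.nan) if collect_tracks else None
    n_degen = 0
    for k in range(n_perm):
        masks = engine.random_assignment(rng)
        if masks is None:
            n_degen += 1
            continue  # degenerate permutation recorded as eSDC 0
        pr, pa = engine.profiles(masks)
        try:
            _, e = esdc(pr, pa)
        except InsufficientDataError:
            n_degen += 1
            continue
        values[k] = e
        if collect_tracks:
            tracks[k] = strucdiff_track(pr.scores, pa.scores)
    null = NullDistribution(values, n_perm, n_degenerate=n_degen)
    return null, tracks


def call_site(
    obs: HetSNPObservation,
    window: SNPWindow,
    partition: AllelePartition,
    cfg: ReactivityConfig | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    per_base: bool = False,
) -> ASRSCall:
    """End-to-end per-SNP call: profiles, eSDC, permutation P, score, group
    and (optionally) the per-base StrucDiff track with P values."""
    cfg = cfg or ReactivityConfig()
    engine = ProfilePairEngine(window, partition, cfg)
    prof_ref, prof_alt = engine.observed_profiles()
    try:
        pcc, e = esdc(prof_ref, prof_alt)
    except InsufficientDataError:
        pcc, e = float("nan"), 0.0
    degenerate = math.isnan(pcc)
    if degenerate:
        # no usable correlation: conservative null call
        p = 1.0
        null = None
        tracks = None
    else:
        null, tracks = permutation_null(
            window, partition, cfg, n_perm, rng, engine=engine, collect_tracks=per_base
        )
        p = p_value(e, null)
    score = astruct_score(p, e, partition.r_d, partition.r_total)
    sd = sd_p = None
    if per_base:
        sd, sd_p = strucdiff(prof_ref, prof_alt, tracks, n_perm)
    return ASRSCall(
        site=obs.site,
        window=window,
        pcc=pcc,
        esdc=e,
        p_value=p,
        astruct_score=score,
        group=classify_group(score),
        r_d=partition.r_d,
        r_total=partition.r_total,
        ref_reads=obs.ref_reads,
        alt_reads=obs.alt_reads,
        degenerate=degenerate,
        strucdiff=sd,
        strucdiff_p=sd_p,
        profile_ref=prof_ref,
        profile_alt=prof_alt,
        null=null,
    )
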