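# Methods

## Input assumptions

`astruct call` consumes coordinate-sorted, indexed BAMs — replicate lists
for a treated (NAI-N3) arm and a control (DMSO) arm — plus a SNP list (VCF
or dbSNP-style 5-column TSV). Reads are assumed trimmed, aligned and
PCR-deduplicated upstream; an identical-read collapse utility exists but is
off by default. Replicates of an arm are pooled, which maximises coverage
under the coverage-hungry retention filter. Coordinates are 0-based
half-open internally; VCF input and tabular output positions are 1-based.

Read hygiene defaults: mapping quality ≥ 20 and base quality ≥ 13 at the
SNP base (both configurable; the published pipeline states no thresholds,
these are ordinary allele-counting practice). Spanning reads carrying a
third base or a deletion at the SNP are excluded from both allele sets but
still counted in the window read total R, since they contribute coverage
but no allele information. "Total reads" in the ≥ 10 filter means spanning
reads with a called allele (ref + alt), not raw window coverage — the
filter sits immediately downstream of the allele-coverage requirement and
is interpreted in those terms.

RT-stops are taken one base upstream of the alignment start in transcript
orientation, using each read's own alignment strand (reverse-strand reads
stop at their reference end). A stop falling outside the SNP window is not
counted: the window is the declared universe of the scoring equations.

## Reactivity scoring

Per allele, each arm's raw stop and background vectors over the window are
divided by their within-window 95th-percentile order statistic. Percentiles
use the nearest-rank convention (1-based sorted index ⌈q·N⌉): bracketed
index notation denotes an order statistic, and nearest rank is exactly
reproducible across platforms, unlike interpolated quantiles. A zero
normalizer (e.g. an all-zero stop vector) leaves the vector unchanged and
flags the profile degenerate rather than dividing by zero.

Enrichment is ES_i = (R_i^T − s·R_i^C) / B_i^C with s = 0.25 by default
(the background-subtraction factor of the icSHAPE-pipe lineage; it is
configurable and surfaced in every output header). Bases with zero raw
control coverage are missing (NaN) and stay missing through every
downstream statistic; the normalized denominator is additionally floored at
a tiny pseudocount (1e−6) so the division is always defined. Negative ES
values are preserved until the final unit scaling — the 5th-percentile
shift depends on the negative tail — and the scaling clamps into [0, 1],
with percentiles computed over non-missing bases only. If the 5th and 95th
percentiles coincide the profile is all-zero and flagged degenerate.

## Window statistics

eSDC = (1 − pCC)·√N uses the Pearson correlation over jointly non-missing
bases (≥ 3 required) and the full window length N. A zero-variance profile
makes the correlation undefined; the call is then degenerate: eSDC 0,
P 1, score 0, group Low — absence of usable signal is read as absence of
evidence for a difference.

The permutation null reassigns SNP-spanning reads (non-spanning reads stay
shared) and recomputes the entire scoring transform from raw counts per
permutation, through the same code path as the observed call. The
pseudo-allele counts are modelled as two independent Poisson variables with
equal means — a 1:1 ratio — conditioned on the observed spanning total,
which reduces to each read flipping a fair coin (Binomial(m, ½)). The
conditioning matters: an unconditioned Poisson count for one side has twice
the variance of a genuine 1:1 binomial split, which makes permuted profiles
noisier than observed ones and the null badly conservative (measured
P ≤ 0.05 rate ≈ 0.006 instead of 0.05). Permutations leaving a pseudo-allele
without any spanning read are redrawn (≤ 100 times, then recorded as a
degenerate eSDC of 0).

P is the add-one one-sided tail (1 + #{null ≥ observed}) / (1 + n_perm),
so P is never 0 and −log10 P is bounded (≈ 3.0 at the default 1000
permutations). The AStruct score −log10(P)·eSDC·(1 − log10(R_d/R)) is
therefore 0 exactly when P = 1 or eSDC = 0; its third factor is 1 when all
window reads span the SNP and grows with the non-spanning fraction, which
dilutes allelic contrast. Groups: Low = 0, Medium (0, 1], High (1, ∞).

StrucDiff_i averages |ES_alt − ES_ref| over bases i−2…i+2 with a fixed
divisor of 5; edge bases and any window containing a missing base are
reported missing rather than renormalized. Per-base P values reuse the
window-level permutation replicates (same add-one tail), for coherence and
speed. No multiple-testing correction is applied across SNPs; the raw P
and the composite score are the intended ranking quantities.

Determinism: each site's permutation stream is seeded from the master seed
and the site's rank in the sorted SNP list, so identical inputs and seed
give byte-identical outputs.

## Simulator

Each synthetic transcript (default 500 nt) carries one heterozygous SNP at
its midpoint and a paired/unpaired mask per allele drawn from a stochastic
stem-loop tiler (alternating 3–8 nt helix/loop segments, default unpaired
fraction 0.5) — externally computed dot-bracket structures can be supplied
instead, since downstream only the mask matters. Non-ASRS transcripts share
one mask between alleles; ASRS transcripts get an independently sampled alt
mask required to differ at ≥ 10 positions within ±50 nt of the SNP.

Reads (default 50 nt, a typical trimmed icSHAPE read length) are sampled
per transcript, arm and pseudo-replicate (two replicates per arm, matching
the usual two treated + two control design) with Poisson counts; each read
takes an allele with probability ½ and carries that allele's base at the
SNP. Control reads start uniformly. Treated reads carry the artificial
stop intervention with probability `stop_rate` (default 1.0): the read
starts one base 3′ of an unpaired base of its allele, chosen uniformly —
i.e. with equal probability per unpaired base. Two design points here are
deliberate:

* Sampling stop positions independently per read keeps reads exchangeable,
  which the permutation test requires. A balanced (round-robin) allocation
  of stops across unpaired bases was evaluated and rejected: it makes the
  two true allele profiles *more* similar than any random 1:1 split, so the
  null becomes conservative and P values pile up at 1.
* `stop_rate = 1.0` reflects the treated arm's read starts being defined by
  modification sites in this idealised design; lower rates mix in uniform
  (control-like) treated reads and weaken the benchmark signal accordingly.

Depth tiers are mean reads per transcript per arm, a desk-scale stand-in
for genome-wide sequencing depth: 10M reads per dataset spread over roughly
2×10⁴ expressed transcripts and two arms is ~250 expected reads per
transcript per arm, which is the default lowest tier (250, 500, 1000). At
tier 250 a retained site typically has ~50 spanning reads — just above the
retention filter, the regime a shallow genome-wide run produces. This is a
scaling argument, not a reproduction of genome-scale runs.

The simulator writes a real reference FASTA, VCF and coordinate-sorted,
indexed BAMs so the entire alignment-facing path is exercised, plus a truth
manifest. One master seed; per-(tier, transcript) child RNGs are derived
with `SeedSequence` spawn keys so any transcript is re-simulable alone.

What the simulator does *not* emulate: sequencing errors, adapters, PCR
duplication, splicing, reverse-strand alignments, expression-level
variation between transcripts, or allelic imbalance in expression. Passing
benchmarks therefore demonstrate the statistical machinery under idealised
read generation, not robustness to those real-data artefacts.

## Benchmark behaviour

With the defaults above (300 transcripts, half ASRS, 200 permutations) the
ROC AUC of the AStruct score is ≈ 0.74–0.77 at tier 250 and rises with
depth (≈ 0.88 at 500, ≈ 0.98 at 1000 in the acceptance suite's fixed-seed
run); on all-null datasets the P ≤ 0.05 rate sits near the nominal 0.05.
Problem sizes in the test suite (300–320 transcripts, 200 permutations,
tiers up to 1000) were chosen to keep Monte-Carlo error on these quantities
small relative to the margins being asserted.

## Known limitations

* The minus-strand convention (which base is "upstream" of a read start)
  follows each read's alignment strand; libraries with non-standard
  strandedness need the inputs oriented accordingly.
* Only biallelic SNVs are considered; indels and multi-allelic records are
  skipped at load time.
* The permutation count bounds the smallest attainable P (add-one
  estimator), so score ceilings grow with `--n-perm`.
* The output's `bh_fdr` column (Benjamini-Hochberg across the retained
  SNPs of the run) is a convenience beyond the published method, whose
  ranking quantities are the raw P and the composite score.
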