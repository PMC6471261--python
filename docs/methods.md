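# Methods

This note records the models, rules and numerical choices behind each
pipeline stage, what the synthetic data emulates, and the known
limitations.

## Read cleaning

Reads are filtered by a fixed cascade; each read is accounted to exactly
one outcome, so per-library rejection counts plus the clean count equal
the raw count exactly.  Order: (1) more than one base at Q ≤ 20
(inclusive threshold); (2) any N; (3) 3′ adapter absent; (4) 5′ adapter
present in the insert; (5) empty insert; (6) polyA insert; (7) insert
< 18 nt; (8) insert > 30 nt (the library protocol size-selects
18–30 nt).  Adapter location is an exact-match search for the first
occurrence of the adapter's leading 8-mer — no mismatch is tolerated, so
the preprocess stage is fully deterministic.  "PolyA" is defined as
≥ 80 % A over the insert or a 3′-terminal run of ≥ 10 A; the polyA rule
is applied to the trimmed insert, after adapter removal.  Only
Phred+33 FASTQ is accepted; quality characters implying Phred+64 are a
parse error rather than a guess.

## Tag classification

Removal order: other ncRNA (exact substring of the rRNA/tRNA/sn(o)RNA
reference) → repeat-like tags (> 10 distinct transcriptome loci) →
transcriptome-mapped tags → mature-reference search → unannotated.  For
a transcriptome-mapped tag the mature-miRNA search takes precedence;
tags that map but neither match a mature reference nor pass the hairpin
screen are classed as mRNA degradation fragments.  The mature search
allows ≤ 2 mismatches, no indels, and ±2 nt at either end — standard
mature-reference search tolerance; ties go to the alphabetically first
reference id.

The hairpin screen excises two windows around the mapped tag,
[start−20, end+150) and [start−150, end+20), folds each with a
maximum-weight nested-pairing dynamic program (pair weights GC = 3,
AU = 2, G:U = 1; minimum hairpin loop 3; score = −total weight), and
accepts the candidate when, in the better window, the tag (i) pairs
only to one side (one arm), (ii) has ≥ 14 bases paired, (iii) ≤ 4 bases
in bulges/loops, and (iv) the window folding score is ≤ −18.  These
thresholds are fixture-calibrated screening constants of this package,
not a reimplementation of any published precursor caller.  The fold
traceback is deterministic (pairing preferred, then left-end deletion,
then leftmost bifurcation), so equal-score structures resolve
identically on every run.  Window length is capped at 320 nt; the fold
routine itself accepts any sequence up to that cap (short inputs are
used directly by the brute-force equivalence tests).

## Quantification

TPM = count / (total clean tags in the library) × 10⁶.  The denominator
is the library's total clean-tag count over all categories — the
literal reading of the formula — not the miRNA-mapped subtotal.  A tag
matching several mature references equally is assigned to the
alphabetically first id and the event is logged.  Consequently Σ TPM
over all tags equals 10⁶ exactly only when every clean tag is a counted
miRNA; this identity is used as a unit-test invariant.

## Exact count test

For counts x, y in libraries of N₁, N₂ total clean tags, y | x follows
the negative-binomial mass p(x|y) = (N₂/N₁)ʸ (x+y)!/(x! y!
(1+N₂/N₁)^(x+y+1)) (r = x+1, success probability N₂/(N₁+N₂)).  The
implementation evaluates the published formula in log space via
log-gamma.  Both tails are summed directly — the upper tail is never
formed as 1 − C, which would lose all precision deep in the tail — and
the two-sided p is 2·min(C, D) capped at 1, with values within 10⁻¹² of
1 reported as exactly 1.  Two idealized properties fail for this
construction and are deliberately not asserted: the statistic
conditions on x, so it is not invariant under swapping (x, N₁) with
(y, N₂) (the pointwise masses differ by exactly N₁/N₂); and p is
monotone in |y − x·N₂/N₁| only away from the discrete distribution
center.  Replicates are summed within group before the two-library
statistic; fold change is computed on mean TPM with a 0.01-TPM
pseudocount on both sides; a DEM requires |log₂FC| ≥ 1 and p < 0.05
(raw, no multiple-testing correction — correction is applied only in
the enrichment stage).

## Temporal profiles

Candidate profiles are all (2c+1)³ integer-step shape vectors of length
4 starting at 0 with |Δ| ≤ c; defaults c = 2, k = 20 representatives
chosen by greedy maximin Euclidean distance starting from the flat
profile (ties to the lexicographically smallest shape).  Expression is
transformed to log₂(TPM_t / TPM_CK) with a 0.01 pseudocount; genes are
assigned to the profile maximizing Pearson correlation (zero-variance
vectors to the flat profile by convention; ties to the smaller id).
Significance: each permutation round independently permutes every
gene's four timepoint values, re-anchors at the first value, and
reassigns; the raw p is the plus-one-corrected fraction of rounds with
a profile count ≥ observed, multiplied by a Bonferroni factor equal to
the number of profiles — the correction this clustering procedure
conventionally applies, and without which a structureless input would
flag spurious profiles roughly a third of the time at α = 0.02.  The
corrected-p resolution floor is k/(n_perm+1); the default 10,000
permutations resolve p = 0.002.

## Target prediction

A site is an ungapped duplex of a miRNA (5′→3′) with an equal-length
mRNA window read in complementary orientation (miRNA position 1 pairs
the window's 3′ base).  G:U wobble counts 0.5 mismatch.  Rules, checked
in order with the first violation reported:

1. total score ≤ 4, and no two adjacent positions whose weights sum
   above 1.5 — i.e. no adjacent full mismatches anywhere;
2. in positions 2–12: no two adjacent non-Watson–Crick positions, and
   positions 10–11 perfectly paired (G:U also disallowed there);
3. score over positions 1–12 ≤ 2.5;
4. |E_dup| / |E_perf| ≥ 0.74.

The energy model is an explicit additive surrogate — GC −3, AU −2,
G:U −1, mismatch 0 with a +1 penalty per maximal mismatch run — chosen
for determinism and the monotonicity the ratio criterion needs (every
degradation of a paired position raises E_dup).  It is not a
nearest-neighbour thermodynamic model; `scan_transcriptome` accepts an
`energy_fn` hook for swapping in an external folding engine.  Scanning
is on the transcript sense strand only (the miRNA binds the mRNA), with
U and T equivalent; per (miRNA, gene) the best site is kept (lowest
mismatch score, then lowest E_dup, then leftmost).  Pearson correlation
(not Spearman) with the t-transform p-value, t = r√(n−2)/√(1−r²) at
n = 8, is used for the anti-correlation criterion r < −0.50, p ≤ 0.05 —
note that at n = 8 the p-condition effectively tightens the cutoff to
r < −0.707.

## Enrichment

Hypergeometric upper tail with log-space binomial coefficients, summed
from m upward (numerically the stable side of the printed 1 − Σ_{i<m}
form, identical in exact arithmetic).  The universe N is the annotated
universe; unannotated target genes are excluded from n and logged.
Q-values are Benjamini–Hochberg across the tested terms of a
comparison.  Report cells are "m (percentage%)" with percentage =
100·m/n, round-half-even to two decimals with trailing zeros trimmed
("11.01", "5.6", "12"); m = 0 renders as a bare "0".  GO terms are a
flat table (no DAG propagation), with a namespace column.

## qPCR validation

ΔCt = mean Ct(target) − mean Ct(U6) within a condition; ΔΔCt =
ΔCt(treatment) − ΔCt(control); fold = 2^−ΔΔCt.  The replicate spread is
the SD of per-replicate ΔCt values in the treatment condition, shown on
the fold scale as the 2^−(ΔΔCt±SD) range.  Replicate means are plain
arithmetic means with no outlier handling and no amplification-
efficiency correction.  Because the scaling that would put qPCR and
sequencing magnitudes on one axis is not defined, concordance is scored
on direction only (fold > 1 vs log₂FC > 0).

## Synthetic data

The generator emulates the study design: 4 timepoints × 2 replicates,
planted known miRNAs (present in the mature reference), novel miRNAs
whose perfect-inverted-repeat precursors are spliced into transcripts,
other-ncRNA fragments, mRNA degradation fragments, unannotated tags,
and contaminant reads (low-quality, N-containing, adapter-less,
5′-adapter, polyA, short-insert) at fixed per-library rates.  Counts
are negative binomial with dispersion 0.1 around the expected TPM —
deliberately noisier than the Poisson-like sampling the exact test
assumes, as a robustness stress.  Planted fold-change classes are up4x
/ down4x / null (4-fold at every treated timepoint); the down-class
baselines are scaled so the expected total tag mass is identical in
every library — without this mass balance, TPM compositionality gives
every "null" miRNA a systematic fold change and a null-error bound is
meaningless.  Anti-correlated pairs are planted as mRNA = a − b·(miRNA
TPM) + noise with the noise SD calibrated so the population correlation
is r_true = −0.9; at n = 8 the sample r then clears the −0.5/−0.707
thresholds for ≈ 90 % of pairs, which is why the recovery criterion is
stated at 80 %.  Half of the planted pass-sites carry one G:U wobble at
miRNA position 5; fail-sites are constructed per rule class (adjacent
mismatches at 18–19; mismatch at 10; mismatches at 2, 4, 6; an A/U-rich
miRNA with four broken pairs for the energy-ratio class) and the
construction is verified against the rule checker at test time.

Shipped study conditions: 60 expressed known miRNAs (500 at the
parameter-recovery scale), 12 novel, 150–200 transcripts, depth
5×10⁴–10⁵ clean reads per library, 24 pass-sites / 8 fail-sites / 16
anti-correlated pairs, 15 pathway terms of which 2 concentrate the
planted target genes.  These sizes keep a complete end-to-end run
around half a minute on one CPU while leaving every recovery metric
far from its decision boundary.

What passing on synthetic data does **not** show: real small-RNA
libraries have sequencing errors inside inserts, isomiR end-variation,
ligation bias, multi-locus miRNA families with shared seeds, and
transcriptome mis-assembly — none of which are simulated.  Recovery
rates here validate the implementation, not the biological error rates
of the method on real data.

### Truth-evaluation metrics

`truth_eval` scores a run against truth.json: recall of planted known /
novel miRNAs, false known-miRNA calls on ncRNA fragments, DEM recall
and null type-I error (CK vs T1), target-site verdict precision and
recall over the planted sites, the planted anti-correlation flag rate,
the worst enrichment P over the planted terms, and exact read
conservation.  Verdict precision is computed over the planted site set
(pass-sites recovered vs fail-sites leaked); chance background sites
that genuinely satisfy rules (1)–(4) in random sequence are tallied
separately (`target_background_pairs`) because an independent literal
evaluation agrees they pass — they measure the rule set's background
rate, not an implementation error.

## Known limitations

* The hairpin screen is a screening surrogate; it does not model
  star-strand read support, Dicer-processing precision, or genomic
  (vs transcriptome) precursor context.
* The duplex energy model is additive; thermodynamically marginal sites
  near the 0.74 ratio boundary may be classified differently than a
  nearest-neighbour model would.
* The exact count test assumes Poisson-like sampling; with biological
  overdispersion its raw p-values are anti-conservative, which the
  fold-change gate only partly offsets (visible as the few-percent null
  call rate on the NB-dispersed synthetic data).
* Profile identity is by shape, not by any external tool's numbering.
* GO annotation is flat; no ontology topology is used.
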