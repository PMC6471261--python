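# mejamir

Small-RNA regulatory analysis of a methyl-jasmonate (MeJA) elicitation
time course, packaged as a tested, reusable pipeline.

MeJA is a jasmonate phytohormone that elicits plant secondary
metabolism.  In the motivating experimental design, leaves are sampled
at four timepoints — CK (0 h, control), T1 (24 h), T2 (36 h), T3 (48 h)
— with two biological replicates each, and eight small-RNA libraries are
sequenced alongside a matching mRNA expression matrix.  `mejamir`
implements the complete downstream analysis:

1. **Read cleaning** — quality/N filtering, 3′-adapter location,
   5′-adapter and polyA removal, 18–30 nt size selection; identical
   inserts collapse to unique *clean tags* with per-library counts.
2. **Tag classification** — other ncRNA (rRNA/tRNA/sn(o)RNA) removal,
   repeat exclusion, known-miRNA identification against a mature
   reference, and a hairpin screen that calls novel miRNA candidates
   from transcriptome context.
3. **Quantification** — tags per million, `TPM = count / total clean
   tags × 10⁶`, plus family presence/abundance tables.
4. **Differential expression** — the exact two-library count statistic

       p(x|y) = (N₂/N₁)ʸ (x+y)! / ( x! y! (1 + N₂/N₁)^(x+y+1) )

   with two-sided p = 2·min(C, D) from the lower/upper tail sums; a
   miRNA is a DEM at fold change ≥ 2 (on TPM) and p < 0.05.
5. **Temporal profiles** — assignment of DEM log₂-ratio trajectories to
   a catalogue of integer-step model profiles with permutation
   significance (p ≤ 0.02, corrected across profiles).
6. **Target prediction** — plant-style complementarity rules (≤ 4
   mismatches with G:U = 0.5, adjacency and seed-region restrictions,
   no mismatch at positions 10–11, duplex/perfect energy ratio ≥ 0.74)
   scanned over the transcriptome.
7. **Anti-correlation pairing** — Pearson r of miRNA TPM vs target mRNA
   expression across the 8 samples; a pair qualifies at r < −0.50 and
   p ≤ 0.05.
8. **Enrichment** — hypergeometric upper-tail
   `P = 1 − Σᵢ₌₀^{m−1} C(M,i)·C(N−M,n−i)/C(N,n)` per pathway/GO term
   with Benjamini–Hochberg Q-values and "m (percentage%)" report cells.
9. **qPCR validation** — 2^−ΔΔCt relative expression against a U6
   reference and direction concordance with the sequencing fold changes.

A truth-tracked synthetic data generator (`mejamir.synthetic_data`)
produces complete input bundles — FASTQ libraries with planted miRNAs,
contaminants, hairpin precursors, target sites, anti-correlated pairs
and enriched pathways — so the whole pipeline runs and is validated
without any external downloads.

## Worked example

```bash
mejamir simulate --seed 2 --out bundle --depth 5000 --mirnas 30
mejamir run -i bundle -o run1
mejamir evaluate --run run1 --truth bundle/truth.json
```

prints (abridged):

```
bundle written to bundle (truth.json included)
run complete: run1/manifest.json
{
 "anticorr_flag_rate": 1.0,
 "conservation_ok": 1.0,
 "dem_recall": 0.9523809523809523,
 "dem_type1": 0.045454545454545456,
 ...
}
```

meaning: every planted anti-correlated miRNA–mRNA pair was flagged at
the r < −0.50, p ≤ 0.05 thresholds; read accounting balanced exactly in
all eight libraries; 95 % of the miRNAs planted at a 4-fold change were
recovered as DEMs; and 4.5 % of the planted null miRNAs were falsely
called at p < 0.05.  The run directory contains the stage outputs
(`clean_tags.fa`, `mirna_counts.tsv`, `dem_<A>_vs_<B>.tsv`,
`targets.tsv`, `pairs.tsv`, `enrichment_<A>_vs_<B>.tsv`,
`stem_profiles.tsv`, `qpcr_folds.tsv`) and a `manifest.json` whose
checksums are byte-identical across reruns with the same seed.

Per-stage subcommands (`preprocess`, `annotate`, `quantify`, `de`,
`stem`, `targets`, `enrich`, `qpcr`) compose with files from earlier
runs; the library API mirrors the same operations for programmatic use.

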