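# cnvsd

Copy-number variants (CNVs) — deletions and duplications of genomic
segments — shape gene content in crop genomes, and segmental duplications
(SDs, high-complexity low-copy repeats ≥ 1 kb at ≥ 90% identity) are the
prime suspects for where CNVs form, via non-allelic homologous
recombination between near-identical copies. `cnvsd` is a Python library
for the complete analysis chain that tests this hypothesis on an
exome-sequenced accession panel (the motivating system is a barley
diversity panel of cultivars, landraces and wild relatives):

- **CNV calling from exome read counts.** For each test sample an
  *optimized reference set* is aggregated from the most correlated panel
  members; the test count at capture target *j* is modelled as
  beta-binomial, `x_j ~ BetaBin(n_j = x_j + r_j, p_j(c), φ)` with
  `p_j(c) = cμ / (cμ + 1 − μ)` for copy ratio `c ∈ {0.5, 1, 1.5}`, and a
  3-state HMM (DEL/DIP/DUP, transition probability `t = 1e-4`, CNV-state
  persistence `exp(−d/L)` over inter-target distance `d`) is decoded by
  Viterbi. Runs of a non-diploid state become calls; calls seen in fewer
  than 3 accessions are discarded and the rest are collapsed into CNV
  *sites* with carrier frequencies.
- **Panel summaries.** Deletion/duplication densities per Mb of captured
  sequence, exact conditional two-sample Poisson tests between chromosome
  rates, group-wise (wild/landrace/cultivar) densities with bootstrap
  intervals, and carrier-frequency spectra.
- **CNV phylogeny.** Binary site genotypes → Euclidean distances →
  neighbor joining (Saitou–Nei; exact on additive matrices) → Newick.
- **SD discovery.** Hard-mask annotated repeats, split the genome into
  250-kb chunks, self-align (exact 31-mer seeds, diagonal chaining, X-drop
  extension, edit-distance identity), keep hits ≥ 1 kb and ≥ 95% identity,
  drop self-hits, merge into SD regions. Precomputed blast `-outfmt 6`
  alignments can be ingested instead of the internal aligner.
- **Association statistics.** Permutation tests (features randomized over
  the non-masked space of each chromosome; empirical p with the add-one
  rule) for SD–gene and SD–CNV overlap/distance, and the Spearman profile
  of per-bin SD vs CNV counts across bin sizes 40 kb – 2 Mb.
- **GO enrichment.** One-sided Fisher (hypergeometric upper tail), the
  *elim* decorrelation over the term DAG, Benjamini–Hochberg FDR, and the
  wild-exclusive differential contrast.
- **Synthetic data.** A generator for genomes (repeats, SD pairs of 1–10 kb
  at 95–99% identity, multi-exon genes whose exons are the capture
  targets) and panels (planted CNVs, deletions ~4× duplications,
  rare-dominated carrier frequencies, ~40× depth with a below-5× tail,
  optional SD-biased CNV placement) with full ground truth, so every stage
  is testable without external downloads.

## Worked example

`examples/01_simulate_and_call_cnvs.py` simulates a 60-accession panel on a
4-Mb genome and runs the caller end to end:

```
panel: 60 samples x 2415 capture targets
coverage filter (5x): kept 2120 targets (295 removed)
caller: 315 per-sample CNV calls (238 DEL / 77 DUP)
panel filter (>= 3 accessions): 44 CNV sites
site-level recall vs planted truth (>= 3 carriers): 0.97 (40 truth sites)
```

295 poorly captured targets fall below the 5× panel-mean depth filter; the
caller then finds 315 per-sample events, three-quarters of them deletions
(the planted deletion:duplication ratio is ~3.8:1), which collapse to 44
recurrent sites; 97% of the planted recurrent sites are rediscovered.

`examples/05_sd_cnv_association.py` shows the SD–CNV co-occurrence
analysis on a 32-Mb genome with SD-biased CNV placement:

```
permutation test (SD features randomized over non-masked space):
  observed SD/CNV overlaps: 121
  null mean 53.9, null max 72
  p = 0.0050, z = 6.2

Spearman rho between binned SD and CNV counts:
 bin_size   rho  ...
    40000 0.366  ...
  1500000 0.819  ...
  2000000 0.896  ...
```

The observed overlap count exceeds the most extreme of 199 random
placements, and the rank correlation between binned SD and CNV densities
climbs with bin size, clearing 0.7 from 1.5-Mb bins — the signature of
CNVs accumulating in SD-rich regions.

The remaining examples cover panel summaries (`02`), the CNV phylogeny
(`03`), SD detection (`04`) and GO enrichment (`06`). A thin CLI wraps the
same entry points (`cnvsd simulate | call-cnv | summarize | phylogeny |
detect-sd | associate | sd-cnv-profile | enrich`).

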