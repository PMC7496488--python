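"""Association between segmental duplications and CNV placement.

Simulates a panel whose CNV sites are preferentially placed in SD-rich
100-kb windows (enrichment weight beta = 100), then quantifies the
association two ways, exactly as a genome analysis would:

1. a permutation test — SD features are randomized 199 times over the
   non-masked space of each chromosome and the observed SD/CNV overlap
   count is compared with the null;
2. the Spearman profile — rank correlation between per-bin SD and CNV
   counts as the bin size grows from 40 kb to 2 Mb.
"""

from cnvsd.association import permutation_test, sd_cnv_profile
from cnvsd.intervals import IntervalSet, complement_intervals
from cnvsd.simulate import (
    SimGenomeParams,
    SimPanelParams,
    simulate_genome,
    simulate_panel_counts,
)

genome = simulate_genome(
    SimGenomeParams(n_chroms=4, chrom_length=8_000_000, n_genes=1600,
                    n_sd_pairs=100, repeat_fraction=0.15,
                    gene_sd_overlap_fraction=0.0, seed=9)
)
lengths = {c: len(s) for c, s in genome.seqs.items()}
_, truth = simulate_panel_counts(
    genome, SimPanelParams(n_samples=20, n_cnv_sites=500, sd_enrichment=100.0, seed=700)
)
sd_features = genome.sd_footprint()
cnv_sites = IntervalSet(truth.sites[["chrom", "start", "end"]])
space = complement_intervals(genome.repeats, lengths)

res = permutation_test(sd_features, cnv_sites, space, n_permutations=199, seed=1)
print("permutation test (SD features randomized over non-masked space):")
print(f"  observed SD/CNV overlaps: {res.observed:.0f}")
print(f"  null mean {res.null_mean:.1f}, null max {res.null_high:.0f}")
print(f"  p = {res.p_value:.4f}, z = {res.z_score:.1f}")
# observed overlaps far exceed the most extreme of 199 random placements

profile = sd_cnv_profile(sd_features, cnv_sites, lengths, alpha=0.001)
print("\nSpearman rho between binned SD and CNV counts:")
print(profile.round(3).to_string(index=False))
# rho rises with bin size and clears 0.7 at >= 1.5 Mb: SD-rich regions are
# where CNVs accumulate, visible once bins are coarse enough to smooth
# placement noise
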