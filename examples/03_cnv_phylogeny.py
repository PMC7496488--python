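"""Accession phylogeny from CNV genotypes.

Simulates a 24-accession panel in which half of the planted CNV sites are
private to one of three groups (wild / landrace / cultivar), encodes
presence/absence genotypes, computes Euclidean distances and builds a
neighbor-joining tree. Groups with distinct CNV repertoires come out as
clean clades, as population structure should.
"""

from cnvsd.phylogeny import (
    euclidean_distances,
    genotype_matrix,
    neighbor_joining,
    write_newick,
)
from cnvsd.simulate import (
    SimGenomeParams,
    SimPanelParams,
    simulate_genome,
    simulate_panel_counts,
)

genome = simulate_genome(
    SimGenomeParams(n_chroms=2, chrom_length=500_000, n_genes=80, n_sd_pairs=8,
                    repeat_fraction=0.2, seed=11)
)
_, truth = simulate_panel_counts(
    genome,
    SimPanelParams(
        n_samples=24, n_cnv_sites=60, group_private_fraction=0.5,
        group_proportions={"wild": 1 / 3, "landrace": 1 / 3, "cultivar": 1 / 3},
        seed=901,
    ),
)

m = genotype_matrix(truth.sites, list(truth.groups.index))
print(f"genotype matrix: {m.shape[0]} accessions x {m.shape[1]} CNV sites")
d = euclidean_distances(m)
print(f"mean within-group distance:  "
      f"{d.to_numpy()[:8, :8][d.to_numpy()[:8, :8] > 0].mean():.2f}")
print(f"mean between-group distance: {d.to_numpy()[:8, 8:16].mean():.2f}")
# between-group distances exceed within-group ones, so NJ separates groups

tree = neighbor_joining(d)
newick = write_newick(tree)
print("\nNewick (truncated):", newick[:120], "...")
for group in ("wild", "landrace", "cultivar"):
    tips = set(truth.groups.index[truth.groups == group])
    clades = [
        frozenset(t.name for t in node.tips())
        for node in tree.non_tips(include_self=False)
    ]
    mono = frozenset(tips) in clades or frozenset(set(truth.groups.index) - tips) in clades
    print(f"{group:10s} monophyletic: {mono}")
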