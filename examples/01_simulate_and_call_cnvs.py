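"""Simulate an exome-capture panel and call CNVs from read counts.

Builds a 2 x 2 Mb genome with genes, repeats and segmental duplications,
draws fragment counts for a 60-accession panel with 80 planted CNV sites at
~40x depth, then runs the full caller: coverage filter, per-sample
optimized reference sets, beta-binomial HMM, Viterbi segmentation. Prints
recovery statistics against the planted truth.
"""

import numpy as np

from cnvsd.calling import call_cnvs_panel, filter_low_coverage_targets
from cnvsd.simulate import (
    SimGenomeParams,
    SimPanelParams,
    simulate_genome,
    simulate_panel_counts,
)
from cnvsd.summary import filter_rare_calls

genome = simulate_genome(SimGenomeParams(seed=1))
cm, truth = simulate_panel_counts(
    genome, SimPanelParams(n_samples=60, n_cnv_sites=80, seed=2)
)
print(f"panel: {len(cm.samples)} samples x {cm.n_targets} capture targets")

cm_filtered = filter_low_coverage_targets(cm).sorted_by_position()
print(
    f"coverage filter (5x): kept {cm_filtered.n_targets} targets "
    f"({cm.n_targets - cm_filtered.n_targets} removed)"
)

calls = call_cnvs_panel(cm_filtered)
print(f"caller: {len(calls)} per-sample CNV calls "
      f"({(calls['type'] == 'DEL').sum()} DEL / {(calls['type'] == 'DUP').sum()} DUP)")

kept_calls, sites = filter_rare_calls(calls, panel_size=60, min_accessions=3)
print(f"panel filter (>= 3 accessions): {len(sites)} CNV sites")

# compare detected sites with the planted truth
def hits(df, chrom, start, end, types):
    sub = df[(df["chrom"] == chrom) & (df["type"].isin(types))]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())

truth_common = truth.sites[truth.sites["n_carriers"] >= 3]
recall = np.mean(
    [hits(sites, r.chrom, r.start, r.end, {r.type}) for r in truth_common.itertuples()]
)
print(
    f"site-level recall vs planted truth (>= 3 carriers): {recall:.2f} "
    f"({len(truth_common)} truth sites)"
)
# recall ~0.9+: nearly every recurrent planted site is rediscovered as a
# same-type site; the residual misses are common variants whose carriers
# contaminate every available reference set.
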