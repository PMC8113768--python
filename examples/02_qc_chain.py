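"""The QC chain: marker filters, sample filters, PIHAT relatedness, LD pruning.

Simulates a small masked dataset, then runs the fixed filter order
(markers -> samples -> relatedness -> LD) and prints the count reduction at
every stage, the way array-QC reports tabulate their arithmetic.
"""

import numpy as np

from ehhscan import qc, simulate as sim
from ehhscan.bookkeeping import CountLedger

# Note on the relatedness step: PIHAT is designed for genome-wide data.  On a
# single 5-Mb chromosome the markers form one LD block, so per-pair estimates
# are noisy and many unrelated pairs cross the 0.15 cutoff — the pruning below
# is therefore much more aggressive than it would be on 30 chromosomes.
# n_templates widens the founder base relative to the default narrow bottleneck.
cfg = sim.neutral_preset(
    seed=2, n_markers=1000, chrom_length_bp=5_000_000, n1=300, n2=300,
    n_founder_haps=1200, n_templates=80, g0=10, g1=10, n_sample1=30, n_sample2=30,
    mask_rate=0.02,  # 2% missing genotype calls
)
p1, p2, _ = sim.simulate_dataset(cfg)
g = sim.combined_genotypes(p1, p2, cfg)
ledger = CountLedger()

g1, report = qc.filter_markers(g, maf_min=0.01, call_rate_min=0.95)
ledger.record("marker_filters", "markers", g.n_markers, n_out=g1.n_markers)

g2 = qc.filter_samples(g1, max_missing=0.05)
ledger.record("sample_missingness", "samples", g1.n_samples, n_out=g2.n_samples)

kept = []
for pop in np.unique(g2.population_labels):
    sub = g2.subset_samples(np.flatnonzero(g2.population_labels == pop))
    rel = qc.pihat_matrix(sub)  # method-of-moments IBD within each population
    kept += qc.prune_related(rel, pihat_max=0.15)
g3 = g2.subset_samples(np.flatnonzero([s in set(kept) for s in g2.sample_ids]))
ledger.record("relatedness", "samples", g2.n_samples, n_out=g3.n_samples)

pruned = qc.ld_prune(g3, window=50, step=5, r2_max=0.5)
ledger.record("ld_prune", "markers", g3.n_markers, n_out=len(pruned))

print(ledger.to_frame().to_string(index=False))
# each row is one filter stage; n_in - n_removed = n_out is checked at record
# time, so the whole data reduction is auditable
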