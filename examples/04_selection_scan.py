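"""The full selection scan: polarize, iHS, Rsb/XP-EHH, regions, intersection.

Simulates the default sweep scenario, polarizes the test-population panel
against simulated outgroup species, computes all three EHH statistics, calls
candidate regions with the sliding-window rules (2 Mb / 20 kb / >= 3
significant SNPs for iHS; 1 Mb / 10 kb / >= 4 for Rsb and XP-EHH at
-log10 p >= 2.5), and intersects them across methods.
"""

import numpy as np

from ehhscan import ehh, polarize as pol, regions as reg, simulate as sim

cfg = sim.sweep_preset(seed=1)
pop1, pop2, truth = sim.simulate_dataset(cfg)
focal_pos = truth.markers.pos_bp[truth.focal_index]
print(f"true sweep at {truth.focal_marker} ({focal_pos/1e6:.2f} Mb), s = {truth.s}")

# --- iHS within the test population (needs ancestral/derived polarization)
outgroups = sim.emit_outgroups(truth, cfg)
calls = pol.infer_ancestral(pop1.markers, outgroups)
print(f"ancestral state resolved for {calls.n_resolved} markers ({calls.n_unresolved} unresolved, dropped)")
polarized = pol.polarize_panel(pop1, calls)
ihs = ehh.ihs_scores(polarized)

# --- Rsb and XP-EHH between test and reference (shared iES computation)
both = ehh.crosspop_scores_both(pop1, pop2)
rsb, xpehh = both["rsb"], both["xpehh"]

per_method = {
    "iHS": reg.call_regions(ihs, "iHS"),
    "Rsb": reg.call_regions(rsb, "Rsb"),
    "XP-EHH": reg.call_regions(xpehh, "XP-EHH"),
}
for name, tab in (("iHS", ihs), ("Rsb", rsb), ("XP-EHH", xpehh)):
    ok = tab[tab.status == "ok"]
    n_sig = int((ok.pscore >= 2.5).sum())
    print(
        f"{name}: {len(ok)} markers scored, {n_sig} significant at -log10 p >= 2.5, "
        f"{len(per_method[name])} candidate region(s)"
    )

joint, _ = reg.intersect_regions(per_method)
print(f"{len(joint)} region(s) supported by >= 2 methods:")
for r in joint:
    contains = "contains" if r.start <= focal_pos <= r.end else "misses"
    print(
        f"  chr{r.chrom}:{r.start/1e6:.2f}-{r.end/1e6:.2f} Mb "
        f"({r.span_mb:.2f} Mb, {sorted(r.methods)}) -- {contains} the true focal marker"
    )
# a joint region containing the focal marker is the scan working end to end:
# the sweep elongated haplotype homozygosity in pop1 enough for at least two
# statistics to flag the same interval
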