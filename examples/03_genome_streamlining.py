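"""Measure ancestral-duplicate loss asymmetry between two sister genomes.

Runs the complete chain (hits -> MCL families -> nearest paralogs -> dN/dS
-> ortholog-anchored speciation threshold -> loss rates) on a simulated
world with a planted 2x loss-rate difference, then tests the resulting 2x2
loss table with a chi-square, exactly as one compares observed lineages.
"""

from dupdyn.enrichment_stats import ContingencyTable2x2, chi2_2x2
from dupdyn.paralog_pipeline import duplicate_history_analysis
from dupdyn.synthetic_data import TwoSpeciesConfig, simulate_hits, simulate_two_species_world

cfg = TwoSpeciesConfig()  # loss 0.9 vs 0.45 per copy per unit time
world = simulate_two_species_world(cfg, seed=31)
hits = simulate_hits(world.proteins)
res = duplicate_history_analysis(
    world.proteins, world.coding, hits, cfg.species_a, cfg.species_b
)

loss = res["loss"]
print(f"speciation threshold (mean 1:1 ortholog dS): {res['speciation_threshold']:.3f}")
print(
    f"{cfg.species_a}: {loss['n_ancestral_a']} ancestral duplicates, "
    f"{loss['n_lost_in_b']} lost in {cfg.species_b} "
    f"({100 * loss['loss_rate_ab']:.0f}%)"
)
print(
    f"{cfg.species_b}: {loss['n_ancestral_b']} ancestral duplicates, "
    f"{loss['n_lost_in_a']} lost in {cfg.species_a} "
    f"({100 * loss['loss_rate_ba']:.0f}%)"
)
test = chi2_2x2(ContingencyTable2x2(*loss["table"]))
print(f"chi-square = {test.statistic:.2f}, d.f. = {test.df}, p = {test.p:.2e}")
print(
    "\nA higher loss percentage in the second row recovers the planted"
    " asymmetry: the first lineage streamlines its genome faster."
)
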