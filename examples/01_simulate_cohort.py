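"""Simulate a phased panel, a mosaic donor, and sequencing reads.

The donor's two haplotypes are recombinant mosaics of the panel plus
novel allele flips the panel has never seen — the situation genotype
imputation is designed for.
"""

from imputefirst.simulate import SimConfig, simulate_donor, simulate_panel, simulate_reads

cfg = SimConfig(genome_length=100_000, n_sites=300, n_haplotypes=20, coverage=2.0, seed=1)
reference, panel = simulate_panel(cfg)
truth = simulate_donor(reference, panel, cfg)
reads = simulate_reads(truth, cfg)

n_het = int(truth.truth_callset.is_het().sum())
n_novel = int(truth.novel_flags.sum())
print(f"reference: {reference.name}, {len(reference):,} bp")
print(f"panel: {panel.n_haplotypes} haplotypes x {panel.n_sites} sites, "
      f"mean ALT frequency {panel.alt_frequencies().mean():.3f}")
print(f"donor: {n_het} heterozygous sites, {n_novel} novel allele flips")
print(f"reads: {len(reads)} x {cfg.read_len} bp at {cfg.coverage}x coverage")
# The donor carries both panel-derived variation (imputable) and novel
# flips (recoverable only from read evidence).
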