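"""Canned desk-scale experiments: the standard study conditions used to
characterise the workflow on synthetic cohorts.

Each function builds its own inputs from a seed, runs the relevant part
of the workflow, and returns plain numbers, so the same experiments back
both the test suite and the reproduction script.

Conditions (defaults):
- imputation-gain grid: 1 Mb genome, 60-haplotype panel, 2,000 sites,
  personalization coverages {0.1, 0.5, 1, 5}x;
- window-accuracy strata: a SNV-dense cohort (one site per ~33 bp) so
  the 1-5, 6-10 and 11+ windows-per-200bp strata are all populated;
- reference-bias cohort: heterozygous SNVs and +-1..10 bp indels, 64
  sites per length category, 30x error-free 50-bp reads — short reads
  make alignment end effects (the mechanism of reference bias) visible
  at SNVs, and 64 sites keep per-category medians stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import align as al
from . import evaluate as ev
from . import personalize as pz
from . import pipeline as pl
from .formats import Contig, GeneticMap, PhasedCallset, VariantSite
from .simulate import SimConfig, TruthSet, simulate_donor, simulate_panel, simulate_reads

__all__ = [
    "GRID_COVERAGES",
    "imputation_gain_grid",
    "window_strata_experiment",
    "bias_cohort",
    "reference_bias_experiment",
    "score_delta_experiment",
    "graph_size_experiment",
]

GRID_COVERAGES = (0.1, 0.5, 1.0, 5.0)


def grid_config(seed: int) -> SimConfig:
    """The 1 Mb / 60 haplotypes / 2,000 sites study conditions."""
    return SimConfig(
        genome_length=1_000_000, n_haplotypes=60, n_sites=2_000, seed=seed
    )


def imputation_gain_grid(
    seeds, coverages=GRID_COVERAGES, cfg_factory=grid_config
) -> pd.DataFrame:
    """Pre- and post-imputation HET F1 per (seed, coverage).

    Reads are simulated at each personalization coverage, rough-genotyped
    against the linear reference, and imputed against the panel; F1 is
    measured against the simulated donor truth (missing rough calls count
    hom-REF).
    """
    rows = []
    for seed in seeds:
        cfg = cfg_factory(seed)
        ref, panel = simulate_panel(cfg)
        truth = simulate_donor(ref, panel, cfg)
        gmap = GeneticMap.uniform(cfg.genome_length)
        for cov in coverages:
            reads = simulate_reads(truth, cfg.with_(coverage=cov), seed=7_000_000 + seed)
            res = pl.run_personalize(
                reads, ref, panel, gmap,
                coverage=cov, input_coverage=cov, seed=seed,
            )
            _, het_pre = ev.allele_accuracy(res.rough_calls, truth.truth_callset)
            _, het_post = ev.allele_accuracy(res.phased_callset, truth.truth_callset)
            rows.append(
                {
                    "seed": seed,
                    "coverage": cov,
                    "het_f1_pre": 0.0 if np.isnan(het_pre.f1) else het_pre.f1,
                    "het_f1_post": het_post.f1,
                }
            )
    return pd.DataFrame(rows)


def window_strata_experiment(seed: int, coverage: float = 0.5) -> dict:
    """Window accuracy of an imputed callset on a SNV-dense cohort."""
    cfg = SimConfig(
        genome_length=120_000,
        n_sites=3_600,
        n_haplotypes=30,
        indel_fraction=0.0,
        max_indel_len=1,
        seed=seed,
    )
    ref, panel = simulate_panel(cfg)
    truth = simulate_donor(ref, panel, cfg)
    gmap = GeneticMap.uniform(cfg.genome_length)
    reads = simulate_reads(truth, cfg.with_(coverage=coverage), seed=8_000_000 + seed)
    res = pl.run_personalize(
        reads, ref, panel, gmap, coverage=coverage, input_coverage=coverage, seed=seed
    )
    truth_dref = pz.build_diploid_fasta(ref, truth.truth_callset)
    return ev.window_accuracy(res.dref, truth_dref, panel.sites)


def bias_cohort(
    seed: int,
    per_category: int = 64,
    read_len: int = 50,
    coverage: float = 30.0,
    spacing: int = 200,
    max_indel: int = 10,
):
    """A donor heterozygous for SNVs and +-1..max_indel bp indels.

    Returns (reference, het callset, diploid reference, reads); reads
    are error-free so every imbalance is attributable to alignment.
    """
    rng = np.random.default_rng(seed)
    cats = (
        [0] * (2 * per_category)
        + [d for d in range(1, max_indel + 1) for _ in range(per_category)]
        + [-d for d in range(1, max_indel + 1) for _ in range(per_category)]
    )
    rng.shuffle(cats)
    L = 2_000 + spacing * len(cats) + 2_000
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
    ref = Contig("chrB", seq)
    sites, gts = [], []
    pos = 1_000
    for i, c in enumerate(cats):
        anchor = seq[pos]
        if c == 0:
            alt = "ACGT"[("ACGT".index(anchor) + 1) % 4]
            site = VariantSite("chrB", pos, anchor, alt, i)
        elif c > 0:
            ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, c)])
            site = VariantSite("chrB", pos, anchor, anchor + ins, i)
        else:
            site = VariantSite("chrB", pos, seq[pos : pos - c + 1], anchor, i)
        sites.append(site)
        gts.append((0, 1) if rng.random() < 0.5 else (1, 0))
        pos += spacing
    callset = PhasedCallset(sites, np.array(gts, dtype=np.uint8))
    dref = pz.build_diploid_fasta(ref, callset)
    truth = TruthSet(
        ref, dref.hap1.sequence, dref.hap2.sequence, callset, np.zeros((2, len(sites)))
    )
    cfg = SimConfig(
        genome_length=L, read_len=read_len, error_rate=0.0, coverage=coverage, seed=seed
    )
    reads = simulate_reads(truth, cfg, seed=seed + 1)
    return ref, callset, dref, reads


def reference_bias_experiment(seed: int, **cohort_kwargs) -> pd.DataFrame:
    """Per-category median allelic balance, personalized vs linear arm."""
    ref, callset, dref, reads = bias_cohort(seed, **cohort_kwargs)
    lin_idx = al.TargetIndex(ref)
    i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
    lin_alns, dip_alns = [], []
    for r in reads:
        a = al.align_read(r, lin_idx)
        d = al.align_diploid(r, i1, i2)
        if a is not None:
            lin_alns.append(a)
        if d is not None:
            dip_alns.append(d)
    lifted = al.lift_alignments(dip_alns, dref)
    bal_pers = ev.allelic_balance(lifted, callset.sites, reference=ref)
    bal_lin = ev.allelic_balance(lin_alns, callset.sites, reference=ref)
    return bal_pers.merge(bal_lin, on="category", suffixes=("_pers", "_lin"))


def score_delta_experiment(seed: int, coverage: float = 2.0) -> tuple[pd.DataFrame, dict]:
    """Score differences of error-free donor reads, diploid vs linear."""
    cfg = SimConfig(
        genome_length=100_000,
        n_sites=300,
        n_haplotypes=12,
        coverage=coverage,
        error_rate=0.0,
        seed=seed,
    )
    ref, panel = simulate_panel(cfg)
    truth = simulate_donor(ref, panel, cfg)
    reads = simulate_reads(truth, cfg, seed=seed + 1)
    dref = pz.build_diploid_fasta(ref, truth.truth_callset)
    return al.score_difference(
        reads,
        al.TargetIndex(ref),
        (al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)),
    )


def graph_size_experiment(seed: int) -> dict:
    """Personal-graph vs full-panel-graph node/edge counts."""
    cfg = SimConfig(genome_length=200_000, n_sites=600, n_haplotypes=20, seed=seed)
    ref, panel = simulate_panel(cfg)
    truth = simulate_donor(ref, panel, cfg)
    personal = pz.build_personal_graph(ref, truth.truth_callset)
    pangenome = pz.build_personal_graph(ref, pz.panel_bubble_callset(panel))
    pn, pe, _ = pz.graph_stats(personal)
    gn, ge, _ = pz.graph_stats(pangenome)
    return {
        "personal_nodes": pn,
        "personal_edges": pe,
        "pangenome_nodes": gn,
        "pangenome_edges": ge,
        "node_ratio": pn / gn,
        "edge_ratio": pe / ge,
    }
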