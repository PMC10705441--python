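"""Two-phase workflow orchestration.

Phase A (personalization): subsample reads -> align to the linear
reference -> pileup + genotype likelihoods at panel sites -> QUAL/DP
filter -> diploid imputation -> personalized phased callset, diploid
consensus FASTA and optional personal graph.

Phase B (downstream): align the full read set to the diploid reference
(haplotype-max), lift alignments back to reference coordinates, re-call
variants, and evaluate; optionally run the linear-reference arm for
comparison.

Every stage is a pure function of (inputs, config, seed); the manifest
records artifact checksums so reruns are checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import align as al
from . import evaluate as ev
from . import genotype as gt
from . import impute as im
from . import personalize as pz
from .formats import Contig, GeneticMap, PhasedCallset, Read, ReferencePanel

__all__ = ["PersonalizationResult", "DownstreamResult", "run_personalize", "run_downstream"]


@dataclass
class PersonalizationResult:
    rough_track: gt.GenotypeLikelihoodTrack
    rough_calls: PhasedCallset
    phased_callset: PhasedCallset
    dref: pz.DiploidReference
    graph: pz.PersonalGraph | None = None
    n_reads_used: int = 0
    manifest: dict = field(default_factory=dict)


@dataclass
class DownstreamResult:
    diploid_alignments: list
    lifted_alignments: list
    linear_alignments: list | None
    calls: PhasedCallset
    linear_calls: PhasedCallset | None
    manifest: dict = field(default_factory=dict)


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_personalize(
    reads: list[Read],
    reference: Contig,
    panel: ReferencePanel,
    gmap: GeneticMap,
    coverage: float,
    input_coverage: float,
    seed: int = 0,
    error_rate: float = 0.01,
    imputation: im.ImputationParams | None = None,
    scoring: al.Scoring = al.Scoring(),
    build_graph: bool = False,
    withhold_filtered_from_imputer: bool = False,
) -> PersonalizationResult:
    """Personalization phase: rough genotyping then diploid imputation."""
    if coverage <= 0:
        raise ValueError("personalization coverage must be positive")
    sub = gt.subsample_reads(reads, coverage, input_coverage, seed=seed)
    index = al.TargetIndex(reference)
    alns = al.align_reads(sub, index, scoring)
    alns.sort(key=lambda a: a.pos)
    pileup = gt.build_pileup(alns, panel.sites, reference=reference)
    track = gt.genotype_likelihoods(pileup, error_rate=error_rate)
    rough_calls = gt.calls_from_track(track)
    imputer_track = (
        gt.filter_rough_calls(track) if withhold_filtered_from_imputer else track
    )
    params = imputation or im.ImputationParams(seed=seed)
    phased = im.impute_diploid(imputer_track, panel, gmap, params)
    dref = pz.build_diploid_fasta(reference, phased)
    graph = pz.build_personal_graph(reference, phased) if build_graph else None
    manifest = {
        "seed": seed,
        "coverage": coverage,
        "n_reads_subsampled": len(sub),
        "n_rough_calls": rough_calls.n_sites,
        "phased_checksum": _checksum(
            "".join(f"{s.pos}:{g[0]}{g[1]};" for s, g in zip(phased.sites, phased.genotypes))
        ),
        "hap1_checksum": _checksum(dref.hap1.sequence),
        "hap2_checksum": _checksum(dref.hap2.sequence),
    }
    return PersonalizationResult(
        rough_track=track,
        rough_calls=rough_calls,
        phased_callset=phased,
        dref=dref,
        graph=graph,
        n_reads_used=len(sub),
        manifest=manifest,
    )


def run_downstream(
    reads: list[Read],
    reference: Contig,
    dref: pz.DiploidReference,
    call_sites=None,
    scoring: al.Scoring = al.Scoring(),
    error_rate: float = 0.01,
    run_linear_arm: bool = False,
) -> DownstreamResult:
    """Downstream phase: diploid alignment, lift-back, re-calling."""
    idx1 = al.TargetIndex(dref.hap1)
    idx2 = al.TargetIndex(dref.hap2)
    dip = []
    for r in reads:
        a = al.align_diploid(r, idx1, idx2, scoring)
        if a is not None:
            dip.append(a)
    lifted = al.lift_alignments(dip, dref)
    lifted.sort(key=lambda a: a.pos)
    calls, _ = al.call_variants_from_alignments(
        lifted, reference, sites=call_sites, error_rate=error_rate
    )
    linear_alns = None
    linear_calls = None
    if run_linear_arm:
        lin_index = al.TargetIndex(reference)
        linear_alns = al.align_reads(reads, lin_index, scoring)
        linear_alns.sort(key=lambda a: a.pos)
        linear_calls, _ = al.call_variants_from_alignments(
            linear_alns, reference, sites=call_sites, error_rate=error_rate
        )
    manifest = {
        "n_reads_aligned_diploid": len(dip),
        "n_lifted": len(lifted),
        "n_calls": calls.n_sites,
    }
    return DownstreamResult(
        diploid_alignments=dip,
        lifted_alignments=lifted,
        linear_alignments=linear_alns,
        calls=calls,
        linear_calls=linear_calls,
        manifest=manifest,
    )
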