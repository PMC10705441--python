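"""Synthetic data generator: phased panel, mosaic donor, error-bearing reads.

The donor is drawn from the same model class the imputer assumes — each
donor haplotype is a Li–Stephens mosaic of panel haplotypes with
distance-dependent switches, plus novel allele flips the panel has never
seen.  That makes parameter recovery a fair test of the imputation
stage, while the novel flips (invisible to the panel) give read evidence
something to contribute at every coverage.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats import Contig, PhasedCallset, Read, ReferencePanel, VariantSite

__all__ = ["SimConfig", "TruthSet", "simulate_panel", "simulate_donor", "simulate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale, human-like megabase: a 60-haplotype
    panel with 2,000 biallelic sites (1 per 500 bp, between the human
    common-variant and all-variant densities), uniform ALT frequency on
    [0.05, 0.5], a mosaic donor switching haplotypes at 5 per Mb
    (matching a Li–Stephens prior with Ne=1e4 and a panel of this size),
    1% novel allele flips per haplotype, and 100-bp reads with 1%
    substitution error.
    """

    genome_length: int = 1_000_000
    n_haplotypes: int = 60
    n_sites: int = 2_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    recomb_rate: float = 5e-6  # per-bp switch probability of the donor mosaic
    novel_mut_rate: float = 0.01  # per site, per donor haplotype
    indel_fraction: float = 0.2
    max_indel_len: int = 10
    read_len: int = 100
    error_rate: float = 0.01
    coverage: float = 30.0
    seed: int = 0
    contig_name: str = "chrS"

    def __post_init__(self) -> None:
        for name in ("recomb_rate", "novel_mut_rate", "indel_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.maf_low <= self.maf_high <= 1.0:
            raise ValueError("need 0 <= maf_low <= maf_high <= 1")
        if self.genome_length < self.read_len:
            raise ValueError("genome_length must be >= read_len")
        if self.n_haplotypes < 1:
            raise ValueError("need at least one panel haplotype")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class TruthSet:
    """Ground truth for one simulated donor."""

    reference: Contig
    donor_hap1: str
    donor_hap2: str
    truth_callset: PhasedCallset  # all panel sites, phased donor genotypes
    source_mosaic: np.ndarray  # (2, n_sites) copied panel haplotype index
    novel_flags: np.ndarray = field(default=None)  # (n_sites, 2) novel-flip mask

    @property
    def n_sites(self) -> int:
        return self.truth_callset.n_sites


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_insertion(rng: np.random.Generator, length: int) -> str:
    return _random_sequence(rng, length)


def simulate_panel(cfg: SimConfig) -> tuple[Contig, ReferencePanel]:
    """Reference contig plus a phased biallelic panel over it.

    Site REF spans never overlap (a 1-bp spacer is kept between spans so
    left-anchored indels stay unambiguous), and per-site ALT frequencies
    are drawn from the configured uniform spectrum.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = _random_sequence(rng, cfg.genome_length)
    reference = Contig(cfg.contig_name, seq)

    # Uniform placement with a minimum gap wide enough for the widest
    # REF span plus a spacer: draw sorted uniform offsets in the span
    # shrunk by n*min_gap, then re-expand — exact uniform spacing
    # conditional on the gap constraint, covering the whole contig.
    min_gap = cfg.max_indel_len + 2
    lo, hi = cfg.read_len, cfg.genome_length - cfg.read_len - min_gap
    slack = (hi - lo) - cfg.n_sites * min_gap
    if hi <= lo or slack <= 0:
        raise ValueError(
            f"cannot place {cfg.n_sites} non-overlapping sites in "
            f"{cfg.genome_length} bp; reduce n_sites or max_indel_len"
        )
    draw = np.sort(rng.integers(0, slack, size=cfg.n_sites))
    positions = [int(lo + d + i * min_gap) for i, d in enumerate(draw)]

    sites: list[VariantSite] = []
    for i, pos in enumerate(positions):
        is_indel = rng.random() < cfg.indel_fraction
        anchor = seq[pos]
        if not is_indel:
            code = "ACGT".index(anchor)
            ref_allele = anchor
            alt_allele = "ACGT"[(code + int(rng.integers(1, 4))) % 4]
        else:
            length = int(rng.integers(1, cfg.max_indel_len + 1))
            if rng.random() < 0.5:  # insertion
                ref_allele = anchor
                alt_allele = anchor + _random_insertion(rng, length)
            else:  # deletion
                ref_allele = seq[pos : pos + length + 1]
                alt_allele = anchor
        sites.append(VariantSite(cfg.contig_name, pos, ref_allele, alt_allele, i))

    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_sites)
    haps = (rng.random((cfg.n_haplotypes, cfg.n_sites)) < freqs).astype(np.uint8)
    samples = [f"S{i:03d}" for i in range(cfg.n_haplotypes // 2)]
    if cfg.n_haplotypes % 2:
        samples = []  # odd haplotype counts have no sample pairing
    return reference, ReferencePanel(sites, haps, samples=samples)


def _mosaic_haplotype(
    rng: np.random.Generator, panel: ReferencePanel, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One donor haplotype: (alleles, source index per site, novel mask)."""
    n_hap, n_sites = panel.haplotypes.shape
    positions = panel.positions
    source = np.zeros(n_sites, dtype=np.int32)
    j = int(rng.integers(n_hap))
    for s in range(n_sites):
        if s > 0:
            d = positions[s] - positions[s - 1]
            p_switch = 1.0 - np.exp(-cfg.recomb_rate * d)
            if rng.random() < p_switch:
                j = int(rng.integers(n_hap))
        source[s] = j
    alleles = panel.haplotypes[source, np.arange(n_sites)].astype(np.uint8)
    novel = rng.random(n_sites) < cfg.novel_mut_rate
    alleles[novel] ^= 1
    return alleles, source, novel


def _apply_haplotype(reference: Contig, sites, alleles: np.ndarray) -> str:
    """Apply ALT alleles to the reference by simple segment stitching.

    Intentionally a different code path from the consensus builder in
    the personalize module, so the two can cross-check each other.
    """
    seq = reference.sequence
    parts: list[str] = []
    cursor = 0
    for site, a in zip(sites, alleles):
        if not a:
            continue
        parts.append(seq[cursor : site.pos])
        parts.append(site.alt)
        cursor = site.end
    parts.append(seq[cursor:])
    return "".join(parts)


def simulate_donor(
    reference: Contig, panel: ReferencePanel, cfg: SimConfig, seed: int | None = None
) -> TruthSet:
    """Draw a diploid donor as two independent panel mosaics.

    Novel mutations flip the copied allele at panel sites; they are
    recorded in the truth callset but leave the panel untouched, so the
    imputer can only learn them from read evidence.
    """
    if panel.n_haplotypes < 2:
        raise ValueError("donor simulation needs a panel with >= 2 haplotypes")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    a1, src1, nov1 = _mosaic_haplotype(rng, panel, cfg)
    a2, src2, nov2 = _mosaic_haplotype(rng, panel, cfg)
    genotypes = np.stack([a1, a2], axis=1)
    callset = PhasedCallset(
        list(panel.sites),
        genotypes,
        posterior=np.ones(panel.n_sites),
        imputed=np.zeros(panel.n_sites, dtype=bool),
    )
    hap1 = _apply_haplotype(reference, panel.sites, a1)
    hap2 = _apply_haplotype(reference, panel.sites, a2)
    return TruthSet(
        reference=reference,
        donor_hap1=hap1,
        donor_hap2=hap2,
        truth_callset=callset,
        source_mosaic=np.stack([src1, src2]),
        novel_flags=np.stack([nov1, nov2], axis=1),
    )


def simulate_reads(
    truth: TruthSet, cfg: SimConfig, seed: int | None = None
) -> list[Read]:
    """Uniform single-end reads from both donor haplotypes.

    Read count is round(coverage * genome_length / read_len).  The read
    id encodes origin as ``sim<i>:hap<h>:<start>`` (0-based start on the
    source haplotype) for truth-based checks downstream.
    """
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive")
    haps = (truth.donor_hap1, truth.donor_hap2)
    if cfg.read_len > min(len(h) for h in haps):
        raise ValueError("read_len exceeds donor haplotype length")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    n_reads = int(round(cfg.coverage * cfg.genome_length / cfg.read_len))
    qual = (
        min(40, int(round(-10 * np.log10(max(cfg.error_rate, 1e-4)))))
        if cfg.error_rate > 0
        else 40
    )
    quals = np.full(cfg.read_len, qual, dtype=np.int16)
    reads: list[Read] = []
    for i in range(n_reads):
        h = int(rng.integers(2))
        start = int(rng.integers(0, len(haps[h]) - cfg.read_len + 1))
        frag = np.frombuffer(
            haps[h][start : start + cfg.read_len].encode(), dtype=np.uint8
        ).copy()
        if cfg.error_rate > 0:
            err = rng.random(cfg.read_len) < cfg.error_rate
            if err.any():
                idx = np.flatnonzero(err)
                shift = rng.integers(1, 4, size=idx.size)
                codes = np.searchsorted(_BASES, frag[idx])
                frag[idx] = _BASES[(codes + shift) % 4]
        reads.append(
            Read(f"sim{i}:hap{h + 1}:{start}", frag.tobytes().decode(), quals.copy())
        )
    return reads


def parse_read_origin(read_id: str) -> tuple[int, int]:
    """(haplotype 1|2, 0-based start on that haplotype) from a read id."""
    _, hap, start = read_id.split(":")
    return int(hap[3:]), int(start)
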