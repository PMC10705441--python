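"""Rough genotyping: read subsampling, pileups at known sites, genotype
likelihoods, and the QUAL/DP call filter.

The likelihood model is the standard biallelic mixture: a read drawn
from a genotype with ALT dosage k supports the ALT allele with
probability (1 - k/2)·eps + (k/2)·(1 - eps), where eps is the per-base
error rate.  Reads matching neither allele contribute a factor eps to
every genotype, which cancels after per-site renormalisation but still
counts toward depth.

QUAL is the phred-scaled posterior probability that the site is
non-reference under a uniform genotype prior, -10·log10 P(hom-REF|data)
— the same monotone confidence bcftools attaches to its variant
records, so the literature thresholds (QUAL >= 20, DP <= 100) carry
over with identical semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import Alignment, Contig, PhasedCallset, Read, VariantSite

__all__ = [
    "Pileup",
    "GenotypeLikelihoodTrack",
    "subsample_reads",
    "build_pileup",
    "genotype_likelihoods",
    "filter_rough_calls",
    "calls_from_track",
]


@dataclass
class Pileup:
    """Per-site REF/ALT/other read counts."""

    sites: list[VariantSite]
    n_ref: np.ndarray
    n_alt: np.ndarray
    n_other: np.ndarray

    def __post_init__(self) -> None:
        for name in ("n_ref", "n_alt", "n_other"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt + self.n_other


@dataclass
class GenotypeLikelihoodTrack:
    """Per-site log10 genotype likelihoods with depth and QUAL.

    ``gl`` has columns (hom-REF, HET, hom-ALT), renormalised so the
    per-site maximum is exactly 0.
    """

    sites: list[VariantSite]
    gl: np.ndarray  # (n_sites, 3) log10
    depth: np.ndarray
    qual: np.ndarray

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=np.float64).reshape(-1, 3)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=np.float64)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def argmax_genotypes(self) -> np.ndarray:
        """ALT dosage (0, 1, 2) of the most likely genotype per site."""
        return np.argmax(self.gl, axis=1)

    def posteriors(self) -> np.ndarray:
        """Per-site genotype posteriors under a uniform prior."""
        lin = 10.0 ** self.gl
        return lin / lin.sum(axis=1, keepdims=True)

    def subset(self, mask: np.ndarray) -> "GenotypeLikelihoodTrack":
        idx = np.flatnonzero(mask)
        return GenotypeLikelihoodTrack(
            [self.sites[i] for i in idx], self.gl[idx], self.depth[idx], self.qual[idx]
        )


def subsample_reads(
    reads: list[Read],
    target_coverage: float,
    input_coverage: float,
    seed: int = 0,
) -> list[Read]:
    """Keep each read (or mate pair) with probability target/input.

    Per-read Bernoulli thinning rather than an exact count, mirroring
    streaming use; mates share one coin flip.
    """
    if target_coverage <= 0:
        raise ValueError("target coverage must be positive")
    p = target_coverage / input_coverage
    if p >= 1.0:
        if p > 1.0:
            warnings.warn(
                f"target coverage {target_coverage} exceeds input "
                f"{input_coverage}; keeping all reads"
            )
        return list(reads)
    rng = np.random.default_rng(seed)
    decisions: dict[str, bool] = {}
    kept = []
    for r in reads:
        key = r.mate if r.mate else r.id
        if key not in decisions:
            decisions[key] = bool(rng.random() < p)
        if decisions[key]:
            kept.append(r)
    return kept


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _read_offset_at(aln: Alignment, target_pos: int) -> int | None:
    """Read offset aligned (M) to ``target_pos``, else None."""
    r, t = 0, aln.pos
    for op, n in aln.cigar:
        if op == "M":
            if t <= target_pos < t + n:
                return r + (target_pos - t)
            r += n
            t += n
        elif op in ("I", "S"):
            r += n
        elif op == "D":
            if t <= target_pos < t + n:
                return None
            t += n
    return None


def classify_read_at_site(
    aln: Alignment,
    site: VariantSite,
    reference: Contig | None = None,
    min_baseq: int = 13,
) -> str | None:
    """'ref' / 'alt' / 'other' for a read overlapping a site, else None.

    SNVs classify by the aligned base.  Indels classify by exact local
    sequence match: the read must spell the whole allele plus enough
    right context (|length difference| + 1 bases) to distinguish the
    two alleles; anything ambiguous or error-bearing counts as 'other'.
    """
    if not (aln.pos < site.end and aln.target_end() > site.pos):
        return None
    o = _read_offset_at(aln, site.pos)
    if o is None:
        return "other"
    if aln.qualities is not None and aln.qualities[o] < min_baseq:
        return None
    if site.indel_length == 0 and len(site.ref) == 1:
        b = aln.sequence[o]
        if b == site.ref:
            return "ref"
        if b == site.alt:
            return "alt"
        return "other"
    # indel: exact match on the minimal prefix that distinguishes the two
    # allele+context strings (extending context through repeats), so REF-
    # and ALT-carrying reads need the same span of evidence
    ctx = abs(site.indel_length) + 1
    while True:
        right = reference.sequence[site.end : site.end + ctx] if reference else ""
        r_full = site.ref + right
        a_full = site.alt + right
        diff = _common_prefix_len(r_full, a_full)
        if diff < min(len(r_full), len(a_full)) or not reference:
            break
        if site.end + ctx >= len(reference.sequence) or ctx > 4 * abs(site.indel_length) + 64:
            break  # repeat runs to the contig end; classify on what exists
        ctx += abs(site.indel_length) + 1
    need = diff + 1
    if r_full[:need] == a_full[:need]:
        return "other"  # unresolvable repeat
    frag = aln.sequence[o : o + need]
    if len(frag) < need:
        return "other"
    if frag == a_full[:need]:
        return "alt"
    if frag == r_full[:need]:
        return "ref"
    return "other"


def build_pileup(
    alignments: list[Alignment],
    sites: list[VariantSite],
    min_mapq: int = 0,
    min_baseq: int = 13,
    reference: Contig | None = None,
) -> Pileup:
    """Count REF/ALT/other reads per site from position-sorted alignments."""
    positions = [a.pos for a in alignments]
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("alignments must be sorted by position")
    n = len(sites)
    n_ref = np.zeros(n, dtype=np.int64)
    n_alt = np.zeros(n, dtype=np.int64)
    n_other = np.zeros(n, dtype=np.int64)
    site_pos = np.array([s.pos for s in sites], dtype=np.int64)
    order = np.argsort(site_pos, kind="stable")
    sorted_pos = site_pos[order]
    max_span = max((len(s.ref) for s in sites), default=1)
    for aln in alignments:
        if aln.mapq < min_mapq:
            continue
        lo = int(np.searchsorted(sorted_pos, aln.pos - max_span, side="left"))
        hi = int(np.searchsorted(sorted_pos, aln.target_end(), side="left"))
        for si in order[lo:hi]:
            site = sites[si]
            if site.contig != aln.target:
                continue
            cls = classify_read_at_site(aln, site, reference, min_baseq)
            if cls == "ref":
                n_ref[si] += 1
            elif cls == "alt":
                n_alt[si] += 1
            elif cls == "other":
                n_other[si] += 1
    return Pileup(sites, n_ref, n_alt, n_other)


def genotype_likelihoods(
    pileup: Pileup, error_rate: float = 0.01
) -> GenotypeLikelihoodTrack:
    """Log10 genotype likelihoods from allele counts.

    With eps = error_rate, a REF-supporting read has probability
    (1 - k/2)(1-eps) + (k/2)eps under ALT dosage k, and symmetrically
    for ALT-supporting reads; 'other' reads contribute eps to every
    genotype.  Likelihoods are renormalised to max 0 per site.
    """
    eps = float(error_rate)
    if not 0.0 < eps < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    k = np.array([0.0, 1.0, 2.0])
    p_alt_read = (1 - k / 2) * eps + (k / 2) * (1 - eps)  # per genotype
    p_ref_read = (1 - k / 2) * (1 - eps) + (k / 2) * eps
    log_l = (
        pileup.n_ref[:, None] * np.log10(p_ref_read)[None, :]
        + pileup.n_alt[:, None] * np.log10(p_alt_read)[None, :]
        + pileup.n_other[:, None] * np.log10(eps)
    )
    log_l -= log_l.max(axis=1, keepdims=True)
    post = 10.0**log_l
    post /= post.sum(axis=1, keepdims=True)
    qual = -10.0 * np.log10(np.maximum(post[:, 0], 1e-300))
    qual = np.minimum(qual, 1000.0)
    return GenotypeLikelihoodTrack(pileup.sites, log_l, pileup.depth, qual)


def filter_rough_calls(
    track: GenotypeLikelihoodTrack, min_qual: float = 20.0, max_depth: int = 100
) -> GenotypeLikelihoodTrack:
    """Sites passing QUAL >= min_qual and DP <= max_depth.

    The filtered track is what the rough-call VCF reports; the unfiltered
    track remains available as likelihood evidence for imputation (the
    two consumers of the personalization stage).
    """
    mask = (track.qual >= min_qual) & (track.depth <= max_depth)
    return track.subset(mask)


def calls_from_track(
    track: GenotypeLikelihoodTrack,
    min_qual: float = 20.0,
    max_depth: int = 100,
) -> PhasedCallset:
    """Unphased argmax genotype calls at passing, non-hom-REF sites."""
    passing = filter_rough_calls(track, min_qual, max_depth)
    dosage = passing.argmax_genotypes()
    keep = dosage > 0
    sites = [s for s, k in zip(passing.sites, keep) if k]
    gts = np.stack(
        [(dosage[keep] > 1).astype(np.uint8), (dosage[keep] > 0).astype(np.uint8)],
        axis=1,
    )
    post = passing.posteriors()[keep, dosage[keep]]
    return PhasedCallset(
        sites, gts, posterior=post, imputed=np.zeros(keep.sum(), bool), phased=False
    )
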