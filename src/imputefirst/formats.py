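"""Domain types and file I/O.

Coordinate convention: every in-memory position is 0-based, half-open.
VCF and SAM are 1-based on disk; the conversion happens exactly once, in
the reader/writer functions of this module, so the rest of the package
never adds or subtracts one.

Readers reject malformed records with messages naming the offending
record; writers emit files their own readers round-trip bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

__all__ = [
    "Contig",
    "Read",
    "VariantSite",
    "GeneticMap",
    "ReferencePanel",
    "PhasedCallset",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_panel_vcf",
    "write_panel_vcf",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "read_sam",
    "write_sam",
]


class FormatError(ValueError):
    """Malformed input record."""


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence (uppercase, over {A,C,G,T,N})."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.name}: empty sequence")
        seq = self.sequence.upper()
        if set(seq) - DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise ValueError(f"contig {self.name}: non-DNA characters {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    """A sequencing read with per-base phred qualities."""

    id: str
    sequence: str
    qualities: np.ndarray  # phred scores, one per base
    mate: str | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError(f"read {self.id}: phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant; ``pos`` is 0-based on the reference contig.

    ``ref`` and ``alt`` are left-anchored allele strings as in VCF, so a
    deletion looks like (``"ACG"``, ``"A"``) and an insertion like
    (``"A"``, ``"ACG"``).  ``site_id`` is the ordinal index of the site
    within its panel / callset.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    site_id: int = -1

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"site {self.contig}:{self.pos}: negative position")
        if not self.ref or not self.alt:
            raise ValueError(f"site {self.contig}:{self.pos}: empty allele")
        if self.ref == self.alt:
            raise ValueError(f"site {self.contig}:{self.pos}: REF == ALT")

    @property
    def end(self) -> int:
        """End of the REF span, half-open."""
        return self.pos + len(self.ref)

    @property
    def indel_length(self) -> int:
        """len(ALT) - len(REF): positive insertion, negative deletion, 0 SNV."""
        return len(self.alt) - len(self.ref)

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


class GeneticMap:
    """Piecewise-linear physical→genetic coordinate map.

    Positions are 0-based bp; cM values non-decreasing.  Queries outside
    the knot range extrapolate at a constant rate (default 1 cM/Mb).
    """

    def __init__(
        self,
        positions: Sequence[int],
        cM: Sequence[float],
        extrapolation_rate: float = 1e-6,  # cM per bp == 1 cM/Mb
    ) -> None:
        self.positions = np.asarray(positions, dtype=np.int64)
        self.cM = np.asarray(cM, dtype=np.float64)
        if self.positions.shape != self.cM.shape:
            raise ValueError("positions and cM must have the same length")
        if len(self.positions) < 1:
            raise ValueError("genetic map needs at least one knot")
        if np.any(np.diff(self.positions) <= 0):
            raise FormatError("genetic map positions must be strictly ascending")
        if np.any(np.diff(self.cM) < 0):
            raise FormatError("genetic map cM values must be non-decreasing")
        self.extrapolation_rate = float(extrapolation_rate)

    def __len__(self) -> int:
        return len(self.positions)

    def interpolate_cM(self, pos):
        """cM at bp position(s) ``pos`` (0-based); vectorised."""
        pos = np.asarray(pos, dtype=np.float64)
        out = np.interp(pos, self.positions, self.cM)
        lo, hi = self.positions[0], self.positions[-1]
        below = pos < lo
        above = pos > hi
        if np.any(below):
            out = np.where(below, self.cM[0] - (lo - pos) * self.extrapolation_rate, out)
        if np.any(above):
            out = np.where(above, self.cM[-1] + (pos - hi) * self.extrapolation_rate, out)
        return out if out.ndim else float(out)

    @classmethod
    def uniform(cls, length: int, rate: float = 1e-6) -> "GeneticMap":
        """A constant-rate map over [0, length) (rate in cM/bp)."""
        return cls([0, length], [0.0, length * rate], extrapolation_rate=rate)


@dataclass
class ReferencePanel:
    """Phased biallelic haplotype panel.

    ``haplotypes`` has shape (n_haplotypes, n_sites) over {0, 1};
    haplotypes 2i and 2i+1 belong to sample ``samples[i]`` when samples
    are known.
    """

    sites: list[VariantSite]
    haplotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError(
                f"haplotype matrix has {self.haplotypes.shape[1]} columns for "
                f"{len(self.sites)} sites"
            )
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("panel alleles must be 0/1 (biallelic)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def alt_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class PhasedCallset:
    """Per-site diploid genotypes for one individual.

    ``genotypes`` has shape (n_sites, 2) over {0, 1}; column 0 is
    haplotype 1 (left of the ``|`` in VCF).  ``phased`` is False for
    callsets whose haplotype assignment is meaningless (e.g. rough
    genotyping output), in which case VCF output uses ``/``.
    """

    sites: list[VariantSite]
    genotypes: np.ndarray
    posterior: np.ndarray | None = None
    imputed: np.ndarray | None = None
    phased: bool = True

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8).reshape(-1, 2)
        if self.genotypes.shape[0] != len(self.sites):
            raise ValueError("genotype rows != number of sites")
        if self.genotypes.size and self.genotypes.max() > 1:
            raise ValueError("alleles must be 0/1")
        if self.posterior is not None:
            self.posterior = np.asarray(self.posterior, dtype=np.float64)
        if self.imputed is not None:
            self.imputed = np.asarray(self.imputed, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def is_het(self) -> np.ndarray:
        return self.genotypes[:, 0] != self.genotypes[:, 1]

    def dosage(self) -> np.ndarray:
        return self.genotypes.sum(axis=1)

    def check_sorted(self) -> None:
        keys = [(s.contig, s.pos) for s in self.sites]
        if keys != sorted(keys):
            raise ValueError("callset sites are not sorted by (contig, pos)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhasedCallset):
            return NotImplemented
        return (
            [s.key() for s in self.sites] == [s.key() for s in other.sites]
            and np.array_equal(self.genotypes, other.genotypes)
            and self.phased == other.phased
        )


@dataclass
class Alignment:
    """A gapped local alignment of a read to one target sequence.

    ``pos`` is the 0-based target start; ``cigar`` is a list of
    (op, length) with ops from MIDS (S = soft clip); the op lengths over
    {M, I, S} sum to the read length.  ``score`` is the affine-gap local
    alignment score.
    """

    read_id: str
    target: str
    pos: int
    cigar: list[tuple[str, int]]
    score: int
    sequence: str = ""
    qualities: np.ndarray | None = None
    mapq: int = 60  # placeholder; no multi-mapping resolution

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def target_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in "MD")

    def aligned_pairs(self) -> Iterable[tuple[int, int]]:
        """Yield (read_offset, target_position) for every M column."""
        r, t = 0, self.pos
        for op, n in self.cigar:
            if op == "M":
                for k in range(n):
                    yield (r + k, t + k)
                r += n
                t += n
            elif op in ("I", "S"):
                r += n
            elif op == "D":
                t += n
            else:
                raise ValueError(f"unsupported cigar op {op}")


def parse_cigar(text: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MIDSHNP=X":
                raise FormatError(f"bad cigar {text!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"bad cigar {text!r}")
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[Contig]:
    contigs = [
        Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not contigs:
        raise FormatError(f"{path}: no FASTA records")
    return contigs


def write_fasta(contigs: Iterable[Contig], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
        reads.append(Read(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_CONTIG_FALLBACK = 2**29  # contig length when unknown


def _vcf_header(contigs, samples) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta("source", "imputefirst")
    for name, length in contigs:
        header.contigs.add(name, length=length or _VCF_HEADER_CONTIG_FALLBACK)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("DP", 1, "Integer", "Raw read depth")
    header.info.add("IMP", 0, "Flag", "Genotype was imputed without read evidence")
    header.info.add("GP", 1, "Float", "Posterior probability of the called genotype")
    for s in samples:
        header.add_sample(s)
    return header


def _split_record_alleles(rec, idx: int) -> tuple[str, str]:
    """Biallelic (ref, alt) for ALT index ``idx`` of a VCF record."""
    ref = rec.ref.upper()
    alt = rec.alts[idx].upper()
    if not alt or set(alt) - DNA_ALPHABET or alt.startswith("<") or alt == "*":
        raise FormatError(
            f"{rec.chrom}:{rec.pos}: symbolic or non-DNA ALT {alt!r} not supported"
        )
    return ref, alt


def read_panel_vcf(
    path,
    exclude_samples: Sequence[str] = (),
    reference: Contig | None = None,
) -> ReferencePanel:
    """Load a phased multi-sample VCF as a haplotype panel.

    Multiallelic records are split into biallelic rows (one per ALT);
    after splitting, any site whose REF span overlaps an earlier kept
    site is dropped with a warning, mirroring what a consensus applier
    could actually use.  Unphased or half-missing genotypes are an
    error.  If ``reference`` is given, sites overlapping N bases (or
    with a mismatching REF) are rejected.
    """
    vcf = pysam.VariantFile(str(path))
    all_samples = list(vcf.header.samples)
    missing = [s for s in exclude_samples if s not in all_samples]
    if missing:
        raise FormatError(f"samples to exclude not found in VCF: {missing}")
    keep = [s for s in all_samples if s not in set(exclude_samples)]

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    last_end_by_contig: dict[str, int] = {}
    for rec in vcf:
        prev_record_end = last_end_by_contig.get(rec.chrom, -1)
        for alt_idx in range(len(rec.alts or ())):
            ref, alt = _split_record_alleles(rec, alt_idx)
            pos0 = rec.pos - 1  # VCF is 1-based
            hap = np.zeros(2 * len(keep), dtype=np.uint8)
            for i, sample in enumerate(keep):
                gt = rec.samples[sample]
                alleles = gt.allele_indices
                if (
                    alleles is None
                    or len(alleles) != 2
                    or any(a is None for a in alleles)
                    or not gt.phased
                ):
                    raise FormatError(
                        f"{rec.chrom}:{rec.pos} sample {sample}: genotype must be "
                        "phased diploid with no missing alleles"
                    )
                # ALT index alt_idx+1 in the original record maps to allele 1
                hap[2 * i] = 1 if alleles[0] == alt_idx + 1 else 0
                hap[2 * i + 1] = 1 if alleles[1] == alt_idx + 1 else 0
            if reference is not None:
                if rec.chrom != reference.name:
                    raise FormatError(
                        f"{rec.chrom}:{rec.pos}: contig not in reference"
                    )
                span = reference.sequence[pos0 : pos0 + len(ref)]
                if span != ref:
                    raise FormatError(
                        f"{rec.chrom}:{rec.pos}: REF {ref!r} does not match "
                        f"reference sequence {span!r}"
                    )
                if "N" in span:
                    warnings.warn(
                        f"{rec.chrom}:{rec.pos}: site overlaps N bases; dropped"
                    )
                    continue
            # sibling ALTs of one record share a span legitimately; only
            # spans overlapping an earlier record conflict
            if pos0 < prev_record_end:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos}: REF span overlaps previous site; dropped"
                )
                continue
            last_end_by_contig[rec.chrom] = max(
                last_end_by_contig.get(rec.chrom, -1), pos0 + len(ref)
            )
            sites.append(VariantSite(rec.chrom, pos0, ref, alt, len(sites)))
            columns.append(hap)
    matrix = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((2 * len(keep), 0), dtype=np.uint8)
    )
    return ReferencePanel(sites, matrix, samples=keep)


def write_panel_vcf(panel: ReferencePanel, path, contig_lengths=None) -> None:
    contig_lengths = contig_lengths or {}
    contigs = sorted({s.contig for s in panel.sites})
    if panel.n_haplotypes % 2:
        raise ValueError("panel VCF output needs an even number of haplotypes")
    samples = panel.samples or [f"S{i}" for i in range(panel.n_haplotypes // 2)]
    header = _vcf_header([(c, contig_lengths.get(c)) for c in contigs], samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(panel.sites):
            rec = out.new_record(
                contig=site.contig,
                start=site.pos,
                alleles=(site.ref, site.alt),
            )
            for i, sample in enumerate(samples):
                rec.samples[sample].allele_indices = (
                    int(panel.haplotypes[2 * i, j]),
                    int(panel.haplotypes[2 * i + 1, j]),
                )
                rec.samples[sample].phased = True
            out.write(rec)


def write_phased_vcf(
    callset: PhasedCallset, path, sample: str = "DONOR", contig_lengths=None
) -> None:
    """Write a single-sample VCF; GT uses ``|`` when the callset is phased."""
    callset.check_sorted()
    contig_lengths = contig_lengths or {}
    contigs = sorted({s.contig for s in callset.sites})
    header = _vcf_header([(c, contig_lengths.get(c)) for c in contigs], [sample])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(callset.sites):
            rec = out.new_record(
                contig=site.contig, start=site.pos, alleles=(site.ref, site.alt)
            )
            rec.samples[sample].allele_indices = (
                int(callset.genotypes[j, 0]),
                int(callset.genotypes[j, 1]),
            )
            rec.samples[sample].phased = callset.phased
            if callset.imputed is not None and callset.imputed[j]:
                rec.info["IMP"] = True
            if callset.posterior is not None:
                rec.info["GP"] = float(callset.posterior[j])
            out.write(rec)


def read_phased_vcf(path) -> PhasedCallset:
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if len(samples) != 1:
        raise FormatError(f"{path}: expected a single-sample VCF, got {samples}")
    sample = samples[0]
    sites, gts, post, imputed = [], [], [], []
    phased = True
    for rec in vcf:
        for alt_idx in range(len(rec.alts or ())):
            ref, alt = _split_record_alleles(rec, alt_idx)
            gt = rec.samples[sample]
            alleles = gt.allele_indices
            if alleles is None or any(a is None for a in alleles):
                raise FormatError(f"{rec.chrom}:{rec.pos}: missing genotype")
            phased = phased and gt.phased
            sites.append(VariantSite(rec.chrom, rec.pos - 1, ref, alt, len(sites)))
            gts.append(
                (1 if alleles[0] == alt_idx + 1 else 0, 1 if alleles[1] == alt_idx + 1 else 0)
            )
            post.append(float(rec.info.get("GP", 1.0)))
            imputed.append(bool(rec.info.get("IMP", False)))
    return PhasedCallset(
        sites,
        np.array(gts, dtype=np.uint8).reshape(-1, 2),
        posterior=np.array(post),
        imputed=np.array(imputed),
        phased=phased,
    )


# ---------------------------------------------------------------------------
# Genetic map (3 columns: position, rate cM/Mb, cM; 1-based positions on disk)


def read_genetic_map(path, extrapolation_rate: float = 1e-6) -> GeneticMap:
    positions, cms = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0] in ("position", "pos", "#position"):
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                positions.append(int(fields[0]) - 1)
                cms.append(float(fields[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return GeneticMap(positions, cms, extrapolation_rate=extrapolation_rate)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("position rate(cM/Mb) cM\n")
        pos = gmap.positions
        cm = gmap.cM
        for i in range(len(pos)):
            if i + 1 < len(pos):
                rate = (cm[i + 1] - cm[i]) / (pos[i + 1] - pos[i]) * 1e6
            else:
                rate = gmap.extrapolation_rate * 1e6
            fh.write(f"{pos[i] + 1} {rate:.6f} {cm[i]:.8f}\n")


# ---------------------------------------------------------------------------
# SAM (minimal dialect: QNAME FLAG RNAME POS MAPQ CIGAR SEQ QUAL + AS:i)


def write_sam(alignments: Iterable[Alignment], contigs: Sequence[Contig], path) -> None:
    header = pysam.AlignmentHeader.from_references(
        [c.name for c in contigs], [len(c) for c in contigs]
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.sequence or None
            seg.flag = 0
            seg.reference_id = header.get_tid(aln.target)
            seg.reference_start = aln.pos
            seg.mapping_quality = aln.mapq
            seg.cigarstring = aln.cigar_string()
            if aln.qualities is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in aln.qualities)
                )
            seg.set_tag("AS", int(aln.score))
            out.write(seg)


def read_sam(path) -> list[Alignment]:
    out = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            cigar = parse_cigar(seg.cigarstring)
            quals = (
                np.asarray(seg.query_qualities, dtype=np.int16)
                if seg.query_qualities is not None
                else None
            )
            out.append(
                Alignment(
                    read_id=seg.query_name,
                    target=seg.reference_name,
                    pos=seg.reference_start,
                    cigar=cigar,
                    score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                    sequence=seg.query_sequence or "",
                    qualities=quals,
                    mapq=seg.mapping_quality,
                )
            )
    return out
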