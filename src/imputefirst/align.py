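"""Seed-and-extend local read alignment, haplotype-max selection,
alignment lift-back, and pileup-based variant calling from alignments.

Scoring follows the BWA-MEM convention: +1 match, -4 mismatch, and
affine gaps costing 6 to open plus 1 per base (a 1-bp gap costs 7).
Seeds are exact k-mer hits against a 2-bit index of the target; the best
seed diagonals are extended with a windowed Smith–Waterman whose window
pads the read span by the band radius, so any alignment within the
expected indel budget is scored exactly.

Aligning a read to both personalized haplotypes and keeping the higher
score is score-equivalent to aligning against the acyclic personal
variation graph built here, because every path through that graph
follows one of the two haplotypes at each bubble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .formats import Alignment, Contig, Read, VariantSite
from .personalize import DiploidReference

__all__ = [
    "Scoring",
    "TargetIndex",
    "align_read",
    "align_reads",
    "align_diploid",
    "score_difference",
    "lift_alignments",
    "call_variants_from_alignments",
]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch_penalty: int = 4
    gap_open_penalty: int = 6
    gap_extend_penalty: int = 1

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gap_open_penalty, self.gap_extend_penalty) <= 0:
            raise ValueError("penalties must be positive")


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit base codes; N and anything unexpected become code 4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class TargetIndex:
    """Exact k-mer index over one target sequence."""

    def __init__(self, contig: Contig, k: int = 21):
        self.contig = contig
        self.k = k
        self.codes = encode(contig.sequence)
        n = len(self.codes) - k + 1
        if n <= 0:
            raise ValueError("target shorter than seed length")
        hashes = np.zeros(n, dtype=np.uint64)
        valid = np.ones(n, dtype=bool)
        for t in range(k):
            c = self.codes[t : t + n]
            hashes = (hashes << np.uint64(2)) | c.astype(np.uint64)
            valid &= c < 4
        hashes[~valid] = np.uint64(2**63)
        order = np.argsort(hashes, kind="stable")
        self._sorted_hashes = hashes[order]
        self._sorted_pos = order.astype(np.int64)

    def lookup(self, kmer_hash: int) -> np.ndarray:
        h = np.uint64(kmer_hash)
        lo = np.searchsorted(self._sorted_hashes, h, side="left")
        hi = np.searchsorted(self._sorted_hashes, h, side="right")
        return np.sort(self._sorted_pos[lo:hi])


def _kmer_hash(codes: np.ndarray) -> int | None:
    if (codes >= 4).any():
        return None
    h = 0
    for c in codes:
        h = (h << 2) | int(c)
    return h


@njit(cache=True)
def _sw_kernel(read, window, match, mismatch, gap_open, gap_extend):
    """Full affine-gap local DP of read vs window, with traceback.

    Returns (score, read_start, read_end, win_start, win_end, ops, lens,
    n_ops); ops are 0=M, 1=I (read gap vs target), 2=D.
    """
    L = read.shape[0]
    W = window.shape[0]
    NEG = -10**9
    H = np.zeros((L + 1, W + 1), dtype=np.int32)
    E = np.full((L + 1, W + 1), NEG, dtype=np.int32)  # gap consuming target (D)
    F = np.full((L + 1, W + 1), NEG, dtype=np.int32)  # gap consuming read (I)
    ptr = np.zeros((L + 1, W + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 fromE, 3 fromF
    ptrE = np.zeros((L + 1, W + 1), dtype=np.uint8)  # 1 open, 0 extend
    ptrF = np.zeros((L + 1, W + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, L + 1):
        for j in range(1, W + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            rc = read[i - 1]
            wc = window[j - 1]
            if rc < 4 and rc == wc:
                s = match
            else:
                s = -mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(2 * L + 4, dtype=np.uint8)
    lens = np.zeros(2 * L + 4, dtype=np.int32)
    n_ops = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                op = 0
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:
            op = 1  # D (consumes target)
            opened = ptrE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            op = 2  # I (consumes read)
            opened = ptrF[i, j]
            i -= 1
            if opened == 1:
                state = 0
        if n_ops > 0 and ops[n_ops - 1] == op:
            lens[n_ops - 1] += 1
        else:
            ops[n_ops] = op
            lens[n_ops] = 1
            n_ops += 1
    # ops were collected end-to-start; reverse
    for t in range(n_ops // 2):
        o = ops[t]
        ops[t] = ops[n_ops - 1 - t]
        ops[n_ops - 1 - t] = o
        l = lens[t]
        lens[t] = lens[n_ops - 1 - t]
        lens[n_ops - 1 - t] = l
    return best, i, bi, j, bj, ops, lens, n_ops


_OP_CHARS = {0: "M", 1: "D", 2: "I"}


def align_read(
    read: Read,
    index: TargetIndex,
    scoring: Scoring = Scoring(),
    seed_stride: int | None = None,
    band_pad: int = 18,
    max_candidates: int = 8,
) -> Alignment | None:
    """Best local alignment of one read, or None when no seed hits.

    Seeds are sampled every ``seed_stride`` bases (default: the seed
    length) plus one flush-right seed; candidate diagonals are ranked by
    seed support and extended in a window padding the read span by
    ``band_pad`` (the band radius: 2 x (max expected indel + 8) / 2).
    Ties in score resolve to the leftmost target position.
    """
    k = index.k
    L = len(read)
    if L < k:
        return None
    codes = encode(read.sequence)
    stride = seed_stride or k
    offsets = list(range(0, L - k + 1, stride))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    support: dict[int, int] = {}
    for off in offsets:
        h = _kmer_hash(codes[off : off + k])
        if h is None:
            continue
        for pos in index.lookup(h):
            diag = int(pos) - off
            support[diag] = support.get(diag, 0) + 1
    if not support:
        return None
    cands = sorted(support, key=lambda d: (-support[d], d))[:max_candidates]
    tlen = len(index.codes)
    best: tuple[int, int] | None = None  # (score, target_start)
    best_parts = None
    for diag in sorted(cands):
        w0 = max(0, diag - band_pad)
        w1 = min(tlen, diag + L + band_pad)
        score, ri, re_, wi, we, ops, lens, n_ops = _sw_kernel(
            codes,
            index.codes[w0:w1],
            scoring.match,
            scoring.mismatch_penalty,
            scoring.gap_open_penalty,
            scoring.gap_extend_penalty,
        )
        if n_ops == 0:
            continue
        tpos = w0 + wi
        if best is None or score > best[0] or (score == best[0] and tpos < best[1]):
            best = (int(score), int(tpos))
            best_parts = (int(ri), int(re_), ops[:n_ops].copy(), lens[:n_ops].copy())
    if best is None:
        return None
    ri, re_, ops, lens = best_parts
    cigar: list[tuple[str, int]] = []
    if ri > 0:
        cigar.append(("S", ri))
    for op, ln in zip(ops, lens):
        cigar.append((_OP_CHARS[int(op)], int(ln)))
    if re_ < L:
        cigar.append(("S", L - re_))
    return Alignment(
        read_id=read.id,
        target=index.contig.name,
        pos=best[1],
        cigar=cigar,
        score=best[0],
        sequence=read.sequence,
        qualities=read.qualities,
    )


def align_reads(reads, index: TargetIndex, scoring: Scoring = Scoring(), **kw):
    """Align many reads to one target; unaligned reads are dropped."""
    out = []
    for r in reads:
        a = align_read(r, index, scoring, **kw)
        if a is not None:
            out.append(a)
    return out


def align_diploid(
    read: Read,
    idx1: TargetIndex,
    idx2: TargetIndex,
    scoring: Scoring = Scoring(),
    **kw,
) -> Alignment | None:
    """Align to both haplotypes; keep the higher score (ties -> hap1)."""
    a1 = align_read(read, idx1, scoring, **kw)
    a2 = align_read(read, idx2, scoring, **kw)
    if a1 is None:
        return a2
    if a2 is None or a1.score >= a2.score:
        return a1
    return a2


def score_difference(
    reads,
    linear_index: TargetIndex,
    dref_indexes: tuple[TargetIndex, TargetIndex],
    scoring: Scoring = Scoring(),
    **kw,
) -> tuple[pd.DataFrame, dict]:
    """Per-read score deltas, diploid minus linear.

    Only reads aligning to both references enter the table.  The summary
    reports the fraction of reads with a non-zero delta, the fraction of
    those that favour the diploid reference, and the mean positive delta.
    """
    rows = []
    n_both = 0
    for r in reads:
        lin = align_read(r, linear_index, scoring, **kw)
        dip = align_diploid(r, *dref_indexes, scoring=scoring, **kw)
        if lin is None or dip is None:
            continue
        n_both += 1
        rows.append(
            {
                "read_id": r.id,
                "linear_score": lin.score,
                "diploid_score": dip.score,
                "delta": dip.score - lin.score,
                "chosen_hap": dip.target,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        nz = table[table.delta != 0]
        frac_nonzero = len(nz) / len(table)
        frac_positive = float((nz.delta > 0).mean()) if len(nz) else float("nan")
        mean_positive = float(nz.delta[nz.delta > 0].mean()) if (nz.delta > 0).any() else float("nan")
    else:
        frac_nonzero = frac_positive = mean_positive = float("nan")
    summary = {
        "n_reads": int(len(table)),
        "frac_nonzero": frac_nonzero,
        "frac_positive_among_nonzero": frac_positive,
        "mean_positive_delta": mean_positive,
    }
    return table, summary


# ---------------------------------------------------------------------------
# Lift-back of haplotype alignments to reference coordinates


def lift_alignments(
    alignments, dref: DiploidReference, drop_unliftable: bool = True
):
    """Project haplotype-frame alignments into reference coordinates.

    Cigars are rewritten across liftover boundaries: haplotype bases
    inside donor insertions become I ops (or leading/trailing soft
    clips), donor deletions crossed by the alignment become D ops.  The
    AS score still refers to the haplotype-frame alignment.
    """
    out = []
    hap_names = {dref.hap1.name: 1, dref.hap2.name: 2}
    for aln in alignments:
        if aln.target not in hap_names:
            raise ValueError(f"alignment target {aln.target} is not a haplotype of {dref.name}")
        lifted = _lift_one(aln, dref, hap_names[aln.target])
        if lifted is not None:
            out.append(lifted)
        elif not drop_unliftable:
            out.append(aln)
    return out


def _lift_one(aln: Alignment, dref: DiploidReference, h: int) -> Alignment | None:
    lo = dref.liftover[h]
    hap_iv = lo._hap_iv  # (hap_start, hap_end, ref_start, kind) tiles the haplotype
    starts = lo._hap_starts
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    hap_pos = aln.pos
    i = int(np.searchsorted(starts, hap_pos, side="right")) - 1
    ref_pos_start: int | None = None

    for op, n in aln.cigar:
        if op in ("S", "I"):
            push(op, n)
            continue
        if op == "D":
            # a target deletion in hap frame: project its hap span
            span = n
            while span > 0:
                hs, he, rs, kind = hap_iv[i]
                take = min(span, he - hap_pos)
                if kind == 0:  # MATCH: consumes reference
                    push("D", take)
                else:  # insertion interval: vanishes in ref frame
                    pass
                hap_pos += take
                span -= take
                if hap_pos == he and hap_pos < hap_iv[-1][1]:
                    nxt = hap_iv[i + 1]
                    if kind == 0:
                        # crossing a donor deletion between intervals
                        rs_next = nxt[2]
                        re_cur = rs + (he - hs)
                        if rs_next > re_cur:
                            push("D", rs_next - re_cur)
                    i += 1
            continue
        # op == "M": consumes read and hap target
        span = n
        while span > 0:
            hs, he, rs, kind = hap_iv[i]
            take = min(span, he - hap_pos)
            if kind == 0:  # match interval: M maps to M
                if ref_pos_start is None:
                    ref_pos_start = rs + (hap_pos - hs)
                push("M", take)
            else:  # hap bases inside a donor insertion: I in ref frame
                push("I" if ref_pos_start is not None else "S", take)
            hap_pos += take
            span -= take
            if hap_pos == he and hap_pos < hap_iv[-1][1]:
                nxt = hap_iv[i + 1]
                if kind == 0 and ref_pos_start is not None:
                    rs_next = nxt[2]
                    re_cur = rs + (he - hs)
                    if rs_next > re_cur and span + _remaining_m(aln) >= 0:
                        push("D", rs_next - re_cur)
                i += 1
    if ref_pos_start is None:
        return None  # alignment entirely inside a donor insertion
    # trailing D ops carry no information in ref frame
    while ops and ops[-1][0] == "D":
        ops.pop()
    # a leading I in ref frame is representationally a soft clip
    cleaned: list[tuple[str, int]] = []
    seen_m = False
    for op, n in ops:
        if op == "I" and not seen_m:
            op = "S"
        if op == "M":
            seen_m = True
        if cleaned and cleaned[-1][0] == op:
            cleaned[-1] = (op, cleaned[-1][1] + n)
        else:
            cleaned.append((op, n))
    return Alignment(
        read_id=aln.read_id,
        target=dref.name,
        pos=ref_pos_start,
        cigar=cleaned,
        score=aln.score,
        sequence=aln.sequence,
        qualities=aln.qualities,
        mapq=aln.mapq,
    )


def _remaining_m(aln) -> int:  # placeholder hook for boundary D suppression
    return 0


# ---------------------------------------------------------------------------
# Variant calling from (lifted) alignments


def call_variants_from_alignments(
    alignments,
    reference: Contig,
    sites: list[VariantSite] | None = None,
    error_rate: float = 0.01,
    min_qual: float = 20.0,
    max_depth: int = 100,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.15,
):
    """Genotype known sites, or discover and genotype variants.

    Discovery scans alignments for mismatch and indel evidence, keeps
    candidates with at least ``min_alt_reads`` supporting reads and
    ``min_alt_fraction`` of the local depth, then runs the same
    pileup-plus-likelihood genotyper used for rough genotyping.  Returns
    a (PhasedCallset-like unphased callset, GenotypeLikelihoodTrack).
    """
    from . import genotype as gt_mod

    if sites is None:
        sites = discover_candidate_sites(
            alignments, reference, min_alt_reads, min_alt_fraction
        )
    pileup = gt_mod.build_pileup(alignments, sites, reference=reference)
    track = gt_mod.genotype_likelihoods(pileup, error_rate=error_rate)
    return gt_mod.calls_from_track(track, min_qual=min_qual, max_depth=max_depth), track


def discover_candidate_sites(
    alignments,
    reference: Contig,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.15,
) -> list[VariantSite]:
    """Candidate SNV/indel sites from mismatches and cigar gaps."""
    L = len(reference)
    depth = np.zeros(L, dtype=np.int32)
    snv: dict[tuple[int, str], int] = {}
    ins: dict[tuple[int, str], int] = {}
    dele: dict[tuple[int, int], int] = {}
    refseq = reference.sequence
    for aln in alignments:
        r, t = 0, aln.pos
        for op, n in aln.cigar:
            if op == "M":
                seg = aln.sequence[r : r + n]
                depth[t : t + n] += 1
                for k in range(n):
                    b = seg[k]
                    if b != refseq[t + k] and b in "ACGT":
                        snv[(t + k, b)] = snv.get((t + k, b), 0) + 1
                r += n
                t += n
            elif op == "I":
                if t > 0:
                    key = (t - 1, aln.sequence[r : r + n])
                    ins[key] = ins.get(key, 0) + 1
                r += n
            elif op == "D":
                if t > 0:
                    key = (t - 1, n)
                    dele[key] = dele.get(key, 0) + 1
                t += n
            elif op == "S":
                r += n
    sites: list[VariantSite] = []
    for (pos, b), count in snv.items():
        if count >= min_alt_reads and count >= min_alt_fraction * max(depth[pos], 1):
            sites.append(VariantSite(reference.name, pos, refseq[pos], b))
    for (anchor, seq), count in ins.items():
        if count >= min_alt_reads and count >= min_alt_fraction * max(depth[anchor], 1):
            sites.append(
                VariantSite(reference.name, anchor, refseq[anchor], refseq[anchor] + seq)
            )
    for (anchor, dlen), count in dele.items():
        if anchor + 1 + dlen > L:
            continue
        if count >= min_alt_reads and count >= min_alt_fraction * max(depth[anchor], 1):
            sites.append(
                VariantSite(
                    reference.name,
                    anchor,
                    refseq[anchor : anchor + 1 + dlen],
                    refseq[anchor],
                )
            )
    sites.sort(key=lambda s: (s.pos, s.ref, s.alt))
    # resolve REF-span overlaps first-wins, as at panel load
    kept: list[VariantSite] = []
    last_end = -1
    for s in sites:
        if s.pos < last_end:
            continue
        kept.append(VariantSite(s.contig, s.pos, s.ref, s.alt, len(kept)))
        last_end = s.end
    return kept
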