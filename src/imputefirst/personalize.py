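"""Personalized reference construction.

Two products from a phased callset: (a) a diploid consensus FASTA — the
reference with each haplotype's ALT alleles applied — carrying exact
bidirectional reference<->haplotype coordinate maps, and (b) a personal
variation graph in which homozygous-ALT calls are substituted into the
backbone in place and each heterozygous call becomes a two-allele
bubble.

Overlap policy: variants are applied first-wins by position; a variant
whose REF span overlaps an already-applied one on the same haplotype is
skipped with a warning (the behaviour consensus tools inherit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .formats import Contig, PhasedCallset, ReferencePanel, VariantSite

__all__ = [
    "DiploidReference",
    "Liftover",
    "DeletedPosition",
    "PersonalGraph",
    "build_diploid_fasta",
    "lift_position",
    "inverse_lift_position",
    "build_personal_graph",
    "graph_stats",
    "panel_bubble_callset",
]

MATCH, INS, DEL = 0, 1, 2


class DeletedPosition(NamedTuple):
    """Marker for a reference position absent from a haplotype."""

    ref_anchor: int  # last surviving reference position to the left
    hap_anchor: int  # its coordinate on the haplotype


class Liftover:
    """Bidirectional coordinate map between a reference and one haplotype.

    Built from an ordered list of interval records (ref_start, ref_end,
    hap_start, hap_end, kind); match intervals map by offset, deletions
    consume reference only, insertions consume haplotype only.
    """

    def __init__(self, intervals: list[tuple[int, int, int, int, int]]) -> None:
        self.intervals = intervals
        ref_iv = [(rs, re, hs, k) for rs, re, hs, he, k in intervals if k != INS]
        hap_iv = [(hs, he, rs, k) for rs, re, hs, he, k in intervals if k != DEL]
        self._ref_starts = np.array([iv[0] for iv in ref_iv], dtype=np.int64)
        self._ref_iv = ref_iv
        self._hap_starts = np.array([iv[0] for iv in hap_iv], dtype=np.int64)
        self._hap_iv = hap_iv

    def lift(self, ref_pos: int):
        """Haplotype coordinate of ``ref_pos``, or a DeletedPosition."""
        i = int(np.searchsorted(self._ref_starts, ref_pos, side="right")) - 1
        if i < 0 or ref_pos >= self._ref_iv[i][1]:
            raise IndexError(f"reference position {ref_pos} out of range")
        rs, re, hs, kind = self._ref_iv[i]
        if kind == MATCH:
            return hs + (ref_pos - rs)
        return DeletedPosition(ref_anchor=rs - 1, hap_anchor=hs - 1)

    def lift_lower(self, ref_pos: int) -> int:
        """Haplotype coordinate of ``ref_pos``, collapsing deletions leftward.

        Accepts ``ref_pos`` one past the end (maps to haplotype length).
        """
        if self._ref_iv and ref_pos == self._ref_iv[-1][1]:
            last = self.intervals[-1]
            return last[3]
        out = self.lift(ref_pos)
        if isinstance(out, DeletedPosition):
            i = int(np.searchsorted(self._ref_starts, ref_pos, side="right")) - 1
            return self._ref_iv[i][2]  # hap_start of the deletion record
        return out

    def inverse(self, hap_pos: int) -> tuple[int, bool]:
        """(reference position, exact) for a haplotype coordinate.

        Positions interior to an insertion map to the insertion's left
        anchor with ``exact=False``.
        """
        i = int(np.searchsorted(self._hap_starts, hap_pos, side="right")) - 1
        if i < 0 or hap_pos >= self._hap_iv[i][1]:
            raise IndexError(f"haplotype position {hap_pos} out of range")
        hs, he, rs, kind = self._hap_iv[i]
        if kind == MATCH:
            return rs + (hap_pos - hs), True
        return rs - 1, False


@dataclass
class DiploidReference:
    """Two consensus haplotypes plus their liftover maps."""

    name: str
    hap1: Contig
    hap2: Contig
    liftover: dict[int, Liftover] = field(default_factory=dict)
    applied: dict[int, list[VariantSite]] = field(default_factory=dict)
    skipped: dict[int, list[VariantSite]] = field(default_factory=dict)

    def haplotype(self, h: int) -> Contig:
        return self.hap1 if h == 1 else self.hap2

    def extract(self, h: int, ref_start: int, ref_end: int) -> str:
        """Haplotype subsequence spelled by the reference interval.

        Deleted reference bases contribute nothing; insertions anchored
        strictly inside the interval are included.
        """
        lo = self.liftover[h]
        return self.haplotype(h).sequence[
            lo.lift_lower(ref_start) : lo.lift_lower(ref_end)
        ]


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _apply_variants(
    reference: Contig, sites: list[VariantSite], take: np.ndarray
) -> tuple[str, Liftover, list[VariantSite], list[VariantSite]]:
    seq = reference.sequence
    parts: list[str] = []
    intervals: list[tuple[int, int, int, int, int]] = []
    cursor = 0  # reference
    hap_cursor = 0
    applied: list[VariantSite] = []
    skipped: list[VariantSite] = []

    def emit_match(ref_to: int) -> None:
        nonlocal cursor, hap_cursor
        if ref_to > cursor:
            n = ref_to - cursor
            parts.append(seq[cursor:ref_to])
            _push(cursor, ref_to, hap_cursor, hap_cursor + n, MATCH)
            cursor = ref_to
            hap_cursor += n

    def _push(rs, re, hs, he, kind) -> None:
        # merge adjacent match intervals
        if kind == MATCH and intervals and intervals[-1][4] == MATCH and intervals[-1][1] == rs:
            prs, pre, phs, phe, _ = intervals[-1]
            intervals[-1] = (prs, re, phs, he, MATCH)
        else:
            intervals.append((rs, re, hs, he, kind))

    for site, use in zip(sites, take):
        if not use:
            continue
        if site.pos < cursor:
            warnings.warn(
                f"{site.contig}:{site.pos + 1}: REF span overlaps an applied "
                "variant; skipped (first-wins)"
            )
            skipped.append(site)
            continue
        if seq[site.pos : site.end] != site.ref:
            raise ValueError(
                f"{site.contig}:{site.pos + 1}: REF allele {site.ref!r} does not "
                f"match reference sequence {seq[site.pos:site.end]!r}"
            )
        cp = _common_prefix_len(site.ref, site.alt)
        emit_match(site.pos + cp)
        r_tail, a_tail = site.ref[cp:], site.alt[cp:]
        if r_tail and a_tail and len(r_tail) == len(a_tail):
            # substitution: same span, different bases; still a match interval
            parts.append(a_tail)
            _push(cursor, cursor + len(r_tail), hap_cursor, hap_cursor + len(a_tail), MATCH)
            cursor += len(r_tail)
            hap_cursor += len(a_tail)
        else:
            if r_tail:
                _push(cursor, cursor + len(r_tail), hap_cursor, hap_cursor, DEL)
                cursor += len(r_tail)
            if a_tail:
                parts.append(a_tail)
                _push(cursor, cursor, hap_cursor, hap_cursor + len(a_tail), INS)
                hap_cursor += len(a_tail)
        applied.append(site)
    emit_match(len(seq))
    return "".join(parts), Liftover(intervals), applied, skipped


def build_diploid_fasta(reference: Contig, callset: PhasedCallset) -> DiploidReference:
    """Apply each haplotype's ALT alleles to the reference.

    Haplotype h receives every variant whose phase-h allele is ALT;
    overlapping REF spans are resolved first-wins with a warning.
    """
    callset.check_sorted()
    out = DiploidReference(name=reference.name, hap1=None, hap2=None)  # type: ignore[arg-type]
    haps = {}
    for h in (1, 2):
        take = callset.genotypes[:, h - 1].astype(bool)
        seq, lo, applied, skipped = _apply_variants(reference, callset.sites, take)
        haps[h] = Contig(f"{reference.name}_hap{h}", seq)
        out.liftover[h] = lo
        out.applied[h] = applied
        out.skipped[h] = skipped
    out.hap1, out.hap2 = haps[1], haps[2]
    return out


def lift_position(dref: DiploidReference, haplotype: int, ref_pos: int):
    """Reference -> haplotype coordinate (or DeletedPosition)."""
    return dref.liftover[haplotype].lift(ref_pos)


def inverse_lift_position(
    dref: DiploidReference, haplotype: int, hap_pos: int
) -> tuple[int, bool]:
    """Haplotype -> reference coordinate; insertion interiors anchor left."""
    return dref.liftover[haplotype].inverse(hap_pos)


# ---------------------------------------------------------------------------
# Personal variation graph


@dataclass
class PersonalGraph:
    """Sequence-labelled DAG for one contig.

    ``backbone_path`` spells the reference-with-hom-ALT backbone;
    ``hap_paths`` spell the two consensus haplotypes.
    """

    contig: str
    nodes: list[tuple[int, str]]
    edges: list[tuple[int, int]]
    backbone_path: list[int]
    hap_paths: tuple[list[int], list[int]]

    def spell(self, path: list[int]) -> str:
        label = {nid: lab for nid, lab in self.nodes}
        return "".join(label[n] for n in path)

    def to_gfa(self) -> str:
        lines = ["H\tVN:Z:1.0"]
        for nid, lab in self.nodes:
            lines.append(f"S\t{nid}\t{lab}")
        for u, v in self.edges:
            lines.append(f"L\t{u}\t+\t{v}\t+\t0M")
        for name, path in (
            ("backbone", self.backbone_path),
            ("hap1", self.hap_paths[0]),
            ("hap2", self.hap_paths[1]),
        ):
            lines.append(
                f"P\t{self.contig}_{name}\t" + ",".join(f"{n}+" for n in path) + "\t*"
            )
        return "\n".join(lines) + "\n"


def build_personal_graph(reference: Contig, callset: PhasedCallset) -> PersonalGraph:
    """Backbone with hom-ALT substitutions; HET calls become bubbles.

    A HET SNV yields two single-base allele nodes (anchor bases join the
    left flank); a HET insertion keeps a one-base left anchor inside both
    allele nodes so neither is empty; a HET pure deletion uses a direct
    flank-to-flank edge around the deleted-sequence node.
    """
    callset.check_sorted()
    seq = reference.sequence
    nodes: list[tuple[int, str]] = []
    edges: list[tuple[int, int]] = []
    backbone: list[int] = []
    hap_paths: tuple[list[int], list[int]] = ([], [])

    pending: list[str] = []  # label parts of the flank node being built
    # allele nodes of the previous bubble waiting for the next flank
    dangling: list[tuple[int, tuple[bool, bool]]] = []

    def new_node(label: str) -> int:
        nid = len(nodes) + 1
        nodes.append((nid, label))
        return nid

    def close_flank() -> None:
        """Finish the pending flank node and wire dangling bubble arms."""
        nonlocal pending, dangling
        label = "".join(pending)
        pending = []
        if not label:
            if dangling or not nodes:
                raise ValueError(
                    "adjacent variants leave an empty flank; graph construction "
                    "requires >= 1 backbone base between heterozygous sites"
                )
            return
        nid = new_node(label)
        for src, _ in dangling:
            edges.append((src, nid))
        backbone.append(nid)
        for hp in hap_paths:
            hp.append(nid)
        dangling = []

    cursor = 0
    for j, site in enumerate(callset.sites):
        g = tuple(int(a) for a in callset.genotypes[j])
        if g == (0, 0):
            continue
        if site.pos < cursor:
            if g[0] != g[1]:
                raise ValueError(
                    f"{site.contig}:{site.pos + 1}: overlapping heterozygous "
                    "variant reached graph construction"
                )
            warnings.warn(
                f"{site.contig}:{site.pos + 1}: overlapping hom-ALT skipped in graph"
            )
            continue
        if seq[site.pos : site.end] != site.ref:
            raise ValueError(
                f"{site.contig}:{site.pos + 1}: REF allele mismatch in graph build"
            )
        if g == (1, 1):
            pending.append(seq[cursor : site.pos])
            pending.append(site.alt)
            cursor = site.end
            continue
        # heterozygous bubble
        cp = _common_prefix_len(site.ref, site.alt)
        r_tail, a_tail = site.ref[cp:], site.alt[cp:]
        if r_tail and a_tail:
            flank_end = site.pos + cp
            ref_label, alt_label = r_tail, a_tail
        elif not a_tail:  # pure deletion: anchor joins flank, ALT arm is an edge
            flank_end = site.pos + cp
            ref_label, alt_label = r_tail, None
        else:  # pure insertion: keep one-base anchor inside both allele nodes
            flank_end = site.pos + cp - 1
            ref_label, alt_label = site.ref[cp - 1 :], site.alt[cp - 1 :]
        pending.append(seq[cursor:flank_end])
        close_flank()
        left = backbone[-1]
        ref_node = new_node(ref_label)
        edges.append((left, ref_node))
        if alt_label is None:
            alt_node = None
            # flank-to-flank edge added when the right flank closes
            dangling.append((ref_node, (False, False)))
            dangling.append((left, (False, False)))
        else:
            alt_node = new_node(alt_label)
            edges.append((left, alt_node))
            dangling.append((ref_node, (False, False)))
            dangling.append((alt_node, (False, False)))
        backbone.append(ref_node)
        for h in (0, 1):
            arm = ref_node if g[h] == 0 else alt_node
            if arm is not None:
                hap_paths[h].append(arm)
        cursor = site.end
    pending.append(seq[cursor:])
    close_flank()
    if dangling:
        raise ValueError("graph ended inside a bubble")
    # deduplicate edges (pure-deletion arms can duplicate flank links)
    edges_unique = sorted(set(edges))
    return PersonalGraph(
        contig=reference.name,
        nodes=nodes,
        edges=edges_unique,
        backbone_path=backbone,
        hap_paths=hap_paths,
    )


def graph_stats(g: PersonalGraph) -> tuple[int, int, int]:
    """(n_nodes, n_edges, total label length)."""
    return (len(g.nodes), len(g.edges), sum(len(lab) for _, lab in g.nodes))


def panel_bubble_callset(panel: ReferencePanel) -> PhasedCallset:
    """Every panel site as a heterozygous bubble.

    This is how a pangenome graph built from the full panel VCF treats
    variation: the reference path plus an alternate path at every
    record, regardless of panel allele frequency.
    """
    gts = np.tile(np.array([[0, 1]], dtype=np.uint8), (len(panel.sites), 1))
    return PhasedCallset(list(panel.sites), gts)
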