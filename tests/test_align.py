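"""Seed-and-extend aligner: hand-scored cases, full-DP oracle
equivalence, haplotype-max selection, lift-back, and re-calling."""

import numpy as np
import pytest

from imputefirst import align as al
from imputefirst import personalize as pz
from imputefirst.formats import Contig, PhasedCallset, Read, VariantSite
from imputefirst.simulate import (
    SimConfig,
    TruthSet,
    parse_read_origin,
    simulate_donor,
    simulate_panel,
    simulate_reads,
)

from conftest import random_contig


def full_smith_waterman(read: str, target: str, sc: al.Scoring) -> int:
    """Plain O(nm) affine-gap local alignment score (independent oracle)."""
    n, m = len(read), len(target)
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    go = sc.gap_open_penalty + sc.gap_extend_penalty
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - sc.gap_extend_penalty)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - sc.gap_extend_penalty)
            s = sc.match if read[i - 1] == target[j - 1] else -sc.mismatch_penalty
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return int(best)


def _q(n):
    return np.full(n, 30, dtype=np.int16)


def rescore(aln: al.Alignment, target: Contig, sc: al.Scoring) -> int:
    score = 0
    r, t = 0, aln.pos
    for op, n in aln.cigar:
        if op == "M":
            for k in range(n):
                score += (
                    sc.match
                    if aln.sequence[r + k] == target.sequence[t + k]
                    else -sc.mismatch_penalty
                )
            r += n
            t += n
        elif op in ("I", "D"):
            score -= sc.gap_open_penalty + n * sc.gap_extend_penalty
            if op == "I":
                r += n
            else:
                t += n
        elif op == "S":
            r += n
    return score


@pytest.fixture(scope="module")
def target():
    return random_contig(np.random.default_rng(1), 5_000, "ref")


@pytest.fixture(scope="module")
def index(target):
    return al.TargetIndex(target)


class TestHandScored:
    def test_perfect_match(self, target, index):
        a = al.align_read(Read("r", target.sequence[1000:1100], _q(100)), index)
        assert (a.score, a.pos, a.cigar_string()) == (100, 1000, "100M")

    def test_one_central_mismatch(self, target, index):
        s = list(target.sequence[1000:1100])
        s[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[50]]
        a = al.align_read(Read("r", "".join(s), _q(100)), index)
        assert a.score == 95  # 99 matches - 4

    def test_one_base_insertion(self, target, index):
        s = target.sequence[1000:1050] + "X" + target.sequence[1050:1099]
        # use a base guaranteed different from the next target base
        nxt = target.sequence[1050]
        s = s.replace("X", {"A": "C", "C": "G", "G": "T", "T": "A"}[nxt])
        a = al.align_read(Read("r", s, _q(100)), index)
        assert a.score == 92  # 99 matches - (6 + 1)

    def test_no_seed_unaligned(self, index):
        a = al.align_read(Read("r", "A" * 50, _q(50)), index)
        assert a is None or a.score < 30


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(40))
    def test_windowed_dp_equals_full_sw(self, trial):
        """Scores match an unbanded Smith–Waterman on short instances."""
        rng = np.random.default_rng(trial)
        target = random_contig(rng, int(rng.integers(120, 200)), "t")
        # read: a mutated substring of the target
        start = int(rng.integers(0, len(target) - 60))
        read = list(target.sequence[start : start + 60])
        for _ in range(int(rng.integers(0, 4))):
            kind = rng.random()
            p = int(rng.integers(5, len(read) - 5))
            if kind < 0.6:
                read[p] = "ACGT"[int(rng.integers(4))]
            elif kind < 0.8:
                read.insert(p, "ACGT"[int(rng.integers(4))])
            else:
                del read[p]
        read = "".join(read)
        sc = al.Scoring()
        idx = al.TargetIndex(target, k=11)
        a = al.align_read(Read("r", read, _q(len(read))), idx, sc, band_pad=32)
        expect = full_smith_waterman(read, target.sequence, sc)
        if a is None:
            assert expect < 11  # nothing seedable
        else:
            assert a.score == expect

    def test_emitted_cigar_rescores_exactly(self, target, index, small_world):
        ref, _, truth, reads = small_world
        idx = al.TargetIndex(ref)
        sc = al.Scoring()
        for r in reads[:300]:
            a = al.align_read(r, idx, sc)
            if a is None:
                continue
            assert rescore(a, ref, sc) == a.score
            assert a.read_length() == len(r)


@pytest.fixture(scope="module")
def het_world():
    rng = np.random.default_rng(8)
    ref = random_contig(rng, 4_000, "c")
    site = VariantSite(
        "c", 2_000, ref.sequence[2_000],
        {"A": "C", "C": "G", "G": "T", "T": "A"}[ref.sequence[2_000]], 0,
    )
    cs = PhasedCallset([site], np.array([[0, 1]], dtype=np.uint8))
    dref = pz.build_diploid_fasta(ref, cs)
    return ref, site, dref


class TestDiploid:
    def test_variant_free_read_ties_to_hap1(self, het_world):
        ref, site, dref = het_world
        i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
        read = Read("r", ref.sequence[100:200], _q(100))
        a = al.align_diploid(read, i1, i2)
        assert a.target == dref.hap1.name

    def test_alt_read_wins_by_five(self, het_world):
        ref, site, dref = het_world
        i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
        lin = al.TargetIndex(ref)
        read = Read("r", dref.hap2.sequence[1_950:2_050], _q(100))
        dip = al.align_diploid(read, i1, i2)
        assert dip.target == dref.hap2.name and dip.score == 100
        assert al.align_read(read, lin).score == 95

    def test_diploid_dominates_linear_on_donor_reads(self, small_world):
        """Error-free donor reads: diploid score >= linear, strictly
        iff the read's source haplotype differs from the reference
        inside the read span."""
        ref, panel, truth, _ = small_world
        cfg = SimConfig(genome_length=30_000, coverage=2.0, error_rate=0.0, seed=6)
        reads = simulate_reads(truth, cfg, seed=7)
        dref = pz.build_diploid_fasta(ref, truth.truth_callset)
        lin = al.TargetIndex(ref)
        i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
        haps = {1: dref.hap1, 2: dref.hap2}
        for r in reads:
            a = al.align_read(r, lin)
            d = al.align_diploid(r, i1, i2)
            assert d is not None and d.score == len(r)
            if a is None:
                continue
            assert d.score >= a.score
            h, start = parse_read_origin(r.id)
            lo = dref.liftover[h]
            span_differs = (
                haps[h].sequence[start : start + len(r)]
                != _ref_projection(ref, lo, start, len(r))
            )
            assert (d.score > a.score) == span_differs, r.id


def _ref_projection(ref: Contig, lo: pz.Liftover, hap_start: int, length: int) -> str:
    """Reference bases facing the haplotype interval [start, start+len)."""
    r0, _ = lo.inverse(hap_start)
    r1, _ = lo.inverse(hap_start + length - 1)
    return ref.sequence[r0 : r1 + 1]


class TestScoreDifference:
    def test_empty_callset_all_zero(self, small_world):
        ref, _, truth, _ = small_world
        cs = PhasedCallset([], np.zeros((0, 2)))
        dref = pz.build_diploid_fasta(ref, cs)
        cfg = SimConfig(genome_length=30_000, coverage=0.5, error_rate=0.0, seed=3)
        reads = simulate_reads(
            TruthSet(ref, ref.sequence, ref.sequence, cs, np.zeros((2, 0))), cfg
        )
        table, summary = al.score_difference(
            reads,
            al.TargetIndex(ref),
            (al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)),
        )
        assert (table.delta == 0).all()
        assert summary["frac_nonzero"] == 0.0

    def test_summary_consistent_with_table(self, small_world):
        ref, panel, truth, _ = small_world
        dref = pz.build_diploid_fasta(ref, truth.truth_callset)
        cfg = SimConfig(genome_length=30_000, coverage=1.0, error_rate=0.0, seed=5)
        reads = simulate_reads(truth, cfg, seed=11)
        table, summary = al.score_difference(
            reads,
            al.TargetIndex(ref),
            (al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)),
        )
        nz = table[table.delta != 0]
        assert summary["frac_nonzero"] == pytest.approx(len(nz) / len(table))
        if len(nz):
            assert summary["frac_positive_among_nonzero"] == pytest.approx(
                (nz.delta > 0).mean()
            )
            assert summary["mean_positive_delta"] == pytest.approx(
                nz.delta[nz.delta > 0].mean()
            )
        assert (nz.delta >= 0).all()  # error-free donor reads


class TestLiftBack:
    def test_identity_without_variants(self):
        rng = np.random.default_rng(2)
        ref = random_contig(rng, 2_000, "c")
        dref = pz.build_diploid_fasta(ref, PhasedCallset([], np.zeros((0, 2))))
        aln = al.Alignment("r", dref.hap1.name, 500, [("M", 100)], 100, "A" * 100)
        (lifted,) = al.lift_alignments([aln], dref)
        assert (lifted.pos, lifted.cigar) == (500, [("M", 100)])
        assert lifted.target == "c"

    def test_position_shift_after_deletion(self):
        ref = Contig("c", "A" * 300)
        cs = PhasedCallset([VariantSite("c", 9, "AAA", "A", 0)], np.array([[1, 1]]))
        dref = pz.build_diploid_fasta(ref, cs)
        aln = al.Alignment("r", dref.hap1.name, 98, [("M", 50)], 50, "A" * 50)
        (lifted,) = al.lift_alignments([aln], dref)
        assert lifted.pos == 100

    def test_read_spanning_donor_insertion_gets_I(self):
        ref = Contig("c", "ACGTACGTACGTACGTACGT")
        cs = PhasedCallset([VariantSite("c", 9, "C", "CTT", 0)], np.array([[1, 1]]))
        dref = pz.build_diploid_fasta(ref, cs)
        read_seq = dref.hap1.sequence[5:17]
        aln = al.Alignment("r", dref.hap1.name, 5, [("M", 12)], 12, read_seq)
        (lifted,) = al.lift_alignments([aln], dref)
        assert lifted.pos == 5
        assert lifted.cigar == [("M", 5), ("I", 2), ("M", 5)]

    def test_read_starting_inside_insertion_is_clipped(self):
        ref = Contig("c", "ACGTACGTACGTACGTACGT")
        cs = PhasedCallset([VariantSite("c", 9, "C", "CTTTT", 0)], np.array([[1, 1]]))
        dref = pz.build_diploid_fasta(ref, cs)
        read_seq = dref.hap1.sequence[11:21]
        aln = al.Alignment("r", dref.hap1.name, 11, [("M", 10)], 10, read_seq)
        (lifted,) = al.lift_alignments([aln], dref)
        assert lifted.cigar[0][0] == "S"
        assert lifted.pos == 10  # first reference-mapped base

    def test_round_trip_matches_truth_origin(self, small_world):
        """Lifted positions of error-free reads equal the reference
        projection of their recorded origin."""
        ref, panel, truth, _ = small_world
        cfg = SimConfig(genome_length=30_000, coverage=2.0, error_rate=0.0, seed=8)
        reads = simulate_reads(truth, cfg, seed=9)
        dref = pz.build_diploid_fasta(ref, truth.truth_callset)
        i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
        checked = 0
        for r in reads:
            h, start = parse_read_origin(r.id)
            idx = i1 if h == 1 else i2
            a = al.align_read(r, idx)
            assert a is not None and a.pos == start and a.score == len(r)
            (lifted,) = al.lift_alignments([a], dref)
            r0, exact = dref.liftover[h].inverse(start)
            if not exact:
                continue  # read starts inside a donor insertion
            assert lifted.pos == r0
            checked += 1
        assert checked > 100


class TestCalling:
    def test_zero_coverage_no_calls(self):
        ref = Contig("c", "A" * 1000)
        calls, _ = al.call_variants_from_alignments([], ref)
        assert calls.n_sites == 0

    def test_known_variants_recovered_at_depth(self):
        cfg = SimConfig(
            genome_length=100_000,
            n_sites=20,
            n_haplotypes=6,
            coverage=30.0,
            error_rate=0.0,
            seed=12,
        )
        ref, panel = simulate_panel(cfg)
        truth = simulate_donor(ref, panel, cfg)
        reads = simulate_reads(truth, cfg)
        dref = pz.build_diploid_fasta(ref, truth.truth_callset)
        i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
        dip = [a for a in (al.align_diploid(r, i1, i2) for r in reads) if a]
        lifted = sorted(al.lift_alignments(dip, dref), key=lambda a: a.pos)
        # min_qual=0: this checks genotype recovery; the QUAL emission
        # filter (which can drop sites with unlucky allele sampling) has
        # its own tests
        calls, _ = al.call_variants_from_alignments(
            lifted, ref, sites=panel.sites, min_qual=0.0
        )
        truth_dosage = truth.truth_callset.dosage()
        call_dosage = dict(
            zip([s.key() for s in calls.sites], calls.genotypes.sum(axis=1))
        )
        for s, td in zip(panel.sites, truth_dosage):
            assert call_dosage.get(s.key(), 0) == td, s

    def test_discovery_mode_finds_planted_variants(self):
        cfg = SimConfig(
            genome_length=50_000,
            n_sites=12,
            n_haplotypes=4,
            coverage=30.0,
            error_rate=0.0,
            seed=21,
        )
        ref, panel = simulate_panel(cfg)
        truth = simulate_donor(ref, panel, cfg)
        reads = simulate_reads(truth, cfg)
        dref = pz.build_diploid_fasta(ref, truth.truth_callset)
        i1, i2 = al.TargetIndex(dref.hap1), al.TargetIndex(dref.hap2)
        dip = [a for a in (al.align_diploid(r, i1, i2) for r in reads) if a]
        lifted = sorted(al.lift_alignments(dip, dref), key=lambda a: a.pos)
        calls, _ = al.call_variants_from_alignments(lifted, ref, sites=None)
        called = {s.key() for s in calls.sites}
        carried = {
            s.key()
            for s, g in zip(panel.sites, truth.truth_callset.genotypes)
            if g.sum() > 0
        }
        assert carried <= called
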