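"""Evaluation metrics: allele- and HET-level precision/recall, window
accuracy with density strata, allelic balance by allele length, and
report assembly.

Allele-level classification treats each diploid call as two allele
calls: a called ALT with at least one true ALT is a TP, a called REF
with at least one true REF is a TN, a called ALT against a true hom-REF
is an FP, and a called REF against a true hom-ALT is an FN.  The HET
class scores called-HET vs truly-HET per site.  Phase is deliberately
ignored here; short-range phasing is what window accuracy measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .formats import Alignment, PhasedCallset, VariantSite
from .genotype import classify_read_at_site
from .personalize import DiploidReference

__all__ = [
    "ClassMetrics",
    "EvaluationReport",
    "allele_accuracy",
    "window_accuracy",
    "allelic_balance",
    "assemble_report",
    "WINDOW_STRATA",
]

WINDOW_STRATA = ("1-5", "6-10", "11+")


@dataclass
class ClassMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if not (p + r) or np.isnan(p) or np.isnan(r):
            return float("nan")
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def allele_accuracy(
    calls: PhasedCallset, truth: PhasedCallset
) -> tuple[ClassMetrics, ClassMetrics]:
    """(allele-level metrics, HET-level metrics) against a truth callset.

    The truth callset defines the site universe; sites it lacks a call
    for are an error, and sites missing from ``calls`` count as hom-REF
    (imputation emits every panel site, so this only matters for rough
    calls).
    """
    truth_idx = {s.key(): j for j, s in enumerate(truth.sites)}
    call_gt: dict = {}
    for j, s in enumerate(calls.sites):
        if s.key() not in truth_idx:
            raise ValueError(
                f"called site {s.contig}:{s.pos + 1} {s.ref}>{s.alt} is outside "
                "the truth site universe"
            )
        call_gt[s.key()] = calls.genotypes[j]
    allele = ClassMetrics()
    het = ClassMetrics()
    for j, s in enumerate(truth.sites):
        t = truth.genotypes[j]
        c = call_gt.get(s.key(), np.zeros(2, dtype=np.uint8))
        t_alt = int(t.sum())
        for a in c:
            if a == 1:
                if t_alt >= 1:
                    allele.tp += 1
                else:
                    allele.fp += 1
            else:
                if t_alt <= 1:
                    allele.tn += 1
                else:
                    allele.fn += 1
        c_het = c[0] != c[1]
        t_het = t[0] != t[1]
        if c_het and t_het:
            het.tp += 1
        elif c_het and not t_het:
            het.fp += 1
        elif t_het and not c_het:
            het.fn += 1
        else:
            het.tn += 1
    return allele, het


def window_accuracy(
    test: DiploidReference,
    truth: DiploidReference,
    panel_sites: list[VariantSite],
    window: int = 200,
) -> dict:
    """Fraction of pivot-anchored windows whose diploid sequence matches.

    For each panel site (the pivot), the window spans the pivot's REF
    span plus ``window`` bp of left flank.  The two truth-haplotype
    window sequences are compared with the two test-haplotype sequences
    as unordered pairs, so global haplotype labelling does not matter
    but any wrong genotype or local switch error in the window fails it.
    Results are stratified by the number of panel sites in the window.
    """
    positions = np.array([s.pos for s in panel_sites], dtype=np.int64)
    order = np.argsort(positions, kind="stable")
    sorted_pos = positions[order]
    counts = {k: [0, 0] for k in WINDOW_STRATA + ("overall",)}
    per_pivot = []
    for s in panel_sites:
        lo, hi = max(0, s.pos - window), s.end
        truth_pair = frozenset(
            (truth.extract(1, lo, hi), truth.extract(2, lo, hi))
        )
        test_pair = frozenset((test.extract(1, lo, hi), test.extract(2, lo, hi)))
        ok = truth_pair == test_pair
        n_in = int(
            np.searchsorted(sorted_pos, s.pos, side="right")
            - np.searchsorted(sorted_pos, lo, side="left")
        )
        stratum = "1-5" if n_in <= 5 else ("6-10" if n_in <= 10 else "11+")
        for key in (stratum, "overall"):
            counts[key][0] += int(ok)
            counts[key][1] += 1
        per_pivot.append((s.pos, n_in, ok))
    out = {
        k: (m / n if n else float("nan")) for k, (m, n) in counts.items()
    }
    out["n_windows"] = {k: n for k, (_, n) in counts.items()}
    out["per_pivot"] = per_pivot
    return out


def allelic_balance(
    alignments: list[Alignment],
    het_sites: list[VariantSite],
    reference=None,
    min_baseq: int = 13,
) -> pd.DataFrame:
    """Per-category median allelic balance at heterozygous sites.

    Balance is ALT-carrying / (ALT- + REF-carrying) reads overlapping
    the site; 'other' reads are excluded from the denominator.  The
    category is the signed allele-length difference (insertions
    positive, deletions negative, SNVs zero).  Sites with zero
    informative reads are excluded from medians and counted separately.
    """
    rows = []
    aln_starts = np.array([a.pos for a in alignments], dtype=np.int64)
    aln_order = np.argsort(aln_starts, kind="stable")
    sorted_alns = [alignments[i] for i in aln_order]
    sorted_starts = aln_starts[aln_order]
    max_read_span = max((a.target_end() - a.pos for a in alignments), default=0)
    for s in het_sites:
        lo = int(np.searchsorted(sorted_starts, s.pos - max_read_span, side="left"))
        hi = int(np.searchsorted(sorted_starts, s.end, side="left"))
        n_ref = n_alt = 0
        for a in sorted_alns[lo:hi]:
            cls = classify_read_at_site(a, s, reference, min_baseq)
            if cls == "ref":
                n_ref += 1
            elif cls == "alt":
                n_alt += 1
        informative = n_ref + n_alt
        rows.append(
            {
                "pos": s.pos,
                "category": s.indel_length,
                "n_ref": n_ref,
                "n_alt": n_alt,
                "balance": n_alt / informative if informative else np.nan,
            }
        )
    per_site = pd.DataFrame(rows)
    if per_site.empty:
        return pd.DataFrame(
            columns=["category", "median_balance", "n_sites", "n_uninformative"]
        )
    grp = per_site.groupby("category")
    table = pd.DataFrame(
        {
            "median_balance": grp["balance"].median(),
            "n_sites": grp["balance"].count(),
            "n_uninformative": grp["balance"].apply(lambda b: int(b.isna().sum())),
        }
    ).reset_index()
    table.attrs["per_site"] = per_site.to_dict(orient="records")
    return table


@dataclass
class EvaluationReport:
    """Machine-readable bundle of all evaluation products for one run."""

    run_id: str
    alt_metrics: dict
    het_metrics: dict
    window_accuracy: dict | None = None
    balance_table: list | None = None
    score_delta_summary: dict | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(**d)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return list(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def assemble_report(
    run_id: str,
    allele: ClassMetrics,
    het: ClassMetrics,
    window: dict | None = None,
    balance: pd.DataFrame | None = None,
    score_delta: dict | None = None,
    parts_run_ids: list[str] | None = None,
    **extra,
) -> EvaluationReport:
    """Bundle metric parts into one report, re-deriving F1 as a check."""
    if parts_run_ids and any(r != run_id for r in parts_run_ids):
        raise ValueError(f"mismatched run ids: {parts_run_ids} vs {run_id}")
    for m in (allele, het):
        p, r = m.precision, m.recall
        if p + r > 0 and not np.isnan(p):
            expect = 2 * p * r / (p + r)
            if abs(expect - m.f1) > 1e-12:
                raise AssertionError("F1 inconsistent with precision/recall")
    win = None
    if window is not None:
        win = {k: v for k, v in window.items() if k != "per_pivot"}
    return EvaluationReport(
        run_id=run_id,
        alt_metrics=allele.as_dict(),
        het_metrics=het.as_dict(),
        window_accuracy=win,
        balance_table=(
            balance.to_dict(orient="records") if balance is not None else None
        ),
        score_delta_summary=score_delta,
        extra=extra,
    )
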