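"""Benchmarking semantics: confusion counts, metrics, cutoff search,
consensus filtering and sequence-context classification.

Matching is position-exact and requires agreement on allele, variant type,
zygosity and indel length; a call at a truth site that disagrees on any of
those counts as one false positive (the call) and one false negative (the
unmatched truth record), mirroring vcfeval-style accounting.  Indels
longer than ``max_indel`` (default 4 bp) are removed from both the truth
and the calls before counting, because exact alleles are only reported up
to that length.  True negatives are defined only in site-restricted mode,
where a fixed set of evaluated sites is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import TruthVariant

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


@dataclass
class MetricSet:
    """FPR, FNR, precision, recall, F1 as fractions in [0, 1].

    Zero-denominator metrics are defined as 0 and flagged ``degenerate``.
    """

    fpr: float
    fnr: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def as_percent(self) -> dict[str, float]:
        return {k: round(100.0 * getattr(self, k), 2)
                for k in ("fpr", "fnr", "precision", "recall", "f1")}


def _call_signature(c) -> tuple:
    """(type, zygosity, alt-or-length) agreement key for a call record."""
    zyg = c.zygosity if hasattr(c, "zygosity") else (
        "het" if c.is_het else "hom")
    vtype = c.var_type if hasattr(c, "var_type") else c.variant_type
    alt = c.alt
    length = c.indel_length
    return (vtype, zyg, alt, length)


def _indel_length(rec) -> int:
    if rec.alt.startswith("<"):  # symbolic allele: length class was >4
        return 10 ** 6
    return rec.indel_length


def _is_indel(rec) -> bool:
    vtype = rec.var_type if hasattr(rec, "var_type") else rec.variant_type
    return vtype in ("Insertion", "Deletion")


def exclude_long_indels(records: Iterable, max_indel: int = 4) -> list:
    return [r for r in records
            if not (_is_indel(r) and _indel_length(r) > max_indel)]


def match_calls(calls: Sequence, truth: Sequence[TruthVariant],
                sites: Iterable[tuple[str, int]] | None = None,
                max_indel: int = 4) -> ConfusionCounts:
    """Site-restricted (or whole-region) confusion counts.

    ``sites`` is an optional iterable of (chrom, 1-based pos) evaluated
    sites; when given, calls outside the site set are ignored and true
    negatives are the evaluated non-truth sites left uncalled.
    """
    calls = exclude_long_indels(calls, max_indel)
    truth = exclude_long_indels(truth, max_indel)
    truth_by_pos: dict[tuple[str, int], TruthVariant] = {}
    for v in truth:
        key = (v.chrom, v.pos)
        if key in truth_by_pos:
            raise ValueError(f"duplicate truth record at {key}")
        truth_by_pos[key] = v
    site_set = set(sites) if sites is not None else None

    c = ConfusionCounts()
    called_at: set[tuple[str, int]] = set()
    seen_calls: set[tuple[str, int]] = set()
    for call in calls:
        key = (call.chrom, call.pos)
        if key in seen_calls:
            raise ValueError(f"duplicate call record at {key}")
        seen_calls.add(key)
        v = truth_by_pos.get(key)
        if v is not None:
            called_at.add(key)
            if _call_signature(call) == _call_signature(v):
                c.tp += 1
            else:
                c.fp += 1  # discrepant match; truth stays unmatched (FN)
        else:
            if site_set is None or key in site_set:
                c.fp += 1
    c.fn = len(truth_by_pos) - c.tp
    if site_set is not None:
        nonvariant_sites = {s for s in site_set if s not in truth_by_pos}
        c.tn = len(nonvariant_sites - seen_calls)
    return c


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The five benchmark formulas.

    FPR = FP/(FP+TN), FNR = FN/(FN+TP), precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2TP/(2TP+FN+FP).
    """
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    fpr = ratio(c.fp, c.fp + c.tn)
    fnr = ratio(c.fn, c.fn + c.tp)
    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)
    return MetricSet(fpr, fnr, precision, recall, f1, degenerate)


def f1_from_precision_fnr(precision: float, fnr: float) -> float:
    """F1 as the harmonic mean of precision and recall (= 1 - FNR).

    Inputs and output are on the percent scale.
    """
    recall = 100.0 - fnr
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def best_quality_cutoff(calls: Sequence, truth: Sequence[TruthVariant],
                        sites: Iterable[tuple[str, int]] | None = None,
                        max_indel: int = 4
                        ) -> tuple[float, MetricSet]:
    """Exhaustive sweep over observed qualities, maximising F1.

    Calls with quality >= cutoff are kept.  Ties prefer the lowest cutoff.
    """
    if not calls:
        raise ValueError("need at least one call")
    site_list = list(sites) if sites is not None else None
    best: tuple[float, MetricSet] | None = None
    for cutoff in sorted({c.quality for c in calls}):
        kept = [c for c in calls if c.quality >= cutoff]
        m = compute_metrics(match_calls(kept, truth, site_list, max_indel))
        if best is None or m.f1 > best[1].f1:
            best = (cutoff, m)
    return best


def consensus_filter(calls_a: Sequence, calls_b: Sequence,
                     min_geomean_quality: float) -> list:
    """Two-caller intersection with a geometric-mean quality filter.

    Calls shared between the two sets (same chrom, pos, alt, type and
    zygosity) are retained iff sqrt(qA*qB) >= the threshold; retained
    records carry the geometric-mean quality.
    """
    from dataclasses import replace

    index_b = {(c.chrom, c.pos) + _call_signature(c)[:3]: c
               for c in calls_b}
    out = []
    for ca in calls_a:
        key = (ca.chrom, ca.pos) + _call_signature(ca)[:3]
        cb = index_b.get(key)
        if cb is None:
            continue
        geomean = math.sqrt(ca.quality * cb.quality)
        if geomean >= min_geomean_quality:
            out.append(replace(ca, quality=geomean))
    return out


def titv_ratio(calls: Sequence) -> float:
    """Transition/transversion ratio over the SNP calls (inf if no Tv)."""
    ti = tv = 0
    for c in calls:
        vtype = c.var_type if hasattr(c, "var_type") else c.variant_type
        if vtype != "SNP":
            continue
        pair = (c.ref[0], c.alt[0])
        if pair in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise ValueError("no SNP calls")
    return math.inf if tv == 0 else ti / tv


HOMOPOLYMER_MIN_RUN = 5
STR_MIN_COPIES = 3


def classify_context(ref: str, pos: int, window: int = 16) -> str:
    """Classify the sequence context at ``pos`` (0-based).

    ``homopolymer`` when a single-base run of length >= 5 covers the
    position or the base immediately after it (where an indel's affected
    bases start); ``short-tandem-repeat`` when >= 3 tandem copies of a
    2-6 bp motif cover it; otherwise ``other``.  Homopolymer wins ties.
    """
    lo = max(0, pos - window)
    hi = min(len(ref), pos + window + 1)
    seq = ref[lo:hi]
    rel = pos - lo

    # homopolymer runs
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= HOMOPOLYMER_MIN_RUN and i <= rel + 1 and rel < j:
            return "homopolymer"
        i = j

    # short tandem repeats, motif sizes 2..6
    for k in range(2, 7):
        for s in range(len(seq) - 2 * k + 1):
            motif = seq[s:s + k]
            if len(set(motif)) == 1:
                continue
            copies = 1
            while seq[s + copies * k:s + (copies + 1) * k] == motif:
                copies += 1
            span_end = s + copies * k
            if copies >= STR_MIN_COPIES and s <= rel + 1 and rel < span_end:
                return "short-tandem-repeat"
    return "other"


def report(calls: Sequence, truth: Sequence[TruthVariant],
           sites: Iterable[tuple[str, int]] | None = None,
           max_indel: int = 4) -> pd.DataFrame:
    """Overall / SNP / indel metric table (percent, 2 decimals)."""
    site_list = list(sites) if sites is not None else None
    rows = []
    subsets = {
        "overall": lambda r: True,
        "SNP": lambda r: not _is_indel(r),
        "indel": _is_indel,
    }
    for name, pred in subsets.items():
        sub_calls = [c for c in calls if pred(c)]
        sub_truth = [v for v in truth if pred(v)]
        m = compute_metrics(
            match_calls(sub_calls, sub_truth, site_list, max_indel))
        row = {"class": name, **m.as_percent()}
        if site_list is None:
            row["fpr"] = float("nan")  # no TN without an evaluated site set
        rows.append(row)
    return pd.DataFrame(rows)
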