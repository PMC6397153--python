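import math
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clairlite.calling import VariantCall
from clairlite.evaluation import (
    ConfusionCounts,
    best_quality_cutoff,
    classify_context,
    compute_metrics,
    consensus_filter,
    f1_from_precision_fnr,
    match_calls,
    report,
    titv_ratio,
)
from clairlite.io_formats import TruthVariant


def _truth(pos, ref="C", alt="A", gt=(0, 1), chrom="c"):
    return TruthVariant(chrom, pos, ref, (alt,), gt)


def _call(pos, ref="C", alt="A", zyg="het", vtype="SNP", q=50.0, chrom="c"):
    lc = 0 if vtype == "SNP" else abs(len(alt) - len(ref))
    gt = "0/1" if zyg == "het" else "1/1"
    return VariantCall(chrom, pos, ref, alt, zyg, vtype, min(lc, 5), q, gt)


def _truth_as_calls(truth):
    return [_call(v.pos, v.ref, v.alt,
                  "het" if v.is_het else "hom", v.variant_type,
                  chrom=v.chrom) for v in truth]


def test_perfect_calls_with_site_set():
    truth = [_truth(10 * i + 10) for i in range(10)]
    sites = [("c", v.pos) for v in truth] + [("c", 500 + i)
                                             for i in range(10)]
    c = match_calls(_truth_as_calls(truth), truth, sites)
    assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)
    m = compute_metrics(c)
    assert m.precision == m.recall == m.f1 == 1.0
    assert m.fpr == m.fnr == 0.0


def test_wrong_zygosity_is_fp_and_truth_unmatched():
    truth = [_truth(10)]
    calls = [_call(10, zyg="hom")]
    c = match_calls(calls, truth)
    assert (c.tp, c.fp, c.fn) == (0, 1, 1)


def test_long_indels_excluded_from_both_sides():
    truth = [_truth(10), _truth(50, "CAAAAA", "C")]   # 5-bp deletion
    calls = _truth_as_calls(truth)
    c = match_calls(calls, truth, max_indel=4)
    assert (c.tp, c.fp, c.fn) == (1, 0, 0)


def test_calls_outside_site_set_ignored():
    truth = [_truth(10)]
    sites = [("c", 10), ("c", 20)]
    calls = _truth_as_calls(truth) + [_call(99)]
    c = match_calls(calls, truth, sites)
    assert (c.tp, c.fp, c.tn) == (1, 0, 1)
    # whole-region mode counts the stray call
    c2 = match_calls(calls, truth)
    assert (c2.tp, c2.fp) == (1, 1)


def test_site_restricted_and_whole_region_agree_on_tp_fn():
    truth = [_truth(10), _truth(30), _truth(60)]
    calls = _truth_as_calls(truth)[:2] + [_call(60, zyg="hom")]
    sites = [("c", v.pos) for v in truth]
    a = match_calls(calls, truth, sites)
    b = match_calls(calls, truth)
    assert (a.tp, a.fn) == (b.tp, b.fn) == (2, 1)


def test_duplicate_records_rejected():
    with pytest.raises(ValueError):
        match_calls([_call(5), _call(5, alt="G")], [_truth(5)])
    with pytest.raises(ValueError):
        match_calls([], [_truth(5), _truth(5)])


@given(tp=st.integers(0, 1000), fp=st.integers(0, 1000),
       tn=st.integers(0, 1000), fn=st.integers(0, 1000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_metric_formulas_match_brute_force(tp, fp, tn, fn):
    m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
    assert m.fpr == (fp / (fp + tn) if fp + tn else 0.0)
    assert m.fnr == (fn / (fn + tp) if fn + tp else 0.0)
    assert m.precision == (tp / (tp + fp) if tp + fp else 0.0)
    assert m.recall == (tp / (tp + fn) if tp + fn else 0.0)
    assert m.f1 == (2 * tp / (2 * tp + fn + fp) if tp + fn + fp else 0.0)
    assert m.recall == pytest.approx(1 - m.fnr) or m.degenerate
    if tp > 0:
        harm = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.f1 == pytest.approx(harm)
        assert min(m.precision, m.recall) <= m.f1 <= max(m.precision,
                                                         m.recall)


def test_degenerate_counts_evaluate_to_zero():
    m = compute_metrics(ConfusionCounts(0, 0, 0, 0))
    assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
    assert m.degenerate


@pytest.mark.parametrize("precision,fnr,f1", [
    (99.75, 0.41, 99.67),
    (97.70, 6.06, 95.78),
    (96.55, 14.78, 90.53),
])
def test_f1_recomputed_from_precision_and_fnr(precision, fnr, f1):
    assert round(f1_from_precision_fnr(precision, fnr), 2) == f1


def test_best_cutoff_separating_and_uniform_cases():
    truth = [_truth(10 * i + 10) for i in range(5)]
    tps = [_call(v.pos, q=100.0) for v in truth]
    fps = [_call(300 + i, q=1.0) for i in range(5)]
    cutoff, m = best_quality_cutoff(tps + fps, truth)
    assert 1.0 < cutoff <= 100.0
    assert m.f1 == 1.0
    cutoff, _ = best_quality_cutoff([_call(10, q=7.5), _call(20, q=7.5)],
                                    truth[:2])
    assert cutoff == 7.5


def test_best_cutoff_equals_brute_force(small_sim):
    rng = np.random.default_rng(17)
    truth = [_truth(30 * i + 20) for i in range(20)]
    calls = [_call(v.pos, q=float(rng.integers(1, 200)))
             for v in truth[:15]]
    calls += [_call(2000 + 7 * i, q=float(rng.integers(1, 200)))
              for i in range(25)]
    cutoff, m = best_quality_cutoff(calls, truth)
    best = (-1.0, None)
    for q in sorted({c.quality for c in calls}):
        kept = [c for c in calls if c.quality >= q]
        f1 = compute_metrics(match_calls(kept, truth)).f1
        if f1 > best[0]:
            best = (f1, q)
    assert m.f1 == best[0] and cutoff == best[1]


def test_consensus_filter_rules():
    a = [_call(10, q=100.0), _call(20, q=200.0), _call(30, q=100.0)]
    b = [_call(10, q=100.0), _call(20, q=50.0)]
    kept = consensus_filter(a, b, 100.0)
    assert [c.pos for c in kept] == [10, 20]      # 30 in one set only
    assert kept[0].quality == pytest.approx(100.0)
    assert kept[1].quality == pytest.approx(math.sqrt(200 * 50))
    assert consensus_filter(a, b, 101.0) == []
    # discordant zygosity at the same site is not shared
    b2 = [_call(10, q=100.0, zyg="hom")]
    assert consensus_filter(a[:1], b2, 0.0) == []


def _context_oracle(seq, rel):
    for m in re.finditer(r"(.)\1{4,}", seq):
        if m.start() <= rel + 1 and rel < m.end():
            return "homopolymer"
    for k in range(2, 7):
        for m in re.finditer(rf"(.{{{k}}})\1{{2,}}", seq):
            if len(set(m.group(1))) == 1:
                continue
            if m.start() <= rel + 1 and rel < m.end():
                return "short-tandem-repeat"
    return "other"


def test_classify_context_canonical_cases():
    ref = "GGTT" + "AAAAAAA" + "GCTT"
    assert classify_context(ref, 7, window=5) == "homopolymer"
    ref = "GTT" + "ACACACACAC" + "GTT"
    assert classify_context(ref, 8, window=6) == "short-tandem-repeat"
    assert classify_context("ACGTTGCAATG", 5, window=5) == "other"


def test_classify_context_matches_regex_oracle():
    rng = np.random.default_rng(23)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        seq = "".join(bases[rng.integers(0, 4, size=33)])
        got = classify_context(seq, 16, window=16)
        assert got == _context_oracle(seq, 16)


def test_titv_ratio():
    ti_only = [_call(10, "A", "G"), _call(20, "C", "T")]
    assert titv_ratio(ti_only) == math.inf
    mixed = [_call(10, "A", "G"), _call(20, "A", "C"),
             _call(30, "A", "T")]
    assert titv_ratio(mixed) == pytest.approx(0.5)
    rng = np.random.default_rng(29)
    subs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
    calls = [_call(5 * i + 5, *subs[j], chrom="c")
             for i, j in enumerate(rng.integers(0, 12, size=6000))]
    assert titv_ratio(calls) == pytest.approx(0.5, abs=0.06)
    with pytest.raises(ValueError):
        titv_ratio([])


def test_report_layout():
    truth = [_truth(10), _truth(40, "CAA", "C", (1, 1))]
    calls = _truth_as_calls(truth)
    df = report(calls, truth)
    assert list(df["class"]) == ["overall", "SNP", "indel"]
    assert set(df.columns) == {"class", "fpr", "fnr", "precision",
                               "recall", "f1"}
    assert df.loc[0, "f1"] == 100.0
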