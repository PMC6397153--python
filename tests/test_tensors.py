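import numpy as np
import pytest

from clairlite import tensors
from clairlite.io_formats import BASE_INDEX, AlignedRead, TruthVariant
from clairlite.tensors import (
    SiteTensor,
    build_training_set,
    encode_from_pileup,
    encode_site,
    find_candidates,
    label_from_truth,
    pileup_region,
    reference_label,
    render_site,
    summarize_column,
)


def _match_reads(n, ref, start, length):
    return [AlignedRead(f"r{i}", "c", start, [("M", length)],
                        ref[start:start + length]) for i in range(n)]


def test_summarize_column_zero_and_full_match():
    ref = "ACGTACGTAC" * 5
    col = summarize_column([], ref, "c", 10)
    assert col.depth == 0 and col.match_counts.sum() == 0
    # 10 reads all matching the reference base at pos 10
    reads = _match_reads(10, ref, 5, 20)
    col = summarize_column(reads, ref, "c", 10)
    assert col.depth == 10
    assert col.match_counts[BASE_INDEX[ref[10]]] == 10
    assert col.sub_counts.sum() == 0


def test_het_snp_column_fractions(clean_sim):
    ref, truth = clean_sim["ref"], clean_sim["truth"]
    snp = next(v for v in truth.variants
               if v.variant_type == "SNP" and v.is_het)
    col = summarize_column(clean_sim["reads"], ref, "ctg1", snp.pos - 1)
    total = col.match_counts.sum() + col.sub_counts.sum()
    assert total == col.depth
    frac = col.sub_counts[BASE_INDEX[snp.alt]] / col.depth
    assert 0.2 < frac < 0.8


def test_encode_site_hand_tally():
    """Five-read fixture, flank 2: channels agree with a hand count."""
    ref = "AACGTAACGTA"
    # 3 reads match; 2 carry a G>T substitution at pos 3 (0-based)
    reads = _match_reads(3, ref, 1, 6)
    sub = ref[1:3] + "T" + ref[4:7]
    reads += [AlignedRead(f"s{i}", "c", 1, [("M", 6)], sub)
              for i in range(2)]
    cols = [summarize_column(reads, ref, "c", p) for p in range(1, 6)]
    t = encode_site(cols, ref[1:6], "c", flank=2)
    g = BASE_INDEX["G"]; tt = BASE_INDEX["T"]
    center = 2  # pos 3
    assert t.values[center, g, 0] == 3          # ref support
    assert t.values[center, tt, 3] == 2         # substitution
    assert t.values[center, g, 3] == -3         # relative to channel 0
    other = 1  # pos 2, all 5 reads match
    b = BASE_INDEX[ref[2]]
    assert t.values[other, b, 0] == 5
    assert np.all(t.values[other, b, 1:] == -5)


def test_zero_coverage_tensor_is_zero():
    ref = "A" * 40
    rp = pileup_region([], ref, "c", 0, 40)
    t = encode_from_pileup(rp, 20, flank=2)
    assert not t.values.any()


def test_truncated_window_raises():
    ref = "A" * 40
    rp = pileup_region([], ref, "c", 0, 40)
    with pytest.raises(ValueError):
        encode_from_pileup(rp, 1, flank=5)


def _fig4_tensor(clean_sim, vtype):
    """A variant of the requested type whose signal cannot be cancelled
    by reference support in the relative encoding (hom for indels, and an
    inserted base differing from the underlying reference)."""
    ref, truth = clean_sim["ref"], clean_sim["truth"]
    for v in truth.variants:
        if v.variant_type != vtype:
            continue
        if vtype == "SNP":
            break
        if v.is_het:
            continue  # het indel signal is offset by the other haplotype
        if vtype == "Insertion":
            ins = v.alt[1:]
            if any(b != ref[v.pos - 1 + j] for j, b in enumerate(ins[:4])):
                break
        else:
            break
    else:  # pragma: no cover - fixture guarantees a suitable variant
        raise AssertionError(f"no suitable {vtype} in fixture")
    rp = pileup_region(clean_sim["reads"], ref, "ctg1", 0, len(ref))
    return v, encode_from_pileup(rp, v.pos - 1, flank=16)


@pytest.mark.parametrize("vtype,channel", [
    ("SNP", 3), ("Insertion", 1), ("Deletion", 2)])
def test_variant_signal_lands_in_its_channel(clean_sim, vtype, channel):
    """The strongest positive signal across channels 1-3 sits in the
    channel dedicated to that variant type, at or right after the
    center (deletions mark the deleted bases, one right of the anchor)."""
    v, t = _fig4_tensor(clean_sim, vtype)
    x = t.values[:, :, 1:]  # signal channels only
    best = np.unravel_index(np.argmax(x), x.shape)
    assert best[2] + 1 == channel
    assert 16 <= best[0] <= 16 + max(v.indel_length, 1)


def test_encoding_additive_in_reads(small_sim):
    ref, reads = small_sim["ref"], small_sim["reads"]
    rp_all = pileup_region(reads, ref, "ctg1", 0, len(ref))
    rp_a = pileup_region(reads[::2], ref, "ctg1", 0, len(ref))
    rp_b = pileup_region(reads[1::2], ref, "ctg1", 0, len(ref))
    for pos in (1000, 2500, 4000):
        t_all = encode_from_pileup(rp_all, pos).values
        t_sum = (encode_from_pileup(rp_a, pos).values
                 + encode_from_pileup(rp_b, pos).values)
        assert np.allclose(t_all, t_sum)


def test_channel0_sum_bounded_by_depth(small_sim):
    ref = small_sim["ref"]
    rp = pileup_region(small_sim["reads"], ref, "ctg1", 0, len(ref))
    for pos in (500, 1500, 3000, 4500):
        t = encode_from_pileup(rp, pos)
        window_depth = rp.depth[pos - 16:pos + 17]
        assert np.all(t.values[:, :, 0].sum(axis=1) <= window_depth)


def _naive_pileup_oracle(reads, ref, start, end):
    """Independent per-read CIGAR walk, scalar accumulation."""
    L = end - start
    aligned = np.zeros((L, 4))
    ins = np.zeros((L, 4))
    dels = np.zeros((L, 4))
    for r in reads:
        rp, qp = r.pos, 0
        for op, n in r.cigar:
            if op in "M=X":
                for k in range(n):
                    p = rp + k
                    base = r.seq[qp + k]
                    if start <= p < end and base in BASE_INDEX:
                        aligned[p - start, BASE_INDEX[base]] += 1
                rp += n; qp += n
            elif op == "I":
                if rp > r.pos:
                    for j in range(min(n, 4)):
                        p = rp - 1 + j
                        base = r.seq[qp + j]
                        if start <= p < end and base in BASE_INDEX:
                            ins[p - start, BASE_INDEX[base]] += 1
                qp += n
            elif op == "D":
                for j in range(n):
                    p = rp + j
                    if start <= p < end and ref[p] in BASE_INDEX:
                        dels[p - start, BASE_INDEX[ref[p]]] += 1
                rp += n
            elif op == "S":
                qp += n
    return aligned, ins, dels


def test_pileup_matches_naive_cigar_walk(small_sim):
    ref = small_sim["ref"]
    reads = small_sim["reads"][:10]
    start, end = 0, len(ref)
    rp = pileup_region(reads, ref, "ctg1", start, end)
    aligned, ins, dels = _naive_pileup_oracle(reads, ref, start, end)
    assert np.array_equal(rp.aligned, aligned)
    assert np.array_equal(rp.ins, ins)
    assert np.array_equal(rp.delmark, dels)


def test_ledger_identity_on_clean_reads(clean_sim):
    """With zero error rates the pileup equals the simulator's ledger."""
    ref = clean_sim["ref"]
    rp = pileup_region(clean_sim["reads"], ref, "ctg1", 0, len(ref))
    assert np.array_equal(rp.aligned, clean_sim["ledger"].base_counts)


def test_ledger_identity_on_noisy_reads(small_sim):
    """The ledger records emitted (post-error) bases, so the identity
    holds for noisy reads too."""
    ref = small_sim["ref"]
    rp = pileup_region(small_sim["reads"], ref, "ctg1", 0, len(ref))
    assert np.array_equal(rp.aligned, small_sim["ledger"].base_counts)


def test_find_candidates_threshold_arithmetic():
    ref = "ACGT" * 20
    pos = 40
    reads = _match_reads(8, ref, 20, 40)
    alt = ref[20:40] + "T" + ref[41:60]  # A>T at pos 40 in 2 reads
    reads += [AlignedRead(f"a{i}", "c", 20, [("M", 40)], alt)
              for i in range(2)]
    rp = pileup_region(reads, ref, "c", 0, len(ref))
    assert pos in find_candidates(rp, 0.2, min_depth=4)
    assert pos not in find_candidates(rp, 0.25, min_depth=4)
    # depth below min_depth is never a candidate
    rp3 = pileup_region(reads[:2] + reads[-1:], ref, "c", 0, len(ref))
    assert pos not in find_candidates(rp3, 0.2, min_depth=4)
    with pytest.raises(ValueError):
        find_candidates(rp, 0.0)


def test_candidate_recall_on_noisy_truth(small_sim):
    ref, truth = small_sim["ref"], small_sim["truth"]
    rp = pileup_region(small_sim["reads"], ref, "ctg1", 0, len(ref))
    cands = set(find_candidates(rp, 0.2, min_depth=4))
    truth_pos = [v.pos - 1 for v in truth.variants]
    recall = sum(p in cands for p in truth_pos) / len(truth_pos)
    assert recall >= 0.95


def test_label_from_truth_cases():
    lab = label_from_truth(TruthVariant("c", 9, "C", ("A",), (0, 1)), "")
    assert np.array_equal(lab.a, [1, 0, 0, 0])
    assert np.array_equal(lab.z, [0, 1])          # heterozygote
    assert np.array_equal(lab.t, [0, 1, 0, 0])    # SNP
    assert lab.l[0] == 1
    ins9 = label_from_truth(
        TruthVariant("c", 9, "A", ("A" + "CGT" * 3,), (1, 1)), "")
    assert np.array_equal(ins9.t, [0, 0, 1, 0])
    assert ins9.l[5] == 1                          # ">4" class
    assert not ins9.a.any()
    assert np.array_equal(ins9.z, [1, 0])
    assert label_from_truth(
        TruthVariant("c", 9, "A", ("C", "G"), (1, 2)), "") is None


def test_label_vectors_are_one_hot(clean_sim):
    for v in clean_sim["truth"].variants:
        lab = label_from_truth(v, clean_sim["ref"])
        for vec in (lab.z, lab.t, lab.l):
            assert vec.sum() == 1 and set(vec) <= {0.0, 1.0}


def test_build_training_set_pairing_and_marginals(small_sim):
    ref = {"ctg1": small_sim["ref"]}
    ts = build_training_set(small_sim["truth"].variants,
                            small_sim["reads"], ref, seed=11)
    n_truth = len(small_sim["truth"].variants)
    assert len(ts) == 3 * n_truth
    ref_frac = np.mean(ts.Y[:, 6] == 1)
    assert ref_frac == pytest.approx(2 / 3)
    truth_pos = {v.pos - 1 for v in small_sim["truth"].variants}
    negatives = [p for (c, p), y in zip(ts.positions, ts.Y) if y[6] == 1]
    assert not (set(negatives) & truth_pos)
    # deterministic for a fixed seed
    ts2 = build_training_set(small_sim["truth"].variants,
                             small_sim["reads"], ref, seed=11)
    assert np.array_equal(ts.X, ts2.X) and ts.positions == ts2.positions


def test_training_set_archive_roundtrip(tmp_path, small_sim):
    ref = {"ctg1": small_sim["ref"]}
    ts = build_training_set(small_sim["truth"].variants,
                            small_sim["reads"], ref, seed=11)
    path = str(tmp_path / "t.h5")
    tensors.save_training_set(ts, path)
    back = tensors.load_training_set(path)
    assert np.array_equal(ts.X, back.X)
    assert np.array_equal(ts.Y, back.Y)
    assert ts.positions == back.positions


def test_render_site_blank_and_injective():
    zero = SiteTensor("c", 50, np.zeros((33, 4, 4)), 16)
    text = render_site(zero)
    body = [ln for ln in text.splitlines() if ln and not ln.startswith("[")]
    assert all(set(ln[2:]) == {" ", "."} for ln in body)
    rng = np.random.default_rng(0)
    a = rng.integers(-9, 10, size=(33, 4, 4)).astype(float)
    b = a.copy(); b[16, 2, 3] += 1
    assert render_site(SiteTensor("c", 50, a, 16)) != \
        render_site(SiteTensor("c", 50, b, 16))


def test_render_site_shows_snp_center(clean_sim):
    v, t = _fig4_tensor(clean_sim, "SNP")
    panel = render_site(t).split("\n\n")[3]  # substitution panel
    rows = panel.splitlines()[1:]
    center_cells = [r[2:][2 * 16:2 * 16 + 2] for r in rows]
    assert any("+" in c for c in center_cells)


def test_reference_label_is_homozygous_reference():
    lab = reference_label("G")
    assert lab.a[BASE_INDEX["G"]] == 1 and lab.z[0] == 1 and lab.t[0] == 1
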