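"""Pileup summarisation and the 33x4x4 input tensor around a candidate site.

A window of 2*flank+1 reference positions (33 at the default flank of 16)
is summarised into four 33x4 channels:

* channel 0 -- the reference sequence and the read support for it: the
  count of reads whose aligned base matches the reference, stored at the
  reference base's cell;
* channels 1-3 -- inserted-sequence, deleted-base and substitution counts,
  each stored *relative* to channel 0 (raw signal count minus the channel-0
  value at the same cell), so a pure-reference column shows negative
  entries at the reference-base cell of channels 1-3.

Insertions are anchored at the reference position immediately left of the
inserted sequence; the first four inserted bases are spread over positions
anchor+0..anchor+3 so the inserted allele can be recovered.  Deletions mark
the deleted reference bases' cells.  Base quality is never read; both
strands are counted indistinctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np

from .io_formats import BASE_INDEX, BASES, AlignedRead, TruthVariant

DEFAULT_FLANK = 16
INDEL_CLASSES = 6  # lengths 0,1,2,3,4,>4
VARIANT_TYPES = ("Reference", "SNP", "Insertion", "Deletion")
LABEL_WIDTH = 4 + 2 + 4 + INDEL_CLASSES  # a | z | t | l


@dataclass
class SiteTensor:
    """The summarised pileup tensor ``x`` for one candidate site."""

    chrom: str
    pos: int  # 0-based center position
    values: np.ndarray  # (2*flank+1, 4 bases, 4 channels)
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        expected = (2 * self.flank + 1, 4, 4)
        if self.values.shape != expected:
            raise ValueError(
                f"tensor shape {self.values.shape} != {expected}")


@dataclass
class VariantLabel:
    """The four training targets for one site.

    ``a`` is the per-base alternate-allele indicator (all zero for indels,
    one-hot on the reference base for a nonvariant); ``z``/``t``/``l`` are
    one-hot over zygosity (hom, het), variant type (Reference, SNP,
    Insertion, Deletion) and indel length (0..4, >4).
    """

    a: np.ndarray
    z: np.ndarray
    t: np.ndarray
    l: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.a, self.z, self.t, self.l])

    @staticmethod
    def split(row: np.ndarray) -> tuple[np.ndarray, ...]:
        return row[0:4], row[4:6], row[6:10], row[10:16]


@dataclass
class PileupColumn:
    """Per-position counts, tallied in the four ways the channels need."""

    pos: int
    match_counts: np.ndarray  # aligned base == ref base, at the ref cell
    ins_counts: np.ndarray    # inserted bases spread onto this position
    del_counts: np.ndarray    # deleted reference bases marked here
    sub_counts: np.ndarray    # aligned base != ref base
    depth: int
    ins_starts: int = 0       # insertions anchored at this position
    del_starts: int = 0       # deletions anchored at this position


class RegionPileup:
    """Vectorised pileup counts over a reference interval.

    Built with one CIGAR walk over the reads; candidate scanning and tensor
    encoding then reduce to array slicing.
    """

    def __init__(self, chrom: str, start: int, end: int, ref: str):
        self.chrom, self.start, self.end = chrom, start, end
        self.ref = ref  # full chromosome sequence
        L = end - start
        self.aligned = np.zeros((L, 4), np.float64)
        self.ins = np.zeros((L, 4), np.float64)
        self.delmark = np.zeros((L, 4), np.float64)
        self.ins_start = np.zeros(L, np.float64)
        self.del_start = np.zeros(L, np.float64)
        self.ref_idx = np.array(
            [BASE_INDEX.get(b, -1) for b in ref[start:end]], np.int64)

    @property
    def depth(self) -> np.ndarray:
        return self.aligned.sum(axis=1)

    def _in(self, p: int) -> bool:
        return self.start <= p < self.end

    def add_read(self, read: AlignedRead) -> None:
        refpos, qpos = read.pos, 0
        s = self.start
        for op, n in read.cigar:
            if op in "M=X":
                for k in range(n):
                    p = refpos + k
                    if self._in(p):
                        b = BASE_INDEX.get(read.seq[qpos + k], -1)
                        if b >= 0:  # N bases contribute no counts
                            self.aligned[p - s, b] += 1
                refpos += n
                qpos += n
            elif op == "I":
                anchor = refpos - 1
                if refpos > read.pos:  # skip insertion before first M
                    if self._in(anchor):
                        self.ins_start[anchor - s] += 1
                    for j in range(min(n, 4)):
                        p = anchor + j
                        if self._in(p):
                            b = BASE_INDEX.get(read.seq[qpos + j], -1)
                            if b >= 0:
                                self.ins[p - s, b] += 1
                qpos += n
            elif op == "D":
                anchor = refpos - 1
                if self._in(anchor):
                    self.del_start[anchor - s] += 1
                for j in range(n):
                    p = refpos + j
                    if self._in(p):
                        b = self.ref_idx[p - s]
                        if b >= 0:
                            self.delmark[p - s, b] += 1
                refpos += n
            elif op == "S":
                qpos += n
            else:  # pragma: no cover - parser restricts ops
                raise ValueError(f"unsupported CIGAR op {op!r}")

    def column(self, pos: int) -> PileupColumn:
        i = pos - self.start
        ref_b = self.ref_idx[i]
        match = np.zeros(4)
        sub = self.aligned[i].copy()
        if ref_b >= 0:
            match[ref_b] = self.aligned[i, ref_b]
            sub[ref_b] = 0
        return PileupColumn(
            pos=pos, match_counts=match, ins_counts=self.ins[i].copy(),
            del_counts=self.delmark[i].copy(), sub_counts=sub,
            depth=int(self.aligned[i].sum()),
            ins_starts=int(self.ins_start[i]),
            del_starts=int(self.del_start[i]),
        )


def pileup_region(reads: Iterable[AlignedRead], ref: str, chrom: str,
                  start: int, end: int) -> RegionPileup:
    """Tally pileup counts for ``[start, end)`` from overlapping reads."""
    rp = RegionPileup(chrom, start, end, ref)
    for read in reads:
        if read.chrom == chrom and read.pos < end and read.end > start:
            rp.add_read(read)
    return rp


def summarize_column(reads: Iterable[AlignedRead], ref: str, chrom: str,
                     pos: int) -> PileupColumn:
    """Summarise a single reference position (zero coverage -> zeros)."""
    # include left context so insertions spread from anchors < pos land here
    start = max(0, pos - 3)
    return pileup_region(reads, ref, chrom, start, pos + 1).column(pos)


def encode_site(columns: Sequence[PileupColumn], ref_window: str,
                chrom: str = "", center: int | None = None,
                flank: int = DEFAULT_FLANK) -> SiteTensor:
    """Build the (2*flank+1, 4, 4) tensor from per-position columns."""
    n = 2 * flank + 1
    if len(columns) != n or len(ref_window) != n:
        raise ValueError(f"expected {n} columns and reference bases")
    x = np.zeros((n, 4, 4))
    for p, col in enumerate(columns):
        x[p, :, 0] = col.match_counts
        x[p, :, 1] = col.ins_counts - col.match_counts
        x[p, :, 2] = col.del_counts - col.match_counts
        x[p, :, 3] = col.sub_counts - col.match_counts
    if center is None:
        center = columns[flank].pos
    return SiteTensor(chrom, center, x, flank)


def encode_from_pileup(rp: RegionPileup, center: int,
                       flank: int = DEFAULT_FLANK) -> SiteTensor:
    """Fast path: slice a window out of a :class:`RegionPileup`."""
    lo, hi = center - flank, center + flank + 1
    if lo < rp.start or hi > rp.end:
        raise ValueError("window truncated by region/contig edge")
    i, j = lo - rp.start, hi - rp.start
    n = hi - lo
    ch0 = np.zeros((n, 4))
    rows = np.arange(n)
    refb = rp.ref_idx[i:j]
    ok = refb >= 0
    ch0[rows[ok], refb[ok]] = rp.aligned[i:j][rows[ok], refb[ok]]
    sub = rp.aligned[i:j].copy()
    sub[rows[ok], refb[ok]] = 0
    x = np.stack([ch0, rp.ins[i:j] - ch0, rp.delmark[i:j] - ch0, sub - ch0],
                 axis=2)
    return SiteTensor(rp.chrom, center, x, flank)


def find_candidates(rp: RegionPileup, af_cutoff: float,
                    min_depth: int = 4) -> list[int]:
    """Positions whose non-reference support fraction reaches the cutoff.

    Non-reference support at a position is the substitution count plus the
    number of insertions and deletions anchored there.
    """
    if not 0 < af_cutoff <= 1:
        raise ValueError("af_cutoff must be in (0, 1]")
    depth = rp.aligned.sum(axis=1)
    rows = np.arange(rp.end - rp.start)
    ref_support = np.zeros_like(depth)
    ok = rp.ref_idx >= 0
    ref_support[ok] = rp.aligned[rows[ok], rp.ref_idx[ok]]
    nonref = (depth - ref_support) + rp.ins_start + rp.del_start
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(depth > 0, nonref / np.maximum(depth, 1), 0.0)
    mask = (depth >= min_depth) & (af >= af_cutoff)
    return [int(p) + rp.start for p in np.nonzero(mask)[0]]


def label_from_truth(v: TruthVariant, ref: str) -> VariantLabel | None:
    """Targets for one truth variant; ``None`` for multi-allelic records.

    Multi-allelic sites are excluded from training; callers count skips.
    """
    if v.is_multiallelic:
        return None
    a = np.zeros(4)
    z = np.zeros(2)
    t = np.zeros(4)
    l = np.zeros(INDEL_CLASSES)
    z[1 if v.is_het else 0] = 1
    vtype = v.variant_type
    t[VARIANT_TYPES.index(vtype)] = 1
    if vtype == "SNP":
        a[BASE_INDEX[v.alt[0]]] = 1
        l[0] = 1
    else:
        l[min(v.indel_length, INDEL_CLASSES - 1)] = 1
    return VariantLabel(a, z, t, l)


def reference_label(ref_base: str) -> VariantLabel:
    """The label of a nonvariant site: homozygous reference."""
    a = np.zeros(4)
    a[BASE_INDEX[ref_base]] = 1
    z = np.array([1.0, 0.0])
    t = np.array([1.0, 0.0, 0.0, 0.0])
    l = np.zeros(INDEL_CLASSES)
    l[0] = 1
    return VariantLabel(a, z, t, l)


@dataclass
class TrainingSet:
    """Encoded tensors and labels, plus bookkeeping counters."""

    X: np.ndarray  # (n, 33, 4, 4)
    Y: np.ndarray  # (n, 16)
    positions: list[tuple[str, int]] = field(default_factory=list)
    skipped_multiallelic: int = 0
    skipped_no_coverage: int = 0

    def __len__(self) -> int:
        return len(self.X)

    def samples(self) -> list[tuple[SiteTensor, VariantLabel]]:
        out = []
        for x, y, (chrom, pos) in zip(self.X, self.Y, self.positions):
            flank = (x.shape[0] - 1) // 2
            out.append((SiteTensor(chrom, pos, x, flank),
                        VariantLabel(*VariantLabel.split(y))))
        return out


def build_training_set(truth: Sequence[TruthVariant],
                       reads: Iterable[AlignedRead],
                       ref: dict[str, str],
                       negatives_per_variant: int = 2, seed: int = 0,
                       flank: int = DEFAULT_FLANK,
                       exclusion_radius: int = 0) -> TrainingSet:
    """Pair each usable truth variant with random nonvariant sites.

    Each truth variant contributes one labelled sample; for every one used,
    ``negatives_per_variant`` reference-labelled samples are drawn from
    nonvariant, nonambiguous sites: an ACGT reference base, depth >= 1, and
    outside the affected span of every truth variant (the variant position,
    plus the deleted bases of a deletion) widened by ``exclusion_radius``.
    Sites merely *near* a variant stay eligible on purpose: candidate scans
    hit them constantly (the variant's signal sits off-center in their
    window) and the model must learn to leave them uncalled.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    reads = list(reads)
    X, Y, positions = [], [], []
    ts = TrainingSet(np.empty(0), np.empty(0))
    by_chrom: dict[str, list[TruthVariant]] = {}
    for v in truth:
        by_chrom.setdefault(v.chrom, []).append(v)

    for chrom in sorted(by_chrom):
        seq = ref[chrom]
        rp = pileup_region([r for r in reads if r.chrom == chrom], seq,
                           chrom, 0, len(seq))
        depth = rp.depth
        truth_pos = np.array([v.pos - 1 for v in by_chrom[chrom]])
        n_used = 0
        for v in by_chrom[chrom]:
            label = label_from_truth(v, seq)
            if label is None:
                ts.skipped_multiallelic += 1
                continue
            c = v.pos - 1
            if c - flank < 0 or c + flank + 1 > len(seq):
                continue
            if depth[c] < 1:
                ts.skipped_no_coverage += 1
                continue
            X.append(encode_from_pileup(rp, c, flank).values)
            Y.append(label.concat())
            positions.append((chrom, c))
            n_used += 1

        # eligible negative sites: exclude each variant's affected span
        near = np.zeros(len(seq), bool)
        for v in by_chrom[chrom]:
            p = v.pos - 1
            span = len(v.ref)  # 1 for SNP/insertion, 1+len for deletion
            lo = max(0, p - exclusion_radius)
            hi = min(len(seq), p + span + exclusion_radius)
            near[lo:hi] = True
        eligible = np.nonzero(
            (depth >= 1) & (rp.ref_idx >= 0) & ~near)[0]
        eligible = eligible[(eligible >= flank)
                            & (eligible < len(seq) - flank)]
        n_neg = n_used * negatives_per_variant
        if n_neg > len(eligible):
            raise ValueError("not enough eligible nonvariant sites")
        chosen = rng.choice(eligible, size=n_neg, replace=False)
        for c in sorted(int(c) for c in chosen):
            X.append(encode_from_pileup(rp, c, flank).values)
            Y.append(reference_label(seq[c]).concat())
            positions.append((chrom, c))

    ts.X = np.array(X)
    ts.Y = np.array(Y)
    ts.positions = positions
    return ts


def save_training_set(ts: TrainingSet, path: str,
                      compress: bool = True) -> None:
    """Store tensors + labels + index in one HDF5 container."""
    kw = {"compression": "gzip"} if compress else {}
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ts.X, **kw)
        f.create_dataset("Y", data=ts.Y, **kw)
        f.create_dataset("chrom", data=np.array(
            [c for c, _ in ts.positions], dtype="S32"))
        f.create_dataset("pos", data=np.array(
            [p for _, p in ts.positions], dtype=np.int64))
        f.attrs["skipped_multiallelic"] = ts.skipped_multiallelic
        f.attrs["skipped_no_coverage"] = ts.skipped_no_coverage


def load_training_set(path: str) -> TrainingSet:
    with h5py.File(path, "r") as f:
        ts = TrainingSet(
            X=f["X"][...], Y=f["Y"][...],
            positions=[(c.decode(), int(p))
                       for c, p in zip(f["chrom"][...], f["pos"][...])],
            skipped_multiallelic=int(f.attrs["skipped_multiallelic"]),
            skipped_no_coverage=int(f.attrs["skipped_no_coverage"]),
        )
    return ts


# ---------------------------------------------------------------------------
# text rendering

_POS_GLYPHS = " 123456789"


def render_site(t: SiteTensor) -> str:
    """Render the four channels as text heatmaps (lossless for |v| <= 9).

    Each cell shows a signed digit whose magnitude grows monotonically with
    the (rounded, clipped-at-9) value; zero renders blank.
    """
    names = ("reference support", "insertion", "deletion", "substitution")
    panels = []
    for ch, name in enumerate(names):
        lines = [f"[{name}]"]
        for b in range(4):
            cells = []
            for p in range(t.values.shape[0]):
                v = int(round(t.values[p, b, ch]))
                v = max(-9, min(9, v))
                if v == 0:
                    cells.append(" .")
                elif v > 0:
                    cells.append("+" + _POS_GLYPHS[v])
                else:
                    cells.append("-" + _POS_GLYPHS[-v])
            lines.append(BASES[b] + " " + "".join(cells))
        panels.append("\n".join(lines))
    return "\n\n".join(panels)
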