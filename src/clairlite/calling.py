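"""Genome-wide scan, batched inference and decoding of the four heads.

``call_region`` runs the full pipeline: candidate sites are found by
alternative-allele frequency, each is encoded into a 33x4x4 tensor, the
network scores batches in inference mode, and each output row is decoded
into a variant call with a Phred-style quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import network as nw
from .io_formats import BASES, read_alignments
from .network import Network, NetworkOutputs
from .tensors import (
    DEFAULT_FLANK,
    SiteTensor,
    encode_from_pileup,
    find_candidates,
    pileup_region,
)

ZYGOSITIES = ("hom", "het")
QUALITY_CAP = 999.0


@dataclass
class VariantCall:
    """A decoded variant call; ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str           # "het" | "hom"
    var_type: str           # "SNP" | "Insertion" | "Deletion"
    length_class: int       # 0..5, 5 meaning ">4"
    quality: float
    genotype: str = "0/1"
    flags: tuple[str, ...] = field(default_factory=tuple)
    support: float = 0.0    # candidate non-reference allele fraction

    @property
    def indel_length(self) -> int:
        if self.var_type == "SNP":
            return 0
        if self.alt.startswith("<"):
            return self.length_class
        return abs(len(self.alt) - len(self.ref))


def phred_quality(row: tuple[np.ndarray, ...]) -> float:
    """Phred-style call quality: -10*log10(1 - p_min), capped at 999.

    ``p_min`` is the minimum of the winning probabilities across the heads
    that take part in the decoded call: zygosity, type and indel length
    always, plus the allele head when the type head picks Reference/SNP
    (the allele group is all-zero for indels by construction).
    """
    a, z, t, l = row
    winners = [float(z.max()), float(t.max()), float(l.max())]
    if int(np.argmax(t)) in (0, 1):
        winners.append(float(a.max()))
    p_min = min(winners)
    if p_min >= 1.0:
        return QUALITY_CAP
    return min(QUALITY_CAP, -10.0 * math.log10(1.0 - p_min))


def decode(row: tuple[np.ndarray, ...], site: SiteTensor,
           ref_window: str) -> VariantCall | None:
    """Turn one network output row into a call (or no-call for Reference).

    The variant-type head is authoritative; the allele and length heads are
    read conditionally on it, and any internal disagreement is flagged on
    the record rather than suppressing the call.  Argmax ties break toward
    the lowest class index.
    """
    a, z, t, l = row
    ti = int(np.argmax(t))
    if ti == 0:
        return None
    flags: list[str] = []
    zi = int(np.argmax(z))
    zyg = ZYGOSITIES[zi]
    genotype = "1/1" if zyg == "hom" else "0/1"
    flank = site.flank
    center_base = ref_window[flank]
    li = int(np.argmax(l))
    pos1 = site.pos + 1

    if ti == 1:  # SNP
        order = np.argsort(-a, kind="stable")
        ref_idx = BASES.index(center_base)
        alt_idx = int(next(i for i in order if i != ref_idx))
        if int(np.argmax(a)) == ref_idx:
            flags.append("allele-head-ref")
        if li != 0:
            flags.append("length-head-nonzero")
        call = VariantCall(site.chrom, pos1, center_base, BASES[alt_idx],
                           zyg, "SNP", 0, 0.0, genotype, tuple(flags))
    else:
        if li == 0:
            flags.append("length-head-zero")
            li = 1 + int(np.argmax(l[1:]))
        length = li if li < 5 else None  # None: >4, no exact allele
        if ti == 2:  # Insertion: consensus of channel-1 bases
            if length is None:
                alt = "<INS>"
            else:
                raw_ins = (site.values[:, :, 1] + site.values[:, :, 0])
                bases = [BASES[int(np.argmax(raw_ins[flank + j]))]
                         for j in range(min(length, 4))]
                alt = center_base + "".join(bases)
            call = VariantCall(site.chrom, pos1, center_base, alt, zyg,
                               "Insertion", li, 0.0, genotype, tuple(flags))
        else:  # Deletion: the deleted bases are the reference bases
            if length is None or flank + 1 + li > len(ref_window):
                ref_allele, alt = center_base, "<DEL>"
            else:
                ref_allele = ref_window[flank:flank + 1 + length]
                alt = center_base
            call = VariantCall(site.chrom, pos1, ref_allele, alt, zyg,
                               "Deletion", li, 0.0, genotype, tuple(flags))
    return replace(call, quality=phred_quality(row))


def call_sites(model: Network, tensors: Sequence[SiteTensor], ref: str,
               batch_size: int = 3000) -> list[VariantCall]:
    """Score encoded sites in batches and decode each output row."""
    calls: list[VariantCall] = []
    for s in range(0, len(tensors), batch_size):
        chunk = tensors[s:s + batch_size]
        X = np.stack([t.values for t in chunk])
        out = nw.forward(model, X)
        for i, site in enumerate(chunk):
            window = ref[site.pos - site.flank:site.pos + site.flank + 1]
            call = decode(out.row(i), site, window)
            if call is not None:
                calls.append(call)
    return calls


def nonref_support_fraction(rp) -> np.ndarray:
    """Per-position non-reference support fraction over a RegionPileup."""
    depth = rp.depth
    rows = np.arange(rp.end - rp.start)
    ref_support = np.where(
        rp.ref_idx >= 0,
        rp.aligned[rows, np.maximum(rp.ref_idx, 0)], 0.0)
    return ((depth - ref_support + rp.ins_start + rp.del_start)
            / np.maximum(depth, 1))


def select_local_maxima(candidates: Sequence[int], support: np.ndarray,
                        offset: int = 0, radius: int = 3) -> list[int]:
    """Keep candidates that locally maximise non-reference support.

    A variant's signal also sits 1-3 bp off-center in the windows of
    neighbouring candidate positions and is frequently re-called there, so
    a candidate is kept only when no position within ``radius`` bp has
    stronger per-column support (ties break to the leftmost position) --
    the same per-column evidence that defines candidates anchors the
    reported position.  The rule depends only on the support track, never
    on the candidate set, so raising the frequency cutoff always yields a
    subset of the lower-cutoff calls.  ``radius=0`` disables the filter.
    Known limitation: two genuinely distinct variants closer than
    ``radius`` suppress the weaker-supported one.
    """
    kept = []
    n = len(support)
    for p in candidates:
        i = p - offset
        lo, hi = max(0, i - radius), min(n, i + radius + 1)
        window = support[lo:hi]
        best = window.max()
        if support[i] < best:
            continue
        first_best = lo + int(np.argmax(window == best))
        if first_best == i:
            kept.append(p)
    return kept


def call_region(model: Network, bam_path: str, ref: dict[str, str],
                chrom: str, start: int | None = None, end: int | None = None,
                af_cutoff: float = 0.2, min_depth: int = 4,
                batch_size: int = 3000, flank: int = DEFAULT_FLANK,
                dedup_radius: int = 3) -> list[VariantCall]:
    """Candidate scan -> tensor encoding -> inference -> decoded calls.

    Deterministic for a fixed model and inputs; returns calls sorted by
    position.  Raising ``af_cutoff`` can only remove candidates, so the
    calls at a higher cutoff are a subset of those at a lower one.
    """
    seq = ref[chrom]
    start = 0 if start is None else start
    end = len(seq) if end is None else end
    lo = max(0, start - flank - 4)
    hi = min(len(seq), end + flank + 4)
    reads = list(read_alignments(bam_path, chrom, lo, hi))
    if not reads:
        return []
    rp = pileup_region(reads, seq, chrom, lo, hi)
    support = nonref_support_fraction(rp)
    cands = [p for p in find_candidates(rp, af_cutoff, min_depth)
             if start <= p < end and p - flank >= 0
             and p + flank + 1 <= len(seq)]
    cands = select_local_maxima(cands, support, offset=rp.start,
                                radius=dedup_radius)
    tensors = [encode_from_pileup(rp, c, flank) for c in cands]
    calls = call_sites(model, tensors, seq, batch_size)
    return [replace(c, support=float(support[c.pos - 1 - rp.start]))
            for c in calls]
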