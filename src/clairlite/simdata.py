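"""Synthetic diploid genomes, planted variants and error-bearing reads.

The simulator emits alignments at their TRUE generative coordinates with
exact CIGARs -- no aligner is involved -- so the pileup truth at every
position is known.  It keeps a per-position ledger of the aligned bases it
actually emitted, which downstream tests use as an independent oracle for
pileup counting.

Two stock error profiles follow the error regimes of the sequencing
technologies the caller targets: short-read-like at ~1% substitutions, and
single-molecule-like at 5-15% total error enriched for indels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    BASES,
    BASE_INDEX,
    AlignedRead,
    TruthVariant,
    write_bam,
    write_reference,
    write_vcf,
)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base i.i.d. sequencing error rates and the nominal read length."""

    substitution: float
    insertion: float
    deletion: float
    read_length: int
    name: str

    def __post_init__(self) -> None:
        rates = (self.substitution, self.insertion, self.deletion)
        if any(r < 0 for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be >= 0 and sum to < 0.5")

    @property
    def total_error(self) -> float:
        return self.substitution + self.insertion + self.deletion


#: Illumina-like short reads: ~1% substitutions, very few indel errors.
ILLUMINA = ErrorProfile(0.01, 0.0005, 0.0005, 148, "illumina")

#: Single-molecule-like long reads: ~14% total error, indel-enriched.
SMS = ErrorProfile(0.05, 0.04, 0.05, 1000, "sms")

PROFILES = {"illumina": ILLUMINA, "sms": SMS}


@dataclass
class SimLedger:
    """Ground truth of what the read simulator actually emitted.

    ``base_counts[p, b]`` counts reads whose alignment places base ``b``
    (post-error) at reference position ``p``; ``depth`` is its row sum.
    """

    base_counts: np.ndarray
    read_haplotypes: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1)


@dataclass
class PlantedTruth:
    """A reference, its planted variants, and the two haplotype edit maps.

    ``segments[h][i]`` is the string haplotype ``h`` emits at reference
    position ``i``: the (possibly substituted) base, followed by any
    inserted sequence anchored there, or ``""`` where the base is deleted.
    """

    chrom: str
    reference: str
    variants: list[TruthVariant]
    segments: tuple[list[str], list[str]]

    def haplotype(self, h: int) -> str:
        return "".join(self.segments[h])


def make_reference(length: int, gc: float = 0.5, seed: int = 0,
                   chrom: str = "ctg1") -> str:
    """Generate a random ACGT sequence with the requested GC fraction."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


DEFAULT_INDEL_LENGTH_WEIGHTS = {1: 0.40, 2: 0.22, 3: 0.14, 4: 0.10,
                                5: 0.06, 6: 0.04, 9: 0.04}


def plant_variants(ref: str, n_snp: int, n_ins: int, n_del: int,
                   het_fraction: float = 0.5,
                   indel_length_weights: dict[int, float] | None = None,
                   min_spacing: int = 40, seed: int = 0,
                   chrom: str = "ctg1") -> PlantedTruth:
    """Plant non-overlapping SNPs and indels on a diploid pair of haplotypes.

    Variant positions are drawn uniformly subject to a minimum spacing so
    that the 33-bp windows of neighbouring variants stay essentially clean.
    Heterozygous variants are assigned to one random haplotype, homozygous
    ones to both.  Indel lengths (including >4 bp) are drawn from
    ``indel_length_weights``.
    """
    rng = np.random.default_rng(seed)
    if indel_length_weights is None:
        indel_length_weights = DEFAULT_INDEL_LENGTH_WEIGHTS
    lengths = np.array(sorted(indel_length_weights))
    weights = np.array([indel_length_weights[k] for k in lengths], float)
    weights /= weights.sum()

    n_total = n_snp + n_ins + n_del
    L = len(ref)
    margin = 50  # keep variants clear of contig edges
    # rejection-sample positions at the required spacing
    positions: list[int] = []
    taken = np.zeros(L, bool)
    max_tries = 200 * max(n_total, 1)
    tries = 0
    while len(positions) < n_total and tries < max_tries:
        tries += 1
        p = int(rng.integers(margin, L - margin))
        lo, hi = max(0, p - min_spacing), min(L, p + min_spacing + 1)
        if not taken[lo:hi].any():
            positions.append(p)
            taken[p] = True
    if len(positions) < n_total:
        raise ValueError("could not place variants at the requested spacing")
    rng.shuffle(positions)

    types = ["SNP"] * n_snp + ["Insertion"] * n_ins + ["Deletion"] * n_del
    seg0, seg1 = list(ref), list(ref)
    segs = [seg0, seg1]
    variants: list[TruthVariant] = []
    for p, vtype in zip(positions, types):
        het = rng.random() < het_fraction
        haps = [int(rng.integers(0, 2))] if het else [0, 1]
        gt = (0, 1) if het else (1, 1)
        anchor = ref[p]
        if vtype == "SNP":
            alt = rng.choice([b for b in BASES if b != anchor])
            ref_allele, alt_allele = anchor, str(alt)
            for h in haps:
                segs[h][p] = alt_allele
        elif vtype == "Insertion":
            n = int(lengths[rng.choice(len(lengths), p=weights)])
            ins = "".join(rng.choice(list(BASES), size=n))
            ref_allele, alt_allele = anchor, anchor + ins
            for h in haps:
                segs[h][p] = segs[h][p] + ins
        else:
            n = int(lengths[rng.choice(len(lengths), p=weights)])
            ref_allele, alt_allele = ref[p:p + n + 1], anchor
            for h in haps:
                for q in range(p + 1, p + n + 1):
                    segs[h][q] = ""
        variants.append(TruthVariant(chrom, p + 1, ref_allele,
                                     (alt_allele,), gt))
    variants.sort(key=lambda v: v.pos)
    return PlantedTruth(chrom, ref, variants, (seg0, seg1))


def simulate_reads(truth: PlantedTruth, depth: int, profile: ErrorProfile,
                   seed: int = 0) -> tuple[list[AlignedRead], SimLedger]:
    """Sample reads uniformly from both haplotypes and inject errors.

    Substitution, insertion and deletion errors are placed i.i.d. per base
    at the profile's rates.  The returned ledger records, per reference
    position, the aligned bases the reads actually carry.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(truth.reference)
    rl = profile.read_length
    n_reads = int(np.ceil(depth * (L + rl - 1) / rl))
    base_counts = np.zeros((L, 4), dtype=np.int64)
    reads: list[AlignedRead] = []
    ledger = SimLedger(base_counts)
    bases = list(BASES)
    for k in range(n_reads):
        hap = int(rng.integers(0, 2))
        # sampling starts below 0 (clipped to 0, full length) keeps the
        # interior coverage flat instead of ramping at the left edge
        start = max(0, int(rng.integers(-(rl - 1), L)))
        read = _emit_read(truth.segments[hap], start, rl, profile, rng,
                          bases)
        if read is None:
            continue
        pos, cigar, seq, aligned = read
        name = f"read{k:06d}"
        r = AlignedRead(name, truth.chrom, pos, cigar, seq)
        reads.append(r)
        ledger.read_haplotypes[name] = hap
        for p, bi in aligned:
            base_counts[p, bi] += 1
    return reads, ledger


def _emit_read(segs, start, target, profile, rng, bases):
    """Walk haplotype segments from ``start``, injecting errors.

    Returns ``(pos, cigar, seq, aligned)`` where ``aligned`` lists the
    (reference position, base index) pairs of M-aligned bases, or ``None``
    if nothing alignable was produced.
    """
    ops: list[tuple[str, int]] = []
    seq: list[str] = []
    aligned: list[tuple[int, int]] = []
    pending: list[tuple[str, int, str | None, int]] = []

    def push(op, base=None, refpos=-1):
        pending.append((op, 1, base, refpos))

    emitted = 0
    i = start
    L = len(segs)
    while emitted < target and i < L:
        seg = segs[i]
        if seg == "":
            push("D")
            i += 1
            continue
        for j, ch in enumerate(seg):
            is_aligned = j == 0
            if rng.random() < profile.deletion:
                if is_aligned:
                    push("D")
                continue
            b = ch
            if rng.random() < profile.substitution:
                b = bases[(BASE_INDEX[b] + int(rng.integers(1, 4))) % 4]
            if is_aligned:
                push("M", b, i)
            else:
                push("I", b)
            emitted += 1
            while rng.random() < profile.insertion and emitted < target:
                push("I", bases[int(rng.integers(0, 4))])
                emitted += 1
            if emitted >= target:
                break
        i += 1

    # trim leading/trailing I and D so the alignment starts and ends on M
    first = next((k for k, p in enumerate(pending) if p[0] == "M"), None)
    last = next((k for k in range(len(pending) - 1, -1, -1)
                 if pending[k][0] == "M"), None)
    if first is None:
        return None
    pending = pending[first:last + 1]
    pos = pending[0][3]
    for op, n, base, refpos in pending:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))
        if base is not None:
            seq.append(base)
        if op == "M":
            aligned.append((refpos, BASE_INDEX[base]))
    return pos, ops, "".join(seq), aligned


def simulate(out_prefix: str | os.PathLike, length: int = 50_000,
             depth: int = 30, profile: ErrorProfile | str = SMS,
             n_snp: int = 430, n_ins: int = 35, n_del: int = 35,
             gc: float = 0.5, seed: int = 0,
             chrom: str = "ctg1") -> dict[str, str]:
    """Generate ref.fa, truth.vcf, reads.bam and ledger.tsv on disk."""
    if isinstance(profile, str):
        profile = PROFILES[profile]
    prefix = str(out_prefix)
    ref = make_reference(length, gc=gc, seed=seed, chrom=chrom)
    truth = plant_variants(ref, n_snp, n_ins, n_del, seed=seed + 1,
                           chrom=chrom)
    reads, ledger = simulate_reads(truth, depth, profile, seed=seed + 2)
    paths = {
        "ref": prefix + ".ref.fa",
        "vcf": prefix + ".truth.vcf",
        "bam": prefix + ".reads.bam",
        "ledger": prefix + ".ledger.tsv",
    }
    write_reference({chrom: ref}, paths["ref"])
    write_vcf([_as_call(v) for v in truth.variants], paths["vcf"],
              {chrom: length})
    write_bam(reads, {chrom: length}, paths["bam"])
    with open(paths["ledger"], "w") as fh:
        fh.write("pos\tA\tC\tG\tT\tdepth\n")
        for p in range(length):
            row = ledger.base_counts[p]
            fh.write(f"{p}\t" + "\t".join(map(str, row)) +
                     f"\t{row.sum()}\n")
    return paths


class _as_call:
    """Adapt a TruthVariant to the record surface ``write_vcf`` expects."""

    def __init__(self, v: TruthVariant):
        self.chrom, self.pos, self.ref, self.alt = (v.chrom, v.pos, v.ref,
                                                    v.alt)
        self.genotype = "0/1" if v.is_het else "1/1"
        self.quality = 100.0
        self.flags = ()
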