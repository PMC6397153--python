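"""Readers and writers for the standard formats the pipeline touches.

All other modules consume only the abstract records defined here:
:class:`AlignedRead`, :class:`TruthVariant` and :class:`RegionSet`.
Coordinates are 0-based half-open everywhere inside the package and are
converted to 1-based only when a VCF is written.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# CIGAR operations that consume the reference / the query.
_REF_CONSUMING = set("MD=X")
_QUERY_CONSUMING = set("MIS=X")
_PYSAM_OPS = "MIDNSHP=XB"


class FormatError(ValueError):
    """Raised on malformed or inconsistent input records."""


@dataclass
class AlignedRead:
    """A single primary alignment of a read against the reference.

    ``pos`` is the 0-based leftmost reference coordinate.  The CIGAR is a
    list of ``(op, length)`` pairs with ``op`` in ``M I D S = X``.
    """

    name: str
    chrom: str
    pos: int
    cigar: list[tuple[str, int]]
    seq: str
    mapq: int = 60

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)
        if qlen != len(self.seq):
            raise FormatError(
                f"read {self.name}: CIGAR consumes {qlen} query bases, "
                f"sequence has {len(self.seq)}"
            )

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def end(self) -> int:
        """0-based exclusive rightmost reference coordinate."""
        return self.pos + self.reference_span


@dataclass
class TruthVariant:
    """A truth (or re-parsed call) variant record; ``pos`` is 1-based."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.ref:
            raise FormatError("empty REF allele")
        self.ref = self.ref.upper()
        self.alts = tuple(a.upper() for a in self.alts)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) != 1

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def variant_type(self) -> str:
        d = len(self.alt) - len(self.ref)
        if d == 0:
            return "SNP"
        return "Insertion" if d > 0 else "Deletion"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass
class RegionSet:
    """Per-chromosome sorted, merged, half-open 0-based intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: _merge(ivs) for chrom, ivs in self.intervals.items()
        }

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def _merge(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            raise FormatError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# FASTA


def load_reference(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into a ``{chrom: uppercase sequence}`` mapping."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with pysam.FastaFile(str(path)) as fa:
        return {name: fa.fetch(name).upper() for name in fa.references}


def write_reference(seqs: Mapping[str, str], path: str | os.PathLike,
                    width: int = 70) -> None:
    """Write sequences as FASTA and build the .fai index."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    pysam.faidx(str(path))


# ---------------------------------------------------------------------------
# SAM/BAM


def read_alignments(path: str | os.PathLike, chrom: str | None = None,
                    start: int | None = None,
                    end: int | None = None) -> Iterator[AlignedRead]:
    """Iterate primary alignments overlapping a region.

    No mapping-quality filter is applied: low-quality mappings carry signal
    about untrustworthy regions and the model is left to learn that.
    Secondary and supplementary alignments are skipped so each read
    contributes one pileup observation; unmapped records are skipped.
    """
    with pysam.AlignmentFile(str(path)) as bam:
        if chrom is not None and chrom not in bam.references:
            raise FormatError(f"unknown chromosome {chrom!r}")
        it = bam.fetch(chrom, start, end) if chrom is not None else bam.fetch()
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cigar = [(_PYSAM_OPS[op], n) for op, n in aln.cigartuples]
            yield AlignedRead(
                name=aln.query_name,
                chrom=aln.reference_name,
                pos=aln.reference_start,
                cigar=cigar,
                seq=aln.query_sequence.upper(),
                mapq=aln.mapping_quality,
            )


def write_bam(reads: Sequence[AlignedRead], ref_lengths: Mapping[str, int],
              path: str | os.PathLike) -> None:
    """Write coordinate-sorted reads as an indexed BAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in ref_lengths.items()],
    }
    order = {c: i for i, c in enumerate(ref_lengths)}
    reads = sorted(reads, key=lambda r: (order[r.chrom], r.pos))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.reference_name = r.chrom
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigartuples = [(_PYSAM_OPS.index(op), n) for op, n in r.cigar]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | os.PathLike) -> list[TruthVariant]:
    """Read a single-sample VCF into :class:`TruthVariant` records."""
    out: list[TruthVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            if samples:
                gt = rec.samples[samples[0]].get("GT", (0, 1))
                gt = tuple(0 if g is None else g for g in gt)
                if len(gt) == 1:
                    gt = (gt[0], gt[0])
            else:
                gt = (0, 1)
            out.append(TruthVariant(rec.chrom, rec.pos, rec.ref,
                                    tuple(rec.alts), gt))
    return out


def write_vcf(calls: Sequence, path: str | os.PathLike,
              ref_lengths: Mapping[str, int],
              sample: str = "SAMPLE") -> None:
    """Write calls as a VCF 4.2 file.

    ``calls`` may be any records exposing ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt``, ``genotype`` and ``quality`` attributes (optionally
    ``flags``), e.g. :class:`clairlite.calling.VariantCall`.  Input must be
    sorted by (chrom, pos).
    """
    order = {c: i for i, c in enumerate(ref_lengths)}
    keys = [(order[c.chrom], c.pos) for c in calls]
    if keys != sorted(keys):
        raise FormatError("calls must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=PASS,Description="All filters passed">')
    header.add_line('##INFO=<ID=HD,Number=0,Type=Flag,'
                    'Description="Prediction heads disagreed">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,'
                    'Description="End position on the reference">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    for chrom, length in ref_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            alt = c.alt
            if not alt.startswith("<"):
                for a in (c.ref, alt):
                    if any(b not in BASES for b in a):
                        raise FormatError(f"non-ACGT allele {a!r}")
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos - 1, stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, alt), qual=float(c.quality), filter="PASS",
            )
            gt = tuple(int(g) for g in c.genotype.split("/"))
            rec.samples[sample]["GT"] = gt
            rec.samples[sample].phased = False
            if getattr(c, "flags", None):
                rec.info["HD"] = True
            vcf.write(rec)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> RegionSet:
    """Read a BED3 file (standard 0-based half-open intervals)."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"malformed BED line: {line!r}")
            ivs.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2])))
    return RegionSet(ivs)


def write_bed(regions: RegionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in regions.intervals.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")
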