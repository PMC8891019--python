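"""Spliced-alignment parsing, read filtering and junction counting.

The quantification re-implements, natively and unit-testably, the standard
workflow for counting cryptic-exon-informative junction reads: PCR
duplicates are dropped via the SAM duplicate flag (the output contract of
duplicate marking), uniquely mapped reads are kept by a MAPQ threshold
(default 255, mirroring ``samtools view -q 255`` on STAR output), reference
gaps (CIGAR N) with at least 6 aligned bases on each side become candidate
junctions, and each junction is classified against the gene model by exact
intron-boundary match.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pysam

from .locus import GeneModel, NAMED_JUNCTIONS, interval_length

__all__ = [
    "SplicedAlignment",
    "Junction",
    "JunctionCountTable",
    "parse_spliced_alignment",
    "passes_filters",
    "extract_junctions",
    "classify_junction",
    "count_sample",
    "count_table_to_frame",
]

#: CIGAR operator codes (SAM spec order)
_CONSUMES_REF_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_GAP = 3  # N
_CONSUMES_QUERY_ONLY = {1, 4}  # I, S
_IGNORED = {5}  # H consumes neither reference nor query
_UNSUPPORTED = {6, 9}  # P, B


class CigarError(ValueError):
    """Raised for CIGAR strings the pipeline cannot interpret."""


@dataclass(frozen=True)
class SplicedAlignment:
    """One read's reference-aligned blocks plus the filter-relevant flags.

    ``blocks`` are 1-based inclusive genomic intervals, sorted, separated by
    at least one base (each separation is a candidate splice junction).
    """

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mapq: int
    is_duplicate: bool

    def __post_init__(self) -> None:
        for s, e in self.blocks:
            if s > e:
                raise ValueError(f"empty block ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1 + 1:
                raise ValueError("blocks must be sorted and gap-separated")


@dataclass(frozen=True)
class Junction:
    """A reference gap: the skipped intron interval (1-based inclusive) and
    the aligned lengths of the flanking blocks."""

    chrom: str
    intron_start: int
    intron_end: int
    left_overhang: int
    right_overhang: int


def parse_spliced_alignment(rec: pysam.AlignedSegment) -> SplicedAlignment:
    """Reconstruct aligned blocks from a SAM record's POS and CIGAR.

    Reference-consuming operators M/=/X extend the current block, D extends
    it too (a deletion is not a splice), N closes the block and opens a new
    one after the gap, and I/S/H consume no reference.  P and B raise
    :class:`CigarError`.
    """
    if rec.cigartuples is None or not rec.cigartuples:
        raise CigarError(f"{rec.query_name}: missing CIGAR")
    pos = rec.reference_start + 1  # 1-based
    blocks: list[tuple[int, int]] = []
    block_start, cursor = pos, pos
    for op, length in rec.cigartuples:
        if op in _CONSUMES_REF_IN_BLOCK:
            cursor += length
        elif op == _GAP:
            if cursor > block_start:
                blocks.append((block_start, cursor - 1))
            cursor += length
            block_start = cursor
        elif op in _CONSUMES_QUERY_ONLY or op in _IGNORED:
            continue
        else:
            raise CigarError(
                f"{rec.query_name}: unsupported CIGAR operator code {op}"
            )
    if cursor > block_start:
        blocks.append((block_start, cursor - 1))
    if not blocks:
        raise CigarError(f"{rec.query_name}: CIGAR aligns no reference bases")
    return SplicedAlignment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        blocks=tuple(blocks),
        mapq=rec.mapping_quality,
        is_duplicate=rec.is_duplicate,
    )


def passes_filters(
    aln: SplicedAlignment,
    unique_mapq: int = 255,
    drop_duplicates: bool = True,
) -> bool:
    """Uniquely-mapped, non-duplicate filter: MAPQ >= ``unique_mapq`` and,
    when ``drop_duplicates``, the SAM duplicate flag unset."""
    if aln.mapq < unique_mapq:
        return False
    if drop_duplicates and aln.is_duplicate:
        return False
    return True


def extract_junctions(
    aln: SplicedAlignment, min_overhang: int = 6
) -> list[Junction]:
    """One junction per inter-block gap whose flanking blocks each align at
    least ``min_overhang`` bases; shorter-overhang gaps are discarded."""
    out = []
    for left, right in zip(aln.blocks, aln.blocks[1:]):
        lo, ro = interval_length(*left), interval_length(*right)
        if lo >= min_overhang and ro >= min_overhang:
            out.append(
                Junction(
                    chrom=aln.chrom,
                    intron_start=left[1] + 1,
                    intron_end=right[0] - 1,
                    left_overhang=lo,
                    right_overhang=ro,
                )
            )
    return out


def classify_junction(j: Junction, model: GeneModel) -> str:
    """Name a junction by exact match of its intron interval against the
    model's named junctions; anything else (including a junction on another
    chromosome) is ``"unclassified"``."""
    if j.chrom != model.chrom:
        return "unclassified"
    for name, (s, e) in model.named_junctions().items():
        if (j.intron_start, j.intron_end) == (s, e):
            return name
    return "unclassified"


@dataclass
class JunctionCountTable:
    """Per-sample junction-read counts plus the expression context needed
    for the suitability gate.

    ``counts`` holds the named junction classes; ``unclassified_junctions``
    tallies filtered junctions matching no named class;
    ``intron_body_reads`` counts reads with aligned bases inside the
    CE-harbouring intron but outside the CE178 footprint (inclusion-neutral
    evidence); ``naive_tpm`` is a simple length- and depth-normalized
    expression value computed from reads overlapping the exon model.
    """

    sample_id: str
    counts: dict[str, int] = field(
        default_factory=lambda: {nm: 0 for nm in NAMED_JUNCTIONS}
    )
    unclassified_junctions: int = 0
    intron_body_reads: int = 0
    within_ce_reads: int = 0
    exonic_model_reads: int = 0
    library_size: int = 0
    naive_tpm: float = 0.0

    def to_dict(self) -> dict:
        d = {"sample_id": self.sample_id}
        d.update(self.counts)
        d.update(
            unclassified_junctions=self.unclassified_junctions,
            intron_body_reads=self.intron_body_reads,
            within_ce_reads=self.within_ce_reads,
            exonic_model_reads=self.exonic_model_reads,
            library_size=self.library_size,
            naive_tpm=self.naive_tpm,
        )
        return d


def _overlaps(block: tuple[int, int], iv: tuple[int, int]) -> bool:
    return block[0] <= iv[1] and iv[0] <= block[1]


def count_alignments(
    alignments: list[SplicedAlignment],
    model: GeneModel,
    sample_id: str = "sample",
    min_overhang: int = 6,
    unique_mapq: int = 255,
    drop_duplicates: bool = True,
) -> JunctionCountTable:
    """Count named junctions over already-parsed alignments.

    Every filtered read contributes at most once per named junction (a read
    spanning two junctions increments both).  Also tallies within-CE reads
    (all blocks inside the CE178 footprint), intron-body reads and the
    exon-model read count used for the naive TPM.
    """
    t = JunctionCountTable(sample_id=sample_id)
    named = model.named_junctions()
    by_interval = {iv: nm for nm, iv in named.items()}
    intron_iv = model.intron_ce_interval()
    ce_iv = model.exons["CE178"]
    exon_ivs = list(model.exons.values())
    exonic_kb = model.model_exonic_length / 1_000.0

    for aln in alignments:
        if aln.chrom != model.chrom:
            raise ValueError(
                f"read {aln.read_id} on {aln.chrom!r}; model is on "
                f"{model.chrom!r}"
            )
        if not passes_filters(aln, unique_mapq, drop_duplicates):
            continue
        t.library_size += 1
        seen: set[str] = set()
        for j in extract_junctions(aln, min_overhang):
            nm = by_interval.get((j.intron_start, j.intron_end))
            if nm is None:
                t.unclassified_junctions += 1
            elif nm not in seen:
                t.counts[nm] += 1
                seen.add(nm)
        if all(ce_iv[0] <= s and e <= ce_iv[1] for s, e in aln.blocks):
            t.within_ce_reads += 1
        for s, e in aln.blocks:
            a, b = max(s, intron_iv[0]), min(e, intron_iv[1])
            if a <= b and (a < ce_iv[0] or b > ce_iv[1]):
                t.intron_body_reads += 1
                break
        if any(_overlaps(b, iv) for b in aln.blocks for iv in exon_ivs):
            t.exonic_model_reads += 1

    if t.library_size > 0:
        t.naive_tpm = (t.exonic_model_reads / exonic_kb) / (
            t.library_size / 1e6
        )
    return t


def count_sample(
    sam_path: str,
    model: GeneModel,
    sample_id: str | None = None,
    min_overhang: int = 6,
    unique_mapq: int = 255,
    drop_duplicates: bool = True,
) -> JunctionCountTable:
    """Quantify one SAM/BAM file against the gene model.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    the model chromosome is absent from the alignment header.
    """
    if not os.path.exists(sam_path):
        raise FileNotFoundError(sam_path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(sam_path))[0]
    mode = "rb" if sam_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(sam_path, mode, check_sq=False) as fh:
        if model.chrom not in fh.references:
            raise ValueError(
                f"chromosome {model.chrom!r} not in header of {sam_path}"
            )
        alignments = [
            parse_spliced_alignment(rec)
            for rec in fh
            if not rec.is_unmapped
        ]
    return count_alignments(
        alignments,
        model,
        sample_id=sample_id,
        min_overhang=min_overhang,
        unique_mapq=unique_mapq,
        drop_duplicates=drop_duplicates,
    )


def count_table_to_frame(tables: list[JunctionCountTable]):
    """Stack count tables into a one-row-per-sample DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame([t.to_dict() for t in tables])


def write_count_tables(tables: list[JunctionCountTable], path: str) -> None:
    """Write count tables as TSV (or JSON when the path ends in .json)."""
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump([t.to_dict() for t in tables], fh, indent=1)
    else:
        count_table_to_frame(tables).to_csv(path, sep="\t", index=False)
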