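"""Strand-aware allele handling and allele-specific cryptic-exon inclusion.

For a gene on the reverse strand, the alleles written in dbSNP/VCF (forward
strand) are the reverse complement of the bases carried by the transcript;
all alleles are stored forward-strand here and converted for display with
:func:`strand_convert`.

Allelic imbalance is measured from amplicon reads spanning the locus in a
heterozygote: CE-containing reads are partitioned by the base they carry at
the exonic CE SNP, and the per-sample risk-allele percentages are compared
with the per-sample reference-allele percentages by a two-sided paired
t-test (a per-sample exact binomial test against 0.5 is available as a
secondary check).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
from scipy import stats

from .junctions import (
    SplicedAlignment,
    classify_junction,
    extract_junctions,
    parse_spliced_alignment,
)
from .locus import GeneModel, SNPSite

__all__ = [
    "AmpliconRead",
    "AlleleTally",
    "PairedTestResult",
    "strand_convert",
    "classify_amplicon_read",
    "tally_alleles",
    "paired_allele_imbalance_test",
    "binomial_imbalance_test",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: junction-chain signatures of the recognised amplicon classes
_CHAIN_CLASSES = {
    frozenset({"e19-e20", "e20-e21"}): "canonical",
    frozenset({"e19-e20", "e20-CE128", "CE-e21"}): "CE128",
    frozenset({"e19-e20", "e20-CE178", "CE-e21"}): "CE178",
}


def strand_convert(allele: str, strand: str) -> str:
    """Convert a forward-strand allele to the given gene strand.

    Identity on '+'; reverse complement on '-' (so the dbSNP G risk allele
    of a minus-strand gene reads C on the transcript, and a CATC repeat
    motif reads GATG).
    """
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not set(allele) <= set("ACGT"):
        raise ValueError(f"allele must be over ACGT, got {allele!r}")
    if strand == "+":
        return allele
    return allele.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconRead:
    """A classified amplicon read: its splice-class and, when the read's
    class contains the CE and its alignment covers the SNP, the base at the
    SNP reported on the forward strand."""

    read_id: str
    splice_class: str  # canonical | CE128 | CE178 | other
    base_at_snp: str | None


def _base_at(rec: pysam.AlignedSegment, aln: SplicedAlignment, pos: int) -> str | None:
    """Read base aligned to reference ``pos`` (1-based), walking the
    gap-separated blocks; None when no block covers the position."""
    if rec.query_sequence is None:
        return None
    offset = 0
    for s, e in aln.blocks:
        if s <= pos <= e:
            return rec.query_sequence[offset + pos - s]
        offset += e - s + 1
    return None


def classify_amplicon_read(
    rec: pysam.AlignedSegment,
    model: GeneModel,
    snp: SNPSite,
    min_overhang: int = 6,
) -> AmpliconRead:
    """Derive an amplicon read's splice class from its junction chain and
    extract the base it carries at the CE SNP.

    The chain must match one of the canonical/CE128/CE178 signatures
    exactly; anything else is class ``"other"``.  The SNP base is reported
    only for CE-class reads whose alignment covers the SNP position.
    """
    aln = parse_spliced_alignment(rec)
    if aln.chrom != model.chrom:
        raise ValueError(
            f"read {aln.read_id} on {aln.chrom!r}, expected {model.chrom!r}"
        )
    chain = frozenset(
        classify_junction(j, model) for j in extract_junctions(aln, min_overhang)
    )
    splice_class = _CHAIN_CLASSES.get(chain, "other")
    base = None
    if splice_class in {"CE128", "CE178"}:
        base = _base_at(rec, aln, snp.pos)
    return AmpliconRead(aln.read_id, splice_class, base)


@dataclass
class AlleleTally:
    """Per-sample partition of CE-class reads by the allele carried at the
    CE SNP; bases matching neither allele (sequencing errors) are tallied
    as ``ce_reads_other`` and excluded from the percentage."""

    sample_id: str
    ce_reads_risk: int = 0
    ce_reads_ref: int = 0
    ce_reads_other: int = 0
    canonical_reads: int = 0

    @property
    def risk_share(self) -> float | None:
        informative = self.ce_reads_risk + self.ce_reads_ref
        if informative == 0:
            return None
        return self.ce_reads_risk / informative

    @property
    def risk_percent(self) -> float | None:
        share = self.risk_share
        return None if share is None else 100.0 * share

    @property
    def ref_percent(self) -> float | None:
        share = self.risk_share
        return None if share is None else 100.0 * (1.0 - share)


def tally_alleles(
    reads: list[AmpliconRead], snp: SNPSite, sample_id: str = "sample"
) -> AlleleTally:
    """Partition classified reads into the allele tally for one sample."""
    t = AlleleTally(sample_id=sample_id)
    for r in reads:
        if r.splice_class == "canonical":
            t.canonical_reads += 1
        elif r.splice_class in {"CE128", "CE178"}:
            if r.base_at_snp == snp.risk_allele:
                t.ce_reads_risk += 1
            elif r.base_at_snp == snp.reference_allele:
                t.ce_reads_ref += 1
            else:
                t.ce_reads_other += 1
    return t


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    mean_diff: float  # percentage points, risk% - reference%
    t_stat: float
    df: int
    p_two_sided: float


def paired_allele_imbalance_test(
    tallies: list[AlleleTally],
) -> PairedTestResult:
    """Two-sided paired t-test of risk% versus reference% across samples.

    Each sample contributes the pair (risk%, ref%); the statistic is
    t = mean(d) / (sd(d)/sqrt(n)) on d = risk% - ref% with n-1 degrees of
    freedom.  Raises for fewer than two samples, for samples with no
    informative CE reads, and for zero variance of the differences (the
    test is undefined).
    """
    if len(tallies) < 2:
        raise ValueError("paired test needs at least 2 samples")
    diffs = []
    for t in tallies:
        if t.risk_percent is None:
            raise ValueError(
                f"sample {t.sample_id!r} has no informative CE reads"
            )
        diffs.append(t.risk_percent - t.ref_percent)
    d = np.asarray(diffs, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; test undefined")
    n = d.size
    t_stat = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return PairedTestResult(
        n_pairs=n,
        mean_diff=float(d.mean()),
        t_stat=float(t_stat),
        df=df,
        p_two_sided=float(p),
    )


def binomial_imbalance_test(tally: AlleleTally) -> float:
    """Secondary per-sample check: exact two-sided binomial test of the
    risk-read count against a 0.5 allelic share."""
    n = tally.ce_reads_risk + tally.ce_reads_ref
    if n == 0:
        raise ValueError("no informative CE reads")
    return float(stats.binomtest(tally.ce_reads_risk, n, 0.5).pvalue)
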