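"""Synthetic-data generators with known ground truth.

Every input the quantification pipeline consumes can be generated here:
spliced single-end RNA-seq alignments (SAM) from a three-isoform mixture
(canonical, CE128-inclusion, CE178-inclusion), cohorts of such samples with
group-specific cryptic-exon prevalence, amplicon reads spanning the locus
with allele-dependent inclusion odds, genotype cohorts with a configurable
degree of linkage disequilibrium between two SNPs and a tandem-repeat indel,
and dose-linear abundance tables.

Reads are sampled uniformly along each isoform, with isoforms weighted by
their molar proportion times effective length, so junction-spanning read
counts are proportional to isoform abundance and the junction PSI estimator
downstream is unbiased.  All generators are deterministic functions of their
seed; identical parameters and seed give byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .locus import NAMED_JUNCTIONS, ToyLocus, interval_length

__all__ = [
    "SampleParams",
    "SampleTruth",
    "GroupDesign",
    "CohortDesign",
    "GenoDesign",
    "simulate_rnaseq_sample",
    "simulate_cohort",
    "simulate_amplicon_reads",
    "simulate_genotype_cohort",
    "simulate_abundance",
    "write_sam",
]

#: MAPQ value marking uniquely mapped reads (mirrors STAR's unique-mapper value)
UNIQUE_MAPQ = 255
#: MAPQ given to reads emitted as non-uniquely mapped
NONUNIQUE_MAPQ = 3
#: minimum aligned bases required on each side of a junction
MIN_OVERHANG = 6

_ISOFORM_CHAINS = {
    "canonical": ("e19", "e20", "e21"),
    "CE128": ("e19", "e20", "CE128", "e21"),
    "CE178": ("e19", "e20", "CE178", "e21"),
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SampleParams:
    """Per-sample generative parameters.

    psi_true
        proportion of transcripts carrying a cryptic exon, in [0, 1].
    ce178_share
        fraction of CE transcripts using the 178-base form (the 128-base
        form dominates in practice, hence the small default).
    depth
        expected number of junction-informative reads (reads spanning some
        junction with adequate overhang).
    duplicate_rate
        probability that a read is re-emitted as a PCR duplicate carrying
        the SAM duplicate flag.
    nonunique_rate
        probability that a read is emitted with sub-unique MAPQ.
    error_rate
        per-base substitution probability.
    unspliced_rate
        fraction of reads drawn from unspliced pre-mRNA instead of the
        mature isoform mixture (produces intron-body reads).
    """

    psi_true: float = 0.0
    ce178_share: float = 0.1
    depth: float = 1_000.0
    read_length: int = 100
    duplicate_rate: float = 0.0
    nonunique_rate: float = 0.0
    error_rate: float = 0.0
    unspliced_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "psi_true",
            "ce178_share",
            "duplicate_rate",
            "nonunique_rate",
            "error_rate",
            "unspliced_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length < 2 * MIN_OVERHANG:
            raise ValueError(
                f"read_length {self.read_length} shorter than twice the "
                f"minimum overhang ({MIN_OVERHANG})"
            )


@dataclass
class SampleTruth:
    """Realized ground truth for one simulated sample."""

    psi_true: float
    junction_counts: dict[str, int]
    n_junction_reads: int  # junction-spanning reads passing filters
    n_reads: int  # primary (non-duplicate) reads emitted
    n_intron_body_reads: int


def _isoform_blocks(locus: ToyLocus) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals of each isoform in genomic ascending order."""
    return {
        iso: sorted(locus.exons[n] for n in chain)
        for iso, chain in _ISOFORM_CHAINS.items()
    }


def _map_read(
    blocks: list[tuple[int, int]], offset: int, read_length: int
) -> list[tuple[int, int]]:
    """Map a read covering ``read_length`` bases of the exon-concatenated
    sequence starting at 0-based ``offset`` onto genomic blocks."""
    out: list[tuple[int, int]] = []
    remaining, skip = read_length, offset
    for s, e in blocks:
        blen = interval_length(s, e)
        if skip >= blen:
            skip -= blen
            continue
        take = min(blen - skip, remaining)
        out.append((s + skip, s + skip + take - 1))
        remaining -= take
        skip = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past the isoform end")
    return out


def _cigar_of(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{interval_length(s, e)}M")
    return "".join(parts)


def _read_sequence(
    locus: ToyLocus, blocks: list[tuple[int, int]], rng: np.random.Generator,
    error_rate: float,
) -> str:
    seq = "".join(locus.reference_sequence[s - 1 : e] for s, e in blocks)
    if error_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = rng.random(arr.size) < error_rate
        if hit.any():
            arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
            seq = arr.tobytes().decode()
    return seq


def _junctions_of_blocks(
    blocks: list[tuple[int, int]], min_overhang: int = MIN_OVERHANG
) -> list[tuple[int, int]]:
    juncs = []
    for left, right in zip(blocks, blocks[1:]):
        if (
            interval_length(*left) >= min_overhang
            and interval_length(*right) >= min_overhang
        ):
            juncs.append((left[1] + 1, right[0] - 1))
    return juncs


def sam_header(locus: ToyLocus) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": locus.chrom, "LN": locus.chrom_length}],
        }
    )


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    blocks: list[tuple[int, int]],
    seq: str,
    mapq: int,
    is_duplicate: bool,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = 0x400 if is_duplicate else 0
    a.reference_id = 0
    a.reference_start = blocks[0][0] - 1  # SAM POS is 1-based; pysam 0-based
    a.mapping_quality = mapq
    a.cigarstring = _cigar_of(blocks)
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def write_sam(
    records: list[pysam.AlignedSegment], locus: ToyLocus, path: str
) -> None:
    """Write alignments as plain-text SAM with an @SQ header line."""
    with pysam.AlignmentFile(path, "w", header=sam_header(locus)) as fh:
        for rec in records:
            fh.write(rec)


def simulate_rnaseq_sample(
    locus: ToyLocus, params: SampleParams, out_sam: str | None = None
) -> tuple[list[pysam.AlignedSegment], SampleTruth]:
    """Simulate one bulk RNA-seq sample over the locus.

    Returns the alignment records and the realized ground truth; if
    ``out_sam`` is given the records are also written there.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    psi, share = params.psi_true, params.ce178_share
    mix = {
        "canonical": 1.0 - psi,
        "CE128": psi * (1.0 - share),
        "CE178": psi * share,
    }
    iso_blocks = _isoform_blocks(locus)
    isoforms = list(mix)
    tlen = {
        iso: sum(interval_length(s, e) for s, e in iso_blocks[iso])
        for iso in isoforms
    }
    for iso in isoforms:
        if tlen[iso] < rl:
            raise ValueError(f"read_length {rl} exceeds isoform {iso} length")

    # length-weighted isoform sampling: reads ~ molar proportion x positions
    w = np.array([mix[iso] * (tlen[iso] - rl + 1) for iso in isoforms])
    wsum = w.sum()
    w = w / wsum
    n_junc = {iso: len(_ISOFORM_CHAINS[iso]) - 1 for iso in isoforms}
    informative_width = rl - 2 * MIN_OVERHANG + 1
    # expected junction-informative reads per emitted mature read
    e_informative = informative_width * sum(
        mix[iso] * n_junc[iso] for iso in isoforms
    ) / wsum
    n_mature = max(1, int(round(params.depth / e_informative)))
    n_pre = (
        0
        if params.unspliced_rate == 0
        else rng.binomial(n_mature, params.unspliced_rate)
    )

    named = locus.named_junctions()
    by_interval = {iv: nm for nm, iv in named.items()}
    intron_lo, intron_hi = locus.intron_ce_interval()
    ce_lo, ce_hi = locus.exons["CE178"]

    records: list[pysam.AlignedSegment] = []
    truth_counts = {nm: 0 for nm in NAMED_JUNCTIONS}
    n_junction_reads = 0
    n_intron_body = 0

    iso_idx = rng.choice(len(isoforms), size=n_mature, p=w)
    for i in range(n_mature + n_pre):
        if i < n_mature:
            iso = isoforms[iso_idx[i]]
            offset = int(rng.integers(0, tlen[iso] - rl + 1))
            blocks = _map_read(iso_blocks[iso], offset, rl)
        else:
            # unspliced pre-mRNA read: contiguous genomic window in the gene
            lo = min(s for s, _ in locus.exons.values())
            hi = max(e for _, e in locus.exons.values())
            start = int(rng.integers(lo, hi - rl + 2))
            blocks = [(start, start + rl - 1)]
        seq = _read_sequence(locus, blocks, rng, params.error_rate)
        mapq = (
            NONUNIQUE_MAPQ
            if rng.random() < params.nonunique_rate
            else UNIQUE_MAPQ
        )
        rec = _make_segment(
            sam_header(locus), f"read{i:07d}", blocks, seq, mapq, False
        )
        records.append(rec)
        if rng.random() < params.duplicate_rate:
            records.append(
                _make_segment(
                    sam_header(locus),
                    f"read{i:07d}_dup",
                    blocks,
                    seq,
                    mapq,
                    True,
                )
            )
        if mapq == UNIQUE_MAPQ:  # ground truth over filter-passing reads
            juncs = _junctions_of_blocks(blocks)
            hit = False
            for iv in juncs:
                nm = by_interval.get(iv)
                if nm is not None:
                    truth_counts[nm] += 1
                    hit = True
            if hit:
                n_junction_reads += 1
            # intron-body read: >=1 aligned base inside the CE-harbouring
            # intron but outside the CE178 footprint
            for s, e in blocks:
                a, b = max(s, intron_lo), min(e, intron_hi)
                if a <= b and (a < ce_lo or b > ce_hi):
                    n_intron_body += 1
                    break

    truth = SampleTruth(
        psi_true=psi,
        junction_counts=truth_counts,
        n_junction_reads=n_junction_reads,
        n_reads=n_mature + n_pre,
        n_intron_body_reads=n_intron_body,
    )
    if out_sam is not None:
        write_sam(records, locus, out_sam)
    return records, truth


@dataclass(frozen=True)
class GroupDesign:
    """One cohort group: ``psi_dist`` is ``("point", v)`` or
    ``("beta", a, b)`` and applies to CE-positive samples only;
    ``ce_prevalence`` is the fraction of samples with nonzero PSI."""

    label: str
    n_samples: int
    psi_dist: tuple = ("point", 0.0)
    ce_prevalence: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.ce_prevalence <= 1.0:
            raise ValueError("ce_prevalence must be in [0, 1]")
        if self.psi_dist[0] not in {"point", "beta"}:
            raise ValueError(f"unknown psi_dist kind {self.psi_dist[0]!r}")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupDesign, ...]
    defaults: SampleParams = SampleParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort design needs at least one group")


def simulate_cohort(
    locus: ToyLocus, design: CohortDesign, out_dir: str | None = None
) -> tuple[dict[str, list[pysam.AlignedSegment]], pd.DataFrame]:
    """Simulate a cohort: one SAM per sample plus a truth table.

    Returns ``(records_by_sample, truth)``; the truth table has one row per
    sample with columns sample_id, group, psi_true, depth and the realized
    junction counts.  With ``out_dir`` set, SAM files and ``truth.tsv`` are
    written there.
    """
    rng = np.random.default_rng(design.seed)
    records_by_sample: dict[str, list[pysam.AlignedSegment]] = {}
    rows = []
    for group in design.groups:
        for i in range(group.n_samples):
            positive = rng.random() < group.ce_prevalence
            if not positive:
                psi = 0.0
            elif group.psi_dist[0] == "point":
                psi = float(group.psi_dist[1])
            else:
                _, a, b = group.psi_dist
                psi = float(rng.beta(a, b))
            sample_id = f"{group.label}_{i:03d}"
            params = replace(
                design.defaults,
                psi_true=psi,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            recs, truth = simulate_rnaseq_sample(locus, params)
            records_by_sample[sample_id] = recs
            row = {
                "sample_id": sample_id,
                "group": group.label,
                "psi_true": psi,
                "depth": params.depth,
                "n_junction_reads": truth.n_junction_reads,
            }
            row.update(truth.junction_counts)
            rows.append(row)
            if out_dir is not None:
                write_sam(recs, locus, os.path.join(out_dir, sample_id + ".sam"))
    truth_df = pd.DataFrame(rows)
    if out_dir is not None:
        truth_df.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return records_by_sample, truth_df


def simulate_amplicon_reads(
    locus: ToyLocus,
    genotype: tuple[str, str],
    inclusion_odds_ratio: float,
    n_reads: int,
    seed: int = 0,
    psi: float = 0.5,
    ce178_share: float = 0.1,
    error_rate: float = 0.0,
    out_sam: str | None = None,
) -> tuple[list[pysam.AlignedSegment], dict[str, int]]:
    """Simulate full-length amplicon reads spanning e19 to e21.

    ``genotype`` gives the individual's two forward-strand alleles at the
    exonic CE SNP and must be heterozygous: allelic imbalance is undefined
    in a homozygote.  Each read is canonical, CE128 or CE178; CE reads carry
    the risk allele with risk:reference odds equal to
    ``inclusion_odds_ratio`` (i.e. probability OR/(OR+1)), while canonical
    reads (which do not contain the SNP) sample their source allele evenly.

    Returns the SAM records and the realized truth counts
    ``{ce_risk, ce_ref, ce_other, canonical}``.
    """
    snp = locus.snp_ce
    if set(genotype) != {snp.dbsnp_ref, snp.dbsnp_alt}:
        raise ValueError(
            f"genotype {genotype} is not heterozygous "
            f"{snp.dbsnp_ref}/{snp.dbsnp_alt}: allelic imbalance undefined"
        )
    if inclusion_odds_ratio <= 0:
        raise ValueError("inclusion odds ratio must be > 0")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")

    rng = np.random.default_rng(seed)
    iso_blocks = _isoform_blocks(locus)
    p_risk_given_ce = inclusion_odds_ratio / (inclusion_odds_ratio + 1.0)
    truth = {"ce_risk": 0, "ce_ref": 0, "ce_other": 0, "canonical": 0}
    records: list[pysam.AlignedSegment] = []
    header = sam_header(locus)
    other_bases = [
        b for b in "ACGT" if b not in (snp.risk_allele, snp.reference_allele)
    ]
    for i in range(n_reads):
        if rng.random() < psi:
            iso = "CE178" if rng.random() < ce178_share else "CE128"
            allele = (
                snp.risk_allele
                if rng.random() < p_risk_given_ce
                else snp.reference_allele
            )
        else:
            iso = "canonical"
            allele = genotype[int(rng.random() < 0.5)]
        blocks = iso_blocks[iso]
        seq = list("".join(locus.reference_sequence[s - 1 : e] for s, e in blocks))
        if iso != "canonical":
            # place the allele at the SNP position within the CE block
            snp_off = 0
            for s, e in blocks:
                if s <= snp.pos <= e:
                    snp_off += snp.pos - s
                    break
                snp_off += interval_length(s, e)
            if error_rate > 0 and rng.random() < error_rate:
                allele = other_bases[int(rng.integers(len(other_bases)))]
            seq[snp_off] = allele
            if allele == snp.risk_allele:
                truth["ce_risk"] += 1
            elif allele == snp.reference_allele:
                truth["ce_ref"] += 1
            else:
                truth["ce_other"] += 1
        else:
            truth["canonical"] += 1
        records.append(
            _make_segment(
                header, f"amp{i:06d}", blocks, "".join(seq), UNIQUE_MAPQ, False
            )
        )
    if out_sam is not None:
        write_sam(records, locus, out_sam)
    return records, truth


def simulate_allele_tallies(
    n_samples: int,
    inclusion_odds_ratio: float,
    n_ce_reads: int,
    seed: int = 0,
):
    """Tally-level counterpart of :func:`simulate_amplicon_reads` for
    replicate studies: draws each sample's CE-read risk-allele count
    directly from Binomial(n_ce_reads, OR/(OR+1)) — the exact allele
    mechanism of the read-level generator — without materialising reads.
    """
    from .alleles import AlleleTally

    if inclusion_odds_ratio <= 0:
        raise ValueError("inclusion odds ratio must be > 0")
    rng = np.random.default_rng(seed)
    p = inclusion_odds_ratio / (inclusion_odds_ratio + 1.0)
    tallies = []
    for i in range(n_samples):
        k = int(rng.binomial(n_ce_reads, p))
        tallies.append(
            AlleleTally(
                sample_id=f"s{i}",
                ce_reads_risk=k,
                ce_reads_ref=n_ce_reads - k,
            )
        )
    return tallies


@dataclass(frozen=True)
class GenoDesign:
    """Design of a genotype cohort with two tag SNPs and a repeat indel.

    A latent risk/reference state is drawn per haplotype at frequency
    ``risk_haplotype_freq``; each of the three markers copies that state
    with probability ``r2_link ** 0.25`` and otherwise re-draws from the
    population frequency, which makes the expected squared correlation
    between any two markers approximately ``r2_link``.  Risk-state
    haplotypes carry 3-5 additional repeat units by default; reference
    haplotypes carry 0-2.
    """

    n_individuals: int = 100
    risk_haplotype_freq: float = 0.35
    r2_link: float = 1.0
    repeat_extra_given_risk: tuple[int, int] = (3, 5)
    repeat_extra_given_ref: tuple[int, int] = (0, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_haplotype_freq <= 1.0:
            raise ValueError("risk_haplotype_freq must be in [0, 1]")
        if not 0.0 <= self.r2_link <= 1.0:
            raise ValueError("r2_link must be in [0, 1]")
        for lo, hi in (self.repeat_extra_given_risk, self.repeat_extra_given_ref):
            if lo < 0 or hi < lo:
                raise ValueError("repeat ranges must be non-negative and ordered")


def simulate_genotype_cohort(
    locus: ToyLocus, design: GenoDesign, out_vcf: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate genotypes at the exonic SNP, the intronic SNP and the
    repeat indel, in LD with a latent risk haplotype.

    Returns ``(genotypes, truth)``: the genotype table has one row per
    individual with allele-pair columns ``snp_ce``, ``snp_intron`` and
    ``repeat_extra`` (extra units per allele); truth records the latent
    haplotype dose.  With ``out_vcf`` set, a VCF v4.2 with the three sites
    is written.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_individuals
    f = design.risk_haplotype_freq
    q = design.r2_link**0.25

    hap_state = rng.random((n, 2)) < f  # latent risk state per haplotype

    def marker_states() -> np.ndarray:
        copy = rng.random((n, 2)) < q
        fresh = rng.random((n, 2)) < f
        return np.where(copy, hap_state, fresh)

    snp_a_state = marker_states()
    snp_b_state = marker_states()
    rep_state = marker_states()
    lo_r, hi_r = design.repeat_extra_given_risk
    lo_n, hi_n = design.repeat_extra_given_ref
    rep_extra = np.where(
        rep_state,
        rng.integers(lo_r, hi_r + 1, size=(n, 2)),
        rng.integers(lo_n, hi_n + 1, size=(n, 2)),
    )

    snp_ce, snp_intron = locus.snp_ce, locus.snp_intron
    rows = []
    for i in range(n):
        rows.append(
            {
                "individual": f"ind{i:04d}",
                "snp_ce": tuple(
                    snp_ce.dbsnp_alt if s else snp_ce.dbsnp_ref
                    for s in snp_a_state[i]
                ),
                "snp_intron": tuple(
                    snp_intron.dbsnp_alt if s else snp_intron.dbsnp_ref
                    for s in snp_b_state[i]
                ),
                "repeat_extra": tuple(int(x) for x in rep_extra[i]),
            }
        )
    genotypes = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "individual": genotypes["individual"],
            "haplotype_dose": hap_state.sum(axis=1),
            "snp_ce_dose": snp_a_state.sum(axis=1),
            "snp_intron_dose": snp_b_state.sum(axis=1),
        }
    )
    if out_vcf is not None:
        _write_genotype_vcf(locus, genotypes, rep_extra, out_vcf)
    return genotypes, truth


def _write_genotype_vcf(
    locus: ToyLocus,
    genotypes: pd.DataFrame,
    rep_extra: np.ndarray,
    path: str,
) -> None:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(locus.chrom, length=locus.chrom_length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for ind in genotypes["individual"]:
        header.add_sample(ind)

    snp_ce, snp_intron, rep = locus.snp_ce, locus.snp_intron, locus.repeat_site
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for snp, col in ((snp_ce, "snp_ce"), (snp_intron, "snp_intron")):
            rec = vcf.new_record(
                contig=locus.chrom,
                start=snp.pos - 1,
                alleles=(snp.dbsnp_ref, snp.dbsnp_alt),
                id=snp.id,
            )
            for ind, gt in zip(genotypes["individual"], genotypes[col]):
                rec.samples[ind]["GT"] = tuple(
                    int(a == snp.dbsnp_alt) for a in gt
                )
                rec.samples[ind].phased = False
            vcf.write(rec)

        # multi-allelic repeat indel: anchor base + k tandem motif copies
        anchor_pos = rep.pos - 1  # base before the repeat array, 1-based
        anchor = locus.base_at(anchor_pos)
        extras = sorted(set(int(x) for x in rep_extra.ravel()) - {0})
        alleles = (anchor,) + tuple(anchor + rep.motif * k for k in extras)
        index_of = {0: 0, **{k: j + 1 for j, k in enumerate(extras)}}
        rec = vcf.new_record(
            contig=locus.chrom,
            start=anchor_pos - 1,
            alleles=alleles,
            id=rep.id,
        )
        for i, ind in enumerate(genotypes["individual"]):
            rec.samples[ind]["GT"] = tuple(
                index_of[int(k)] for k in rep_extra[i]
            )
            rec.samples[ind].phased = False
        vcf.write(rec)


def simulate_abundance(
    doses: np.ndarray | list[int],
    beta0: float,
    beta1: float,
    sigma: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-individual abundance ``beta0 + beta1 * dose + N(0, sigma)``.

    ``doses`` must take values in {0, 1, 2} (risk-haplotype copies);
    ``sigma`` must be non-negative.
    """
    doses = np.asarray(doses)
    if not np.isin(doses, (0, 1, 2)).all():
        raise ValueError("doses must be in {0, 1, 2}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=doses.size) if sigma > 0 else 0.0
    return pd.DataFrame(
        {
            "individual": [f"ind{i:04d}" for i in range(doses.size)],
            "dose": doses,
            "abundance": beta0 + beta1 * doses + noise,
        }
    )
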