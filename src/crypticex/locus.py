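"""Gene models for cryptic-exon quantification.

The object of study is a multi-exon locus on the reverse strand carrying two
overlapping cryptic exons (CEs) between two canonical exons.  The two CEs
share their transcript 3' end (on the minus strand this is the lower genomic
coordinate) and differ by 50 bases at the 5' end: a 128-base form and a
178-base form.  The locus also carries an exonic SNP inside the shorter CE, an
intronic SNP between the upstream canonical exon and the CE, and a 4-base
tandem-repeat site in the same intron.

All genomic coordinates are 1-based inclusive throughout the package.
Junctions are represented by the genomic interval of the skipped intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SNPSite",
    "RepeatSite",
    "GeneModel",
    "ToyLocus",
    "LayoutError",
    "build_toy_locus",
    "interval_length",
    "write_bed12",
    "read_bed12",
    "write_gff3",
    "read_gff3",
]

#: canonical order of exon names along the transcript (5' -> 3')
TRANSCRIPT_ORDER = ("e19", "e20", "CE128", "CE178", "e21")

#: the junction classes quantified by the pipeline
NAMED_JUNCTIONS = ("e19-e20", "e20-CE128", "e20-CE178", "CE-e21", "e20-e21")


class LayoutError(ValueError):
    """Raised when exon intervals violate the locus geometry."""


def interval_length(start: int, end: int) -> int:
    """Inclusive length of a 1-based genomic interval."""
    return end - start + 1


@dataclass(frozen=True)
class SNPSite:
    """A biallelic SNP with dbSNP-style forward-strand alleles.

    ``dbsnp_ref``/``dbsnp_alt`` are single bases on the genomic forward
    strand, as dbSNP reports them; for a minus-strand gene the gene-strand
    alleles are their reverse complements.  ``risk_is_alt`` marks which
    allele is the disease-risk allele.
    """

    id: str
    chrom: str
    pos: int
    dbsnp_ref: str
    dbsnp_alt: str
    risk_is_alt: bool = True

    def __post_init__(self) -> None:
        for b in (self.dbsnp_ref, self.dbsnp_alt):
            if b not in {"A", "C", "G", "T"}:
                raise ValueError(f"allele must be a single ACGT base, got {b!r}")
        if self.dbsnp_ref == self.dbsnp_alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def risk_allele(self) -> str:
        return self.dbsnp_alt if self.risk_is_alt else self.dbsnp_ref

    @property
    def reference_allele(self) -> str:
        return self.dbsnp_ref if self.risk_is_alt else self.dbsnp_alt


@dataclass(frozen=True)
class RepeatSite:
    """A tandem-repeat indel site: ``baseline_units`` copies of ``motif``
    (forward strand) starting at ``pos``; alleles add further whole units."""

    chrom: str
    pos: int
    motif: str = "CATC"
    baseline_units: int = 6
    id: str = "repeat"


@dataclass
class GeneModel:
    """Named exon intervals on one chromosome, as used for junction
    classification.  ``exons`` maps exon name -> (start, end), 1-based
    inclusive."""

    chrom: str
    strand: str
    exons: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self._validate_exons()

    def _validate_exons(self) -> None:
        for name, (s, e) in self.exons.items():
            if s > e or s < 1:
                raise LayoutError(f"exon {name}: bad interval ({s}, {e})")
        # pairwise non-overlapping except CE128 within CE178
        items = list(self.exons.items())
        for i, (na, (sa, ea)) in enumerate(items):
            for nb, (sb, eb) in items[i + 1 :]:
                if sa <= eb and sb <= ea:  # overlap
                    if {na, nb} == {"CE128", "CE178"}:
                        continue
                    raise LayoutError(f"exons {na} and {nb} overlap")
        if "CE128" in self.exons and "CE178" in self.exons:
            (s1, e1), (s2, e2) = self.exons["CE128"], self.exons["CE178"]
            if not (s2 <= s1 and e1 <= e2):
                raise LayoutError("CE128 must lie within CE178")
            shared = e1 == e2 if self.strand == "+" else s1 == s2
            if not shared:
                raise LayoutError("CE128 and CE178 must share the transcript 3' end")

    def exon_length(self, name: str) -> int:
        s, e = self.exons[name]
        return interval_length(s, e)

    @property
    def model_exonic_length(self) -> int:
        """Total bases covered by the exon union (CE128 lies inside CE178)."""
        ivs = sorted(self.exons.values())
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += interval_length(cur_s, cur_e)
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += interval_length(cur_s, cur_e)
        return total

    def named_junctions(self) -> dict[str, tuple[int, int]]:
        """Intron interval (1-based inclusive) of each named junction.

        A junction X-Y spans the genomic gap between the adjacent boundaries
        of exons X and Y.  ``CE-e21`` is a single junction shared by both CE
        forms (they share the transcript 3' end).
        """

        def gap(a: str, b: str) -> tuple[int, int]:
            (sa, ea), (sb, eb) = self.exons[a], self.exons[b]
            if ea < sb:
                return (ea + 1, sb - 1)
            if eb < sa:
                return (eb + 1, sa - 1)
            raise LayoutError(f"exons {a} and {b} are not separated")

        return {
            "e19-e20": gap("e19", "e20"),
            "e20-CE128": gap("e20", "CE128"),
            "e20-CE178": gap("e20", "CE178"),
            "CE-e21": gap("CE128", "e21"),
            "e20-e21": gap("e20", "e21"),
        }

    def intron_ce_interval(self) -> tuple[int, int]:
        """Genomic interval of the intron between e20 and e21 (the intron
        that harbours the cryptic exons)."""
        (s20, e20), (s21, e21) = self.exons["e20"], self.exons["e21"]
        if e21 < s20:
            return (e21 + 1, s20 - 1)
        return (e20 + 1, s21 - 1)


@dataclass
class ToyLocus(GeneModel):
    """A fully specified synthetic locus: a :class:`GeneModel` plus
    chromosome length, SNP/repeat sites and a reference sequence."""

    chrom_length: int = 12_000
    snp_ce: SNPSite | None = None
    snp_intron: SNPSite | None = None
    repeat_site: RepeatSite | None = None
    reference_sequence: str = ""

    def base_at(self, pos: int) -> str:
        return self.reference_sequence[pos - 1]


_DEFAULT_EXONS = {
    "e21": (1_001, 1_200),
    "CE128": (3_001, 3_128),
    "CE178": (3_001, 3_178),
    "e20": (5_001, 5_150),
    "e19": (7_001, 7_200),
}


def build_toy_locus(
    chrom: str = "chrT",
    chrom_length: int = 12_000,
    strand: str = "-",
    exons: dict[str, tuple[int, int]] | None = None,
    snp_ce_pos: int = 3_050,
    snp_intron_pos: int = 4_500,
    repeat_pos: int = 4_000,
    repeat_motif: str = "CATC",
    repeat_baseline_units: int = 6,
    seed: int = 0,
) -> ToyLocus:
    """Construct the default synthetic locus.

    The default layout places, on the minus strand of a 12 kb chromosome,
    e21 at 1,001-1,200, the two cryptic exons at 3,001-3,128 / 3,001-3,178
    (sharing the lower coordinate, the transcript 3' end), e20 at
    5,001-5,150 and e19 at 7,001-7,200.  The exonic SNP sits at 3,050
    (inside CE128), the intronic SNP at 4,500 and the repeat site at 4,000.
    The reference sequence is a deterministic function of ``seed`` with the
    repeat array and SNP reference bases planted.
    """
    exons = dict(exons) if exons is not None else dict(_DEFAULT_EXONS)
    span_end = max(e for _, e in exons.values())
    if chrom_length < span_end:
        raise LayoutError(
            f"chrom_length {chrom_length} shorter than exon span {span_end}"
        )

    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_length)

    # plant the repeat array (forward strand) and the SNP reference bases
    repeat = repeat_motif * repeat_baseline_units
    seq[repeat_pos - 1 : repeat_pos - 1 + len(repeat)] = list(
        np.frombuffer(repeat.encode(), dtype="S1")
    )
    # dbSNP-style alleles: exonic-CE SNP C>G, intronic SNP A>C (forward strand)
    seq[snp_ce_pos - 1] = b"C"
    seq[snp_intron_pos - 1] = b"A"
    reference_sequence = seq.tobytes().decode()

    return ToyLocus(
        chrom=chrom,
        strand=strand,
        exons=exons,
        chrom_length=chrom_length,
        snp_ce=SNPSite("snp_ce", chrom, snp_ce_pos, "C", "G", risk_is_alt=True),
        snp_intron=SNPSite(
            "snp_intron", chrom, snp_intron_pos, "A", "C", risk_is_alt=True
        ),
        repeat_site=RepeatSite(
            chrom, repeat_pos, repeat_motif, repeat_baseline_units
        ),
        reference_sequence=reference_sequence,
    )


def mirror_locus(locus: ToyLocus) -> ToyLocus:
    """Reflect a minus-strand locus onto the plus strand (or vice versa).

    Coordinates are mapped x -> L - x + 1, the reference sequence is reverse
    complemented, and exon names are preserved, so named junction counts on
    mirrored reads must be identical.
    """
    L = locus.chrom_length

    def refl(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (L - e + 1, L - s + 1)

    comp = str.maketrans("ACGT", "TGCA")
    new_strand = "+" if locus.strand == "-" else "-"

    def refl_snp(snp: SNPSite | None) -> SNPSite | None:
        if snp is None:
            return None
        return replace(
            snp,
            pos=L - snp.pos + 1,
            dbsnp_ref=snp.dbsnp_ref.translate(comp),
            dbsnp_alt=snp.dbsnp_alt.translate(comp),
        )

    rep = locus.repeat_site
    if rep is not None:
        rep_len = len(rep.motif) * rep.baseline_units
        rep = replace(
            rep,
            pos=L - (rep.pos + rep_len - 1) + 1,
            motif=rep.motif.translate(comp)[::-1],
        )
    return ToyLocus(
        chrom=locus.chrom,
        strand=new_strand,
        exons={n: refl(iv) for n, iv in locus.exons.items()},
        chrom_length=L,
        snp_ce=refl_snp(locus.snp_ce),
        snp_intron=refl_snp(locus.snp_intron),
        repeat_site=rep,
        reference_sequence=locus.reference_sequence.translate(comp)[::-1],
    )


# ---------------------------------------------------------------------------
# gene-model serialization: BED12 (one line per isoform) and GFF3
# ---------------------------------------------------------------------------

_ISOFORM_CHAINS = {
    "canonical": ("e19", "e20", "e21"),
    "inclusion128": ("e19", "e20", "CE128", "e21"),
    "inclusion178": ("e19", "e20", "CE178", "e21"),
}


def write_bed12(model: GeneModel, path: str) -> None:
    """Write the gene model as BED12, one line per isoform; block structure
    encodes the exon chain of each isoform."""
    lines = []
    for iso, chain in _ISOFORM_CHAINS.items():
        ivs = sorted(model.exons[n] for n in chain)
        chrom_start = ivs[0][0] - 1  # BED is 0-based half-open
        chrom_end = ivs[-1][1]
        sizes = ",".join(str(interval_length(s, e)) for s, e in ivs)
        starts = ",".join(str(s - 1 - chrom_start) for s, _ in ivs)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    model.chrom,
                    chrom_start,
                    chrom_end,
                    iso,
                    0,
                    model.strand,
                    chrom_start,
                    chrom_end,
                    "0,0,0",
                    len(ivs),
                    sizes,
                    starts,
                )
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bed12(path: str) -> GeneModel:
    """Reconstruct the named gene model from the three-isoform BED12 file
    produced by :func:`write_bed12`."""
    blocks: dict[str, list[tuple[int, int]]] = {}
    chrom = strand = None
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, strand = f[0], f[5]
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks[f[3]] = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
    if set(blocks) != set(_ISOFORM_CHAINS):
        raise ValueError(
            f"expected isoforms {sorted(_ISOFORM_CHAINS)}, got {sorted(blocks)}"
        )
    canon = sorted(blocks["canonical"])
    exons: dict[str, tuple[int, int]] = {}
    # name the canonical blocks by transcript order (strand-aware)
    order = ("e21", "e20", "e19") if strand == "-" else ("e19", "e20", "e21")
    for name, iv in zip(order, canon):
        exons[name] = iv
    for iso, ce in (("inclusion128", "CE128"), ("inclusion178", "CE178")):
        novel = [iv for iv in blocks[iso] if iv not in canon]
        if len(novel) != 1:
            raise ValueError(f"{iso}: expected exactly one novel block")
        exons[ce] = novel[0]
    return GeneModel(chrom=chrom, strand=strand, exons=exons)


def write_gff3(model: GeneModel, path: str, gene_id: str = "toygene") -> None:
    """Write the gene model as GFF3 with named exon features."""
    rows = [f"##gff-version 3"]
    span = (
        min(s for s, _ in model.exons.values()),
        max(e for _, e in model.exons.values()),
    )
    rows.append(
        "\t".join(
            [
                model.chrom,
                "crypticex",
                "gene",
                str(span[0]),
                str(span[1]),
                ".",
                model.strand,
                ".",
                f"ID={gene_id}",
            ]
        )
    )
    for name, (s, e) in sorted(model.exons.items(), key=lambda kv: kv[1]):
        rows.append(
            "\t".join(
                [
                    model.chrom,
                    "crypticex",
                    "exon",
                    str(s),
                    str(e),
                    ".",
                    model.strand,
                    ".",
                    f"ID=exon-{name};Parent={gene_id};Name={name}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def read_gff3(path: str) -> GeneModel:
    """Load a gene model from GFF3 exon features carrying ``Name``
    attributes (via :mod:`gffutils`)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    exons: dict[str, tuple[int, int]] = {}
    chrom = strand = None
    for feat in db.features_of_type("exon"):
        name = feat.attributes.get("Name", [feat.id])[0]
        exons[name] = (feat.start, feat.end)
        chrom, strand = feat.seqid, feat.strand
    if not exons:
        raise ValueError(f"no exon features found in {path}")
    return GeneModel(chrom=chrom, strand=strand, exons=exons)
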