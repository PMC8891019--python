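"""Linkage-disequilibrium tagging, repeat dosage and dose-association.

The LD check is a genotype-independence chi-square: individuals are
cross-tabulated by unphased genotype class at two loci and the usual
sum((O-E)^2/E) statistic is referred to the chi-square distribution, with
degrees of freedom counted from the observed non-empty genotype classes
(no continuity correction, no cell pooling).  The repeat locus is scored as
additional tandem motif units per allele; haplotype dose (0/1/2 risk
copies) is inferred only for individuals whose risk-allele counts agree at
both tag SNPs, others are excluded with a recorded reason.  The dose to
abundance association is an ordinary least-squares regression with the
dose coded additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenotypeTable",
    "ChiSqResult",
    "OLSResult",
    "read_genotypes_vcf",
    "genotype_chisq",
    "repeat_dosage",
    "haplotype_dose",
    "ols_association",
    "spearman_corr",
    "delta_delta_ct",
]


@dataclass
class LocusMeta:
    id: str
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]


@dataclass
class GenotypeTable:
    """Unphased genotypes: per locus, one unordered allele-string pair per
    individual (None for missing)."""

    individuals: list[str]
    loci: dict[str, LocusMeta]
    genotypes: dict[str, list[tuple[str, str] | None]]

    def genotype_classes(self, locus_id: str) -> list[str | None]:
        """Genotype class labels (sorted allele pair) per individual."""
        out = []
        for gt in self.genotypes[locus_id]:
            out.append(None if gt is None else "/".join(sorted(gt)))
        return out

    def allele_count(self, locus_id: str) -> int:
        meta = self.loci[locus_id]
        return 1 + len(meta.alts)


def read_genotypes_vcf(path: str) -> GenotypeTable:
    """Load a GT-only VCF (v4.2, multi-allelic records allowed) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    loci: dict[str, LocusMeta] = {}
    genotypes: dict[str, list[tuple[str, str] | None]] = {}
    for var in vcf:
        locus_id = var.ID or f"{var.CHROM}:{var.POS}"
        alleles = [var.REF] + list(var.ALT)
        loci[locus_id] = LocusMeta(
            id=locus_id,
            chrom=var.CHROM,
            pos=var.POS,
            ref=var.REF,
            alts=tuple(var.ALT),
        )
        col: list[tuple[str, str] | None] = []
        for g in var.genotypes:  # [allele1, allele2, phased]
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col.append(None)
            else:
                col.append((alleles[a], alleles[b]))
        genotypes[locus_id] = col
    vcf.close()
    return GenotypeTable(individuals=individuals, loci=loci, genotypes=genotypes)


@dataclass(frozen=True)
class ChiSqResult:
    chi2: float
    df: int
    p: float
    table_dims: tuple[int, int]


def genotype_chisq(
    classes_a: list[str | None], classes_b: list[str | None]
) -> ChiSqResult:
    """Genotype-independence chi-square between two loci.

    Takes per-individual genotype-class labels (missing as None); builds
    the observed contingency table over individuals genotyped at both
    loci; chi2 = sum((O-E)^2/E) over cells with E > 0, df =
    (rows-1)(cols-1) counting observed non-empty classes.  Raises when a
    locus shows a single genotype class (independence is undefined).
    """
    if len(classes_a) != len(classes_b):
        raise ValueError("class vectors must have equal length")
    pairs = [
        (a, b) for a, b in zip(classes_a, classes_b) if a is not None and b is not None
    ]
    if len(pairs) < 2:
        raise ValueError("need >= 2 individuals genotyped at both loci")
    rows = sorted({a for a, _ in pairs})
    cols = sorted({b for _, b in pairs})
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("a locus with one observed genotype class is degenerate")
    obs = np.zeros((len(rows), len(cols)))
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for a, b in pairs:
        obs[ri[a], ci[b]] += 1
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = expected > 0
    chi2 = float(((obs - expected) ** 2 / np.where(mask, expected, 1.0))[mask].sum())
    df = (len(rows) - 1) * (len(cols) - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ChiSqResult(chi2=chi2, df=df, p=p, table_dims=(len(rows), len(cols)))


def genotype_chisq_table(
    table: GenotypeTable, locus_a: str, locus_b: str,
    min_alleles: int = 2, max_alleles: int = 8,
) -> ChiSqResult:
    """Chi-square between two loci of a :class:`GenotypeTable`, enforcing
    the allele-count bounds applied when scanning multi-allelic sites."""
    for lid in (locus_a, locus_b):
        k = table.allele_count(lid)
        if not min_alleles <= k <= max_alleles:
            raise ValueError(
                f"locus {lid!r} has {k} alleles, outside "
                f"[{min_alleles}, {max_alleles}]"
            )
    return genotype_chisq(
        table.genotype_classes(locus_a), table.genotype_classes(locus_b)
    )


def repeat_dosage(
    ref: str, alts: tuple[str, ...], motif: str = "CATC"
) -> list[int | None]:
    """Additional repeat units per allele of a tandem-repeat indel locus.

    The reference allele scores 0.  An alternate allele scores
    (len(alt) - len(ref)) / len(motif) when it equals the reference with a
    contiguous exact tandem of the motif inserted; otherwise it is
    non-conforming and scored None.
    """
    out: list[int | None] = [0]
    for alt in alts:
        if alt == ref:
            out.append(0)
            continue
        diff = len(alt) - len(ref)
        if diff <= 0 or diff % len(motif) != 0:
            out.append(None)
            continue
        k = diff // len(motif)
        insert = motif * k
        conforms = any(
            alt == ref[:i] + insert + ref[i:] for i in range(len(ref) + 1)
        )
        out.append(k if conforms else None)
    return out


def individual_repeat_dosage(
    table: GenotypeTable, locus_id: str, motif: str = "CATC"
) -> list[int | None]:
    """Per-individual summed additional units over the two alleles; None
    when the genotype is missing or either allele is non-conforming."""
    meta = table.loci[locus_id]
    per_allele = dict(
        zip((meta.ref,) + meta.alts, repeat_dosage(meta.ref, meta.alts, motif))
    )
    out: list[int | None] = []
    for gt in table.genotypes[locus_id]:
        if gt is None:
            out.append(None)
            continue
        d1, d2 = per_allele.get(gt[0]), per_allele.get(gt[1])
        out.append(None if d1 is None or d2 is None else d1 + d2)
    return out


def haplotype_dose(
    gt_intron: tuple[str, str] | None,
    gt_ce: tuple[str, str] | None,
    risk_intron: str,
    risk_ce: str,
) -> tuple[int | None, str | None]:
    """Risk-haplotype copies from two unphased tag-SNP genotypes.

    Returns ``(dose, reason)``: the shared risk-allele count when the two
    loci agree, else ``(None, reason)`` — discordant counts or missing
    data.  Concordance is the evidence that the individual carries intact
    reference/risk haplotypes rather than a recombinant.
    """
    if gt_intron is None or gt_ce is None:
        return None, "missing genotype"
    n_intron = sum(a == risk_intron for a in gt_intron)
    n_ce = sum(a == risk_ce for a in gt_ce)
    if n_intron != n_ce:
        return None, f"discordant risk-allele counts ({n_intron} vs {n_ce})"
    return n_intron, None


def haplotype_dose_table(
    table: GenotypeTable,
    locus_intron: str,
    locus_ce: str,
    risk_intron: str,
    risk_ce: str,
) -> pd.DataFrame:
    """Dose (or exclusion reason) for every individual in the table."""
    rows = []
    for ind, gi, gc in zip(
        table.individuals,
        table.genotypes[locus_intron],
        table.genotypes[locus_ce],
    ):
        dose, reason = haplotype_dose(gi, gc, risk_intron, risk_ce)
        rows.append({"individual": ind, "dose": dose, "excluded_reason": reason})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OLSResult:
    beta0: float
    beta1: float
    se1: float | None
    t1: float | None
    p1: float | None
    n: int
    zero_residual: bool = False


def ols_association(
    abundance: np.ndarray | list[float],
    dose: np.ndarray | list[float],
    covariates: pd.DataFrame | None = None,
) -> OLSResult:
    """Ordinary least squares of abundance on additively coded dose.

    Optional covariate columns enter the design after the dose.  A
    rank-deficient design raises; an exactly-fitting model returns the
    coefficients with ``zero_residual=True`` and undefined inference.
    """
    y = np.asarray(abundance, dtype=float)
    x = np.asarray(dose, dtype=float)
    X = pd.DataFrame({"dose": x})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    design = sm.add_constant(X, has_constant="add")
    if y.size <= design.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError("collinear design: rank-deficient regression")
    fit = sm.OLS(y, design).fit()
    resid_var = float(fit.ssr / max(fit.df_resid, 1))
    zero_residual = np.isclose(resid_var, 0.0, atol=1e-24)
    if zero_residual:
        return OLSResult(
            beta0=float(fit.params["const"]),
            beta1=float(fit.params["dose"]),
            se1=None,
            t1=None,
            p1=None,
            n=int(y.size),
            zero_residual=True,
        )
    return OLSResult(
        beta0=float(fit.params["const"]),
        beta1=float(fit.params["dose"]),
        se1=float(fit.bse["dose"]),
        t1=float(fit.tvalues["dose"]),
        p1=float(fit.pvalues["dose"]),
        n=int(y.size),
    )


def spearman_corr(x, y) -> float | None:
    """Spearman rank correlation (average ranks for ties); None when either
    rank vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return None
    rho, _ = stats.pearsonr(rx, ry)
    return float(rho)


def delta_delta_ct(
    ct_target: float,
    ct_housekeepers: list[float],
    ref_ct_target: float,
    ref_ct_housekeepers: list[float],
    ct_limit: float = 40.0,
) -> float:
    """Relative expression 2^(-ddCt) against housekeeper genes and a
    reference condition; Ct values above ``ct_limit`` are clamped to it.
    """
    if not ct_housekeepers or not ref_ct_housekeepers:
        raise ValueError("need at least one housekeeper Ct")

    def clamp(v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
        return min(v, ct_limit)

    d_sample = clamp(ct_target) - np.mean([clamp(c) for c in ct_housekeepers])
    d_ref = clamp(ref_ct_target) - np.mean(
        [clamp(c) for c in ref_ct_housekeepers]
    )
    return float(2.0 ** (-(d_sample - d_ref)))
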