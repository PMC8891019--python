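"""Sample suitability gating, cryptic-exon calling and cohort summaries.

A sample is suitable for splice-variant analysis when the gene is expressed
well enough to see junctions at all: naive TPM >= 1.55 OR at least 20 reads
at the constitutive e19-e20 junction (both thresholds inclusive).  A
suitable sample is CE-positive when at least 2 filtered reads span the
inclusion junctions (union of e20-CE and CE-e21 by default; a strict mode
requires the threshold at a single junction class).

Inclusion is quantified two ways: ``inclusion_fraction`` (CE-supporting
reads over CE-supporting plus exclusion-junction reads, with reads wholly
inside the CE footprint counted as supporting) and ``psi_ce``, a junction
PSI that averages the two inclusion junction counts to avoid double
counting reads spanning both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .junctions import JunctionCountTable

__all__ = [
    "CEDetectionParams",
    "CECall",
    "CohortSummary",
    "is_suitable",
    "detect_ce",
    "inclusion_fraction",
    "psi_ce",
    "call_sample",
    "summarize_cohort",
    "qc_junction_correlation",
]


@dataclass(frozen=True)
class CEDetectionParams:
    tpm_min: float = 1.55
    min_e19_e20_reads: int = 20
    min_ce_junction_reads: int = 2
    #: when True, require min_ce_junction_reads at a single junction class
    #: instead of over the union of inclusion junctions
    strict_per_junction: bool = False

    def __post_init__(self) -> None:
        if self.tpm_min < 0 or self.min_e19_e20_reads < 0 or (
            self.min_ce_junction_reads < 0
        ):
            raise ValueError("thresholds must be >= 0")


@dataclass
class CECall:
    sample_id: str
    suitable: bool
    ce_positive: bool
    inclusion_fraction: float | None
    psi: float | None

    def __post_init__(self) -> None:
        if self.ce_positive and not self.suitable:
            raise ValueError("ce_positive requires suitable")


def is_suitable(
    t: JunctionCountTable, p: CEDetectionParams = CEDetectionParams()
) -> bool:
    """Expression gate: TPM >= tpm_min OR e19-e20 reads >= min (inclusive)."""
    return (
        t.naive_tpm >= p.tpm_min
        or t.counts["e19-e20"] >= p.min_e19_e20_reads
    )


def _ce_junction_counts(t: JunctionCountTable) -> tuple[int, int]:
    inclusion_upstream = t.counts["e20-CE128"] + t.counts["e20-CE178"]
    return inclusion_upstream, t.counts["CE-e21"]


def detect_ce(
    t: JunctionCountTable, p: CEDetectionParams = CEDetectionParams()
) -> CECall:
    """Apply the suitability gate then the CE-positive read threshold.

    An unsuitable sample is never positive, whatever its CE counts.
    """
    suitable = is_suitable(t, p)
    up, down = _ce_junction_counts(t)
    if p.strict_per_junction:
        enough = max(up, down) >= p.min_ce_junction_reads
    else:
        enough = up + down >= p.min_ce_junction_reads
    return CECall(
        sample_id=t.sample_id,
        suitable=suitable,
        ce_positive=suitable and enough,
        inclusion_fraction=inclusion_fraction(t),
        psi=psi_ce(t),
    )


def inclusion_fraction(t: JunctionCountTable) -> float | None:
    """Fraction of inclusion-informative reads supporting the CE.

    Numerator: reads spanning e20-CE128, e20-CE178 or CE-e21, plus reads
    aligned wholly within the CE178 footprint.  Denominator adds the
    exclusion-junction (e20-e21) reads.  Intron-body reads support neither
    isoform and are excluded.  ``None`` when no informative reads exist.
    """
    up, down = _ce_junction_counts(t)
    supporting = up + down + t.within_ce_reads
    denom = supporting + t.counts["e20-e21"]
    if denom == 0:
        return None
    return supporting / denom


def psi_ce(t: JunctionCountTable) -> float | None:
    """Junction percent-spliced-in for the cryptic exon.

    inclusion = mean(upstream inclusion junctions, CE-e21);
    PSI = inclusion / (inclusion + e20-e21).  ``None`` when the denominator
    is zero.
    """
    up, down = _ce_junction_counts(t)
    inclusion = (up + down) / 2.0
    denom = inclusion + t.counts["e20-e21"]
    if denom == 0:
        return None
    return inclusion / denom


def call_sample(
    t: JunctionCountTable, p: CEDetectionParams = CEDetectionParams()
) -> CECall:
    """Alias of :func:`detect_ce` returning the full per-sample call."""
    return detect_ce(t, p)


@dataclass
class CohortSummary:
    """Per-group detection summary over suitable samples only."""

    groups: dict[str, dict]

    def positive_fraction(self, label: str) -> float | None:
        g = self.groups[label]
        if g["n_suitable"] == 0:
            return None
        return g["n_positive"] / g["n_suitable"]


def summarize_cohort(
    calls: list[CECall], labels: dict[str, str]
) -> CohortSummary:
    """Group calls by sample label and report positive fractions among
    suitable samples.  Raises ``KeyError`` for an unlabelled sample."""
    groups: dict[str, dict] = {}
    for call in calls:
        if call.sample_id not in labels:
            raise KeyError(f"no group label for sample {call.sample_id!r}")
        label = labels[call.sample_id]
        g = groups.setdefault(
            label, {"n_samples": 0, "n_suitable": 0, "n_positive": 0}
        )
        g["n_samples"] += 1
        if call.suitable:
            g["n_suitable"] += 1
            if call.ce_positive:
                g["n_positive"] += 1
    for g in groups.values():
        g["positive_fraction"] = (
            g["n_positive"] / g["n_suitable"] if g["n_suitable"] else None
        )
    return CohortSummary(groups=groups)


def qc_junction_correlation(tables: list[JunctionCountTable]) -> float | None:
    """Pearson correlation between e19-e20 and e20-e21 junction counts
    across samples — a coverage-consistency QC (expected near 1 when the
    constitutive junctions are measured evenly).

    Requires >= 3 samples; ``None`` when either count vector has zero
    variance.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 samples for the junction QC")
    x = np.array([t.counts["e19-e20"] for t in tables], dtype=float)
    y = np.array([t.counts["e20-e21"] for t in tables], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r)
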