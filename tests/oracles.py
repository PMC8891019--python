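"""Independent brute-force oracles used to cross-check the pipeline.

Everything here re-derives results from first principles without calling the
package's parsing or counting code: SAM text is re-parsed with a regex CIGAR
walk, and every read is tested against every named junction definition
computed directly from exon coordinates.
"""

from __future__ import annotations

import math
import re

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=XB])")


def brute_force_blocks(pos: int, cigar: str) -> list[tuple[int, int]]:
    """Aligned blocks (1-based inclusive) from POS + CIGAR, by definition."""
    blocks = []
    cur = pos
    start = pos
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op in "M=XD":
            cur += n
        elif op == "N":
            if cur > start:
                blocks.append((start, cur - 1))
            cur += n
            start = cur
        # I, S, H consume no reference
    if cur > start:
        blocks.append((start, cur - 1))
    return blocks


def brute_force_count_sam(
    sam_path: str,
    exons: dict[str, tuple[int, int]],
    min_overhang: int = 6,
    unique_mapq: int = 255,
    drop_duplicates: bool = True,
) -> dict[str, int]:
    """Re-scan a SAM text file and count reads spanning each named junction.

    A read supports junction X-Y when two consecutive aligned blocks flank
    exactly the genomic gap between X and Y, with at least ``min_overhang``
    aligned bases in each flanking block.
    """

    def gap(a, b):
        (sa, ea), (sb, eb) = exons[a], exons[b]
        return (ea + 1, sb - 1) if ea < sb else (eb + 1, sa - 1)

    named = {
        "e19-e20": gap("e19", "e20"),
        "e20-CE128": gap("e20", "CE128"),
        "e20-CE178": gap("e20", "CE178"),
        "CE-e21": gap("CE128", "e21"),
        "e20-e21": gap("e20", "e21"),
    }
    counts = {nm: 0 for nm in named}
    unclassified = 0
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag, pos, mapq, cigar = int(f[1]), int(f[3]), int(f[4]), f[5]
            if flag & 0x4:
                continue
            if mapq < unique_mapq:
                continue
            if drop_duplicates and flag & 0x400:
                continue
            blocks = brute_force_blocks(pos, cigar)
            seen = set()
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if e1 - s1 + 1 < min_overhang or e2 - s2 + 1 < min_overhang:
                    continue
                iv = (e1 + 1, s2 - 1)
                hit = [nm for nm, niv in named.items() if niv == iv]
                if hit:
                    seen.update(hit)
                else:
                    unclassified += 1
            for nm in seen:
                counts[nm] += 1
    counts["unclassified"] = unclassified
    return counts


def student_t_tail_numeric(t: float, df: int) -> float:
    """Two-sided Student-t tail probability by numerical integration of the
    density written out explicitly (independent of scipy.stats.t)."""
    from scipy.integrate import quad

    c = math.gamma((df + 1) / 2) / (
        math.sqrt(df * math.pi) * math.gamma(df / 2)
    )

    def pdf(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    upper, _ = quad(pdf, abs(t), math.inf)
    return 2.0 * upper
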