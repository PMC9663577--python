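"""TF affinity scores and subgenome balance classification.

The regulatory effect of a TF on a gene is the TF affinity score

    TFAS = sum_k rpkm_k * exp(-d_k / 2000)

summed over the peaks whose summit falls in the promoter, where d_k is the
distance from the peak summit to the gene TSS and the promoter is the 5-kb
window centered on the TSS. A triad's three TFAS values, normalized to
proportions, are assigned to the nearest of seven standard patterns: the
balanced pattern (1/3, 1/3, 1/3) and six unbalanced patterns dominated by
two subgenomes (0.5/0.5/0) or one (1/0/0). Standards use exact thirds; the
commonly printed "0.33" is display rounding of proportions that sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Gene, Peak

#: The seven standard proportion patterns, in tie-break priority order.
STANDARD_PATTERNS: dict[str, tuple[float, float, float]] = {
    "ABD": (1 / 3, 1 / 3, 1 / 3),
    "AB": (0.5, 0.5, 0.0),
    "AD": (0.5, 0.0, 0.5),
    "BD": (0.0, 0.5, 0.5),
    "A": (1.0, 0.0, 0.0),
    "B": (0.0, 1.0, 0.0),
    "D": (0.0, 0.0, 1.0),
}

#: Minimum Euclidean distance between two standards (ABD vs any
#: two-subgenome pattern) = sqrt(1/6); half of it bounds the noise radius
#: below which nearest-standard classification provably recovers the
#: planted pattern.
MIN_STANDARD_SEPARATION = math.sqrt(1 / 6)


@dataclass(frozen=True, slots=True)
class TFASRecord:
    tf_id: str
    gene_id: str
    tfas: float
    n_peaks: int


@dataclass(frozen=True, slots=True)
class TriadPattern:
    triad_id: str
    tf_id: str
    proportions: tuple[float, float, float]
    pattern: str
    distance_to_pattern: float


def compute_tfas(
    gene: Gene,
    peaks: Sequence[Peak],
    half_width: int = 2500,
    decay: float = 2000.0,
) -> TFASRecord:
    """Distance-decayed sum of promoter peak densities for one TF.

    A peak contributes iff its summit lies in [tss - half_width,
    tss + half_width); genes without any qualifying peak score 0.
    """
    tf_ids = {p.tf_id for p in peaks}
    if len(tf_ids) > 1:
        raise ValueError(f"peaks from multiple TFs: {sorted(tf_ids)}")
    lo, hi = gene.tss - half_width, gene.tss + half_width
    total, n = 0.0, 0
    for p in peaks:
        if p.interval.chrom != gene.interval.chrom:
            continue
        if lo <= p.summit < hi:
            if p.rpkm < 0:
                raise ValueError(f"negative rpkm for {p.tf_id}")
            total += p.rpkm * math.exp(-abs(p.summit - gene.tss) / decay)
            n += 1
    tf_id = next(iter(tf_ids)) if tf_ids else ""
    return TFASRecord(tf_id, gene.gene_id, total if n else 0.0, n)


def classify_pattern(
    tfas_triple: Sequence[float],
    triad_id: str = "",
    tf_id: str = "",
    min_tfas: float = 0.25,
) -> TriadPattern | None:
    """Assign a triad's (A, B, D) TFAS values to the nearest standard.

    Returns None when all three values are below ``min_tfas`` (the triad is
    filtered from the balance analysis). Ties between equidistant standards
    are broken by the fixed priority ABD > AB > AD > BD > A > B > D.
    """
    v = np.asarray(tfas_triple, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected three TFAS values")
    if (v < 0).any():
        raise ValueError("negative TFAS")
    if (v < min_tfas).all():
        return None
    props = v / v.sum()
    names = list(STANDARD_PATTERNS)
    standards = np.array([STANDARD_PATTERNS[n] for n in names])
    dists = np.linalg.norm(standards - props, axis=1)
    best = int(np.argmin(dists))  # argmin returns the first = highest priority
    return TriadPattern(
        triad_id, tf_id, tuple(props.tolist()), names[best], float(dists[best])
    )


def regulatory_divergence(
    densities: Mapping[str, tuple[float, float]],
    min_tfas: float = 0.25,
    pseudocount: float = 0.5,
) -> float | None:
    """Summed |log2 fold-change| of promoter binding over qualifying TFs.

    ``densities`` maps TF id -> (score gene 1, score gene 2); a TF qualifies
    when either side exceeds ``min_tfas``. The pseudocount is added on both
    sides unconditionally so the statistic is symmetric and finite at zero.
    Returns None (pair excluded) when no TF qualifies.
    """
    total = 0.0
    used = 0
    for tf, (a, b) in densities.items():
        if a < 0 or b < 0:
            raise ValueError(f"negative density for {tf}")
        if max(a, b) <= min_tfas:
            continue
        total += abs(math.log2((a + pseudocount) / (b + pseudocount)))
        used += 1
    return total if used else None


def expression_divergence(
    tpm_a: float, tpm_b: float, pseudocount: float = 0.5
) -> float:
    """|log2 fold-change| of expression between 1:1 orthologs."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("negative TPM")
    return abs(math.log2((tpm_a + pseudocount) / (tpm_b + pseudocount)))


def dhs_divergence(dhs_triple: Sequence[float]) -> float:
    """Euclidean distance of the DHS proportion vector to the balance point."""
    v = np.asarray(dhs_triple, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected three DHS values")
    if (v < 0).any():
        raise ValueError("negative DHS density")
    s = v.sum()
    if s == 0:
        raise ValueError("all-zero DHS triple")
    return float(np.linalg.norm(v / s - np.full(3, 1 / 3)))
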