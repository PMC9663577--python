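"""TE-subfamily selection and enrichment scores for binding-site overlap.

The enrichment score of query intervals (one TF's peaks, DHSs, ...) in a
TE subfamily is the ratio of two genome fractions measured in base pairs:

    ES = (query bp in subfamily / total query bp)
         / (subfamily bp / total TE bp in the genome)

Only subfamilies covering more than 0.1% of the genome are scored. For
the degenerated-TE variant the background lengths (subfamily bp and total
TE bp) are computed from non-degenerated TEs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    GenomicInterval,
    TEAnnotation,
    flatten_by_chrom,
    intersect_flat,
    point_in_flat,
    total_bp,
)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    query_label: str
    subfamily: str
    es: float | None  # None when the subfamily background is empty
    query_bp_in_subfamily: int
    query_bp_total: int
    subfamily_bp: int
    te_bp_total: int


def subfamily_footprints(
    tes: Iterable[TEAnnotation],
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Flattened per-subfamily footprints (same-subfamily overlaps collapsed)."""
    by_sub: dict[str, list[GenomicInterval]] = {}
    for te in tes:
        by_sub.setdefault(te.subfamily, []).append(te.interval)
    return {sub: flatten_by_chrom(ivs) for sub, ivs in by_sub.items()}


def select_subfamilies(
    tes: Sequence[TEAnnotation], genome_bp: int, min_fraction: float = 0.001
) -> list[str]:
    """Subfamilies whose flattened length exceeds ``min_fraction`` of the genome."""
    foots = subfamily_footprints(tes)
    return sorted(
        sub for sub, flat in foots.items() if total_bp(flat) > min_fraction * genome_bp
    )


def enrichment_score(
    query: Sequence[GenomicInterval],
    subfamily: str,
    tes: Sequence[TEAnnotation],
    genome_bp: int,
    query_label: str = "query",
    background_tes: Sequence[TEAnnotation] | None = None,
) -> EnrichmentResult:
    """ES of query intervals in one subfamily.

    Overlap is measured in the subfamily's annotated footprint; the
    background denominators come from ``background_tes`` when given (the
    dTE variant passes the non-degenerated annotations there), else from
    ``tes`` itself.
    """
    qflat = flatten_by_chrom(query)
    q_total = total_bp(qflat)
    if q_total == 0:
        raise ValueError("empty query")
    sub_flat = subfamily_footprints(tes).get(subfamily, {})
    q_in = total_bp(intersect_flat(qflat, sub_flat))

    bg = tes if background_tes is None else background_tes
    bg_foots = subfamily_footprints(bg)
    sub_bp = total_bp(bg_foots.get(subfamily, {}))
    te_bp = total_bp(flatten_by_chrom(t.interval for t in bg))
    if sub_bp == 0:
        return EnrichmentResult(query_label, subfamily, None, q_in, q_total, 0, te_bp)
    es = (q_in / q_total) / (sub_bp / te_bp)
    return EnrichmentResult(query_label, subfamily, es, q_in, q_total, sub_bp, te_bp)


def enrichment_table(
    query: Sequence[GenomicInterval],
    tes: Sequence[TEAnnotation],
    genome_bp: int,
    query_label: str = "query",
    min_fraction: float = 0.001,
    background_tes: Sequence[TEAnnotation] | None = None,
) -> pd.DataFrame:
    """ES for every selected subfamily, as a tidy frame."""
    rows = []
    for sub in select_subfamilies(tes, genome_bp, min_fraction):
        r = enrichment_score(
            query, sub, tes, genome_bp, query_label, background_tes=background_tes
        )
        rows.append(
            {
                "query": r.query_label,
                "subfamily": r.subfamily,
                "es": r.es,
                "query_bp_in_subfamily": r.query_bp_in_subfamily,
                "query_bp_total": r.query_bp_total,
                "subfamily_bp": r.subfamily_bp,
                "te_bp_total": r.te_bp_total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subfamily", "es", "query_bp_in_subfamily",
            "query_bp_total", "subfamily_bp", "te_bp_total",
        ],
    )


def te_overlap_fraction(
    tfbs: Sequence[GenomicInterval], tes: Sequence[TEAnnotation]
) -> float:
    """Fraction of binding sites whose midpoint falls inside the TE footprint."""
    if not tfbs:
        raise ValueError("empty TFBS list")
    flat = flatten_by_chrom(t.interval for t in tes)
    inside = sum(1 for iv in tfbs if point_in_flat(flat, iv.chrom, iv.midpoint))
    return inside / len(tfbs)
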