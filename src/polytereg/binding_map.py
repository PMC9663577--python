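"""Cistrome-level interval analysis: merged binding sites, HOT regions,
binarized-bin TF correlation, and interval-class fold enrichment.

A merged TFBS is a maximal union of overlapping peak intervals (half-open;
bookended peaks stay separate). HOT (high-occupancy target) regions are
merged sites bound by strictly more than ``threshold`` distinct TFs — a TF
with several peaks in one merged site counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    Peak,
    flatten_by_chrom,
    intersect_flat,
    merge_intervals,
    subtract_flat,
    total_bp,
)


@dataclass(frozen=True, slots=True)
class MergedSite:
    interval: GenomicInterval
    tf_ids: frozenset[str]

    @property
    def tf_count(self) -> int:
        return len(self.tf_ids)


def merge_tfbs(peaks: Sequence[Peak]) -> list[MergedSite]:
    """Union all peak intervals into maximal disjoint merged sites."""
    if not peaks:
        raise ValueError("no peaks to merge")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    sites: list[MergedSite] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        cur_s, cur_e = ps[0].interval.start, ps[0].interval.end
        cur_tfs = {ps[0].tf_id}
        for p in ps[1:]:
            if p.interval.start < cur_e:  # >=1 bp overlap merges
                cur_e = max(cur_e, p.interval.end)
                cur_tfs.add(p.tf_id)
            else:
                sites.append(
                    MergedSite(GenomicInterval(chrom, cur_s, cur_e), frozenset(cur_tfs))
                )
                cur_s, cur_e, cur_tfs = p.interval.start, p.interval.end, {p.tf_id}
        sites.append(MergedSite(GenomicInterval(chrom, cur_s, cur_e), frozenset(cur_tfs)))
    return sites


def call_hot(
    sites: Sequence[MergedSite], threshold: int = 12
) -> tuple[list[MergedSite], list[MergedSite]]:
    """Partition merged sites into (HOT, non-HOT): HOT iff tf_count > threshold."""
    if threshold < 1:
        raise ValueError("HOT threshold must be >= 1")
    hot = [s for s in sites if s.tf_count > threshold]
    non_hot = [s for s in sites if s.tf_count <= threshold]
    return hot, non_hot


def tf_binding_correlation(
    peaks_by_tf: Mapping[str, Sequence[Peak]],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 2000,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of binarized binding occupancy across genome bins.

    The genome is tiled into consecutive ``bin_size`` bins anchored at
    coordinate 0 per chromosome (trailing partial bin kept); each TF gets a
    0/1 vector marking bins overlapped by at least one peak. TFs whose
    vector is constant (all-zero or all-one) have undefined correlation and
    are reported as NaN, not 0. Returns the correlation matrix and a
    display order from average-linkage clustering on 1 - r.
    """
    tf_ids = sorted(peaks_by_tf)
    if len(tf_ids) < 2:
        raise ValueError("need at least two TFs")
    chroms = sorted(chrom_sizes)
    offsets: dict[str, int] = {}
    n_bins = 0
    for c in chroms:
        offsets[c] = n_bins
        n_bins += -(-chrom_sizes[c] // bin_size)
    mat = np.zeros((len(tf_ids), n_bins), dtype=bool)
    for i, tf in enumerate(tf_ids):
        for p in peaks_by_tf[tf]:
            c = p.interval.chrom
            if c not in offsets:
                raise ValueError(f"peak on unknown chromosome {c!r}")
            b0 = p.interval.start // bin_size
            b1 = (p.interval.end - 1) // bin_size
            mat[i, offsets[c] + b0 : offsets[c] + b1 + 1] = True
    valid = [i for i in range(len(tf_ids)) if 0 < mat[i].sum() < n_bins]
    corr = np.full((len(tf_ids), len(tf_ids)), np.nan)
    np.fill_diagonal(corr, 1.0)
    if len(valid) >= 2:
        sub = np.corrcoef(mat[valid].astype(float))
        for a, i in enumerate(valid):
            for b, j in enumerate(valid):
                corr[i, j] = sub[a, b]
    df = pd.DataFrame(corr, index=tf_ids, columns=tf_ids)
    order = _cluster_order(df, [tf_ids[i] for i in valid])
    return df, order


def _cluster_order(corr: pd.DataFrame, valid_tfs: list[str]) -> list[str]:
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    if len(valid_tfs) < 3:
        return list(corr.index)
    d = 1.0 - corr.loc[valid_tfs, valid_tfs].to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    link = average(squareform(d, checks=False))
    ordered = [valid_tfs[i] for i in leaves_list(link)]
    return ordered + [t for t in corr.index if t not in set(ordered)]


def interval_enrichment(
    query: Iterable[GenomicInterval],
    classes: Mapping[str, Iterable[GenomicInterval]],
    genome_bp: int,
) -> pd.DataFrame:
    """Per-class fold enrichment of query base pairs over genome fraction.

    enrichment(c) = (query bp in c / total query bp) / (class bp / genome bp)
    """
    qflat = flatten_by_chrom(query)
    q_total = total_bp(qflat)
    if q_total == 0:
        raise ValueError("empty query")
    rows = []
    for label in sorted(classes):
        cflat = flatten_by_chrom(classes[label])
        c_bp = total_bp(cflat)
        if c_bp == 0:
            raise ValueError(f"zero-length background class {label!r}")
        q_in = total_bp(intersect_flat(qflat, cflat))
        rows.append(
            {
                "class": label,
                "query_bp_in_class": q_in,
                "query_bp_total": q_total,
                "class_bp": c_bp,
                "genome_bp": genome_bp,
                "enrichment": (q_in / q_total) / (c_bp / genome_bp),
            }
        )
    return pd.DataFrame(rows)


def tad_boundary_windows(
    tads: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int = 20_000,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """TAD boundary / interior / non-TAD partition of the genome.

    Boundaries are ``window``-bp regions centered at each TAD start and end
    point, truncated at chromosome edges, with overlapping windows merged
    (adjacent TADs sharing a boundary point yield one window). Interior is
    the TAD footprint minus boundary windows; non-TAD is the remainder.
    """
    half = window // 2
    bounds: dict[str, list[tuple[int, int]]] = {}
    for t in tads:
        size = chrom_sizes[t.chrom]
        for point in (t.start, t.end):
            s, e = max(0, point - half), min(size, point + half)
            if s < e:
                bounds.setdefault(t.chrom, []).append((s, e))
    boundary = {c: merge_intervals(v) for c, v in bounds.items()}
    tad_flat = flatten_by_chrom(tads)
    genome = {c: [(0, n)] for c, n in chrom_sizes.items()}
    interior = subtract_flat(tad_flat, boundary)
    covered = {
        c: merge_intervals(boundary.get(c, []) + tad_flat.get(c, []))
        for c in set(boundary) | set(tad_flat)
    }
    non_tad = subtract_flat(genome, covered)
    return {"boundary": boundary, "interior": interior, "non_tad": non_tad}


def flat_to_intervals(flat: Mapping[str, list[tuple[int, int]]]) -> list[GenomicInterval]:
    return [
        GenomicInterval(c, s, e) for c in sorted(flat) for s, e in flat[c]
    ]
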