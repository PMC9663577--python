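"""Subgenome homology classification from reciprocal alignment blocks.

A base on subgenome X counts as "aligned to subgenome Y" iff it lies in
the intersection of the X->Y block footprint and the back-projected Y->X
footprint (the strictest symmetric reading of a reciprocal alignment),
inside a contiguous run longer than ``min_len`` (400 bp by default).
Bases aligned to both other subgenomes are homo3, to exactly one homo2,
to none subgenome-specific. homo3 runs falling inside a synteny block are
additionally reported as homoeo3 (syntenic homo3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentBlock, GenomicInterval, SUBGENOME_PATTERN, SUBGENOMES

CLASSES = ("specific", "homo2", "homo3")


@dataclass(frozen=True, slots=True)
class RegionClass:
    interval: GenomicInterval
    klass: str  # specific | homo2 | homo3 | homoeo3


def _footprint(size: int, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = np.zeros(size, dtype=bool)
    for s, e in intervals:
        arr[max(0, s) : min(size, e)] = True
    return arr


def _drop_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Zero out True-runs of length <= min_len (threshold is strict '>')."""
    if not mask.any():
        return mask
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    out = mask.copy()
    for s, e in zip(starts, ends):
        if e - s <= min_len:
            out[s:e] = False
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    return list(
        zip(np.flatnonzero(diff == 1).tolist(), np.flatnonzero(diff == -1).tolist())
    )


def classify_regions(
    blocks: Mapping[tuple[str, str], Sequence[AlignmentBlock]],
    synteny: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    min_len: int = 400,
    subgenome_pattern: str = SUBGENOME_PATTERN,
    subgenomes: Sequence[str] = SUBGENOMES,
) -> list[RegionClass]:
    """Classify every base of every chromosome; returns merged maximal runs.

    ``blocks`` must hold all directed subgenome pairs, keyed (query_sg,
    subject_sg); block coordinates live on the query subgenome for the
    query interval and on the subject subgenome for the subject interval.
    homoeo3 regions are reported in addition to (not instead of) homo3.
    """
    for x in subgenomes:
        for y in subgenomes:
            if x != y and (x, y) not in blocks:
                raise ValueError(f"missing alignment direction ({x}, {y})")

    syn_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in synteny:
        syn_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    out: list[RegionClass] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        sg = GenomicInterval(chrom, 0, size).subgenome(subgenome_pattern)
        others = [s for s in subgenomes if s != sg]
        n_aligned = np.zeros(size, dtype=np.int8)
        for other in others:
            fwd = _footprint(
                size,
                (
                    (b.query.start, b.query.end)
                    for b in blocks[(sg, other)]
                    if b.query.chrom == chrom
                ),
            )
            rev = _footprint(
                size,
                (
                    (b.subject.start, b.subject.end)
                    for b in blocks[(other, sg)]
                    if b.subject.chrom == chrom
                ),
            )
            recip = _drop_short_runs(fwd & rev, min_len)
            n_aligned += recip
        homo3 = n_aligned == 2
        for klass, mask in (
            ("specific", n_aligned == 0),
            ("homo2", n_aligned == 1),
            ("homo3", homo3),
        ):
            for s, e in _runs(mask):
                out.append(RegionClass(GenomicInterval(chrom, s, e), klass))
        syn = _footprint(size, syn_by_chrom.get(chrom, []))
        for s, e in _runs(homo3 & syn):
            out.append(RegionClass(GenomicInterval(chrom, s, e), "homoeo3"))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.klass))
    return out


def locate_in_classes(
    queries: Sequence[GenomicInterval],
    classes: Sequence[RegionClass],
    include_homoeo3: bool = False,
) -> tuple[list[str], dict[str, float]]:
    """Label each query by the class containing its midpoint.

    By default the primary partition (specific/homo2/homo3) is used; with
    ``include_homoeo3`` queries whose midpoint also falls in a homoeo3 run
    are labelled homoeo3. Returns per-query labels and the fraction of
    queries per label.
    """
    primary: dict[str, list[tuple[int, int, str]]] = {}
    homoeo: dict[str, list[tuple[int, int]]] = {}
    for rc in classes:
        if rc.klass == "homoeo3":
            homoeo.setdefault(rc.interval.chrom, []).append(
                (rc.interval.start, rc.interval.end)
            )
        else:
            primary.setdefault(rc.interval.chrom, []).append(
                (rc.interval.start, rc.interval.end, rc.klass)
            )
    for v in primary.values():
        v.sort()
    for v in homoeo.values():
        v.sort()

    labels: list[str] = []
    for q in queries:
        if q.chrom not in primary:
            raise ValueError(f"query on unknown chromosome {q.chrom!r}")
        mid = q.midpoint
        ivs = primary[q.chrom]
        i = int(np.searchsorted([s for s, _, _ in ivs], mid, side="right")) - 1
        if i < 0 or not (ivs[i][0] <= mid < ivs[i][1]):
            raise ValueError(f"midpoint {q.chrom}:{mid} outside classified space")
        label = ivs[i][2]
        if include_homoeo3 and label == "homo3":
            hv = homoeo.get(q.chrom, [])
            j = int(np.searchsorted([s for s, _ in hv], mid, side="right")) - 1
            if j >= 0 and hv[j][0] <= mid < hv[j][1]:
                label = "homoeo3"
        labels.append(label)
    n = len(labels)
    summary = {k: v / n for k, v in sorted(Counter(labels).items())} if n else {}
    return labels, summary


def locate_by_majority_overlap(
    queries: Sequence[GenomicInterval], classes: Sequence[RegionClass]
) -> list[str]:
    """Alternative assignment: the class covering most of each query."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for rc in classes:
        if rc.klass == "homoeo3":
            continue
        by_chrom.setdefault(rc.interval.chrom, []).append(
            (rc.interval.start, rc.interval.end, rc.klass)
        )
    for v in by_chrom.values():
        v.sort()
    labels = []
    for q in queries:
        cover: Counter = Counter()
        for s, e, k in by_chrom.get(q.chrom, []):
            ov = min(e, q.end) - max(s, q.start)
            if ov > 0:
                cover[k] += ov
        if not cover:
            raise ValueError(f"query {q.chrom}:{q.start}-{q.end} outside classified space")
        # deterministic tie-break: larger overlap, then class name
        labels.append(sorted(cover.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return labels


def class_fractions(classes: Sequence[RegionClass], chrom_sizes: Mapping[str, int]) -> pd.Series:
    """Per-base genome fraction of each class (primary classes sum to 1)."""
    total = sum(chrom_sizes.values())
    bp: Counter = Counter()
    for rc in classes:
        bp[rc.klass] += len(rc.interval)
    return pd.Series({k: bp.get(k, 0) / total for k in (*CLASSES, "homoeo3")})


def classes_to_frame(classes: Sequence[RegionClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": rc.interval.chrom,
                "start": rc.interval.start,
                "end": rc.interval.end,
                "class": rc.klass,
            }
            for rc in classes
        ],
        columns=["chrom", "start", "end", "class"],
    )
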