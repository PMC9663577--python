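"""Degenerated-TE (dTE) detection in sister triad promoters.

A TE relic is a promoter region that no longer carries a canonical,
annotatable TE structure but still aligns to a TE-embedded binding site
present in a sister subgenome of the same triad. Detection: the TE
sequence (with its TFBS window marked) is locally aligned — both
orientations, Smith-Waterman with affine gaps — against each sister
promoter lacking an annotated copy of the element. Alignable regions
overlapping any annotated TE are removed; runs with alignment length
> 50 bp and identity >= 60% within the aligned region are reported as
dTEs. The TFBS window is projected through the alignment columns and
called conserved when it aligns at >= 70% identity over >= 70% of its
length (gapped columns are ignored, consistent with the distance model).

The score thresholds are deterministic substitutes for a database-size-
dependent E-value cutoff and are exposed as parameters. A permutation
control pairs TE sequences with promoters of randomly chosen *different*
triads under identical cutoffs; matched pairs should align, permuted
pairs should almost never.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval, flatten_by_chrom, intersect_flat, total_bp

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class TFBSQuery:
    """A TE-embedded binding-site sequence from one triad promoter."""

    triad_id: str
    source_subgenome: str
    te_id: str
    seq: str  # TE (or TE-with-TFBS) sequence
    tfbs_start: int  # TFBS window on ``seq``, half-open
    tfbs_end: int

    def __post_init__(self):
        if not 0 <= self.tfbs_start < self.tfbs_end <= len(self.seq):
            raise ValueError(f"TFBS window outside TE sequence for {self.te_id}")


@dataclass(frozen=True, slots=True)
class PromoterTarget:
    """A candidate sister promoter to scan for relics."""

    triad_id: str
    subgenome: str
    interval: GenomicInterval
    seq: str


@dataclass(frozen=True, slots=True)
class DTEHit:
    triad_id: str
    source_subgenome: str
    target_subgenome: str
    target_region: GenomicInterval
    alignment_length: int
    identity: float  # percent over alignment columns
    tfbs_conserved: bool
    strand: str  # orientation of the match on the target
    te_id: str = ""


def _local_aligner(match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _evaluate(aln, query: TFBSQuery, min_tfbs_identity: float, min_tfbs_coverage: float):
    """(columns, identities, tstart, tend, tfbs_conserved) for one alignment."""
    blocks_q, blocks_t = aln.aligned
    if len(blocks_q) == 0:
        return 0, 0, 0, 0, False
    qseq, tseq = aln.sequences
    columns = identities = 0
    win_cols = win_idents = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if prev_q is not None:
            columns += (qs - prev_q) + (ts - prev_t)
        columns += qe - qs
        for k in range(qe - qs):
            match = qseq[qs + k] == tseq[ts + k]
            identities += match
            if query.tfbs_start <= qs + k < query.tfbs_end:
                win_cols += 1
                win_idents += match
        prev_q, prev_t = qe, te
    win_len = query.tfbs_end - query.tfbs_start
    conserved = (
        win_cols >= min_tfbs_coverage / 100.0 * win_len
        and win_cols > 0
        and win_idents / win_cols >= min_tfbs_identity / 100.0
    )
    return columns, identities, int(blocks_t[0][0]), int(blocks_t[-1][1]), conserved


def find_dte(
    query: TFBSQuery,
    target: PromoterTarget,
    te_annotations: Sequence[GenomicInterval],
    min_len: int = 51,
    min_identity: float = 60.0,
    min_tfbs_identity: float = 70.0,
    min_tfbs_coverage: float = 70.0,
    scoring: tuple[int, int, int, int] = (1, -2, -5, -2),
) -> list[DTEHit]:
    """Scan one sister promoter for a relic of one TE-embedded TFBS.

    Both orientations are searched; the best qualifying alignment per
    orientation is reported. Alignable regions overlapping any annotated
    TE are discarded (a relic is by definition annotation-free).
    """
    if len(target.seq) < min_len:
        return []
    al = _local_aligner(*scoring)
    te_flat = flatten_by_chrom(te_annotations)
    hits: list[DTEHit] = []
    for strand, tseq in (("+", target.seq), ("-", revcomp(target.seq))):
        alns = al.align(query.seq, tseq)
        if alns.score <= 0:
            continue
        cols, idents, ts, te_, conserved = _evaluate(
            alns[0], query, min_tfbs_identity, min_tfbs_coverage
        )
        if cols < min_len:
            continue
        identity = 100.0 * idents / cols
        if identity < min_identity:
            continue
        if strand == "-":  # map back to forward promoter coordinates
            ts, te_ = len(target.seq) - te_, len(target.seq) - ts
        region = GenomicInterval(
            target.interval.chrom,
            target.interval.start + ts,
            target.interval.start + te_,
        )
        overlap = total_bp(
            intersect_flat(flatten_by_chrom([region]), te_flat)
        )
        if overlap > 0:
            continue
        hits.append(
            DTEHit(
                triad_id=query.triad_id,
                source_subgenome=query.source_subgenome,
                target_subgenome=target.subgenome,
                target_region=region,
                alignment_length=cols,
                identity=identity,
                tfbs_conserved=conserved,
                strand=strand,
                te_id=query.te_id,
            )
        )
    hits.sort(key=lambda h: (-h.alignment_length, h.strand))
    return hits[:1] if hits else []


def validate_hit(
    hit: DTEHit,
    te_annotations: Sequence[GenomicInterval],
    min_len: int = 51,
) -> bool:
    """Independent post-hoc check of the DTEHit invariants."""
    if hit.alignment_length < min_len:
        return False
    if len(hit.target_region) == 0:
        return False
    te_flat = flatten_by_chrom(te_annotations)
    ov = total_bp(intersect_flat(flatten_by_chrom([hit.target_region]), te_flat))
    return ov == 0


def classify_te_presence(
    te_presence: Mapping[str, set[str]],
    dte_hits: Sequence[DTEHit],
) -> dict[str, tuple[int, int]]:
    """Per-triad subgenome-presence counts, TE-only vs TE+dTE.

    ``te_presence`` maps triad id -> subgenomes with an annotated
    TE-embedded TFBS in the promoter. Triads without any TE are excluded.
    Returns triad id -> (n_subgenomes TE-only, n_subgenomes TE+dTE).
    """
    dte_by_triad: dict[str, set[str]] = {}
    for h in dte_hits:
        dte_by_triad.setdefault(h.triad_id, set()).add(h.target_subgenome)
    out = {}
    for triad_id, sgs in te_presence.items():
        if not sgs:
            continue
        combined = sgs | dte_by_triad.get(triad_id, set())
        out[triad_id] = (len(sgs), len(combined))
    return out


def dte_permutation_control(
    queries: Sequence[TFBSQuery],
    promoters: Sequence[PromoterTarget],
    te_annotations: Sequence[GenomicInterval],
    n_perm: int = 1000,
    seed: int = 0,
    **detection_kwargs,
) -> np.ndarray:
    """Null hit counts: TE sequences vs promoters of *different* triads.

    Each permutation pairs every query with one randomly chosen promoter
    from another triad and applies the same detection cutoffs. Returns the
    per-permutation hit counts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    by_triad: dict[str, list[int]] = {}
    for i, p in enumerate(promoters):
        by_triad.setdefault(p.triad_id, []).append(i)
    if len(by_triad) < 2:
        raise ValueError("need promoters from at least two triads")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_perm, dtype=int)
    triad_ids = sorted(by_triad)
    # the draw space is (query, promoter) pairs; cache each pair's outcome
    memo: dict[tuple[int, int], bool] = {}
    for it in range(n_perm):
        n_hits = 0
        for qi, q in enumerate(queries):
            candidates = [t for t in triad_ids if t != q.triad_id]
            tid = candidates[rng.integers(len(candidates))]
            pi = by_triad[tid][rng.integers(len(by_triad[tid]))]
            key = (qi, pi)
            if key not in memo:
                memo[key] = bool(
                    find_dte(q, promoters[pi], te_annotations, **detection_kwargs)
                )
            n_hits += memo[key]
        counts[it] = n_hits
    return counts


# ---------------------------------------------------------------------------
# Pipeline glue: derive queries and candidate promoters from annotations
# ---------------------------------------------------------------------------

def te_embedded_promoter_sites(
    triads,
    genes,
    peaks_by_tf: Mapping[str, Sequence],
    tes,
    genome: Mapping[str, str],
    half_width: int = 2500,
    window: int = 60,
) -> tuple[dict[str, set[str]], list[TFBSQuery], dict[str, list[PromoterTarget]]]:
    """Find TE-embedded promoter binding sites and relic-search candidates.

    A triad promoter has a TE-embedded TFBS when a peak summit (any TF)
    falls both inside the 5-kb promoter and inside an annotated TE.
    Returns (per-triad subgenome presence, TE queries with a
    ``window``-bp TFBS window centered on the summit, and per-triad
    sister promoters lacking an annotated copy of the element).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    by_chrom: dict[str, list] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    for v in by_chrom.values():
        v.sort(key=lambda t: t.interval.start)

    def containing_te(chrom: str, pos: int):
        for te in by_chrom.get(chrom, []):
            if te.interval.start <= pos < te.interval.end:
                return te
            if te.interval.start > pos:
                break
        return None

    all_peaks = [p for ps in peaks_by_tf.values() for p in ps]
    peaks_by_chrom: dict[str, list] = {}
    for p in all_peaks:
        peaks_by_chrom.setdefault(p.interval.chrom, []).append(p)
    for v in peaks_by_chrom.values():
        v.sort(key=lambda p: p.summit)

    presence: dict[str, set[str]] = {}
    embedded: dict[str, dict[str, list]] = {}
    prom_iv: dict[tuple[str, str], GenomicInterval] = {}
    for triad in triads:
        presence[triad.triad_id] = set()
        embedded[triad.triad_id] = {}
        for sg in ("A", "B", "D"):
            gene = gene_by_id[triad.gene_of(sg)]
            chrom = gene.interval.chrom
            lo = max(0, gene.tss - half_width)
            hi = min(len(genome[chrom]), gene.tss + half_width)
            prom_iv[(triad.triad_id, sg)] = GenomicInterval(chrom, lo, hi)
            import bisect

            chrom_peaks = peaks_by_chrom.get(chrom, [])
            summits = [p.summit for p in chrom_peaks]
            i0 = bisect.bisect_left(summits, lo)
            i1 = bisect.bisect_left(summits, hi)
            for p in chrom_peaks[i0:i1]:
                te = containing_te(chrom, p.summit)
                if te is not None:
                    presence[triad.triad_id].add(sg)
                    embedded[triad.triad_id].setdefault(sg, []).append((te, p))

    queries: list[TFBSQuery] = []
    targets: dict[str, list[PromoterTarget]] = {}
    for triad in triads:
        tid = triad.triad_id
        sgs = presence[tid]
        if not 1 <= len(sgs) <= 2:
            continue
        subfams = set()
        for sg in sorted(sgs):
            best: dict[str, tuple] = {}
            for te, p in embedded[tid][sg]:
                if te.te_id not in best or p.rpkm > best[te.te_id][1].rpkm:
                    best[te.te_id] = (te, p)
            for te, p in best.values():
                subfams.add(te.subfamily)
                seq = genome[te.interval.chrom][te.interval.start : te.interval.end]
                rel = p.summit - te.interval.start
                w0 = max(0, rel - window // 2)
                w1 = min(len(seq), rel + window // 2)
                queries.append(TFBSQuery(tid, sg, te.te_id, seq, w0, w1))
        for sg in ("A", "B", "D"):
            if sg in sgs:
                continue
            iv = prom_iv[(tid, sg)]
            has_copy = any(
                te.subfamily in subfams and te.interval.overlaps(iv)
                for te in by_chrom.get(iv.chrom, [])
            )
            if has_copy:
                continue
            targets.setdefault(tid, []).append(
                PromoterTarget(tid, sg, iv, genome[iv.chrom][iv.start : iv.end])
            )
    return presence, queries, targets


def detect_dtes(
    queries: Sequence[TFBSQuery],
    targets_by_triad: Mapping[str, Sequence[PromoterTarget]],
    te_intervals: Sequence[GenomicInterval],
    **detection_kwargs,
) -> list[DTEHit]:
    """Run relic detection for every query against its sister promoters."""
    hits: list[DTEHit] = []
    for q in queries:
        for t in targets_by_triad.get(q.triad_id, []):
            if t.subgenome == q.source_subgenome:
                continue
            hits.extend(find_dte(q, t, te_intervals, **detection_kwargs))
    # one best hit per (triad, target subgenome)
    best: dict[tuple[str, str], DTEHit] = {}
    for h in hits:
        key = (h.triad_id, h.target_subgenome)
        if key not in best or h.alignment_length > best[key].alignment_length:
            best[key] = h
    return sorted(
        best.values(), key=lambda h: (h.triad_id, h.target_subgenome)
    )
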