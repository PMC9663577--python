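"""Kimura two-parameter distances, LTR insertion dating and TE/TFBS
expansion profiling.

The K2P model separates transitions (purine-purine, pyrimidine-
pyrimidine) from transversions; with transition proportion p and
transversion proportion q over the gap-free columns of an alignment,

    d = -1/2 ln(1 - 2p - q) - 1/4 ln(1 - 2q)

substitutions per site. Columns containing a gap or an ambiguous base in
either sequence are ignored. An LTR retrotransposon's two LTRs are
identical at insertion, so their K2P distance dates the copy:
age = d / (2 * mu) with a substitution rate mu per site per year.

Distances between many sequences are computed per pair from pairwise
global alignments (affine gaps), not from a multiple alignment: for two
sequences the pairwise optimum is deterministic and dependency-free.
Expansion events show up as modes in the pairwise-distance distribution;
modes are detected on a Silverman-bandwidth KDE with a prominence floor,
making the visual "apparent peak" criterion explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("polytereg")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class K2PSaturationError(ValueError):
    """The log arguments are non-positive: distance is saturated."""


class K2PUndefinedError(ValueError):
    """No gap-free unambiguous columns to compare."""


@dataclass(frozen=True, slots=True)
class K2PResult:
    p: float  # transition proportion
    q: float  # transversion proportion
    sites: int  # gap-free unambiguous columns compared
    distance: float  # substitutions per site


@dataclass(frozen=True, slots=True)
class TEAge:
    te_id: str
    ltr_distance: float
    age_years: float


def _encode(seq: str) -> np.ndarray:
    """Map to 0..3 for ACGT, -1 for gaps/ambiguity codes."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a, b = _encode(seq_a), _encode(seq_b)
    ok = (a >= 0) & (b >= 0)
    sites = int(ok.sum())
    if sites == 0:
        raise K2PUndefinedError("no comparable (gap-free, unambiguous) columns")
    diff = ok & (a != b)
    # transitions flip the second bit in the A=0,C=1,G=2,T=3 encoding
    transitions = diff & ((a ^ b) == 2)
    p = int(transitions.sum()) / sites
    q = int((diff & ~transitions).sum()) / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PSaturationError(
            f"saturated alignment (p={p:.3f}, q={q:.3f})"
        )
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(p, q, sites, float(d))


# ---------------------------------------------------------------------------
# Pairwise alignment helpers
# ---------------------------------------------------------------------------

def _global_aligner():
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def align_global(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Gapped strings of the optimal global alignment (affine gaps)."""
    aln = _global_aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def k2p_distance_unaligned(seq_a: str, seq_b: str) -> K2PResult:
    ga, gb = align_global(seq_a, seq_b)
    return k2p_distance(ga, gb)


def te_insertion_age(
    te_id: str,
    ltr5_seq: str,
    ltr3_seq: str,
    mutation_rate: float = 1.3e-8,
) -> TEAge:
    """Date a full-length TE copy from the divergence of its two LTRs."""
    if not ltr5_seq or not ltr3_seq:
        raise ValueError(f"missing LTR sequence for {te_id}")
    if mutation_rate <= 0:
        raise ValueError("mutation rate must be positive")
    res = k2p_distance_unaligned(ltr5_seq, ltr3_seq)
    return TEAge(te_id, res.distance, res.distance / (2.0 * mutation_rate))


def te_ages_from_annotations(
    tes, genome: Mapping[str, str], mutation_rate: float = 1.3e-8
) -> list[TEAge]:
    """Insertion ages for every full-length TE with both LTRs annotated."""
    ages = []
    for te in tes:
        if not te.full_length:
            continue
        seq = genome[te.interval.chrom]
        ltr5 = seq[te.ltr5.start : te.ltr5.end]
        ltr3 = seq[te.ltr3.start : te.ltr3.end]
        try:
            ages.append(te_insertion_age(te.te_id, ltr5, ltr3, mutation_rate))
        except K2PSaturationError:
            logger.warning("saturated LTR pair for %s; skipped", te.te_id)
    return ages


# ---------------------------------------------------------------------------
# Distance distributions and expansion modes
# ---------------------------------------------------------------------------

def pairwise_k2p_distances(
    seqs: Sequence[str],
) -> tuple[np.ndarray, int]:
    """All-vs-all K2P distances from pairwise global alignments.

    Returns (distances, number of saturated pairs dropped).
    """
    dists, saturated = [], 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            try:
                dists.append(k2p_distance_unaligned(seqs[i], seqs[j]).distance)
            except K2PSaturationError:
                saturated += 1
    return np.asarray(dists), saturated


def cross_k2p_distances(
    seqs_a: Sequence[str], seqs_b: Sequence[str]
) -> tuple[np.ndarray, int]:
    dists, saturated = [], 0
    for sa in seqs_a:
        for sb in seqs_b:
            try:
                dists.append(k2p_distance_unaligned(sa, sb).distance)
            except K2PSaturationError:
                saturated += 1
    return np.asarray(dists), saturated


def detect_modes(
    distances: np.ndarray,
    prominence_fraction: float = 0.05,
    grid_points: int = 512,
) -> list[tuple[float, float]]:
    """Local maxima of a Silverman-bandwidth KDE of the distances.

    Returns (mode location, density) pairs sorted by decreasing density;
    peaks need prominence >= ``prominence_fraction`` of the maximum
    density. Degenerate samples (n < 3 or zero variance) yield a single
    mode at the sample point.
    """
    from scipy.signal import find_peaks
    from scipy.stats import gaussian_kde

    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return []
    if d.size < 3 or np.allclose(d, d[0]):
        return [(float(np.median(d)), float("inf"))]
    kde = gaussian_kde(d, bw_method="silverman")
    pad = 3 * d.std()
    grid = np.linspace(max(0.0, d.min() - pad), d.max() + pad, grid_points)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_fraction * dens.max())
    modes = sorted(
        ((float(grid[i]), float(dens[i])) for i in peaks), key=lambda m: -m[1]
    )
    return modes


@dataclass(frozen=True, slots=True)
class ExpansionProfile:
    distances: np.ndarray
    modes: list[tuple[float, float]]
    n_sampled: int
    n_saturated: int


def tfbs_expansion_profile(
    seqs: Sequence[str],
    n_sample: int = 500,
    seed: int = 0,
    prominence_fraction: float = 0.05,
) -> ExpansionProfile:
    """Pairwise-distance distribution of (sampled) TFBS sequences.

    Samples ``n_sample`` sequences without replacement (all when fewer),
    aligns every pair globally, and reports K2P distances with the KDE
    modes marking expansion events.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    rng = np.random.default_rng(seed)
    if len(seqs) > n_sample:
        idx = rng.choice(len(seqs), size=n_sample, replace=False)
        sample = [seqs[i] for i in sorted(idx)]
    else:
        sample = list(seqs)
    dists, saturated = pairwise_k2p_distances(sample)
    return ExpansionProfile(
        dists, detect_modes(dists, prominence_fraction), len(sample), saturated
    )


# ---------------------------------------------------------------------------
# TFBS pair-similarity search
# ---------------------------------------------------------------------------

def _local_aligner():
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -2
    return al


def _alignment_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(columns, identities, qstart, qend, tstart, tend) of a local alignment.

    Columns count aligned positions plus internal gaps (the BLAST
    "alignment length" convention).
    """
    blocks_q, blocks_t = aln.aligned
    if len(blocks_q) == 0:
        return 0, 0, 0, 0, 0, 0
    qseq, tseq = aln.sequences
    identities = 0
    columns = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if prev_q is not None:
            columns += (qs - prev_q) + (ts - prev_t)  # internal gaps
        columns += qe - qs
        for k in range(qe - qs):
            if qseq[qs + k] == tseq[ts + k]:
                identities += 1
        prev_q, prev_t = qe, te
    return columns, identities, blocks_q[0][0], blocks_q[-1][1], blocks_t[0][0], blocks_t[-1][1]


def find_similar_tfbs_pairs(
    seqs: Sequence[str],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    min_score: float = 40.0,
) -> list[tuple[int, int, float, float]]:
    """All-vs-all local alignment keeping high-similarity pairs.

    A pair is reported when identity exceeds ``min_identity`` percent over
    the alignment, the aligned query span exceeds ``min_coverage`` percent
    of the query length, and the alignment score clears ``min_score`` — a
    deterministic floor standing in for a database-size-dependent E-value
    cutoff. Returns (i, j, identity, coverage) tuples.
    """
    al = _local_aligner()
    out = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            alns = al.align(seqs[i], seqs[j])
            if alns.score < min_score:
                continue
            cols, idents, qs, qe, _, _ = _alignment_stats(alns[0])
            if cols == 0:
                continue
            identity = 100.0 * idents / cols
            coverage = 100.0 * (qe - qs) / len(seqs[i])
            if identity > min_identity and coverage > min_coverage:
                out.append((i, j, identity, coverage))
    return out


# ---------------------------------------------------------------------------
# Cross-lineage TE distance distributions (paleo- vs neo-expansion)
# ---------------------------------------------------------------------------

def merged_ltr_sequences(tes, genome: Mapping[str, str]) -> list[str]:
    """5' + 3' LTR concatenated per full-length copy (the dating unit)."""
    out = []
    for te in tes:
        if not te.full_length:
            continue
        seq = genome[te.interval.chrom]
        out.append(seq[te.ltr5.start : te.ltr5.end] + seq[te.ltr3.start : te.ltr3.end])
    return out


def cross_lineage_te_distance(
    copies_by_lineage: Mapping[str, Sequence[str]],
    n_sample: int = 500,
    seed: int = 0,
    min_copies: int = 25,
    prominence_fraction: float = 0.05,
) -> dict[tuple[str, str], ExpansionProfile]:
    """Between-lineage merged-LTR K2P distributions for one TE family.

    Lineages with fewer than ``min_copies`` full-length copies are skipped
    (with a warning). The largest lineage is subsampled to ``n_sample``;
    the others proportionally to their total copy numbers, mirroring
    abundance-matched sampling. A family expanded before lineage
    divergence shows one shared mode across all lineage pairs; a family
    expanded within a single lineage leaves no shared cross-lineage mode.
    """
    kept = {}
    for lin in sorted(copies_by_lineage):
        copies = list(copies_by_lineage[lin])
        if len(copies) < min_copies:
            logger.warning(
                "lineage %s has %d (<%d) full-length copies; skipped",
                lin, len(copies), min_copies,
            )
            continue
        kept[lin] = copies
    rng = np.random.default_rng(seed)
    if not kept:
        return {}
    ref_total = max(len(v) for v in kept.values())
    sampled: dict[str, list[str]] = {}
    for lin, copies in kept.items():
        target = min(len(copies), max(2, round(n_sample * len(copies) / ref_total)))
        if len(copies) > target:
            idx = rng.choice(len(copies), size=target, replace=False)
            sampled[lin] = [copies[i] for i in sorted(idx)]
        else:
            sampled[lin] = copies
    out: dict[tuple[str, str], ExpansionProfile] = {}
    lins = sorted(sampled)
    for i in range(len(lins)):
        for j in range(i + 1, len(lins)):
            dists, sat = cross_k2p_distances(sampled[lins[i]], sampled[lins[j]])
            if dists.size == 0 and sat > 0:
                raise K2PSaturationError(
                    f"all pairs saturated between {lins[i]} and {lins[j]}"
                )
            out[(lins[i], lins[j])] = ExpansionProfile(
                dists,
                detect_modes(dists, prominence_fraction),
                len(sampled[lins[i]]) + len(sampled[lins[j]]),
                sat,
            )
    return out


def shared_cross_lineage_mode(
    profiles: Mapping[tuple[str, str], ExpansionProfile],
    max_spread: float = 0.20,
) -> tuple[float, float] | None:
    """Common primary mode across lineage pairs, if any.

    Requires at least two lineage pairs, each with a detected mode, whose
    primary modes agree within ``max_spread`` (relative range / mean).
    Returns (mean mode, spread) or None.
    """
    if len(profiles) < 2:
        return None
    primaries = []
    for prof in profiles.values():
        if not prof.modes:
            return None
        primaries.append(prof.modes[0][0])
    mean = float(np.mean(primaries))
    if mean <= 0:
        return None
    spread = (max(primaries) - min(primaries)) / mean
    return (mean, spread) if spread < max_spread else None
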