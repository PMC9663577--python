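"""Synthetic three-subgenome polyploid with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* three subgenomes descended from a common ancestor ``divergence_time_years``
  ago (default 5 Myr), mutated independently under a K2P substitution
  process (transition:transversion rate ratio 2, rate ``mutation_rate``
  substitutions/site/year, default 1.3e-8) with no indels, so sequence
  distances have closed-form expectations;
* 1:1:1 gene triads at homologous positions, each with a 5-kb promoter
  centered on the TSS;
* TE families expanded either in the common ancestor (copies present at
  homologous positions in all subgenomes, insertion ages > divergence
  time) or within a single lineage (copies private to one subgenome, ages
  uniform on [0, divergence time]); every copy carries its family motif,
  and the two LTRs of a copy accumulate mutations independently so their
  divergence encodes the insertion age;
* TE relics: a configured fraction of ancestral promoter TE copies is
  "degenerated" in the non-keeper subgenomes — bases outside the
  motif-centered 60-bp window are hypermutated (substitution probability
  0.35/site) and the annotation row is dropped, while the binding-site
  window stays intact;
* per-TF peak sets whose triad-promoter densities follow planted
  balanced/unbalanced proportion patterns perturbed within a Euclidean
  ``noise_radius`` of the standard; relic-completed triads are planted
  balanced;
* expression coupled monotonically to summed promoter binding, with
  lognormal noise.

Alignment blocks are emitted from the known homologous coordinates
(homology classification, not alignment, is the unit under test), and
every emitted entity has exactly one ground-truth row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AlignmentBlock,
    Gene,
    GenomicInterval,
    Peak,
    TEAnnotation,
    Triad,
    write_alignment_blocks,
    write_bed,
    write_fasta,
    write_gff_genes,
    write_peaks,
    write_table,
    write_te_table,
    write_tpm,
    write_triads,
)
from .tfas import STANDARD_PATTERNS

SUBGENOMES = ("A", "B", "D")
PROMOTER_HALF = 2500
GENE_LEN = 800
PEAK_HALF = 100
MOTIF_WINDOW = 60
DEGENERATION_RATE = 0.35
KAPPA = 2.0
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimSizeError(ValueError):
    """The requested TEs/genes cannot be packed into the sequence length."""


@dataclass
class TEFamilyConfig:
    name: str
    subfamily: str
    copies_per_subgenome: int
    epoch: str  # 'ancestral' | 'lineage_A' | 'lineage_B' | 'lineage_D'
    element_length: int = 1000
    ltr_length: int = 220
    motif: str = "TGACGTCAGC"

    def __post_init__(self):
        valid = {"ancestral"} | {f"lineage_{s}" for s in SUBGENOMES}
        if self.epoch not in valid:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.element_length < 2 * self.ltr_length + len(self.motif):
            raise SimSizeError(f"element too short for two LTRs in {self.name}")


def default_te_families() -> list[TEFamilyConfig]:
    return [
        TEFamilyConfig("RLC_famc1", "RLC_famc1.4", 40, "ancestral",
                       element_length=900, ltr_length=200, motif="TGACGTCAGC"),
        TEFamilyConfig("RLG_famc7", "RLG_famc7.3", 40, "lineage_A",
                       element_length=1100, ltr_length=240, motif="CACGTGGCAT"),
        TEFamilyConfig("RLG_famc13", "RLG_famc13", 30, "lineage_D",
                       element_length=1000, ltr_length=220, motif="GGCCAATCAG"),
    ]


@dataclass
class SimConfig:
    subgenome_length: int = 2_000_000
    n_triads: int = 300
    n_tfs: int = 5
    te_families: list[TEFamilyConfig] = field(default_factory=default_te_families)
    mutation_rate: float = 1.3e-8
    divergence_time_years: float = 5e6
    relic_fraction: float = 0.3
    promoter_te_fraction: float = 0.4
    segment_loss_fraction: float = 0.04
    balance_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "ABD": 0.40, "AB": 0.10, "AD": 0.10, "BD": 0.10,
            "A": 0.10, "B": 0.10, "D": 0.10,
        }
    )
    noise_radius: float = 0.15
    total_signal: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name, frac in (
            ("relic_fraction", self.relic_fraction),
            ("promoter_te_fraction", self.promoter_te_fraction),
            ("segment_loss_fraction", self.segment_loss_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if set(self.balance_mixture) != set(STANDARD_PATTERNS):
            raise ValueError("balance_mixture must cover the seven patterns")
        if abs(sum(self.balance_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("balance_mixture must sum to 1")
        if not 0.0 <= self.noise_radius < math.sqrt(1 / 6):
            raise ValueError("noise_radius must be below the standard separation")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        fams = d.pop("te_families", None)
        cfg = cls(**d) if fams is None else cls(
            te_families=[TEFamilyConfig(**f) for f in fams], **d
        )
        return cfg


@dataclass
class TruthTables:
    te: pd.DataFrame        # te_id, chrom, start, end, subfamily, epoch, age_years, full_length
    patterns: pd.DataFrame  # triad_id, tf_id, pattern, pA, pB, pD, forced
    dte: pd.DataFrame       # triad_id, subgenome, chrom, start, end, source_te_id, win_start, win_end
    regions: pd.DataFrame   # chrom, start, end, class
    promoter_te: pd.DataFrame  # triad_id, subgenome, te_id, annotated


@dataclass
class Dataset:
    config: SimConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[Gene]
    triads: list[Triad]
    tes: list[TEAnnotation]
    peaks_by_tf: dict[str, list[Peak]]
    dhs_intervals: list[GenomicInterval]
    dhs_density: dict[str, float]
    tpm: dict[str, float]
    blocks: dict[tuple[str, str], list[AlignmentBlock]]
    synteny: list[GenomicInterval]
    tads: list[GenomicInterval]
    truth: TruthTables

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        for sg in SUBGENOMES:
            chroms = {c: s for c, s in self.genome.items() if c.endswith(sg)}
            write_fasta(chroms, out / f"genome_{sg}.fa")
        write_gff_genes(self.genes, out / "genes.gff3")
        write_te_table(self.tes, out / "te.tsv")
        write_triads(self.triads, out / "triads.tsv")
        for tf, peaks in sorted(self.peaks_by_tf.items()):
            write_peaks(peaks, out / "peaks" / f"{tf}.narrowPeak")
        write_bed(self.dhs_intervals, out / "dhs.bed")
        write_table(
            pd.DataFrame(
                sorted(self.dhs_density.items()), columns=["gene_id", "density"]
            ),
            out / "dhs.tsv", sort_by=["gene_id"],
        )
        write_tpm(self.tpm, out / "tpm.tsv")
        all_blocks = [b for bl in self.blocks.values() for b in bl]
        write_alignment_blocks(all_blocks, out / "blocks.tsv")
        write_bed(self.synteny, out / "synteny.bed")
        write_bed(self.tads, out / "tads.bed")
        write_table(self.truth.te, out / "truth" / "te.tsv", sort_by=["te_id"])
        write_table(self.truth.patterns, out / "truth" / "patterns.tsv",
                    sort_by=["triad_id", "tf_id"])
        write_table(self.truth.dte, out / "truth" / "dte.tsv",
                    sort_by=["triad_id", "subgenome"])
        write_table(self.truth.regions, out / "truth" / "regions.tsv")
        write_table(self.truth.promoter_te, out / "truth" / "promoter_te.tsv",
                    sort_by=["triad_id", "subgenome"])


# ---------------------------------------------------------------------------
# K2P mutation process
# ---------------------------------------------------------------------------

def k2p_substitution_probs(
    t_years: float, mutation_rate: float, kappa: float = KAPPA
) -> tuple[float, float]:
    """Exact per-site (transition, each-transversion) change probabilities."""
    beta = mutation_rate / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t_years)
    e2 = math.exp(-2.0 * (alpha + beta) * t_years)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return p_ts, p_tv


def mutate_k2p(
    arr: np.ndarray, t_years: float, mutation_rate: float,
    rng: np.random.Generator, kappa: float = KAPPA,
) -> np.ndarray:
    """Evolve a 0..3-coded sequence for t years under the K2P process."""
    p_ts, p_tv = k2p_substitution_probs(t_years, mutation_rate, kappa)
    r = rng.random(arr.size)
    out = arr.copy()
    out[r < p_ts] ^= 2                                   # transition
    out[(r >= p_ts) & (r < p_ts + p_tv)] ^= 1            # transversion 1
    out[(r >= p_ts + p_tv) & (r < p_ts + 2 * p_tv)] ^= 3  # transversion 2
    return out


def hypermutate(
    arr: np.ndarray, rng: np.random.Generator, rate: float = DEGENERATION_RATE
) -> np.ndarray:
    """Substitute each site to a uniformly random other base with prob ``rate``."""
    hit = rng.random(arr.size) < rate
    out = arr.copy()
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def perturb_proportions(
    standard: Sequence[float], radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform perturbation within a Euclidean disc on the simplex plane."""
    std = np.asarray(standard, dtype=float)
    e1 = np.array([1.0, -1.0, 0.0]) / math.sqrt(2)
    e2 = np.array([1.0, 1.0, -2.0]) / math.sqrt(6)
    while True:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        r = radius * math.sqrt(rng.uniform())
        cand = std + r * math.cos(ang) * e1 + r * math.sin(ang) * e2
        if (cand >= 0.0).all():
            return cand


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class _Segment:
    sid: int
    kind: str           # 'bg' | 'prom' | 'gene' | 'te'
    arr: np.ndarray     # ancestral sequence (already aged by extra_age for TEs)
    insertable: bool = False
    deletable: bool = False
    locus: int = -1
    fam: TEFamilyConfig | None = None
    age_extra: float = 0.0      # pre-divergence age of an ancestral TE copy
    motif_span: tuple[int, int] | None = None  # within segment
    relic_keeper: str | None = None            # subgenome keeping the annotation


def _build_element(
    fam: TEFamilyConfig, consensus: dict, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, int]]:
    """Fresh copy of a family consensus; returns (sequence, motif span)."""
    ltr, internal, motif_off = consensus[fam.name]
    arr = np.concatenate([ltr, internal, ltr])
    span = (fam.ltr_length + motif_off, fam.ltr_length + motif_off + len(fam.motif))
    return arr.copy(), span


def simulate(config: SimConfig) -> Dataset:
    rng = np.random.default_rng(config.seed)
    L, n_triads = config.subgenome_length, config.n_triads
    T, mu = config.divergence_time_years, config.mutation_rate
    locus_len = L // n_triads
    reserve = PROMOTER_HALF - GENE_LEN + 100  # keeps next locus out of promoters
    spacer_len = locus_len - PROMOTER_HALF - GENE_LEN
    insertable_len = spacer_len - reserve
    max_elem = max((f.element_length for f in config.te_families), default=0)
    if insertable_len < max_elem + 120 or spacer_len < reserve:
        raise SimSizeError(
            f"locus length {locus_len} bp cannot hold promoter, gene and TEs "
            f"(need >= {PROMOTER_HALF + GENE_LEN + reserve + max_elem + 120} bp/triad)"
        )

    # family consensus sequences: LTR, internal (motif centered), motif offset
    consensus: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for fam in config.te_families:
        internal_len = fam.element_length - 2 * fam.ltr_length
        internal = _random_seq(rng, internal_len)
        off = (internal_len - len(fam.motif)) // 2
        internal[off : off + len(fam.motif)] = _encode(fam.motif)
        consensus[fam.name] = (_random_seq(rng, fam.ltr_length), internal, off)

    ancestral_fams = [f for f in config.te_families if f.epoch == "ancestral"]
    lineage_fams = [f for f in config.te_families if f.epoch != "ancestral"]
    if config.promoter_te_fraction > 0 and not ancestral_fams:
        raise SimSizeError("promoter TEs require an ancestral-epoch family")

    # --- plan ancestral copies -------------------------------------------
    n_prom_te = round(config.promoter_te_fraction * n_triads)
    prom_fam = ancestral_fams[0] if ancestral_fams else None
    if prom_fam is not None and prom_fam.element_length > PROMOTER_HALF - 500:
        raise SimSizeError("promoter TE family element does not fit in the promoter")
    prom_te_loci = sorted(rng.choice(n_triads, size=min(n_prom_te, n_triads),
                                     replace=False).tolist())
    n_relics = round(config.relic_fraction * len(prom_te_loci))
    relic_loci = set(
        int(x) for x in rng.choice(prom_te_loci, size=n_relics, replace=False)
    ) if n_relics else set()

    spacer_copies: dict[int, list[TEFamilyConfig]] = {i: [] for i in range(n_triads)}
    for fam in ancestral_fams:
        n_spacer = fam.copies_per_subgenome - (
            len(prom_te_loci) if fam is prom_fam else 0
        )
        n_spacer = max(0, n_spacer)
        free = [i for i in range(n_triads) if not spacer_copies[i]]
        if n_spacer > len(free):
            raise SimSizeError(
                f"too many ancestral copies of {fam.name} for {n_triads} loci"
            )
        for i in rng.choice(free, size=n_spacer, replace=False):
            spacer_copies[int(i)].append(fam)

    # --- build ancestral segment list ------------------------------------
    segs: list[_Segment] = []
    sid = 0

    def add(kind, arr, **kw):
        nonlocal sid
        segs.append(_Segment(sid, kind, arr, **kw))
        sid += 1

    prom_te_keeper: dict[int, str] = {}
    for i in range(n_triads):
        add("bg", _random_seq(rng, reserve), locus=i)  # promoter-shielding spacer
        budget = insertable_len
        for fam in spacer_copies[i]:
            lead = int(rng.integers(50, max(51, budget - fam.element_length - 60)))
            add("bg", _random_seq(rng, lead), insertable=True, deletable=True, locus=i)
            arr, span = _build_element(fam, consensus, rng)
            extra = float(rng.uniform(0.0, 0.5 * T))
            arr = mutate_k2p(arr, extra, mu, rng)
            add("te", arr, locus=i, fam=fam, age_extra=extra, motif_span=span)
            budget -= lead + fam.element_length
        add("bg", _random_seq(rng, budget), insertable=True, deletable=True, locus=i)

        if i in prom_te_loci:
            assert prom_fam is not None
            elem, span = _build_element(prom_fam, consensus, rng)
            prom_right = int(rng.integers(300, 600))
            prom_left = PROMOTER_HALF - prom_fam.element_length - prom_right
            keeper = SUBGENOMES[int(rng.integers(3))] if i in relic_loci else None
            add("prom", _random_seq(rng, prom_left), locus=i)
            extra = float(rng.uniform(0.0, 0.5 * T))
            add("te", mutate_k2p(elem, extra, mu, rng), locus=i, fam=prom_fam,
                age_extra=extra, motif_span=span, relic_keeper=keeper)
            if keeper:
                prom_te_keeper[i] = keeper
            add("prom", _random_seq(rng, prom_right), locus=i)
        else:
            add("prom", _random_seq(rng, PROMOTER_HALF), locus=i)
        add("gene", _random_seq(rng, GENE_LEN), locus=i)
    tail = L - locus_len * n_triads
    if tail > 0:
        # tail stays insertion-free so the last promoter window is clean
        add("bg", _random_seq(rng, tail))

    # --- lineage plans ----------------------------------------------------
    deleted: dict[str, set[int]] = {s: set() for s in SUBGENOMES}
    for seg in segs:
        if seg.deletable:
            for s in SUBGENOMES:
                if rng.random() < config.segment_loss_fraction:
                    deleted[s].add(seg.sid)

    inserts: dict[str, dict[int, list[tuple[int, TEFamilyConfig, float]]]] = {
        s: {} for s in SUBGENOMES
    }
    for fam in lineage_fams:
        s = fam.epoch.split("_")[1]
        hosts = [g for g in segs
                 if g.insertable and g.sid not in deleted[s] and len(g.arr) >= 200]
        if not hosts:
            raise SimSizeError(f"no host segments for {fam.name} in {s}")
        weights = np.array([len(g.arr) for g in hosts], dtype=float)
        weights /= weights.sum()
        for _ in range(fam.copies_per_subgenome):
            host = hosts[int(rng.choice(len(hosts), p=weights))]
            taken = {o for o, _, _ in inserts[s].get(host.sid, [])}
            off = int(rng.integers(50, len(host.arr) - 50))
            while off in taken:
                off = int(rng.integers(50, len(host.arr) - 50))
            age = float(rng.uniform(0.0, T))
            inserts[s].setdefault(host.sid, []).append((off, fam, age))
    for plan in inserts.values():
        for lst in plan.values():
            lst.sort()

    # --- assemble subgenomes ---------------------------------------------
    genome_arr: dict[str, np.ndarray] = {}
    chrom_sizes: dict[str, int] = {}
    # sid -> subgenome -> list of (anc_off0, anc_off1, genome_start)
    piece_map: dict[int, dict[str, list[tuple[int, int, int]]]] = {}
    te_rows: list[dict] = []
    gene_pos: dict[str, dict[int, int]] = {s: {} for s in SUBGENOMES}  # locus->tss
    dte_rows: list[dict] = []
    prom_te_rows: list[dict] = []
    te_counter = 0

    for s in SUBGENOMES:
        chrom = f"1{s}"
        parts: list[np.ndarray] = []
        pos = 0
        for seg in segs:
            if seg.sid in deleted[s]:
                continue
            arr = mutate_k2p(seg.arr, T, mu, rng)
            annotated = seg.kind == "te"
            if seg.kind == "te" and seg.relic_keeper and seg.relic_keeper != s:
                m0, m1 = seg.motif_span
                c = (m0 + m1) // 2
                w0, w1 = max(0, c - MOTIF_WINDOW // 2), min(len(arr), c + MOTIF_WINDOW // 2)
                degen = hypermutate(arr, rng)
                degen[w0:w1] = arr[w0:w1]  # binding-site window left intact
                arr = degen
                annotated = False
                dte_rows.append({
                    "triad_id": f"triad{seg.locus:05d}",
                    "subgenome": s, "chrom": chrom,
                    "start": pos, "end": pos + len(arr),
                    "source_te_id": f"anc{seg.sid}",
                    "win_start": pos + w0, "win_end": pos + w1,
                })
            pieces = []
            seg_inserts = inserts[s].get(seg.sid, [])
            cur = 0
            for off, fam, age in seg_inserts:
                pieces.append((cur, off))
                cur = off
            pieces.append((cur, len(arr)))
            # interleave: ancestral piece, element, ancestral piece, ...
            pm = piece_map.setdefault(seg.sid, {}).setdefault(s, [])
            ins_iter = iter(seg_inserts)
            for k, (a0, a1) in enumerate(pieces):
                parts.append(arr[a0:a1])
                pm.append((a0, a1, pos))
                if seg.kind == "te" and k == 0:
                    te_id = f"anc{seg.sid}"
                    fam_c = seg.fam
                    if annotated:
                        te_rows.append({
                            "te_id": f"{te_id}_{s}", "chrom": chrom,
                            "start": pos, "end": pos + len(arr),
                            "family": fam_c.name, "subfamily": fam_c.subfamily,
                            "epoch": "ancestral",
                            "age_years": seg.age_extra + T,
                            "full_length": 1,
                            "ltr5_start": pos, "ltr5_end": pos + fam_c.ltr_length,
                            "ltr3_start": pos + len(arr) - fam_c.ltr_length,
                            "ltr3_end": pos + len(arr),
                            "motif_start": pos + seg.motif_span[0],
                            "motif_end": pos + seg.motif_span[1],
                            "locus": seg.locus,
                            "in_promoter": int(seg.relic_keeper is not None
                                               or _is_prom_te(segs, seg)),
                        })
                    if seg.relic_keeper is not None or _is_prom_te(segs, seg):
                        prom_te_rows.append({
                            "triad_id": f"triad{seg.locus:05d}", "subgenome": s,
                            "te_id": f"{te_id}_{s}", "annotated": int(annotated),
                        })
                if seg.kind == "gene" and a0 == 0:
                    gene_pos[s][seg.locus] = pos
                pos += a1 - a0
                nxt = next(ins_iter, None) if k < len(pieces) - 1 else None
                if nxt is not None:
                    off, fam, age = nxt
                    elem, span = _build_element(fam, consensus, rng)
                    elem = mutate_k2p(elem, age, mu, rng)
                    parts.append(elem)
                    te_counter += 1
                    te_rows.append({
                        "te_id": f"lin{te_counter}_{s}", "chrom": chrom,
                        "start": pos, "end": pos + len(elem),
                        "family": fam.name, "subfamily": fam.subfamily,
                        "epoch": fam.epoch, "age_years": age, "full_length": 1,
                        "ltr5_start": pos, "ltr5_end": pos + fam.ltr_length,
                        "ltr3_start": pos + len(elem) - fam.ltr_length,
                        "ltr3_end": pos + len(elem),
                        "motif_start": pos + span[0], "motif_end": pos + span[1],
                        "locus": -1, "in_promoter": 0,
                    })
                    pos += len(elem)
        genome_arr[chrom] = np.concatenate(parts)
        chrom_sizes[chrom] = pos

    te_df = pd.DataFrame(te_rows)
    genome = {c: _decode(a) for c, a in genome_arr.items()}

    # --- genes and triads -------------------------------------------------
    genes: list[Gene] = []
    triads: list[Triad] = []
    gene_ids: dict[tuple[int, str], str] = {}
    for i in range(n_triads):
        ids = {}
        for s in SUBGENOMES:
            tss = gene_pos[s][i]
            gid = f"G{i:05d}{s}"
            genes.append(Gene(gid, GenomicInterval(f"1{s}", tss, tss + GENE_LEN, "+"),
                              tss, s))
            ids[s] = gid
            gene_ids[(i, s)] = gid
        triads.append(Triad(f"triad{i:05d}", ids["A"], ids["B"], ids["D"]))

    # --- alignment blocks (both directions per pair) ----------------------
    blocks: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for x in SUBGENOMES:
        for y in SUBGENOMES:
            if x == y:
                continue
            bl: list[AlignmentBlock] = []
            for seg in segs:
                pm = piece_map.get(seg.sid, {})
                if x not in pm or y not in pm:
                    continue
                cuts = sorted({p[0] for p in pm[x]} | {p[1] for p in pm[x]}
                              | {p[0] for p in pm[y]} | {p[1] for p in pm[y]})
                for u, v in zip(cuts, cuts[1:]):
                    qx = _map_offset(pm[x], u)
                    qy = _map_offset(pm[y], u)
                    seq_x = genome_arr[f"1{x}"][qx : qx + (v - u)]
                    seq_y = genome_arr[f"1{y}"][qy : qy + (v - u)]
                    ident = 100.0 * float((seq_x == seq_y).mean())
                    bl.append(AlignmentBlock(
                        GenomicInterval(f"1{x}", qx, qx + (v - u)),
                        GenomicInterval(f"1{y}", qy, qy + (v - u)),
                        ident,
                    ))
            blocks[(x, y)] = bl

    synteny = [
        GenomicInterval(c, int(0.2 * n), int(0.8 * n)) for c, n in chrom_sizes.items()
    ]

    # --- region-class truth (per-base, threshold-aware) --------------------
    region_rows = _region_truth(segs, piece_map, deleted, chrom_sizes, synteny)

    # --- peaks, DHS, expression -------------------------------------------
    tf_ids = [f"TF{k + 1}" for k in range(config.n_tfs)]
    fam_tf: dict[str, str] = {
        fam.name: tf_ids[k % len(tf_ids)]
        for k, fam in enumerate(config.te_families)
    }
    mix_names = list(STANDARD_PATTERNS)
    mix_p = np.array([config.balance_mixture[n] for n in mix_names])

    prom_te_motif_offset: dict[int, int] = {}
    prom_te_span: dict[int, tuple[int, int]] = {}  # TE span as TSS offsets
    for seg in segs:
        if seg.kind == "te" and _is_prom_te(segs, seg):
            nxt = segs[segs.index(seg) + 1]  # prom_right segment
            prom_te_motif_offset[seg.locus] = -(
                len(nxt.arr) + len(seg.arr) - (seg.motif_span[0] + seg.motif_span[1]) // 2
            )
            prom_te_span[seg.locus] = (
                -(len(nxt.arr) + len(seg.arr)), -len(nxt.arr)
            )

    peaks_by_tf: dict[str, list[Peak]] = {tf: [] for tf in tf_ids}
    pattern_rows = []
    promoter_signal: dict[str, float] = {g.gene_id: 0.0 for g in genes}
    for tf in tf_ids:
        for i in range(n_triads):
            forced = (
                i in relic_loci
                and prom_fam is not None
                and fam_tf[prom_fam.name] == tf
            )
            pattern = "ABD" if forced else mix_names[
                int(rng.choice(len(mix_names), p=mix_p))
            ]
            props = perturb_proportions(
                STANDARD_PATTERNS[pattern], config.noise_radius, rng
            )
            if (
                i in prom_te_loci
                and prom_fam is not None
                and fam_tf[prom_fam.name] == tf
            ):
                offset = prom_te_motif_offset[i]
            else:
                # keep non-family peaks out of the promoter TE so that every
                # TE-embedded binding site is the planted motif; the upstream
                # stretch beyond the TE is always wide enough
                span = prom_te_span.get(i, (0, 0))
                offset = int(rng.integers(-2400, -200))
                while span[0] - PEAK_HALF <= offset < span[1] + PEAK_HALF:
                    offset = int(rng.integers(-2400, -200))
            for s, prop in zip(SUBGENOMES, props):
                rpkm = float(prop * config.total_signal)
                if rpkm <= 1e-9:
                    continue
                tss = gene_pos[s][i]
                summit = tss + offset
                iv = GenomicInterval(f"1{s}", summit - PEAK_HALF, summit + PEAK_HALF)
                peaks_by_tf[tf].append(Peak(iv, summit, rpkm, tf))
                promoter_signal[gene_ids[(i, s)]] += rpkm
            pattern_rows.append({
                "triad_id": f"triad{i:05d}", "tf_id": tf, "pattern": pattern,
                "pA": props[0], "pB": props[1], "pD": props[2],
                "forced": int(forced),
            })

    # TE-embedded peaks outside promoters (enrichment signal)
    if len(te_df):
        for _, row in te_df[te_df["in_promoter"] == 0].iterrows():
            tf = fam_tf[row["family"]]
            summit = (int(row["motif_start"]) + int(row["motif_end"])) // 2
            iv = GenomicInterval(row["chrom"], summit - PEAK_HALF, summit + PEAK_HALF)
            peaks_by_tf[tf].append(
                Peak(iv, summit, float(rng.lognormal(0.8, 0.4)), tf)
            )
    # background peaks, confined to zones outside every promoter window so
    # they cannot perturb the planted triad proportions
    safe_zones: dict[str, list[tuple[int, int]]] = {}
    margin = PROMOTER_HALF - GENE_LEN  # downstream reach past the gene end
    for s in SUBGENOMES:
        chrom = f"1{s}"
        tss_list = sorted(gene_pos[s].values())
        zones = []
        prev_end = 0
        for tss in tss_list:
            lo, hi = prev_end, tss - PROMOTER_HALF
            if hi - lo > 2 * PEAK_HALF:
                zones.append((lo + PEAK_HALF, hi - PEAK_HALF))
            prev_end = tss + GENE_LEN + margin
        if chrom_sizes[chrom] - prev_end > 2 * PEAK_HALF:
            zones.append((prev_end + PEAK_HALF, chrom_sizes[chrom] - PEAK_HALF))
        safe_zones[chrom] = zones
    for tf in tf_ids:
        for _ in range(max(5, n_triads // 2)):
            chrom = f"1{SUBGENOMES[int(rng.integers(3))]}"
            zones = safe_zones[chrom]
            lengths = np.array([e - s0 for s0, e in zones], dtype=float)
            zi = int(rng.choice(len(zones), p=lengths / lengths.sum()))
            summit = int(rng.integers(zones[zi][0], zones[zi][1]))
            iv = GenomicInterval(chrom, summit - PEAK_HALF, summit + PEAK_HALF)
            peaks_by_tf[tf].append(Peak(iv, summit, float(rng.lognormal(0.0, 0.4)), tf))

    dhs_intervals: list[GenomicInterval] = []
    dhs_density: dict[str, float] = {}
    tpm: dict[str, float] = {}
    for i in range(n_triads):
        for s in SUBGENOMES:
            gid = gene_ids[(i, s)]
            sig = promoter_signal[gid]
            dhs = sig * float(rng.lognormal(0.0, 0.15))
            dhs_density[gid] = dhs
            if dhs > 0.3:
                tss = gene_pos[s][i]
                dhs_intervals.append(GenomicInterval(f"1{s}", tss - 400, tss - 100))
            tpm[gid] = 2.0 * sig * float(rng.lognormal(0.0, 0.25))

    # --- TADs --------------------------------------------------------------
    tads: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        pos = int(rng.integers(0, 20_000))
        while pos + 60_000 < size:
            tl = int(rng.integers(80_000, 250_000))
            end = min(pos + tl, size - 1)
            if end - pos > 40_000:
                tads.append(GenomicInterval(chrom, pos, end))
            pos = end + (0 if rng.random() < 0.5 else int(rng.integers(20_000, 40_000)))

    # --- assemble outputs ---------------------------------------------------
    te_annotations = _te_annotations_from_rows(te_rows)
    truth = TruthTables(
        te=te_df.drop(columns=["locus"]) if len(te_df) else te_df,
        patterns=pd.DataFrame(pattern_rows),
        dte=pd.DataFrame(
            dte_rows, columns=["triad_id", "subgenome", "chrom", "start", "end",
                               "source_te_id", "win_start", "win_end"]
        ),
        regions=pd.DataFrame(
            region_rows, columns=["chrom", "start", "end", "class"]
        ),
        promoter_te=pd.DataFrame(
            prom_te_rows, columns=["triad_id", "subgenome", "te_id", "annotated"]
        ),
    )
    return Dataset(
        config=config, genome=genome, chrom_sizes=chrom_sizes, genes=genes,
        triads=triads, tes=te_annotations, peaks_by_tf=peaks_by_tf,
        dhs_intervals=dhs_intervals, dhs_density=dhs_density, tpm=tpm,
        blocks=blocks, synteny=synteny, tads=tads, truth=truth,
    )


def _is_prom_te(segs: list[_Segment], seg: _Segment) -> bool:
    """A TE segment sitting inside the promoter (followed by a prom segment)."""
    i = segs.index(seg)
    return i + 1 < len(segs) and segs[i + 1].kind == "prom"


def _map_offset(pieces: list[tuple[int, int, int]], off: int) -> int:
    for a0, a1, g in pieces:
        if a0 <= off < a1:
            return g + (off - a0)
    raise KeyError(off)


def _region_truth(segs, piece_map, deleted, chrom_sizes, synteny, min_len=400):
    """Per-base homology-class truth, independent of the classifier."""
    rows = []
    syn_spans = {iv.chrom: (iv.start, iv.end) for iv in synteny}
    for s in SUBGENOMES:
        chrom = f"1{s}"
        size = chrom_sizes[chrom]
        count = np.zeros(size, dtype=np.int8)
        for other in SUBGENOMES:
            if other == s:
                continue
            mask = np.zeros(size, dtype=bool)
            for seg in segs:
                pm = piece_map.get(seg.sid, {})
                if s not in pm or other not in pm:
                    continue
                for a0, a1, g in pm[s]:
                    mask[g : g + (a1 - a0)] = True
            # drop runs <= min_len (the reciprocal-run rule)
            padded = np.concatenate(([False], mask, [False]))
            diff = np.diff(padded.astype(np.int8))
            for s0, e0 in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
                if e0 - s0 <= min_len:
                    mask[s0:e0] = False
            count += mask
        klass = np.where(count == 2, 2, np.where(count == 1, 1, 0))
        names = {0: "specific", 1: "homo2", 2: "homo3"}
        padded = np.concatenate(([-1], klass, [-1]))
        change = np.flatnonzero(np.diff(padded) != 0)
        for s0, e0 in zip(change[:-1], change[1:]):
            rows.append({"chrom": chrom, "start": int(s0), "end": int(e0),
                         "class": names[int(klass[s0])]})
        syn0, syn1 = syn_spans[chrom]
        homoeo = (klass == 2).copy()
        homoeo[:syn0] = False
        homoeo[syn1:] = False
        padded = np.concatenate(([False], homoeo, [False]))
        diff = np.diff(padded.astype(np.int8))
        for s0, e0 in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            rows.append({"chrom": chrom, "start": int(s0), "end": int(e0),
                         "class": "homoeo3"})
    return rows


def _te_annotations_from_rows(te_rows: list[dict]) -> list[TEAnnotation]:
    out = []
    for r in te_rows:
        iv = GenomicInterval(r["chrom"], r["start"], r["end"], "+")
        out.append(TEAnnotation(
            r["te_id"], iv, r["family"], r["subfamily"], bool(r["full_length"]),
            GenomicInterval(r["chrom"], r["ltr5_start"], r["ltr5_end"]),
            GenomicInterval(r["chrom"], r["ltr3_start"], r["ltr3_end"]),
        ))
    return out


# ---------------------------------------------------------------------------
# Focused generators used by property checks
# ---------------------------------------------------------------------------

def simulate_ltr_pairs(
    n: int, age_years: float, ltr_length: int = 2000,
    mutation_rate: float = 1.3e-8, seed: int = 0,
) -> list[tuple[str, str, str, float]]:
    """Full-length-TE LTR pairs of known insertion age.

    Each copy's two LTRs start identical and accumulate K2P substitutions
    independently for ``age_years``; their divergence is 2*mu*age in
    expectation. Returns (te_id, ltr5, ltr3, true_age) tuples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        cons = _random_seq(rng, ltr_length)
        l5 = mutate_k2p(cons, age_years, mutation_rate, rng)
        l3 = mutate_k2p(cons, age_years, mutation_rate, rng)
        out.append((f"te{k}", _decode(l5), _decode(l3), age_years))
    return out


def simulate_relic_promoters(
    n: int,
    seed: int = 0,
    identity_range: tuple[float, float] = (0.75, 0.90),
    length_range: tuple[int, int] = (80, 300),
    te_length: int = 400,
    promoter_length: int = 600,
    tfbs_window: int = 60,
):
    """Planted TE relics inside otherwise random promoters.

    For each of ``n`` triads: a TE sequence with a centered TFBS window,
    and a sister promoter carrying a remnant of the TE — a subsequence of
    planted length mutated to a planted identity, with the TFBS window
    kept nearly intact — at a random position. Returns (queries, targets,
    truth frame); truth holds the remnant span on each promoter.
    """
    from .dte import PromoterTarget, TFBSQuery

    rng = np.random.default_rng(seed)
    queries, targets, truth = [], [], []
    w0 = (te_length - tfbs_window) // 2
    w1 = w0 + tfbs_window
    for k in range(n):
        te = _random_seq(rng, te_length)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        length = max(length, tfbs_window + 10)
        lo = max(0, w1 - length)
        hi = min(te_length - length, w0)
        start = int(rng.integers(lo, hi + 1))
        ident = float(rng.uniform(*identity_range))
        remnant = hypermutate(te[start : start + length], rng, rate=1.0 - ident)
        rw0, rw1 = w0 - start, w1 - start
        remnant[rw0:rw1] = hypermutate(te[w0:w1], rng, rate=0.02)
        ins = int(rng.integers(0, promoter_length - length))
        prom = _random_seq(rng, promoter_length)
        prom[ins : ins + length] = remnant
        tid = f"triad{k:04d}"
        queries.append(TFBSQuery(tid, "A", f"te{k}", _decode(te), w0, w1))
        targets.append(PromoterTarget(
            tid, "B", GenomicInterval("1B", 10_000 * k, 10_000 * k + promoter_length),
            _decode(prom),
        ))
        truth.append({
            "triad_id": tid, "length": length, "identity": ident,
            "start": 10_000 * k + ins, "end": 10_000 * k + ins + length,
        })
    return queries, targets, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    rates: dict[str, float]
    tables: dict[str, pd.DataFrame]
    missing: dict[str, int]


def truth_check(truth: TruthTables, results: Mapping[str, object]) -> RecoveryReport:
    """Score pipeline outputs against the planted ground truth.

    ``results`` may carry any of: 'patterns' (frame with triad_id, tf_id,
    pattern), 'regions' (frame with chrom, start, end, class), 'dte'
    (list of DTEHit), 'ages' (frame with te_id, age_years). Stages absent
    from ``results`` score recovery 0 with an explicit missing count.
    """
    rates: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}
    missing: dict[str, int] = {}

    pat = results.get("patterns")
    if pat is not None and len(pat):
        merged = truth.patterns.merge(
            pd.DataFrame(pat), on=["triad_id", "tf_id"], suffixes=("_true", "_called")
        )
        if len(merged) == 0:
            raise ValueError("pattern results share no (triad, TF) ids with truth")
        acc = float((merged["pattern_true"] == merged["pattern_called"]).mean())
        rates["patterns"] = acc
        tables["pattern_confusion"] = pd.crosstab(
            merged["pattern_true"], merged["pattern_called"]
        )
        missing["patterns"] = len(truth.patterns) - len(merged)
    else:
        rates["patterns"] = 0.0
        missing["patterns"] = len(truth.patterns)

    reg = results.get("regions")
    if reg is not None and len(reg):
        reg = pd.DataFrame(reg)
        agree = both = 0
        for chrom in truth.regions["chrom"].unique():
            t = truth.regions[(truth.regions["chrom"] == chrom)
                              & (truth.regions["class"] != "homoeo3")]
            c = reg[(reg["chrom"] == chrom) & (reg["class"] != "homoeo3")]
            size = int(t["end"].max())
            lab_t = np.full(size, -1, dtype=np.int8)
            lab_c = np.full(size, -1, dtype=np.int8)
            code = {"specific": 0, "homo2": 1, "homo3": 2}
            for _, r in t.iterrows():
                lab_t[r["start"]:r["end"]] = code[r["class"]]
            for _, r in c.iterrows():
                lab_c[r["start"]:min(r["end"], size)] = code[r["class"]]
            agree += int(((lab_t == lab_c) & (lab_t >= 0)).sum())
            both += int((lab_t >= 0).sum())
        rates["regions"] = agree / both if both else 0.0
        missing["regions"] = 0
    else:
        rates["regions"] = 0.0
        missing["regions"] = len(truth.regions)

    hits = results.get("dte")
    if hits is not None and len(truth.dte):
        found = 0
        for _, r in truth.dte.iterrows():
            ok = any(
                h.triad_id == r["triad_id"]
                and h.target_subgenome == r["subgenome"]
                and h.target_region.chrom == r["chrom"]
                and h.target_region.start < r["end"]
                and r["start"] < h.target_region.end
                for h in hits
            )
            found += ok
        rates["dte"] = found / len(truth.dte)
        missing["dte"] = len(truth.dte) - found
    elif len(truth.dte):
        rates["dte"] = 0.0
        missing["dte"] = len(truth.dte)

    ages = results.get("ages")
    if ages is not None and len(ages) and len(truth.te):
        merged = truth.te.merge(
            pd.DataFrame(ages), on="te_id", suffixes=("_true", "_est")
        )
        if len(merged):
            rel = (
                (merged["age_years_est"] - merged["age_years_true"]).abs()
                / merged["age_years_true"].clip(lower=1.0)
            )
            rates["ages_median_rel_error"] = float(rel.median())
            missing["ages"] = len(truth.te) - len(merged)
            tables["ages"] = merged
    return RecoveryReport(rates=rates, tables=tables, missing=missing)
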