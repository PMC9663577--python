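"""Domain types, coordinate conventions and file I/O.

All genomic coordinates are 0-based half-open internally (BED-native).
GFF3 is converted at the boundary and round-trips exactly. The subgenome
of an interval is derived from the chromosome-name suffix (``...A``,
``...B``, ``...D`` by default), configurable through a regex so that
IWGSC-style names ("1A", "chr3B") work without hard-coding.

Every downstream module consumes these types only; no other module
touches raw files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("polytereg")

#: Regex with one capturing group extracting the subgenome from a chromosome name.
SUBGENOME_PATTERN = r"([ABD])$"

SUBGENOMES = ("A", "B", "D")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


class RecordValidationError(ValueError):
    """A single record violates an invariant (e.g. summit outside peak)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise RecordValidationError("empty chromosome name")
        if self.start < 0 or self.end <= self.start:
            raise RecordValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise RecordValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def subgenome(self, pattern: str = SUBGENOME_PATTERN) -> str:
        m = re.search(pattern, self.chrom)
        if m is None:
            raise RecordValidationError(
                f"cannot derive subgenome from chromosome {self.chrom!r}"
            )
        return m.group(1)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Peak:
    interval: GenomicInterval
    summit: int
    rpkm: float
    tf_id: str

    def __post_init__(self):
        if not self.interval.start <= self.summit < self.interval.end:
            raise RecordValidationError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.rpkm < 0:
            raise RecordValidationError(f"negative rpkm {self.rpkm}")


@dataclass(frozen=True, slots=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    tss: int
    subgenome: str

    @classmethod
    def from_interval(
        cls, gene_id: str, interval: GenomicInterval,
        subgenome_pattern: str = SUBGENOME_PATTERN,
    ) -> "Gene":
        # TSS: start on '+', end-1 on '-' (half-open convention).
        tss = interval.start if interval.strand != "-" else interval.end - 1
        return cls(gene_id, interval, tss, interval.subgenome(subgenome_pattern))


@dataclass(frozen=True, slots=True)
class Triad:
    triad_id: str
    gene_A: str
    gene_B: str
    gene_D: str

    def gene_of(self, subgenome: str) -> str:
        return {"A": self.gene_A, "B": self.gene_B, "D": self.gene_D}[subgenome]


@dataclass(frozen=True, slots=True)
class TEAnnotation:
    te_id: str
    interval: GenomicInterval
    family: str
    subfamily: str
    full_length: bool
    ltr5: GenomicInterval | None = None
    ltr3: GenomicInterval | None = None
    degenerated: bool = False

    def __post_init__(self):
        if not self.subfamily.startswith(self.family):
            raise RecordValidationError(
                f"subfamily {self.subfamily!r} lacks family prefix {self.family!r}"
            )
        if self.full_length:
            if self.ltr5 is None or self.ltr3 is None:
                raise RecordValidationError(
                    f"full-length TE {self.te_id} missing an LTR"
                )
            for ltr in (self.ltr5, self.ltr3):
                if not (
                    self.interval.start <= ltr.start and ltr.end <= self.interval.end
                ):
                    raise RecordValidationError(
                        f"LTR outside TE body for {self.te_id}"
                    )
            if self.ltr5.overlaps(self.ltr3):
                raise RecordValidationError(f"overlapping LTRs for {self.te_id}")


@dataclass(frozen=True, slots=True)
class AlignmentBlock:
    query: GenomicInterval
    subject: GenomicInterval
    identity: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise RecordValidationError(f"identity {self.identity} not in [0,100]")


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    gene_id: str
    tpm: float

    def __post_init__(self):
        if self.tpm < 0:
            raise RecordValidationError(f"negative TPM for {self.gene_id}")


# ---------------------------------------------------------------------------
# Interval-set arithmetic (shared primitives; per-chromosome, half-open)
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of half-open intervals; >=1 bp overlap merges, bookended do not."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def flatten_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: merge_intervals(v) for c, v in by_chrom.items()}


def total_bp(flat: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for ivs in flat.values() for s, e in ivs)


def intersect_flat(
    a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a) & set(b):
        res, i, j = [], 0, 0
        av, bv = a[chrom], b[chrom]
        while i < len(av) and j < len(bv):
            s = max(av[i][0], bv[j][0])
            e = min(av[i][1], bv[j][1])
            if s < e:
                res.append((s, e))
            if av[i][1] < bv[j][1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = res
    return out


def subtract_flat(
    a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in a.items():
        cuts = b.get(chrom, [])
        res = []
        for s, e in ivs:
            cur = s
            for cs, ce in cuts:
                if ce <= cur or cs >= e:
                    continue
                if cs > cur:
                    res.append((cur, cs))
                cur = max(cur, ce)
                if cur >= e:
                    break
            if cur < e:
                res.append((cur, e))
        if res:
            out[chrom] = res
    return out


def point_in_flat(flat: dict[str, list[tuple[int, int]]], chrom: str, pos: int) -> bool:
    ivs = flat.get(chrom)
    if not ivs:
        return False
    starts = [s for s, _ in ivs]
    i = np.searchsorted(starts, pos, side="right") - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, tf_id: str, signal_column: int = 6) -> list[Peak]:
    """Read a narrowPeak (10-column) or BED6+summit+rpkm (8-column) file.

    narrowPeak: summit = start + column 10 (relative offset; -1 means unknown
    and falls back to the interval midpoint). The normalized density is taken
    from ``signal_column`` (0-based; default the signalValue column), because
    published peak files differ in which column carries the normalized count.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                if len(fields) >= 10:  # narrowPeak
                    rpkm = float(fields[signal_column])
                    rel = int(fields[9])
                    summit = start + rel if rel >= 0 else (start + end) // 2
                elif len(fields) == 8:  # BED6 + absolute summit + rpkm
                    summit = int(fields[6])
                    rpkm = float(fields[7])
                else:
                    raise ValueError(f"expected 8 or 10 columns, got {len(fields)}")
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
                interval = GenomicInterval(chrom, start, end, strand)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                peaks.append(Peak(interval, summit, rpkm, tf_id))
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak, sorted (chrom, start, end)."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        f"{p.tf_id}_peak{i}",
                        "0",
                        p.interval.strand,
                        f"{p.rpkm:.6g}",
                        "-1",
                        "-1",
                        str(p.summit - p.interval.start),
                    ]
                )
                + "\n"
            )


def read_gff_genes(
    path: str | Path, subgenome_pattern: str = SUBGENOME_PATTERN
) -> list[Gene]:
    """Read gene features from GFF3, converting to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: list[Gene] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ParseError(f"{path}: gene feature without ID at {feat.seqid}:{feat.start}")
        gid = feat.attributes["ID"][0]
        if gid in seen:
            raise ParseError(f"{path}: duplicate gene ID {gid!r}")
        seen.add(gid)
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        genes.append(Gene.from_interval(gid, iv, subgenome_pattern))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def write_gff_genes(genes: Sequence[Gene], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in rows:
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        "polytereg",
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.interval.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


TE_COLUMNS = [
    "chrom", "start", "end", "strand", "family", "subfamily", "full_length",
    "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
]


def read_te_table(path: str | Path) -> list[TEAnnotation]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing TE columns {sorted(missing)}")
    tes = []
    for i, row in df.iterrows():
        iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"])
        full = bool(row["full_length"])
        ltr5 = ltr3 = None
        if full:
            ltr5 = GenomicInterval(row["chrom"], int(row["ltr5_start"]), int(row["ltr5_end"]))
            ltr3 = GenomicInterval(row["chrom"], int(row["ltr3_start"]), int(row["ltr3_end"]))
        te_id = f"{row['subfamily']}:{row['chrom']}:{int(row['start'])}"
        tes.append(
            TEAnnotation(te_id, iv, row["family"], row["subfamily"], full, ltr5, ltr3)
        )
    return tes


def write_te_table(tes: Sequence[TEAnnotation], path: str | Path) -> None:
    rows = []
    for t in sorted(tes, key=lambda t: (t.interval.chrom, t.interval.start, t.te_id)):
        rows.append(
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.interval.strand,
                "family": t.family,
                "subfamily": t.subfamily,
                "full_length": int(t.full_length),
                "ltr5_start": t.ltr5.start if t.ltr5 else -1,
                "ltr5_end": t.ltr5.end if t.ltr5 else -1,
                "ltr3_start": t.ltr3.start if t.ltr3 else -1,
                "ltr3_end": t.ltr3.end if t.ltr3 else -1,
            }
        )
    pd.DataFrame(rows, columns=TE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t")
    blocks = []
    for _, row in df.iterrows():
        blocks.append(
            AlignmentBlock(
                GenomicInterval(row["qchrom"], int(row["qstart"]), int(row["qend"])),
                GenomicInterval(row["schrom"], int(row["sstart"]), int(row["send"])),
                float(row["identity"]),
            )
        )
    return blocks


def write_alignment_blocks(blocks: Sequence[AlignmentBlock], path: str | Path) -> None:
    rows = [
        {
            "qchrom": b.query.chrom, "qstart": b.query.start, "qend": b.query.end,
            "schrom": b.subject.chrom, "sstart": b.subject.start, "send": b.subject.end,
            "identity": round(b.identity, 3),
        }
        for b in sorted(
            blocks, key=lambda b: (b.query.chrom, b.query.start, b.subject.chrom, b.subject.start)
        )
    ]
    pd.DataFrame(
        rows, columns=["qchrom", "qstart", "qend", "schrom", "sstart", "send", "identity"]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
                ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except (ValueError, IndexError, RecordValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ivs


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names=None) -> None:
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for i, iv in enumerate(rows):
            name = names[i] if names is not None else f"region{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_triads(path: str | Path) -> list[Triad]:
    df = pd.read_csv(path, sep="\t")
    return [
        Triad(row["triad_id"], row["gene_A"], row["gene_B"], row["gene_D"])
        for _, row in df.iterrows()
    ]


def write_triads(triads: Sequence[Triad], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"triad_id": t.triad_id, "gene_A": t.gene_A, "gene_B": t.gene_B, "gene_D": t.gene_D}
            for t in sorted(triads, key=lambda t: t.triad_id)
        ],
        columns=["triad_id", "gene_A", "gene_B", "gene_D"],
    ).to_csv(path, sep="\t", index=False)


def read_tpm(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    recs = {row["gene_id"]: ExpressionRecord(row["gene_id"], float(row["tpm"])).tpm
            for _, row in df.iterrows()}
    return recs


def write_tpm(tpm: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(tpm.items()), columns=["gene_id", "tpm"]
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a TSV with deterministic column and row order."""
    if sort_by is None:
        sort_by = [c for c in ("chrom", "start", "end") if c in df.columns]
        if not sort_by:
            sort_by = list(df.columns[:1])
    out = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True) if len(df) else df
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
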