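"""Input/output for every external format the pipeline touches.

All records are normalised at the boundary to a single internal coordinate
convention: 0-based, half-open intervals; CpGs are strand-combined units keyed
by the position of the C on the plus strand.  GTF and Bismark-coverage files
(both 1-based, inclusive) are converted on read and converted back on write, so
round trips preserve external coordinates exactly.

The module also provides the small set of interval primitives (merge, subtract,
covered length) that the segmentation and overlap analyses are built on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: RepeatMasker repFamily values mapped onto the transposable-element family
#: vocabulary used throughout the analysis.  Anything else becomes "other".
TE_FAMILY_MAP = {
    "L1": "L1",
    "L2": "L2",
    "B2": "S2",
    "B4": "S4",
    "ERV1": "ERV1",
    "ERVK": "ERVK",
    "ERVL": "ERVL",
    "ERVL-MaLR": "MaLR",
    "MaLR": "MaLR",
}

TE_FAMILIES = ("L1", "L2", "S2", "S4", "ERV1", "ERVK", "ERVL", "MaLR")


class GenomicIOError(ValueError):
    """Raised for malformed or invalid input files."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class CpGRecord(NamedTuple):
    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def meth_pct(self) -> float:
        """Methylation percentage; defined only for covered CpGs."""
        cov = self.coverage
        if cov == 0:
            raise ValueError("methylation undefined at zero coverage")
        return 100.0 * self.n_meth / cov


class MethylomeTable:
    """Per-chromosome sorted CpG methylation counts.

    Internally one ``DataFrame`` per chromosome with columns ``pos``,
    ``n_meth``, ``n_unmeth``; positions strictly increasing, duplicates summed
    at construction.
    """

    def __init__(self, label: str = "") -> None:
        self.label = label
        self._chroms: dict[str, pd.DataFrame] = {}

    @classmethod
    def from_records(
        cls, records: Iterable[CpGRecord], label: str = ""
    ) -> "MethylomeTable":
        table = cls(label)
        rows = [(r.chrom, r.pos, r.n_meth, r.n_unmeth) for r in records]
        if not rows:
            return table
        df = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])
        table._ingest(df)
        return table

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "MethylomeTable":
        table = cls(label)
        if len(df):
            table._ingest(df)
        return table

    def _ingest(self, df: pd.DataFrame) -> None:
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise GenomicIOError("negative read counts in methylation table")
        grouped = (
            df.groupby(["chrom", "pos"], sort=True)[["n_meth", "n_unmeth"]]
            .sum()
            .reset_index()
        )
        for chrom, sub in grouped.groupby("chrom", sort=True):
            sub = sub[["pos", "n_meth", "n_unmeth"]].reset_index(drop=True)
            self._chroms[str(chrom)] = sub.astype(
                {"pos": np.int64, "n_meth": np.int64, "n_unmeth": np.int64}
            )

    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(positions, n_meth, n_unmeth)`` for one chromosome."""
        df = self._chroms.get(chrom)
        if df is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        return (
            df["pos"].to_numpy(),
            df["n_meth"].to_numpy(),
            df["n_unmeth"].to_numpy(),
        )

    def records(self) -> Iterator[CpGRecord]:
        for chrom in self.chroms():
            pos, nm, nu = self.arrays(chrom)
            for p, m, u in zip(pos, nm, nu):
                yield CpGRecord(chrom, int(p), int(m), int(u))

    def n_cpgs(self) -> int:
        return sum(len(df) for df in self._chroms.values())

    def __len__(self) -> int:
        return self.n_cpgs()


@dataclass
class TranscriptModel:
    """An exon-structured transcript; exons are sorted, non-overlapping."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    category: str | None = None
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon in transcript {self.id}")
            if s < prev_end:
                raise ValueError(f"overlapping exons in transcript {self.id}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """First transcribed base: first base on +, last base on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def mono_exonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneModel:
    """Transcripts sharing a gene_id; the span covers all member exons."""

    id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def mono_exonic(self) -> bool:
        return all(t.mono_exonic for t in self.transcripts)

    @property
    def most_upstream_tss(self) -> int:
        """Gene-level TSS: most upstream transcript start in strand terms."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def fpkm(self, stage: str) -> float:
        """Gene expression: sum of member-transcript FPKM at one stage."""
        return float(sum(t.fpkm.get(stage, 0.0) for t in self.transcripts))

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationSet:
    """Transcripts grouped into genes by gene_id."""

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        genes: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            if t.id in self.transcripts:
                raise GenomicIOError(f"duplicate transcript id {t.id}")
            self.transcripts[t.id] = t
            genes.setdefault(t.gene_id, []).append(t)
        self.genes: dict[str, GeneModel] = {}
        for gid, ts in genes.items():
            chroms = {t.chrom for t in ts}
            strands = {t.strand for t in ts}
            if len(chroms) > 1 or len(strands) > 1:
                raise GenomicIOError(
                    f"gene {gid} mixes chromosomes or strands"
                )
            self.genes[gid] = GeneModel(gid, ts[0].chrom, ts[0].strand, ts)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_list(self) -> list[GeneModel]:
        return [self.genes[g] for g in sorted(self.genes)]

    def transcript_list(self) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in sorted(self.transcripts)]

    def subset_transcripts(self, keep: Iterable[str]) -> "AnnotationSet":
        keep = set(keep)
        return AnnotationSet(
            [t for t in self.transcript_list() if t.id in keep]
        )


class FeatureTrack:
    """A typed collection of intervals (CGI, TE, igDMR, contig, mask ...)."""

    COLUMNS = ["chrom", "start", "end", "strand", "name"]

    def __init__(self, kind: str, df: pd.DataFrame | None = None) -> None:
        self.kind = kind
        if df is None or not len(df):
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df.copy()
        for col, default in (("strand", "."), ("name", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS]
        df = df.astype({"start": np.int64, "end": np.int64})
        if (df["end"] <= df["start"]).any():
            raise GenomicIOError(f"empty interval in {kind} track")
        self.df = df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    @classmethod
    def from_intervals(
        cls, kind: str, intervals: Iterable[GenomicInterval],
        names: Sequence[str] | None = None,
    ) -> "FeatureTrack":
        rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        if names is not None:
            df["name"] = list(names)
        return cls(kind, df)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.df.itertuples()
        ]

    def per_chrom(self, strand: str | None = None) -> dict[str, np.ndarray]:
        """``chrom -> (n, 2)`` raw start/end arrays, optionally one strand."""
        df = self.df
        if strand is not None:
            df = df[df["strand"] == strand]
        return {
            str(c): sub[["start", "end"]].to_numpy()
            for c, sub in df.groupby("chrom", sort=True)
        }

    def merged_per_chrom(self, strand: str | None = None) -> dict[str, np.ndarray]:
        """Strand-collapsed (unless given) merged intervals per chromosome."""
        return {
            c: merge_intervals(iv)
            for c, iv in self.per_chrom(strand).items()
        }

    def total_length(self) -> int:
        return int(
            sum(union_length(iv) for iv in self.per_chrom().values())
        )

    def normalized(self) -> "FeatureTrack":
        """Strand-collapsed, merged copy (mask semantics)."""
        rows = []
        for chrom, iv in self.merged_per_chrom().items():
            for s, e in iv:
                rows.append((chrom, int(s), int(e)))
        return FeatureTrack(
            self.kind, pd.DataFrame(rows, columns=["chrom", "start", "end"])
        )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: np.ndarray, bookended: bool = True) -> np.ndarray:
    """Merge a ``(n, 2)`` array into sorted disjoint intervals.

    With ``bookended`` (the default) touching intervals are unioned as well,
    which is the normalisation required of exclusion masks.
    """
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    order = np.lexsort((iv[:, 1], iv[:, 0]))
    iv = iv[order]
    out = [[iv[0, 0], iv[0, 1]]]
    for s, e in iv[1:]:
        if s < out[-1][1] or (bookended and s == out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def union_length(intervals: np.ndarray) -> int:
    merged = merge_intervals(intervals)
    if len(merged) == 0:
        return 0
    return int((merged[:, 1] - merged[:, 0]).sum())


def covered_length(start: int, end: int, merged: np.ndarray) -> int:
    """Base pairs of ``[start, end)`` covered by merged disjoint intervals."""
    if len(merged) == 0 or end <= start:
        return 0
    s = np.minimum(np.maximum(merged[:, 0], start), end)
    e = np.minimum(np.maximum(merged[:, 1], start), end)
    return int(np.maximum(e - s, 0).sum())


def subtract_intervals(start: int, end: int, merged: np.ndarray) -> list[tuple[int, int]]:
    """``[start, end)`` minus merged disjoint intervals, as surviving pieces."""
    pieces: list[tuple[int, int]] = []
    cur = start
    for ms, me in merged:
        if me <= start or ms >= end:
            continue
        if ms > cur:
            pieces.append((cur, min(ms, end)))
        cur = max(cur, me)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


# ---------------------------------------------------------------------------
# CpG methylation tables
# ---------------------------------------------------------------------------

def read_cpg_table(
    path: str | Path, dialect: str = "bismark_cov", label: str | None = None
) -> MethylomeTable:
    """Read a per-CpG methylation call table.

    ``bismark_cov`` rows are ``chrom start end meth% n_meth n_unmeth`` with
    1-based inclusive coordinates; ``bedgraph_counts`` uses the same column
    layout but 0-based half-open coordinates.  Rows for the same position are
    summed.
    """
    if dialect not in ("bismark_cov", "bedgraph_counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    label = label if label is not None else path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise GenomicIOError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise GenomicIOError(f"{path}:{lineno}: negative read count")
            pos = start - 1 if dialect == "bismark_cov" else start
            if pos < 0:
                raise GenomicIOError(f"{path}:{lineno}: position out of range")
            rows.append((chrom, pos, n_meth, n_unmeth))
    if not rows:
        return MethylomeTable(label)
    return MethylomeTable.from_frame(
        pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"]),
        label,
    )


def write_cpg_table(
    table: MethylomeTable, path: str | Path, dialect: str = "bismark_cov"
) -> None:
    """Write a methylome as a Bismark-coverage style table."""
    if dialect not in ("bismark_cov", "bedgraph_counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    offset = 1 if dialect == "bismark_cov" else 0
    with open(path, "w") as fh:
        for rec in table.records():
            cov = rec.coverage
            pct = 100.0 * rec.n_meth / cov if cov else 0.0
            p = rec.pos + offset
            fh.write(
                f"{rec.chrom}\t{p}\t{p}\t{pct:.6g}\t{rec.n_meth}\t{rec.n_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read an exon-structured GTF into an :class:`AnnotationSet`.

    Only ``exon`` rows are used; ``gene_id``/``transcript_id`` attributes are
    required, and an optional ``FPKM`` attribute (optionally suffixed with a
    stage as ``FPKM_<stage>``) populates the transcript expression map.
    """
    path = Path(path)
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomicIOError(
                    f"{path}:{lineno}: expected 9 GTF columns"
                )
            chrom, _, feature, start, end, _, strand, _, attr_field = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attrs(attr_field)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GenomicIOError(
                    f"{path}:{lineno}: missing gene_id/transcript_id"
                )
            tid = attrs["transcript_id"]
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strands": set(),
                    "exons": [],
                    "fpkm": {},
                    "category": attrs.get("class_code"),
                },
            )
            rec["strands"].add(strand)
            rec["exons"].append((int(start) - 1, int(end)))
            for key, value in attrs.items():
                if key == "FPKM":
                    rec["fpkm"]["default"] = float(value)
                elif key.startswith("FPKM_"):
                    rec["fpkm"][key[5:]] = float(value)
    transcripts = []
    for tid, rec in exons.items():
        strands = rec["strands"] - {"."} or {"."}
        if len(strands) > 1:
            raise GenomicIOError(f"transcript {tid} has exons on mixed strands")
        transcripts.append(
            TranscriptModel(
                id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=next(iter(strands)),
                exons=rec["exons"],
                category=rec["category"],
                fpkm=rec["fpkm"],
            )
        )
    return AnnotationSet(transcripts)


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Write exon rows (1-based inclusive); inverse of :func:`read_gtf`."""
    with open(path, "w") as fh:
        for t in annotation.transcript_list():
            attr_extra = ""
            if t.category:
                attr_extra += f' class_code "{t.category}";'
            for stage in sorted(t.fpkm):
                key = "FPKM" if stage == "default" else f"FPKM_{stage}"
                attr_extra += f' {key} "{t.fpkm[stage]!r}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tmethdomain\texon\t{s + 1}\t{e}\t.\t{t.strand}\t."
                    f'\tgene_id "{t.gene_id}"; transcript_id "{t.id}";'
                    f"{attr_extra}\n"
                )


# ---------------------------------------------------------------------------
# BED and feature tracks
# ---------------------------------------------------------------------------

def read_feature_bed(path: str | Path, kind: str) -> FeatureTrack:
    """Read a BED3/BED6 file (0-based half-open) as a feature track.

    Unsorted input is sorted on load.  Column 4 is kept as the interval name
    (TE family for TE tracks, igDMR name for igDMR tracks).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise GenomicIOError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, strand, name))
    df = pd.DataFrame(rows, columns=FeatureTrack.COLUMNS)
    return FeatureTrack(kind, df)


def write_feature_bed(track: FeatureTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in track.df.itertuples():
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n"
            )


def read_repeatmasker(path: str | Path) -> FeatureTrack:
    """Read a RepeatMasker-derived TSV into a TE track.

    Expected tab-separated columns (UCSC rmsk naming): ``genoName genoStart
    genoEnd strand repName repClass repFamily``; a header row is allowed.
    ``repFamily`` is mapped onto the fixed family vocabulary; unknown families
    pass through labelled ``other``.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "genoName":
                continue
            if len(fields) < 7:
                raise GenomicIOError(f"{path}:{lineno}: expected 7 columns")
            chrom, start, end, strand = (
                fields[0], int(fields[1]), int(fields[2]), fields[3],
            )
            family = TE_FAMILY_MAP.get(fields[6], "other")
            rows.append((chrom, start, end, strand, family))
    df = pd.DataFrame(rows, columns=FeatureTrack.COLUMNS)
    return FeatureTrack("TE", df)


# ---------------------------------------------------------------------------
# Domain output
# ---------------------------------------------------------------------------

def write_domains(domains, path: str | Path, stats: pd.DataFrame | None = None) -> None:
    """Write a DomainSet as BED6 plus a TSV sidecar with per-domain stats.

    ``path`` names the BED file; the sidecar is ``<path>.stats.tsv``.  The BED
    name column is ``<id>|<parent_id>|<class>``, which makes the BED alone
    sufficient to reconstruct the domain set (:func:`read_domains`).
    """
    path = Path(path)
    with open(path, "w") as fh:
        for d in domains:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.id}|{d.parent_id}|{d.cls}\t0\t.\n"
            )
    sidecar = path.with_name(path.name + ".stats.tsv")
    if stats is not None:
        stats.to_csv(sidecar, sep="\t", index=False)
    else:
        base = pd.DataFrame(
            [
                {
                    "id": d.id,
                    "parent_id": d.parent_id,
                    "class": d.cls,
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "length": d.length,
                }
                for d in domains
            ]
        )
        base.to_csv(sidecar, sep="\t", index=False)


def read_domains(path: str | Path):
    """Read a BED written by :func:`write_domains` back into a DomainSet."""
    from .domain_caller import Domain, DomainSet  # cycle kept import-local

    domains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4 or fields[3].count("|") != 2:
                raise GenomicIOError(f"{path}:{lineno}: not a domain BED row")
            did, parent, cls = fields[3].split("|")
            domains.append(
                Domain(
                    id=did,
                    parent_id=parent,
                    cls=cls,
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                )
            )
    return DomainSet(domains)


# ---------------------------------------------------------------------------
# Plain per-chromosome sequences (GC/CpG-density contract)
# ---------------------------------------------------------------------------

def read_genome_seq(path: str | Path) -> dict[str, str]:
    """Read a minimal FASTA-like per-chromosome sequence file."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = []
            else:
                if current is None:
                    raise GenomicIOError(f"{path}: sequence before header")
                seqs[current].append(line.upper())
    return {c: "".join(parts) for c, parts in seqs.items()}


def write_genome_seq(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            seq = seqs[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
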