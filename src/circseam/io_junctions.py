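"""Parsers and writers for the external formats used by the pipeline.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
on the forward genomic axis.  CIRI2 tables and GTF annotation (both 1-based
inclusive) are converted exactly once, at parse time; records never carry
1-based values.  The human-readable ``circ_id`` string keeps the external
(1-based) start so ids match CIRI2-style naming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


def make_circ_id(chrom: str, start: int, end: int, strand: str) -> str:
    """Coordinate-derived circRNA identifier, ``chrom:start-end:strand``.

    ``start``/``end`` are internal (0-based half-open); the printed start is
    external 1-based so the id matches detector output.
    """
    return f"{chrom}:{start + 1}-{end}:{strand}"


def parse_circ_id(circ_id: str) -> tuple[str, int, int, str]:
    """Invert :func:`make_circ_id`; returns internal coordinates."""
    chrom, span, strand = circ_id.rsplit(":", 2)
    lo, hi = span.split("-")
    return chrom, int(lo) - 1, int(hi), strand


@dataclass(frozen=True)
class BsjRecord:
    """One back-splicing junction observed in one sample.

    ``bsj_reads`` counts reads spanning the back-splicing junction;
    ``linear_reads`` is the sum of reads mapping linearly over both splice
    junctions engaged by the back-splice.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str | None
    bsj_reads: int
    linear_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for BSJ on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.bsj_reads < 0 or self.linear_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def circ_id(self) -> str:
        return make_circ_id(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Exon:
    start: int
    end: int
    number: int  # 1..n in transcript 5'->3' order


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[Exon] = field(default_factory=list)  # transcript 5'->3' order
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str


@dataclass
class AnnotationModel:
    """Genes, transcripts and their exon/CDS/UTR structure."""

    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


@dataclass(frozen=True)
class Peak:
    """narrowPeak interval with an absolute summit coordinate."""

    chrom: str
    start: int
    end: int
    summit: int
    signal: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# CIRI2-style BSJ tables


_CIRI2_ALIASES = {
    "chrom": ("chr", "chrom", "chromosome"),
    "start": ("circrna_start", "start"),
    "end": ("circrna_end", "end"),
    "bsj": ("#junction_reads", "junction_reads", "bsj_reads"),
    "linear": ("#non_junction_reads", "non_junction_reads", "linear_reads"),
    "strand": ("strand",),
    "gene": ("gene_id", "gene"),
}


def _ciri2_columns(header: Sequence[str]) -> dict[str, int]:
    low = [h.strip().lower() for h in header]
    cols: dict[str, int] = {}
    for key, names in _CIRI2_ALIASES.items():
        for name in names:
            if name in low:
                cols[key] = low.index(name)
                break
    missing = [k for k in ("chrom", "start", "end", "bsj", "linear", "strand") if k not in cols]
    if missing:
        raise ValueError(f"CIRI2 header is missing required columns: {missing}")
    return cols


def parse_ciri2(path: str | Path, sample_id: str) -> list[BsjRecord]:
    """Parse a CIRI2 result table (tab-separated, 1-based inclusive coordinates).

    Junction and non-junction read columns map to ``bsj_reads`` and
    ``linear_reads``; the non-junction count is taken as already summed over
    both splice junctions.  Duplicate BSJs within one sample are rejected.
    """
    records: list[BsjRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = _ciri2_columns(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                chrom = parts[cols["chrom"]]
                start1 = int(parts[cols["start"]])
                end1 = int(parts[cols["end"]])
                bsj = int(parts[cols["bsj"]])
                lin = int(parts[cols["linear"]])
                strand = parts[cols["strand"]].strip()
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            if strand not in STRANDS:
                raise ValueError(
                    f"{path}: unknown strand symbol {strand!r} at line {lineno}"
                )
            gene = None
            if "gene" in cols and cols["gene"] < len(parts):
                gene = parts[cols["gene"]].strip().rstrip(",") or None
                if gene and "," in gene:
                    first = gene.split(",")[0]
                    log.warning(
                        "%s line %d: multiple gene ids %r, keeping %r",
                        path, lineno, gene, first,
                    )
                    gene = first
            try:
                rec = BsjRecord(
                    chrom=chrom,
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                    gene_id=gene,
                    bsj_reads=bsj,
                    linear_reads=lin,
                    sample_id=sample_id,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            if rec.circ_id in seen:
                raise ValueError(
                    f"{path}: duplicate BSJ in sample at line {lineno}: {rec.circ_id}"
                )
            seen.add(rec.circ_id)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# GTF annotation


def _attr(feature: gffutils.Feature, *names: str, default: str | None = None) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return default


def parse_gtf(path: str | Path) -> AnnotationModel:
    """Parse an Ensembl-dialect GTF into an :class:`AnnotationModel`.

    Uses gffutils for attribute/dialect handling.  ``exon_number`` attributes
    are honoured when present, otherwise numbering is derived by strand-aware
    sorting.  1-based inclusive GTF intervals become 0-based half-open.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    model = AnnotationModel()
    raw_exons: dict[str, list[tuple[int, int, int | None]]] = {}

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype == "gene":
            gid = _attr(feat, "gene_id")
            if gid is None:
                raise ValueError(f"gene feature without gene_id at {feat.seqid}:{feat.start}")
            model.genes[gid] = Gene(
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                biotype=_attr(feat, "gene_biotype", "gene_type", default="protein_coding"),
            )
        elif ftype == "transcript":
            tid = _attr(feat, "transcript_id")
            gid = _attr(feat, "gene_id")
            if tid is None or gid is None:
                raise ValueError("transcript feature without transcript_id/gene_id")
            model.transcripts[tid] = Transcript(
                transcript_id=tid,
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                biotype=_attr(
                    feat, "transcript_biotype", "transcript_type", default="protein_coding"
                ),
            )
        elif ftype in ("exon", "cds", "five_prime_utr", "three_prime_utr", "utr"):
            tid = _attr(feat, "transcript_id")
            if tid is None:
                raise ValueError(
                    f"{feat.featuretype} without transcript parent at "
                    f"{feat.seqid}:{feat.start}-{feat.end}"
                )
            iv = (feat.start - 1, feat.end)  # to 0-based half-open
            if ftype == "exon":
                num = _attr(feat, "exon_number")
                raw_exons.setdefault(tid, []).append(
                    (iv[0], iv[1], int(num) if num is not None else None)
                )
            else:
                if tid not in model.transcripts:
                    raise ValueError(f"{feat.featuretype} for unknown transcript {tid}")
                tr = model.transcripts[tid]
                if ftype == "cds":
                    tr.cds.append(iv)
                elif ftype == "five_prime_utr":
                    tr.utr5.append(iv)
                elif ftype == "three_prime_utr":
                    tr.utr3.append(iv)

    for tid, exons in raw_exons.items():
        if tid not in model.transcripts:
            raise ValueError(f"exon without transcript parent: {tid}")
        tr = model.transcripts[tid]
        if all(num is not None for _, _, num in exons):
            ordered = sorted(exons, key=lambda t: t[2])
        else:
            # strand-aware 5'->3' order
            ordered = sorted(exons, key=lambda t: t[0], reverse=(tr.strand == "-"))
            ordered = [(s, e, i + 1) for i, (s, e, _) in enumerate(ordered)]
        tr.exons = [Exon(s, e, int(num)) for s, e, num in ordered]
        for a, b in zip(tr.exons, tr.exons[1:]):
            if max(a.start, b.start) < min(a.end, b.end):
                raise ValueError(f"overlapping exons in transcript {tid}")
        tr.cds.sort()
        tr.utr5.sort()
        tr.utr3.sort()
    return model


# ---------------------------------------------------------------------------
# narrowPeak


def parse_narrowpeak(path: str | Path, sample_id: str) -> list[Peak]:
    """Parse an ENCODE narrowPeak (BED6+4) file.

    The absolute summit is ``start + offset`` (10th column); a ``-1`` offset
    falls back to the interval midpoint.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ValueError(
                    f"{path}: narrowPeak needs 10 columns, got {len(parts)} at line {lineno}"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise ValueError(f"{path}: negative start at line {lineno}")
            signal = float(parts[6])
            offset = int(parts[9])
            summit = start + offset if offset >= 0 else (start + end) // 2
            peaks.append(
                Peak(
                    chrom=chrom, start=start, end=end,
                    summit=summit, signal=signal, sample_id=sample_id,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path, name_prefix: str = "peak") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            fh.write(
                "\t".join(
                    [
                        p.chrom, str(p.start), str(p.end), f"{name_prefix}_{i}", "0", ".",
                        f"{p.signal:g}", "-1", "-1", str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Documented internal TSV dialect for BSJ records (round-trip safe)

_BSJ_TSV_HEADER = [
    "circ_id", "chrom", "start", "end", "strand",
    "gene_id", "bsj_reads", "linear_reads", "sample_id",
]


def write_bsj_tsv(records: Iterable[BsjRecord], path: str | Path) -> None:
    """Write records in the internal dialect (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_BSJ_TSV_HEADER) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.circ_id, r.chrom, str(r.start), str(r.end), r.strand,
                        r.gene_id or ".", str(r.bsj_reads), str(r.linear_reads),
                        r.sample_id,
                    ]
                )
                + "\n"
            )


def read_bsj_tsv(path: str | Path) -> list[BsjRecord]:
    """Re-read the internal dialect written by :func:`write_bsj_tsv`."""
    out: list[BsjRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _BSJ_TSV_HEADER:
            raise ValueError(f"{path}: not an internal BSJ table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) != len(_BSJ_TSV_HEADER):
                raise ValueError(f"{path}: malformed row at line {lineno}")
            out.append(
                BsjRecord(
                    chrom=p[1], start=int(p[2]), end=int(p[3]), strand=p[4],
                    gene_id=None if p[5] == "." else p[5],
                    bsj_reads=int(p[6]), linear_reads=int(p[7]), sample_id=p[8],
                )
            )
    return out
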