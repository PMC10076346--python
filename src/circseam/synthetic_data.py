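"""Seeded synthetic genome / annotation / junction-count / peak generator.

The generator emulates the statistical structure the pipeline is built for:

* a toy genome with multi-exonic genes (UTR/CDS annotation, mixed biotypes)
  hosting one circRNA each, with BSJ boundaries on exon junctions;
* negative-binomially distributed back-splicing and linear junction counts in
  a two-condition design, with per-circRNA planted concordance categories
  (fold change on the circular isoform, the linear one, both, or neither);
* RIP-style narrowPeak replicates whose peaks are either uniform over the
  genome or planted near the BSJ 5' extremity of a designated target set, with
  GC-rich summit motifs written into the genome sequence.

Every emitted file derives from its own pseudo-random stream (master seed +
fixed label), so regenerating one output never shifts the others; a (seed,
config) pair gives byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_junctions import (
    AnnotationModel,
    BsjRecord,
    Exon,
    Gene,
    Peak,
    Transcript,
    make_circ_id,
    write_narrowpeak,
)

CATEGORY_NAMES = ("Concordant", "DiscordantCirc", "DiscordantLin", "Unaltered")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a knock-down-like contrast: 3 vs 3 samples, NB counts
    with dispersion 0.1 around a circular baseline mean of 100 (linear 400),
    planted |log2FC| = 2 on deregulated isoforms, and binding peaks planted
    near the BSJ 5' extremity of the downregulated-discordant circRNAs.
    """

    n_genes: int = 60
    n_circ: int = 60
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (150, 300)
    intron_len: tuple[int, int] = (400, 900)
    intergenic: int = 3000
    n_chroms: int = 2
    genome_gc: float = 0.45
    lnc_fraction: float = 0.2

    samples_per_group: int = 3
    group_names: tuple[str, str] = ("ctrl", "kd")
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Concordant": 0.04,
            "DiscordantCirc": 0.10,
            "DiscordantLin": 0.06,
            "Unaltered": 0.80,
        }
    )
    circ_log2fc: float = -2.0
    lin_log2fc: float = -2.0
    opposite_linear: bool = False  # DiscordantCirc linear moves opposite instead of flat
    circ_mean: float = 100.0
    lin_mean: float = 400.0
    dispersion: float = 0.1
    dropout_fraction: float = 0.15

    peak_rule: str = "near_bsj"  # or "uniform"
    peak_max_distance: int = 50
    peak_width: tuple[int, int] = (50, 100)
    n_peak_replicates: int = 3
    n_background_peaks: int = 10
    n_uniform_peaks: int = 120
    summit_motif_gc: float = 0.9
    summit_motif_len: int = 30

    def __post_init__(self) -> None:
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.circ_mean <= 0 or self.lin_mean <= 0:
            raise ValueError("means must be positive")
        if self.n_circ > self.n_genes:
            raise ValueError("n_circ cannot exceed n_genes")


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


@dataclass(frozen=True)
class CircDef:
    circ_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    first_exon_number: int

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class SyntheticAnnotation:
    genome: dict[str, bytearray]
    ann: AnnotationModel
    gtf_text: str
    circs: list[CircDef]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def genome_strings(self) -> dict[str, str]:
        return {c: s.decode() for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# Genome + annotation


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> bytearray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bytearray(rng.choice([65, 67, 71, 84], size=n, p=probs).astype(np.uint8).tobytes())


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def gen_genome_annotation(cfg: ScenarioConfig, seed: int) -> SyntheticAnnotation:
    """Toy genome + GTF + circRNA definitions, deterministic given the seed."""
    layout_rng = _rng(seed, "annotation")
    circ_rng = _rng(seed, "circdefs")

    ann = AnnotationModel()
    gtf_lines: list[str] = []
    circs: list[CircDef] = []
    chrom_cursor = {f"chrS{i + 1}": 0 for i in range(cfg.n_chroms)}
    chrom_names = list(chrom_cursor)

    for g_idx in range(cfg.n_genes):
        chrom = chrom_names[g_idx % cfg.n_chroms]
        gid = f"G{g_idx:03d}"
        tid = f"T{g_idx:03d}"
        strand = "+" if layout_rng.random() < 0.5 else "-"
        biotype = "lncRNA" if layout_rng.random() < cfg.lnc_fraction else "protein_coding"
        n_ex = int(layout_rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        cursor = chrom_cursor[chrom] + cfg.intergenic
        exon_iv: list[tuple[int, int]] = []
        for e in range(n_ex):
            ln = int(layout_rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
            exon_iv.append((cursor, cursor + ln))
            cursor += ln
            if e < n_ex - 1:
                cursor += int(layout_rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        chrom_cursor[chrom] = cursor

        # transcript 5'->3' exon order
        ordered = exon_iv if strand == "+" else exon_iv[::-1]
        exons = [Exon(s, e, i + 1) for i, (s, e) in enumerate(ordered)]

        cds: list[tuple[int, int]] = []
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        if biotype == "protein_coding":
            if n_ex == 1:
                s, e = ordered[0]
                ln = e - s
                if strand == "+":
                    utr5, cds, utr3 = [(s, s + ln // 4)], [(s + ln // 4, e - ln // 4)], [(e - ln // 4, e)]
                else:
                    utr3, cds, utr5 = [(s, s + ln // 4)], [(s + ln // 4, e - ln // 4)], [(e - ln // 4, e)]
            else:
                first, last = ordered[0], ordered[-1]
                mid1 = (first[0] + first[1]) // 2
                midl = (last[0] + last[1]) // 2
                if strand == "+":
                    utr5 = [(first[0], mid1)]
                    cds = [(mid1, first[1])] + list(ordered[1:-1]) + [(last[0], midl)]
                    utr3 = [(midl, last[1])]
                else:
                    utr5 = [(mid1, first[1])]
                    cds = [(first[0], mid1)] + list(ordered[1:-1])[::-1] + [(midl, last[1])]
                    utr3 = [(last[0], midl)]
                cds = sorted(cds)

        ann.genes[gid] = Gene(gene_id=gid, chrom=chrom, strand=strand, biotype=biotype)
        tr = Transcript(
            transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            biotype=biotype, exons=exons,
            cds=sorted(cds), utr5=sorted(utr5), utr3=sorted(utr3),
        )
        ann.transcripts[tid] = tr

        g_start, g_end = exon_iv[0][0], exon_iv[-1][1]
        base = {"gene_id": gid, "gene_biotype": biotype}
        tbase = dict(base, transcript_id=tid, transcript_biotype=biotype)
        gtf_lines.append(
            f"{chrom}\tcircseam\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            + _gtf_attrs(**base)
        )
        gtf_lines.append(
            f"{chrom}\tcircseam\ttranscript\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            + _gtf_attrs(**tbase)
        )
        for ex in exons:
            gtf_lines.append(
                f"{chrom}\tcircseam\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\t"
                + _gtf_attrs(**tbase, exon_number=str(ex.number))
            )
        for ftype, ivs in (("CDS", cds), ("five_prime_utr", utr5), ("three_prime_utr", utr3)):
            for s, e in ivs:
                gtf_lines.append(
                    f"{chrom}\tcircseam\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    + _gtf_attrs(**tbase)
                )

        if g_idx < cfg.n_circ:
            k = int(circ_rng.choice([1, 2, 3, 4], p=[0.15, 0.35, 0.3, 0.2]))
            k = min(k, n_ex)
            a = int(circ_rng.integers(1, n_ex - k + 2))  # first exon number included
            span_exons = [e for e in exons if a <= e.number <= a + k - 1]
            c_start = min(e.start for e in span_exons)
            c_end = max(e.end for e in span_exons)
            circs.append(
                CircDef(
                    circ_id=make_circ_id(chrom, c_start, c_end, strand),
                    gene_id=gid, chrom=chrom, start=c_start, end=c_end,
                    strand=strand, exon_count=k, first_exon_number=a,
                )
            )

    genome_rng = _rng(seed, "genome")
    genome = {
        chrom: _random_seq(genome_rng, chrom_cursor[chrom] + cfg.intergenic, cfg.genome_gc)
        for chrom in chrom_names
    }
    return SyntheticAnnotation(
        genome=genome, ann=ann, gtf_text="\n".join(gtf_lines) + "\n", circs=circs
    )


# ---------------------------------------------------------------------------
# Counts with planted truth


def _planted_lfc(cfg: ScenarioConfig, category: str) -> tuple[float, float]:
    if category == "Concordant":
        return cfg.circ_log2fc, cfg.lin_log2fc
    if category == "DiscordantCirc":
        return cfg.circ_log2fc, (-cfg.lin_log2fc if cfg.opposite_linear else 0.0)
    if category == "DiscordantLin":
        return 0.0, cfg.lin_log2fc
    return 0.0, 0.0


def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size: int) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def sample_names(cfg: ScenarioConfig) -> list[str]:
    return [
        f"{grp}_{i + 1}"
        for grp in cfg.group_names
        for i in range(cfg.samples_per_group)
    ]


def sample_groups(cfg: ScenarioConfig) -> dict[str, str]:
    return {s: s.rsplit("_", 1)[0] for s in sample_names(cfg)}


def gen_counts(
    cfg: ScenarioConfig, bundle: SyntheticAnnotation, seed: int
) -> tuple[dict[str, list[BsjRecord]], pd.DataFrame]:
    """Per-sample BSJ records plus the planted-truth table.

    The second group's NB means are scaled by the planted log2 fold changes.
    A ``dropout_fraction`` of circRNAs is detected in only one group: half of
    those still report linear-junction reads in the undetected samples (the
    completion path), half are absent entirely.
    """
    truth_rng = _rng(seed, "truth")
    circs = bundle.circs
    n = len(circs)

    cats: list[str] = []
    for name in CATEGORY_NAMES:
        cats += [name] * int(round(cfg.category_fractions.get(name, 0.0) * n))
    while len(cats) < n:
        cats.append("Unaltered")
    cats = cats[:n]
    perm = truth_rng.permutation(n)
    categories = [cats[perm[i]] for i in range(n)]

    dropout_flags = truth_rng.random(n) < cfg.dropout_fraction
    dropout_group = truth_rng.integers(0, 2, size=n)  # group lacking detection
    dropout_linear = truth_rng.random(n) < 0.5  # linear reads still reported

    rows = []
    for c, cat, drop in zip(circs, categories, dropout_flags):
        clfc, llfc = _planted_lfc(cfg, cat)
        rows.append(
            {
                "circ_id": c.circ_id, "gene_id": c.gene_id, "chrom": c.chrom,
                "start": c.start, "end": c.end, "strand": c.strand,
                "exon_count": c.exon_count, "category": cat,
                "circ_log2fc": clfc, "lin_log2fc": llfc,
                "dropout": bool(drop),
                "target": cat == "DiscordantCirc" and clfc < 0,
                "five_prime_pos": c.five_prime_pos,
            }
        )
    truth = pd.DataFrame(rows).set_index("circ_id")

    tables: dict[str, list[BsjRecord]] = {}
    for s_idx, sid in enumerate(sample_names(cfg)):
        rng = _rng(seed, f"counts:{sid}")
        grp = 0 if s_idx < cfg.samples_per_group else 1
        recs: list[BsjRecord] = []
        for i, c in enumerate(circs):
            clfc, llfc = _planted_lfc(cfg, categories[i])
            c_mean = cfg.circ_mean * (2.0 ** clfc if grp == 1 else 1.0)
            l_mean = cfg.lin_mean * (2.0 ** llfc if grp == 1 else 1.0)
            bsj = int(_nb_draw(rng, c_mean, cfg.dispersion, 1)[0])
            lin = int(_nb_draw(rng, l_mean, cfg.dispersion, 1)[0])
            if dropout_flags[i] and grp == dropout_group[i]:
                if dropout_linear[i]:
                    bsj = 0  # linear-only row: the rerun-completed table
                else:
                    continue  # absent from this sample entirely
            recs.append(
                BsjRecord(
                    chrom=c.chrom, start=c.start, end=c.end, strand=c.strand,
                    gene_id=c.gene_id, bsj_reads=bsj, linear_reads=lin,
                    sample_id=sid,
                )
            )
        tables[sid] = recs
    return tables, truth


# ---------------------------------------------------------------------------
# Peaks


def gen_peaks(
    cfg: ScenarioConfig,
    bundle: SyntheticAnnotation,
    truth: pd.DataFrame,
    seed: int,
    plant_motifs: bool = True,
) -> dict[str, list[Peak]]:
    """narrowPeak replicates under the configured placement rule.

    ``near_bsj`` guarantees each target circRNA a peak covering its 5'
    extremity in at least two of the replicates (summit within
    ``peak_max_distance``); ``uniform`` scatters peaks anywhere.  GC-rich
    summit motifs are written into the genome sequence in place.
    """
    reps = [f"rep{i + 1}" for i in range(cfg.n_peak_replicates)]
    peaks: dict[str, list[Peak]] = {r: [] for r in reps}
    sizes = bundle.chrom_sizes

    if cfg.peak_rule == "near_bsj":
        rng = _rng(seed, "peaks:near_bsj")
        targets = truth[truth["target"]]
        for cid, row in targets.iterrows():
            n_reps = int(rng.integers(2, cfg.n_peak_replicates + 1))
            chosen = sorted(rng.choice(len(reps), size=n_reps, replace=False))
            pos = int(row["five_prime_pos"])
            for r_idx in chosen:
                delta = int(rng.integers(-cfg.peak_max_distance, cfg.peak_max_distance + 1))
                summit = pos + delta
                w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
                start = summit - w // 2
                end = summit + (w - w // 2)
                start = min(start, pos - 5)  # always cover the extremity
                end = max(end, pos + 5)
                start = max(start, 0)
                end = min(end, sizes[row["chrom"]])
                peaks[reps[r_idx]].append(
                    Peak(chrom=row["chrom"], start=start, end=end,
                         summit=min(max(summit, start), end - 1),
                         signal=float(rng.uniform(5, 50)), sample_id=reps[r_idx])
                )
        bg_rng = _rng(seed, "peaks:background")
        for rep in reps:
            for _ in range(cfg.n_background_peaks):
                chrom = list(sizes)[int(bg_rng.integers(0, len(sizes)))]
                w = int(bg_rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
                start = int(bg_rng.integers(0, sizes[chrom] - w))
                peaks[rep].append(
                    Peak(chrom=chrom, start=start, end=start + w,
                         summit=start + w // 2,
                         signal=float(bg_rng.uniform(5, 50)), sample_id=rep)
                )
    elif cfg.peak_rule == "uniform":
        for rep in reps:
            rng = _rng(seed, f"peaks:{rep}")
            for _ in range(cfg.n_uniform_peaks):
                chrom = list(sizes)[int(rng.integers(0, len(sizes)))]
                w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
                start = int(rng.integers(0, sizes[chrom] - w))
                peaks[rep].append(
                    Peak(chrom=chrom, start=start, end=start + w,
                         summit=start + w // 2,
                         signal=float(rng.uniform(5, 50)), sample_id=rep)
                )
    else:
        raise ValueError(f"unknown peak rule {cfg.peak_rule!r}")

    if plant_motifs:
        motif_rng = _rng(seed, "motif")
        half = cfg.summit_motif_len // 2
        for rep in reps:
            for p in peaks[rep]:
                lo = max(0, p.summit - half)
                hi = min(sizes[p.chrom], p.summit + (cfg.summit_motif_len - half))
                motif = _random_seq(motif_rng, hi - lo, cfg.summit_motif_gc)
                bundle.genome[p.chrom][lo:hi] = motif
    return peaks


# ---------------------------------------------------------------------------
# Orchestration and file output


@dataclass
class SyntheticDataset:
    cfg: ScenarioConfig
    seed: int
    bundle: SyntheticAnnotation
    tables: dict[str, list[BsjRecord]]
    truth: pd.DataFrame
    peaks: dict[str, list[Peak]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.bundle.genome_strings(), outdir / "genome.fa")
        (outdir / "annotation.gtf").write_text(self.bundle.gtf_text)
        for sid, recs in self.tables.items():
            write_ciri2(recs, outdir / f"ciri2_{sid}.tsv")
        for rep, ps in self.peaks.items():
            write_narrowpeak(ps, outdir / f"peaks_{rep}.narrowPeak", name_prefix=rep)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t")


def simulate(cfg: ScenarioConfig, seed: int) -> SyntheticDataset:
    """Full scenario: genome, annotation, counts with truth, peaks, motifs."""
    bundle = gen_genome_annotation(cfg, seed)
    tables, truth = gen_counts(cfg, bundle, seed)
    peaks = gen_peaks(cfg, bundle, truth, seed)
    interactor = {}
    from .bsj_binding import interactor_call  # local import to avoid a cycle

    for cid, row in truth.iterrows():
        rec = BsjRecord(
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            strand=row["strand"], gene_id=row["gene_id"],
            bsj_reads=0, linear_reads=0, sample_id="truth",
        )
        interactor[cid] = interactor_call(rec, peaks)
    truth = truth.assign(interactor=pd.Series(interactor))
    return SyntheticDataset(
        cfg=cfg, seed=seed, bundle=bundle, tables=tables, truth=truth, peaks=peaks
    )


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_CIRI2_HEADER = [
    "circRNA_ID", "chr", "circRNA_start", "circRNA_end",
    "#junction_reads", "#non_junction_reads", "gene_id", "strand",
]


def write_ciri2(records: list[BsjRecord], path: str | Path) -> None:
    """Emit a CIRI2-style table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CIRI2_HEADER) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.circ_id, r.chrom, str(r.start + 1), str(r.end),
                        str(r.bsj_reads), str(r.linear_reads),
                        r.gene_id or "n/a", r.strand,
                    ]
                )
                + "\n"
            )
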