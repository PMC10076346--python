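"""Shared fixtures: hand-built annotation models and a small simulated scenario."""

from __future__ import annotations

import pytest

from circseam.io_junctions import AnnotationModel, BsjRecord, Exon, Gene, Transcript
from circseam import synthetic_data as sd


def make_transcript(
    tid: str,
    gene_id: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    biotype: str = "protein_coding",
    cds: list[tuple[int, int]] | None = None,
    utr5: list[tuple[int, int]] | None = None,
    utr3: list[tuple[int, int]] | None = None,
) -> Transcript:
    """Exon intervals given left-to-right genomically; numbering is strand-aware."""
    ordered = exons if strand == "+" else exons[::-1]
    return Transcript(
        transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
        biotype=biotype,
        exons=[Exon(s, e, i + 1) for i, (s, e) in enumerate(ordered)],
        cds=sorted(cds or []), utr5=sorted(utr5 or []), utr3=sorted(utr3 or []),
    )


def make_annotation(*transcripts: Transcript, gene_biotypes: dict[str, str] | None = None) -> AnnotationModel:
    ann = AnnotationModel()
    for t in transcripts:
        if t.gene_id not in ann.genes:
            biotype = (gene_biotypes or {}).get(t.gene_id, "protein_coding")
            ann.genes[t.gene_id] = Gene(
                gene_id=t.gene_id, chrom=t.chrom, strand=t.strand, biotype=biotype
            )
        ann.transcripts[t.transcript_id] = t
    return ann


def bsj(chrom="chr1", start=1000, end=2000, strand="+", gene_id="G1",
        bsj_reads=5, linear_reads=10, sample_id="s1") -> BsjRecord:
    return BsjRecord(chrom=chrom, start=start, end=end, strand=strand,
                     gene_id=gene_id, bsj_reads=bsj_reads,
                     linear_reads=linear_reads, sample_id=sample_id)


def distance_to_planted_extremity(sig_bins, down_models):
    """Per significant bin: can its window lie near the planted 5' extremity?

    Returns (near, far) boolean lists: ``near`` marks bins whose 100-nt window
    intersects +/-100 nt of the 5' extremity for at least one target circRNA
    (three_prime_ss bins of short circRNAs legitimately reach it at offset
    ~ -span); ``far`` marks bins lying fully beyond +/-500 nt of the 5'
    extremity for every target circRNA.
    """
    spans = sorted({m.end - m.start for m in down_models})
    near, far = [], []
    for _, r in sig_bins.iterrows():
        if r.extremity == "five_prime_ss":
            ivs = [(r.offset, r.offset + 100)]
        else:
            ivs = [(r.offset + L, r.offset + L + 100) for L in spans]
        near.append(any(lo <= 100 and hi >= -100 for lo, hi in ivs))
        far.append(all(lo > 500 or hi < -500 for lo, hi in ivs))
    return near, far


@pytest.fixture(scope="session")
def scenario():
    """One default near-BSJ scenario shared across tests (seed 11)."""
    return sd.simulate(sd.ScenarioConfig(), seed=11)


@pytest.fixture(scope="session")
def scenario_models(scenario):
    """Representative transcripts for every simulated circRNA."""
    from circseam.bsj_binding import representative_transcript

    models = {}
    for cid, row in scenario.truth.iterrows():
        rec = BsjRecord(
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            strand=row["strand"], gene_id=row["gene_id"],
            bsj_reads=1, linear_reads=1, sample_id="x",
        )
        models[cid] = representative_transcript(rec, scenario.bundle.ann)
    return models
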