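"""Meta-BSJ binding enrichment around back-splicing junction splice sites.

For every circRNA in a target set (e.g. the high-confidence downregulated
species in a knock-down) a representative host transcript is chosen, exons
and introns within the circularized span are labelled, and 100-nt windows
slide in 10-nt steps over +/-1000 nt of each extremity of the BSJ.  Each
target window is paired with property-matched control windows drawn from
invariant circRNAs at the same relative position, and peak containment is
compared target-vs-control with two-tailed Fisher exact tests, per RIP
replicate.

Orientation convention: the ``five_prime_ss`` extremity is the transcript-5'
boundary of the circularized span (genomic start on ``+``, genomic end on
``-``); window offsets are strand-relative, negative meaning upstream in
transcript orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io_junctions import AnnotationModel, BsjRecord, Peak, Transcript
from .structure_profile import merge_longest

log = logging.getLogger(__name__)

REGION_TAGS = ("Ex_A", "Intr_A", "Ex_M", "Intr_M", "Intr_Z", "Ex_Z")
EXTREMITIES = ("five_prime_ss", "three_prime_ss")


@dataclass(frozen=True)
class Region:
    tag: str
    start: int
    end: int


@dataclass(frozen=True)
class WindowProps:
    pct_exon: float
    pct_5utr: float
    pct_cds: float
    pct_3utr: float
    host_biotype: str
    exon_class: str  # '1' | '2' | '3' | '4+'

    def vector(self) -> np.ndarray:
        return np.array([self.pct_exon, self.pct_5utr, self.pct_cds, self.pct_3utr])


@dataclass
class CircModel:
    """A circRNA tied to its representative host transcript."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str | None
    transcript: Transcript
    exon_count: int
    first_exon_number: int
    boundaries_on_exons: bool
    host_biotype: str
    regions: list[Region] = field(default_factory=list)

    @property
    def exon_class(self) -> str:
        return str(self.exon_count) if self.exon_count < 4 else "4+"

    @property
    def five_prime_pos(self) -> int:
        """Transcript-5' boundary of the circularized span."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime_pos(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    strand: str
    extremity: str
    offset: int  # window start relative to the extremity, transcript orientation
    circ_id: str
    props: WindowProps | None = None


@dataclass(frozen=True)
class EnrichmentBin:
    extremity: str
    offset: int
    replicate: str
    a: int  # target windows with a peak
    b: int  # target windows without
    c: int  # control windows with a peak
    d: int  # control windows without
    odds_ratio: float
    pvalue: float
    significant: bool


class PeakIndex:
    """Interval overlap queries against a fixed peak set."""

    def __init__(self, peaks: Iterable[Peak]):
        by_chrom: dict[str, list[Peak]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        self._starts: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        for chrom, ps in by_chrom.items():
            ps.sort(key=lambda p: p.start)
            starts = np.array([p.start for p in ps])
            ends = np.array([p.end for p in ps])
            self._starts[chrom] = starts
            self._maxend[chrom] = np.maximum.accumulate(ends)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._starts:
            return False
        idx = np.searchsorted(self._starts[chrom], end, side="left")
        if idx == 0:
            return False
        return bool(self._maxend[chrom][idx - 1] > start)


# ---------------------------------------------------------------------------
# Representative transcript & region labels


def _exons_in_span(tr: Transcript, start: int, end: int):
    return [e for e in tr.exons if e.start < end and e.end > start]


def _boundaries_on_exons(tr: Transcript, start: int, end: int) -> bool:
    return any(e.start == start for e in tr.exons) and any(e.end == end for e in tr.exons)


def representative_transcript(circ: BsjRecord, ann: AnnotationModel) -> CircModel:
    """Choose the host isoform that best represents the circularized span.

    Lexicographic priority: (1) transcript biotype equal to the gene biotype,
    (2) both BSJ boundaries coincident with annotated exon junctions,
    (3) fewest exons within the span, (4) lowest number of the first included
    exon; remaining ties break on transcript id.
    """
    if circ.gene_id and circ.gene_id in ann.genes:
        candidates = ann.transcripts_of(circ.gene_id)
        gene_biotype = ann.genes[circ.gene_id].biotype
    else:
        candidates = [
            t for t in ann.transcripts.values()
            if t.chrom == circ.chrom and t.strand == circ.strand
        ]
        gene_biotype = None
    candidates = [
        t for t in candidates
        if t.exons and t.start < circ.end and t.end > circ.start
    ]
    if not candidates:
        raise ValueError(f"unannotated circRNA: {circ.circ_id}")

    def priority(t: Transcript):
        g_bt = gene_biotype if gene_biotype is not None else (
            ann.genes[t.gene_id].biotype if t.gene_id in ann.genes else t.biotype
        )
        span_exons = _exons_in_span(t, circ.start, circ.end)
        first = min((e.number for e in span_exons), default=10**9)
        return (
            0 if t.biotype == g_bt else 1,
            0 if _boundaries_on_exons(t, circ.start, circ.end) else 1,
            len(span_exons) if span_exons else 10**9,
            first,
            t.transcript_id,
        )

    best = min(candidates, key=priority)
    span_exons = _exons_in_span(best, circ.start, circ.end)
    if not span_exons:
        raise ValueError(f"unannotated circRNA: {circ.circ_id}")
    biotype = (
        ann.genes[circ.gene_id].biotype
        if circ.gene_id and circ.gene_id in ann.genes
        else (ann.genes[best.gene_id].biotype if best.gene_id in ann.genes else best.biotype)
    )
    return CircModel(
        circ_id=circ.circ_id, chrom=circ.chrom, start=circ.start, end=circ.end,
        strand=circ.strand, gene_id=circ.gene_id or best.gene_id,
        transcript=best, exon_count=len(span_exons),
        first_exon_number=min(e.number for e in span_exons),
        boundaries_on_exons=_boundaries_on_exons(best, circ.start, circ.end),
        host_biotype=biotype,
    )


def label_regions(model: CircModel) -> CircModel:
    """Label exons/introns inside the circular span in transcript 5'->3' order.

    The exon at the transcript-5' extremity is ``Ex_A`` and its neighbouring
    intron ``Intr_A``; the 3'-extremity exon/intron are ``Ex_Z``/``Intr_Z``;
    medial regions are ``Ex_M``/``Intr_M``.  A bi-exonic circRNA has a single
    intron which is labelled ``Intr_A``.
    """
    if not model.boundaries_on_exons:
        raise ValueError(f"not labelable: {model.circ_id} boundaries not on exon junctions")
    exons = sorted(
        _exons_in_span(model.transcript, model.start, model.end),
        key=lambda e: e.number,
    )
    n = len(exons)
    exon_tags = ["Ex_A"] + ["Ex_M"] * max(0, n - 2) + (["Ex_Z"] if n > 1 else [])
    intron_tags: list[str] = []
    if n >= 2:
        intron_tags = ["Intr_A"] + ["Intr_M"] * max(0, n - 3) + (["Intr_Z"] if n > 2 else [])
    regions: list[Region] = []
    for i, (exon, tag) in enumerate(zip(exons, exon_tags)):
        regions.append(Region(tag, exon.start, exon.end))
        if i < n - 1:
            a, b = exons[i], exons[i + 1]
            if model.strand == "+":
                iv = (a.end, b.start)
            else:
                iv = (b.end, a.start)
            regions.append(Region(intron_tags[i], iv[0], iv[1]))
    model.regions = regions
    return model


# ---------------------------------------------------------------------------
# Sliding windows


def make_windows(
    model: CircModel,
    span: int = 1000,
    width: int = 100,
    step: int = 10,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicWindow]:
    """100-nt windows sliding in 10-nt steps over +/-span of each extremity.

    Offsets are strand-relative (negative = upstream in transcript
    orientation) and run from ``-span`` to ``span - width``; at defaults that
    is 191 windows per extremity.  Windows extending past chromosome bounds
    are dropped with a warning.
    """
    if span < width:
        raise ValueError("span must be >= width")
    if (2 * span - width) % step != 0:
        raise ValueError("step must divide (2*span - width)")
    out: list[GenomicWindow] = []
    size = chrom_sizes.get(model.chrom) if chrom_sizes else None
    for extremity, pos in (
        ("five_prime_ss", model.five_prime_pos),
        ("three_prime_ss", model.three_prime_pos),
    ):
        for offset in range(-span, span - width + 1, step):
            if model.strand == "+":
                g_start = pos + offset
            else:
                g_start = pos - offset - width
            g_end = g_start + width
            if g_start < 0 or (size is not None and g_end > size):
                log.warning(
                    "window %s%+d of %s extends past chromosome bounds; dropped",
                    extremity, offset, model.circ_id,
                )
                continue
            out.append(
                GenomicWindow(
                    chrom=model.chrom, start=g_start, end=g_end,
                    strand=model.strand, extremity=extremity,
                    offset=offset, circ_id=model.circ_id,
                )
            )
    return out


def _overlap_len(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> int:
    return sum(max(0, min(end, e) - max(start, s)) for s, e in intervals)


def window_props(w: GenomicWindow, model: CircModel) -> WindowProps:
    """Annotation composition of a window against the representative transcript."""
    tr = model.transcript
    width = w.end - w.start
    exon_iv = [(e.start, e.end) for e in tr.exons]
    return WindowProps(
        pct_exon=100.0 * _overlap_len(w.start, w.end, exon_iv) / width,
        pct_5utr=100.0 * _overlap_len(w.start, w.end, tr.utr5) / width,
        pct_cds=100.0 * _overlap_len(w.start, w.end, tr.cds) / width,
        pct_3utr=100.0 * _overlap_len(w.start, w.end, tr.utr3) / width,
        host_biotype=model.host_biotype,
        exon_class=model.exon_class,
    )


def annotate_windows(
    windows: Iterable[GenomicWindow], models: Mapping[str, CircModel]
) -> list[GenomicWindow]:
    return [replace(w, props=window_props(w, models[w.circ_id])) for w in windows]


# ---------------------------------------------------------------------------
# Matched controls


def match_controls(
    target_w: GenomicWindow,
    pool: Sequence[GenomicWindow],
    k: int = 2,
) -> list[GenomicWindow]:
    """The k control windows most similar to the target in annotation space.

    The pool (invariant-circRNA windows at the same extremity and offset) is
    first restricted to the target's host biotype and exon class; candidates
    are ranked by Euclidean distance on (pct_exon, pct_5utr, pct_cds,
    pct_3utr), ties broken by circ id.  Scarce pools relax exon class, then
    biotype, logging each relaxation.
    """
    if target_w.props is None:
        raise ValueError("target window lacks annotation properties")
    pool = [w for w in pool if w.props is not None and w.circ_id != target_w.circ_id]
    if not pool:
        return []
    tp = target_w.props

    tiers = [
        [w for w in pool
         if w.props.host_biotype == tp.host_biotype and w.props.exon_class == tp.exon_class],
        [w for w in pool if w.props.host_biotype == tp.host_biotype],
        list(pool),
    ]
    chosen: list[GenomicWindow] = []
    seen: set[int] = set()
    tvec = tp.vector()
    for level, tier in enumerate(tiers):
        cands = [w for w in tier if id(w) not in seen]
        cands.sort(key=lambda w: (float(np.linalg.norm(w.props.vector() - tvec)), w.circ_id))
        for w in cands:
            if len(chosen) >= k:
                break
            chosen.append(w)
            seen.add(id(w))
        if len(chosen) >= k:
            break
        if level == 0 and len(chosen) < k:
            log.info("relaxing exon-class match for window %s%+d of %s",
                     target_w.extremity, target_w.offset, target_w.circ_id)
        elif level == 1 and len(chosen) < k:
            log.info("relaxing biotype match for window %s%+d of %s",
                     target_w.extremity, target_w.offset, target_w.circ_id)
    return chosen


# ---------------------------------------------------------------------------
# Fisher enrichment


def _fisher_bin(a: int, b: int, c: int, d: int, alpha: float) -> tuple[float, float, bool]:
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    aa, bb, cc, dd = (a, b, c, d)
    if min(aa, bb, cc, dd) == 0:
        aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
    orat = (aa * dd) / (bb * cc)
    return orat, float(p), p < alpha


def window_enrichment(
    target_windows: Sequence[GenomicWindow],
    control_windows: Sequence[GenomicWindow],
    peaks_by_replicate: Mapping[str, Sequence[Peak]],
    alpha: float = 0.05,
    merge: bool = True,
) -> pd.DataFrame:
    """Per-(extremity, offset, replicate) Fisher test of peak containment.

    A window "contains a peak" when it overlaps a (within-replicate
    longest-merged) peak by at least one nucleotide.  Testing is done per
    replicate, never pooled.
    """
    rows = []
    t_key: dict[tuple[str, int], list[GenomicWindow]] = {}
    c_key: dict[tuple[str, int], list[GenomicWindow]] = {}
    for w in target_windows:
        t_key.setdefault((w.extremity, w.offset), []).append(w)
    for w in control_windows:
        c_key.setdefault((w.extremity, w.offset), []).append(w)
    for rep, peaks in peaks_by_replicate.items():
        merged = merge_longest(list(peaks)) if merge else list(peaks)
        index = PeakIndex(merged)
        for key in sorted(t_key):
            targets = t_key[key]
            controls = c_key.get(key, [])
            a = sum(index.overlaps(w.chrom, w.start, w.end) for w in targets)
            b = len(targets) - a
            c = sum(index.overlaps(w.chrom, w.start, w.end) for w in controls)
            d = len(controls) - c
            orat, p, sig = _fisher_bin(a, b, c, d, alpha)
            rows.append(
                {
                    "extremity": key[0], "offset": key[1], "replicate": rep,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": orat, "pvalue": p, "significant": sig,
                }
            )
    return pd.DataFrame(rows)


def region_enrichment(
    down: Sequence[CircModel],
    invariant: Sequence[CircModel],
    peaks: Sequence[Peak],
    alpha: float = 0.05,
    merge: bool = True,
) -> pd.DataFrame:
    """Peak containment per (exon-class group, region label), down vs invariant.

    Only circRNAs with BSJ boundaries on exon junctions participate; groups
    are bi-exonic, three-exonic and multi-exonic (2 / 3 / 4+).  Region tags
    with no representation in the invariant set are skipped with a warning.
    """
    merged = merge_longest(list(peaks)) if merge else list(peaks)
    index = PeakIndex(merged)

    def tally(models: Sequence[CircModel]) -> dict[tuple[str, str], tuple[int, int]]:
        out: dict[tuple[str, str], list[int]] = {}
        for mdl in models:
            if not mdl.boundaries_on_exons or mdl.exon_count < 2:
                continue
            regions = mdl.regions or label_regions(mdl).regions
            for reg in regions:
                if reg.end <= reg.start:
                    continue
                key = (mdl.exon_class, reg.tag)
                hit = index.overlaps(mdl.chrom, reg.start, reg.end)
                cnt = out.setdefault(key, [0, 0])
                cnt[0 if hit else 1] += 1
        return {k: (v[0], v[1]) for k, v in out.items()}

    t_down, t_inv = tally(down), tally(invariant)
    rows = []
    for key in sorted(t_down):
        if key not in t_inv:
            log.warning("region %s of group %s absent from invariant set; skipped",
                        key[1], key[0])
            continue
        a, b = t_down[key]
        c, d = t_inv[key]
        orat, p, sig = _fisher_bin(a, b, c, d, alpha)
        rows.append(
            {
                "exon_class": key[0], "region": key[1],
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": orat, "pvalue": p, "significant": sig,
            }
        )
    return pd.DataFrame(rows)


def interactor_call(
    circ: BsjRecord | CircModel,
    peaks_by_sample: Mapping[str, Sequence[Peak]],
    min_samples: int = 2,
) -> bool:
    """True when the circRNA span overlaps >=1 peak in >= min_samples replicates."""
    hits = 0
    for peaks in peaks_by_sample.values():
        index = PeakIndex(peaks)
        if index.overlaps(circ.chrom, circ.start, circ.end):
            hits += 1
            if hits >= min_samples:
                return True
    return False


def balance_check(
    target_windows: Sequence[GenomicWindow],
    control_windows: Sequence[GenomicWindow],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher checks that window properties are balanced target-vs-control.

    Continuous properties are dichotomized at the pooled median; biotype and
    exon class are tested category-vs-rest.
    """
    if not target_windows or not control_windows:
        raise ValueError("both window sets must be nonempty")
    tprops = [w.props for w in target_windows]
    cprops = [w.props for w in control_windows]
    if any(p is None for p in tprops + cprops):
        raise ValueError("windows lack annotation properties")
    rows = []
    for name in ("pct_exon", "pct_5utr", "pct_cds", "pct_3utr"):
        tv = np.array([getattr(p, name) for p in tprops])
        cv = np.array([getattr(p, name) for p in cprops])
        med = float(np.median(np.concatenate([tv, cv])))
        a, b = int((tv > med).sum()), int((tv <= med).sum())
        c, d = int((cv > med).sum()), int((cv <= med).sum())
        orat, p, sig = _fisher_bin(a, b, c, d, alpha)
        rows.append({"property": name, "level": f">{med:g}",
                     "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": orat, "pvalue": p, "significant": sig})
    for name in ("host_biotype", "exon_class"):
        levels = sorted({getattr(p, name) for p in tprops + cprops})
        for lev in levels:
            a = sum(getattr(p, name) == lev for p in tprops)
            b = len(tprops) - a
            c = sum(getattr(p, name) == lev for p in cprops)
            d = len(cprops) - c
            orat, p, sig = _fisher_bin(a, b, c, d, alpha)
            rows.append({"property": name, "level": lev,
                         "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": orat, "pvalue": p, "significant": sig})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end helper


def run_meta_bsj(
    down_models: Sequence[CircModel],
    invariant_models: Sequence[CircModel],
    peaks_by_replicate: Mapping[str, Sequence[Peak]],
    span: int = 1000,
    width: int = 100,
    step: int = 10,
    k_controls: int = 2,
    alpha: float = 0.05,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, list[GenomicWindow], list[GenomicWindow]]:
    """Window construction, control matching and enrichment in one call."""
    models = {m.circ_id: m for m in list(down_models) + list(invariant_models)}
    t_windows: list[GenomicWindow] = []
    for mdl in down_models:
        t_windows.extend(make_windows(mdl, span, width, step, chrom_sizes))
    pool_windows: list[GenomicWindow] = []
    for mdl in invariant_models:
        pool_windows.extend(make_windows(mdl, span, width, step, chrom_sizes))
    t_windows = annotate_windows(t_windows, models)
    pool_windows = annotate_windows(pool_windows, models)

    pool_by_key: dict[tuple[str, int], list[GenomicWindow]] = {}
    for w in pool_windows:
        pool_by_key.setdefault((w.extremity, w.offset), []).append(w)

    controls: list[GenomicWindow] = []
    kept_targets: list[GenomicWindow] = []
    for w in t_windows:
        matched = match_controls(w, pool_by_key.get((w.extremity, w.offset), []), k=k_controls)
        if not matched:
            log.info("no controls for window %s%+d of %s; excluded",
                     w.extremity, w.offset, w.circ_id)
            continue
        kept_targets.append(w)
        controls.extend(matched)

    bins = window_enrichment(kept_targets, controls, peaks_by_replicate, alpha=alpha)
    return bins, kept_targets, controls
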