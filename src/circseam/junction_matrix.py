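"""Dense circular/linear junction count matrices and feature selection.

Each back-splicing junction contributes two paired features to the matrix:
``<circ_id>|circ`` (reads over the back-splicing junction) and
``<circ_id>|linear`` (reads mapping linearly over the same splice sites).
The library size of a sample is the sum over this junction universe, which is
also the universe CPM values are computed on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_junctions import BsjRecord, parse_circ_id

CIRC_SUFFIX = "|circ"
LINEAR_SUFFIX = "|linear"


def circ_feature(circ_id: str) -> str:
    return circ_id + CIRC_SUFFIX


def linear_feature(circ_id: str) -> str:
    return circ_id + LINEAR_SUFFIX


def feature_circ_id(feature_id: str) -> str:
    for suf in (CIRC_SUFFIX, LINEAR_SUFFIX):
        if feature_id.endswith(suf):
            return feature_id[: -len(suf)]
    raise ValueError(f"not a junction feature id: {feature_id}")


def feature_kind(feature_id: str) -> str:
    if feature_id.endswith(CIRC_SUFFIX):
        return "circ"
    if feature_id.endswith(LINEAR_SUFFIX):
        return "linear"
    raise ValueError(f"not a junction feature id: {feature_id}")


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative junction read counts.

    ``counts`` is indexed by feature id (``|circ``/``|linear`` suffixed);
    ``meta`` holds per-circRNA coordinates and host gene.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def kind(self) -> pd.Series:
        return pd.Series(
            [feature_kind(f) for f in self.counts.index],
            index=self.counts.index, name="kind",
        )

    def circ_ids(self) -> list[str]:
        return [feature_circ_id(f) for f in self.counts.index if f.endswith(CIRC_SUFFIX)]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class CpmMatrix:
    """Counts-per-million values on the same feature universe."""

    values: pd.DataFrame

    def circ_ids(self) -> list[str]:
        return [feature_circ_id(f) for f in self.values.index if f.endswith(CIRC_SUFFIX)]


def complete_counts(per_sample_records: Iterable[Iterable[BsjRecord]]) -> CountMatrix:
    """Build the dense matrix over the union of BSJs seen in any sample.

    A sample lacking a BSJ gets a circular count of 0; its linear count is the
    sample's linear-junction count at those splice sites when a record with
    ``bsj_reads == 0`` supplies it, else 0 (mirroring the realignment rerun
    that recovers linear reads for circRNAs detected only in other samples).
    """
    groups: list[list[BsjRecord]] = [list(g) for g in per_sample_records]
    if not groups:
        raise ValueError("at least one sample required")
    sample_ids: list[str] = []
    meta_rows: dict[str, dict] = {}
    cells: dict[tuple[str, str], tuple[int, int]] = {}
    strand_of: dict[tuple[str, int, int], str] = {}
    for group in groups:
        for rec in group:
            if rec.sample_id not in sample_ids:
                sample_ids.append(rec.sample_id)
            coord = (rec.chrom, rec.start, rec.end)
            if strand_of.setdefault(coord, rec.strand) != rec.strand:
                raise ValueError(
                    f"inconsistent strand for {rec.chrom}:{rec.start}-{rec.end} across samples"
                )
            cid = rec.circ_id
            if cid not in meta_rows:
                meta_rows[cid] = {
                    "chrom": rec.chrom, "start": rec.start, "end": rec.end,
                    "strand": rec.strand, "gene_id": rec.gene_id,
                }
            if rec.gene_id and not meta_rows[cid]["gene_id"]:
                meta_rows[cid]["gene_id"] = rec.gene_id
            cells[(cid, rec.sample_id)] = (rec.bsj_reads, rec.linear_reads)

    circ_ids = sorted(meta_rows)
    features = [circ_feature(c) for c in circ_ids] + [linear_feature(c) for c in circ_ids]
    mat = np.zeros((len(features), len(sample_ids)), dtype=np.int64)
    for i, cid in enumerate(circ_ids):
        for j, sid in enumerate(sample_ids):
            bsj, lin = cells.get((cid, sid), (0, 0))
            mat[i, j] = bsj
            mat[i + len(circ_ids), j] = lin
    counts = pd.DataFrame(mat, index=features, columns=sample_ids)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "circ_id"
    return CountMatrix(counts=counts, meta=meta.loc[circ_ids])


def expression_filter(
    m: CountMatrix, min_count: int = 2, min_samples: int = 3
) -> CountMatrix:
    """Keep features with ``>= min_count`` reads in ``>= min_samples`` samples.

    Circular and linear partners are filtered independently.  Idempotent.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_samples > len(m.samples):
        raise ValueError("min_samples exceeds the number of samples")
    keep = (m.counts >= min_count).sum(axis=1) >= min_samples
    counts = m.counts.loc[keep]
    kept_circ = {feature_circ_id(f) for f in counts.index}
    meta = m.meta.loc[[c for c in m.meta.index if c in kept_circ]] if len(m.meta) else m.meta
    return CountMatrix(counts=counts, meta=meta)


def cpm(m: CountMatrix, tmm_factors: Mapping[str, float] | pd.Series | None = None) -> CpmMatrix:
    """Counts per million over the junction universe.

    With TMM factors supplied, the effective library size of each sample is
    ``library_size * factor``.
    """
    lib = m.library_sizes().astype(float)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples: {zero}")
    if tmm_factors is not None:
        factors = pd.Series(tmm_factors).reindex(lib.index)
        if factors.isna().any():
            raise ValueError("TMM factors missing for some samples")
        lib = lib * factors
    values = m.counts.astype(float).div(lib, axis=1) * 1e6
    return CpmMatrix(values=values)


def top_expressed(m: CpmMatrix, fraction: float = 0.2) -> set[str]:
    """The top fraction of circRNAs ranked by mean CPM (ties by id)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    circ_rows = m.values.loc[[f for f in m.values.index if f.endswith(CIRC_SUFFIX)]]
    if circ_rows.empty:
        raise ValueError("empty matrix")
    means = circ_rows.mean(axis=1)
    order = sorted(means.index, key=lambda f: (-means[f], f))
    n_keep = math.ceil(fraction * len(order))
    return {feature_circ_id(f) for f in order[:n_keep]}


def high_confidence(
    ciri: set[str], tool2: set[str], tool3: set[str], slack: int = 0
) -> set[str]:
    """CircRNAs called by all three detectors.

    With ``slack > 0``, ids match when chrom/strand agree and both junction
    coordinates differ by at most ``slack`` nt (detectors can disagree on
    junction bases).  Returns the matching ids in the first (CIRI2) set.
    """
    if slack == 0:
        return set(ciri) & set(tool2) & set(tool3)
    if not (0 <= slack <= 2):
        raise ValueError("slack must be within 0-2 nt")

    def parse_all(ids: set[str]) -> list[tuple[str, int, int, str]]:
        return [parse_circ_id(i) for i in ids]

    def matches(rec: tuple[str, int, int, str], pool: list[tuple[str, int, int, str]]) -> bool:
        c, s, e, st = rec
        return any(
            c == pc and st == pst and abs(s - ps) <= slack and abs(e - pe) <= slack
            for pc, ps, pe, pst in pool
        )

    p2, p3 = parse_all(tool2), parse_all(tool3)
    out = set()
    for cid in ciri:
        rec = parse_circ_id(cid)
        if matches(rec, p2) and matches(rec, p3):
            out.add(cid)
    return out


# ---------------------------------------------------------------------------
# TSV round trip


def write_matrix_tsv(m: CountMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path: str | Path, meta: pd.DataFrame | None = None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="feature_id")
    return CountMatrix(counts=counts, meta=meta if meta is not None else pd.DataFrame())
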