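"""Concordance classification of circular/linear pairs and the summary tests.

A gene's circular and linear isoforms are "concordant" when both change
significantly in the same direction, "discordant circ" when the circular
isoform changes while the linear is unaltered or moves the other way, and
"discordant lin" for the symmetric case.  Proportion differences are tested
with two-tailed Fisher exact tests, and circular-to-linear ratio (CLR)
distributions are compared with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ks_2samp

from .diffexp import DeResult

CATEGORIES = ("Concordant", "DiscordantCirc", "DiscordantLin", "Unaltered")


@dataclass(frozen=True)
class PairClass:
    circ_id: str
    gene_id: str | None
    category: str
    circ_log2fc: float
    lin_log2fc: float
    circ_p: float
    lin_p: float


@dataclass(frozen=True)
class ClrValue:
    circ_id: str
    condition: str
    clr: float


def _corrected_or(table: Sequence[Sequence[float]]) -> float:
    (a, b), (c, d) = table
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def classify_pair(circ: DeResult, lin: DeResult, alpha: float = 0.05) -> PairClass:
    """Assign one of the four concordance categories to a circ/linear pair."""
    from .junction_matrix import feature_circ_id

    circ_cid = feature_circ_id(circ.feature_id)
    lin_cid = feature_circ_id(lin.feature_id)
    if circ_cid != lin_cid:
        raise ValueError(f"mismatched pair: {circ.feature_id} vs {lin.feature_id}")
    circ_sig = circ.pvalue < alpha
    lin_sig = lin.pvalue < alpha
    if circ_sig and lin_sig and np.sign(circ.log2fc) == np.sign(lin.log2fc):
        cat = "Concordant"
    elif circ_sig:
        cat = "DiscordantCirc"  # linear unaltered or opposite direction
    elif lin_sig:
        cat = "DiscordantLin"
    else:
        cat = "Unaltered"
    return PairClass(
        circ_id=circ_cid, gene_id=None, category=cat,
        circ_log2fc=circ.log2fc, lin_log2fc=lin.log2fc,
        circ_p=circ.pvalue, lin_p=lin.pvalue,
    )


def classify_pairs(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify every circRNA with both isoforms tested in a DE result frame."""
    circ = de[de["kind"] == "circ"].set_index("circ_id")
    lin = de[de["kind"] == "linear"].set_index("circ_id")
    shared = circ.index.intersection(lin.index)
    rows = []
    for cid in shared:
        c, l = circ.loc[cid], lin.loc[cid]
        c_sig, l_sig = c["pvalue"] < alpha, l["pvalue"] < alpha
        if c_sig and l_sig and np.sign(c["log2fc"]) == np.sign(l["log2fc"]):
            cat = "Concordant"
        elif c_sig:
            cat = "DiscordantCirc"
        elif l_sig:
            cat = "DiscordantLin"
        else:
            cat = "Unaltered"
        rows.append(
            {
                "circ_id": cid, "category": cat,
                "circ_log2fc": c["log2fc"], "lin_log2fc": l["log2fc"],
                "circ_p": c["pvalue"], "lin_p": l["pvalue"],
            }
        )
    return pd.DataFrame(rows, columns=[
        "circ_id", "category", "circ_log2fc", "lin_log2fc", "circ_p", "lin_p",
    ])


def proportion_summary(down: int, up: int) -> tuple[float, float]:
    """Percent down / percent up among the deregulated species."""
    total = down + up
    if total == 0:
        raise ValueError("no deregulated features")
    return 100.0 * down / total, 100.0 * up / total


def proportion_test(
    set1_up: int, set1_down: int, set2_up: int, set2_down: int
) -> tuple[float, float]:
    """Two-tailed Fisher exact test on up/down proportions of two sets.

    Returns (odds_ratio, p); the odds ratio uses a Haldane-Anscombe 0.5
    correction when any cell is zero (for reporting only; the p-value is the
    exact one).
    """
    if min(set1_up, set1_down, set2_up, set2_down) < 0:
        raise ValueError("counts must be non-negative")
    if set1_up + set1_down == 0 or set2_up + set2_down == 0:
        raise ValueError("each set must be nonempty")
    table = [[set1_up, set1_down], [set2_up, set2_down]]
    _, p = fisher_exact(table, alternative="two-sided")
    return _corrected_or(table), float(p)


def clr_values(
    cpm_values: pd.DataFrame,
    condition_samples: Mapping[str, Sequence[str]],
) -> list[ClrValue]:
    """Per-condition CLR: mean circ CPM / mean linear CPM.

    Pairs with zero linear CPM in a condition are excluded (CLR undefined).
    """
    from .junction_matrix import CIRC_SUFFIX, feature_circ_id, linear_feature

    out: list[ClrValue] = []
    circ_feats = [f for f in cpm_values.index if f.endswith(CIRC_SUFFIX)]
    for cond, samples in condition_samples.items():
        for f in circ_feats:
            cid = feature_circ_id(f)
            lf = linear_feature(cid)
            if lf not in cpm_values.index:
                continue
            c = float(cpm_values.loc[f, list(samples)].mean())
            l = float(cpm_values.loc[lf, list(samples)].mean())
            if l == 0:
                continue
            out.append(ClrValue(circ_id=cid, condition=cond, clr=c / l))
    return out


def clr_cdf_compare(
    clr_a: Iterable[ClrValue | float], clr_b: Iterable[ClrValue | float]
) -> tuple[float, float]:
    """Two-sample KS comparison of CLR distributions (asymptotic p)."""

    def _vals(xs) -> np.ndarray:
        return np.array([x.clr if isinstance(x, ClrValue) else float(x) for x in xs])

    a, b = _vals(clr_a), _vals(clr_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("CLR lists must be nonempty")
    res = ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def overlap_test(
    down_a: set[str], down_b: set[str], universe: set[str],
    denominator: str = "union",
) -> tuple[int, float, float, float]:
    """Fisher test of two down-regulated sets' overlap over a universe.

    Returns (overlap_count, overlap_pct, odds_ratio, p).  The overlap
    percentage denominator is configurable: ``union`` (default, Jaccard
    style), ``setA`` or ``setB``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not down_a <= universe or not down_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    inter = down_a & down_b
    a = len(inter)
    b = len(down_a - down_b)
    c = len(down_b - down_a)
    d = len(universe) - len(down_a | down_b)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    denom = {
        "union": len(down_a | down_b),
        "setA": len(down_a),
        "setB": len(down_b),
    }[denominator]
    pct = 100.0 * a / denom if denom else 0.0
    return a, pct, _corrected_or([[a, b], [c, d]]), float(p)


def binding_by_cutoff(
    de: pd.DataFrame,
    interactors: set[str],
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Fraction of significant circRNAs that are binding interactors, per cutoff.

    For each p-value cutoff, circRNAs with p < cutoff are split by fold-change
    sign; the fraction bound is reported per stratum, NA for empty strata.
    """
    circ = de[de["kind"] == "circ"]
    if circ.empty:
        raise ValueError("empty DE input")
    rows = []
    for c in cutoffs:
        for direction, sel in (
            ("down", (circ["pvalue"] < c) & (circ["log2fc"] < 0)),
            ("up", (circ["pvalue"] < c) & (circ["log2fc"] > 0)),
        ):
            ids = set(circ.loc[sel, "circ_id"])
            frac = len(ids & interactors) / len(ids) if ids else np.nan
            rows.append({"cutoff": c, "direction": direction,
                         "n": len(ids), "fraction_bound": frac})
    return pd.DataFrame(rows)
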