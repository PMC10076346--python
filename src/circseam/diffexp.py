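"""Between-sample TMM normalization and negative-binomial LRT.

The testing contract mirrors the standard count-based differential-expression
stage: library sizes are rescaled by trimmed-mean-of-M-values (TMM) factors,
each junction feature is fitted with a negative-binomial GLM (log link,
intercept-only null vs two-group alternative, effective library sizes as
offsets), and the likelihood ratio is referred to chi-square with one degree
of freedom.  Significance uses the raw p-value at alpha = 0.05; a BH-FDR
column is emitted alongside but unused by default.

Dispersion is either a fixed value or a common dispersion estimated by
maximizing the profile likelihood over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2, rankdata

from .junction_matrix import CountMatrix, feature_circ_id, feature_kind

_PSEUDO = 0.5  # pseudo-count on normalized (CPM-scale) group means


@dataclass(frozen=True)
class DeResult:
    """Per-feature differential-expression outcome."""

    feature_id: str
    kind: str  # 'circ' | 'linear'
    log2fc: float
    pvalue: float
    mean_cpm: float
    status: str  # 'up' | 'down' | 'unaltered'


# ---------------------------------------------------------------------------
# TMM


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    # per-sample p-quantile of counts scaled by library size
    return np.quantile(counts, p, axis=0) / lib


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    log_ratio_trim: float = 0.3, sum_trim: float = 0.05,
) -> float:
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep2 = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep2.any():
        return 1.0
    w = 1.0 / var[keep2]
    f = np.sum(w * log_r[keep2]) / np.sum(w)
    return float(2.0 ** f)


def tmm_factors(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference sample: upper-quartile (of counts/library-size) closest to the
    mean upper quartile.  For each sample vs the reference, features with a
    zero in either sample are excluded; M-values are trimmed by 30% and
    A-values by 5% (both tails), and the factor is the inverse-variance
    weighted mean of the surviving M-values.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    f75 = _quantile_factor(x, lib)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# NB GLM LRT


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise NB log-likelihood with mean mu and dispersion phi (var = mu + phi mu^2)."""
    mu = np.maximum(mu, 1e-12)
    if phi < 1e-8:  # Poisson limit; avoids gammaln cancellation at huge 1/phi
        return np.sum(xlogy(y, mu) - mu - gammaln(y + 1.0), axis=-1)
    r = 1.0 / phi
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + xlogy(y, mu) - (y + r) * np.log(r + mu) + r * np.log(r),
        axis=-1,
    )


def _fit_mu(y: np.ndarray, s: np.ndarray, phi: float, n_iter: int = 60) -> np.ndarray:
    """MLE of the per-feature rate q (mu_ij = s_j * q_i) by Fisher scoring.

    ``y`` is features x samples, ``s`` the effective library sizes.  Features
    with all-zero rows get a rate of ~0.
    """
    tot = y.sum(axis=1)
    q = np.maximum(tot / s.sum(), 1e-12)
    eta = np.log(q)
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + phi * mu
        score = np.sum((y - mu) / denom, axis=1)
        info = np.sum(mu / denom, axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        eta = np.clip(eta, np.log(1e-14), 50.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    q = np.exp(eta)
    q[tot == 0] = 1e-14
    return q


def _fit_loglik(y: np.ndarray, s: np.ndarray, groups: np.ndarray, phi: float) -> tuple:
    """(ll_null, ll_alt, q_per_group) at a given dispersion."""
    q_null = _fit_mu(y, s, phi)
    mu_null = s[None, :] * q_null[:, None]
    ll_null = _nb_loglik(y, mu_null, phi)
    levels = np.unique(groups)
    q_group = {}
    ll_alt = np.zeros(y.shape[0])
    mu_alt = np.empty_like(y, dtype=float)
    for lev in levels:
        sel = groups == lev
        q_group[lev] = _fit_mu(y[:, sel], s[sel], phi)
        mu_alt[:, sel] = s[sel][None, :] * q_group[lev][:, None]
    ll_alt = _nb_loglik(y, mu_alt, phi)
    return ll_null, ll_alt, q_group


def estimate_common_dispersion(
    y: np.ndarray, s: np.ndarray, groups: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Common dispersion maximizing the adjusted profile likelihood on a log grid.

    The group means are profiled out per feature; the Cox-Reid adjustment
    (minus half the log determinant of the per-group Fisher information)
    corrects the downward bias of the plain profile likelihood at small
    group sizes.
    """
    if grid is None:
        grid = np.logspace(np.log10(1e-4), np.log10(4.0), 200)
    levels = np.unique(groups)
    best_phi, best_apl = grid[0], -np.inf
    for phi in grid:
        phi = float(phi)
        apl = 0.0
        for lev in levels:
            sel = groups == lev
            q = _fit_mu(y[:, sel], s[sel], phi)
            mu = s[sel][None, :] * q[:, None]
            w = mu / (1.0 + phi * mu)
            apl += float(
                np.sum(_nb_loglik(y[:, sel], mu, phi))
                - 0.5 * np.sum(np.log(np.maximum(w.sum(axis=1), 1e-300)))
            )
        if apl > best_apl:
            best_apl, best_phi = apl, phi
    return best_phi


def nb_lrt(
    m: CountMatrix,
    groups: Mapping[str, str] | pd.Series,
    factors: pd.Series | None = None,
    dispersion: float | str = "estimate",
    alpha: float = 0.05,
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test per junction feature.

    Returns a DataFrame indexed by feature id with columns ``kind``,
    ``log2fc`` (second level vs first; levels sort alphabetically unless
    ``levels`` gives (control, condition) explicitly), ``pvalue``, ``fdr``,
    ``mean_cpm`` and ``status``.  Features that are all-zero in both groups
    are excluded.
    """
    groups = pd.Series(groups)
    samples = [s for s in m.samples if s in groups.index]
    if len(samples) != len(m.samples):
        missing = set(m.samples) - set(samples)
        raise ValueError(f"samples without group assignment: {sorted(missing)}")
    if levels is None:
        levels = sorted(set(groups[samples]))
    if len(levels) != 2 or set(levels) != set(groups[samples]):
        raise ValueError(f"design must have exactly two levels, got {sorted(set(groups[samples]))}")
    gvec = groups[samples].to_numpy()
    for lev in levels:
        if (gvec == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than two samples")

    counts = m.counts[samples]
    nonzero = counts.sum(axis=1) > 0
    y = counts.loc[nonzero].to_numpy(dtype=float)
    feats = counts.index[nonzero]

    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if factors is None:
        factors = tmm_factors(m)
    s = lib * pd.Series(factors).reindex(samples).to_numpy(dtype=float)

    if dispersion == "estimate":
        phi = estimate_common_dispersion(y, s, gvec)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be >= 0")

    ll_null, ll_alt, q_group = _fit_loglik(y, s, gvec, phi)
    lr = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    pvals = chi2.sf(lr, df=1)

    # effective-library CPM-scale group means with a pseudo-count guard
    mean_ctrl = q_group[levels[0]] * 1e6
    mean_cond = q_group[levels[1]] * 1e6
    log2fc = np.log2((mean_cond + _PSEUDO) / (mean_ctrl + _PSEUDO))

    cpm_all = (y / s[None, :]) * 1e6
    mean_cpm = cpm_all.mean(axis=1)

    order = np.argsort(pvals, kind="stable")
    n = len(pvals)
    fdr = np.empty(n)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    fdr[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.clip(fdr, 0, 1)

    status = np.where(
        (pvals < alpha) & (log2fc > 0), "up",
        np.where((pvals < alpha) & (log2fc < 0), "down", "unaltered"),
    )

    out = pd.DataFrame(
        {
            "kind": [feature_kind(f) for f in feats],
            "circ_id": [feature_circ_id(f) for f in feats],
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "mean_cpm": mean_cpm,
            "status": status,
        },
        index=feats,
    )
    out.index.name = "feature_id"
    out.attrs["dispersion"] = phi
    out.attrs["levels"] = levels
    return out


def de_results(df: pd.DataFrame) -> list[DeResult]:
    """View a result frame as a list of :class:`DeResult` records."""
    return [
        DeResult(
            feature_id=f, kind=row["kind"], log2fc=float(row["log2fc"]),
            pvalue=float(row["pvalue"]), mean_cpm=float(row["mean_cpm"]),
            status=row["status"],
        )
        for f, row in df.iterrows()
    ]
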