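"""MAS5-style probeset summarization, detection calls and per-array scaling.

This module implements the classic Affymetrix "Statistical Algorithms"
expression pipeline for 3'-IVT GeneChips:

* a one-step Tukey biweight over background-adjusted ``log2`` probe
  intensities yields the probeset *signal*,
* a one-sided Wilcoxon signed-rank test on the per-pair discrimination
  scores ``R = (PM - MM) / (PM + MM)`` against a small threshold ``tau``
  yields the *detection p-value* and the Present/Marginal/Absent call,
* a trimmed-mean global scaling puts every array on a common target
  intensity, one array at a time, so that adding arrays to a study never
  changes the values of arrays already processed.

The signed-rank test is computed by exact enumeration of all ``2^m`` sign
assignments for up to ``exact_limit`` informative pairs (the production
path for 11-pair probesets) and by a tie- and continuity-corrected normal
approximation above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Mas5Params",
    "ExpressionMatrix",
    "tukey_biweight",
    "specific_background",
    "ideal_mismatch",
    "probeset_signal",
    "detection_pvalue",
    "detection_call",
    "trimmed_mean",
    "scale_array",
    "normalize_dataset",
]

_TINY = 1e-300
_LOG_CLIP = 1e-12

CALL_PRESENT = "P"
CALL_MARGINAL = "M"
CALL_ABSENT = "A"


@dataclass(frozen=True)
class Mas5Params:
    """Tuning constants of the summarization / detection / scaling pipeline.

    Defaults follow the published Affymetrix statistical-algorithms
    reference values; every constant can be overridden per run.
    """

    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06
    biweight_c: float = 5.0
    biweight_epsilon: float = 1e-4
    contrast_tau: float = 0.03
    scale_tau: float = 10.0
    delta_floor: float = 2.0 ** -20
    scale_target: float = 500.0
    trim: float = 0.02
    exact_limit: int = 12

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < self.alpha2 < 1.0):
            raise ValueError("require 0 < alpha1 < alpha2 < 1")
        if self.biweight_c <= 0 or self.biweight_epsilon <= 0:
            raise ValueError("biweight constants must be positive")
        if self.contrast_tau <= 0 or self.scale_tau <= 0:
            raise ValueError("ideal-mismatch taus must be positive")
        if self.delta_floor <= 0 or self.scale_target <= 0:
            raise ValueError("delta_floor and scale_target must be positive")
        if not (0.0 <= self.trim < 0.5):
            raise ValueError("trim must lie in [0, 0.5)")
        if self.exact_limit < 0:
            raise ValueError("exact_limit must be >= 0")


def tukey_biweight(values, c: float = 5.0, epsilon: float = 1e-4, axis=None):
    """One-step Tukey biweight location estimate.

    With ``M`` the median and ``S`` the median absolute deviation,
    ``u_i = (x_i - M) / (c * S + epsilon)`` and weights
    ``w_i = (1 - u_i^2)^2`` for ``|u_i| < 1`` (zero otherwise); the result
    is ``sum(w_i x_i) / sum(w_i)``.  Works along ``axis`` for stacked
    inputs; ``axis=None`` flattens.
    """
    x = np.asarray(values, dtype=float)
    scalar = axis is None
    if scalar:
        x = x.ravel()
        axis = 0
    if x.shape[axis] == 0:
        raise ValueError("tukey_biweight of an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("tukey_biweight requires finite values")
    med = np.median(x, axis=axis, keepdims=True)
    mad = np.median(np.abs(x - med), axis=axis, keepdims=True)
    u = (x - med) / (c * mad + epsilon)
    w = np.square(1.0 - np.square(u))
    w[np.abs(u) >= 1.0] = 0.0
    out = np.sum(w * x, axis=axis) / np.sum(w, axis=axis)
    return float(out) if scalar else out


def specific_background(pm, mm, c: float = 5.0, epsilon: float = 1e-4, axis=None):
    """Robust mean of ``log2(PM/MM)`` over the probe pairs of a probeset."""
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    ratio = np.log2(np.maximum(pm, _LOG_CLIP) / np.maximum(mm, _LOG_CLIP))
    return tukey_biweight(ratio, c=c, epsilon=epsilon, axis=axis)


def _im_formula(pm, mm, sb, contrast_tau: float, scale_tau: float):
    """Branch rules for the ideal mismatch, broadcasting over arrays."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        exp_small = contrast_tau / (1.0 + (contrast_tau - sb) / scale_tau)
        alt = np.where(sb > contrast_tau, pm / 2.0 ** np.minimum(sb, 1022.0),
                       pm / 2.0 ** exp_small)
    return np.where(mm < pm, mm, alt)


def ideal_mismatch(pm, mm, sb: float | None = None, contrast_tau: float = 0.03,
                   scale_tau: float = 10.0, c: float = 5.0,
                   epsilon: float = 1e-4) -> np.ndarray:
    """Per-pair ideal mismatch: the MM itself when informative (``MM < PM``),
    otherwise a fraction of PM derived from the probeset's specific
    background ``sb`` (robust mean of ``log2(PM/MM)``)."""
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape:
        raise ValueError("pm and mm must have the same length")
    if sb is None:
        sb = specific_background(pm, mm, c=c, epsilon=epsilon)
    return _im_formula(pm, mm, sb, contrast_tau, scale_tau)


def probeset_signal(pm, mm, params: Mas5Params | None = None) -> float:
    """Linear-scale signal of one probeset from its PM/MM pairs."""
    p = params or Mas5Params()
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1 or pm.size == 0:
        raise ValueError("pm and mm must be equal-length non-empty vectors")
    im = ideal_mismatch(pm, mm, contrast_tau=p.contrast_tau, scale_tau=p.scale_tau,
                        c=p.biweight_c, epsilon=p.biweight_epsilon)
    v = np.maximum(pm - im, p.delta_floor)
    return float(2.0 ** tukey_biweight(np.log2(v), c=p.biweight_c,
                                       epsilon=p.biweight_epsilon))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank detection
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _signed_rank_tail(m: int) -> np.ndarray:
    """Exact null tail of the signed-rank statistic for ranks ``1..m``.

    ``tail[w] = P(W+ >= w)`` where ``W+`` is the sum of a uniformly random
    subset of ``{1..m}`` — equivalent to enumerating all ``2^m`` sign
    assignments.
    """
    counts = np.zeros(m * (m + 1) // 2 + 1)
    counts[0] = 1.0
    for k in range(1, m + 1):
        shifted = np.zeros_like(counts)
        shifted[k:] = counts[:-k]
        counts = counts + shifted
    return np.cumsum(counts[::-1])[::-1] / 2.0 ** m


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact one-sided p by enumeration of all 2^m sign assignments.

    Zero differences are dropped before ranking; midranks handle ties.
    """
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0.0].sum())
    signs = (np.arange(2 ** m)[:, None] >> np.arange(m)) & 1
    sums = signs @ ranks
    return float(np.mean(sums >= w_obs - 1e-9))


def _tie_term(a: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the finite entries of ``a``."""
    vals = a[np.isfinite(a)]
    _, counts = np.unique(vals, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _normal_signed_rank_p(w: float, m: int, tie_term: float = 0.0) -> float:
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return 1.0
    z = (w - mu - 0.5) / math.sqrt(var)
    return float(min(1.0, max(stats.norm.sf(z), _TINY)))


def _detection_pvalues(d: np.ndarray, exact_limit: int) -> np.ndarray:
    """Vectorized one-sided signed-rank p-values.

    ``d`` has shape (n_cases, n_pairs) and holds ``R - tau`` per pair.
    The exact enumeration distribution is used whenever the number of
    informative (non-zero) pairs is at most ``exact_limit``; midrank ties
    fall back to per-case enumeration, larger probesets use a tie- and
    continuity-corrected normal approximation.
    """
    n_cases, _ = d.shape
    nz = d != 0.0
    m = nz.sum(axis=1)
    a = np.where(nz, np.abs(d), np.inf)
    ranks = stats.rankdata(a, axis=1)
    w = np.where(d > 0.0, ranks, 0.0).sum(axis=1)
    asort = np.sort(a, axis=1)
    tied = ((asort[:, 1:] == asort[:, :-1]) & np.isfinite(asort[:, :-1])).any(axis=1)

    p = np.ones(n_cases)
    clean = ~tied & (m > 0) & (m <= exact_limit)
    for mi in np.unique(m[clean]):
        tail = _signed_rank_tail(int(mi))
        rows = clean & (m == mi)
        p[rows] = tail[np.rint(w[rows]).astype(int)]

    big = m > exact_limit
    if big.any():
        mb = m[big].astype(float)
        mu = mb * (mb + 1) / 4.0
        var = mb * (mb + 1) * (2 * mb + 1) / 24.0
        tie_rows = np.nonzero(big & tied)[0]
        tt = np.zeros(int(big.sum()))
        if tie_rows.size:
            pos = {i: j for j, i in enumerate(np.nonzero(big)[0])}
            for i in tie_rows:
                tt[pos[i]] = _tie_term(a[i])
        var = var - tt / 48.0
        z = (w[big] - mu - 0.5) / np.sqrt(np.maximum(var, _TINY))
        p[big] = np.clip(stats.norm.sf(z), _TINY, 1.0)

    for i in np.nonzero(tied & (m > 0) & (m <= exact_limit))[0]:
        p[i] = _exact_signed_rank_p(d[i])
    return p


def detection_pvalue(pm, mm, tau: float = 0.015, exact_limit: int = 12) -> float:
    """One-sided signed-rank p-value that the discrimination scores
    ``R = (PM - MM)/(PM + MM)`` exceed ``tau``.

    Pairs with ``R == tau`` are dropped before ranking.  Exact enumeration
    of all sign assignments is used for up to ``exact_limit`` informative
    pairs; beyond that a continuity-corrected normal approximation.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1 or pm.size == 0:
        raise ValueError("pm and mm must be equal-length non-empty vectors")
    tot = pm + mm
    if np.any(tot <= 0):
        raise ValueError("pm + mm must be positive for every pair")
    d = (pm - mm) / tot - tau
    m = int(np.count_nonzero(d))
    if m <= exact_limit:
        return _exact_signed_rank_p(d)
    return float(_detection_pvalues(d[None, :], exact_limit)[0])


def detection_call(p, alpha1: float = 0.04, alpha2: float = 0.06):
    """Map a detection p-value to P (< alpha1), M (< alpha2) or A."""
    if not (0.0 < alpha1 < alpha2 < 1.0):
        raise ValueError("require 0 < alpha1 < alpha2 < 1")
    arr = np.asarray(p, dtype=float)
    calls = np.where(arr < alpha1, CALL_PRESENT,
                     np.where(arr < alpha2, CALL_MARGINAL, CALL_ABSENT))
    if np.ndim(p) == 0:
        return str(calls[()])
    return calls


# ---------------------------------------------------------------------------
# Global scaling
# ---------------------------------------------------------------------------

def trimmed_mean(values, trim: float = 0.02) -> float:
    """Mean after cutting ``floor(trim * n)`` values from each tail."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("trimmed_mean of an empty vector")
    k = int(math.floor(trim * n))
    if 2 * k >= n:
        raise ValueError("trim removes every value")
    return float(x[k:n - k].mean())


def scale_array(signals, target: float = 500.0, trim: float = 0.02):
    """Scale one array's signals so their trimmed mean equals ``target``.

    Returns ``(scaled, factor)``.  Scaling is strictly per array: the
    factor depends only on this array's signals.
    """
    x = np.asarray(signals, dtype=float)
    tm = trimmed_mean(x, trim)
    if tm <= 0:
        raise ValueError("trimmed mean must be positive to scale")
    factor = target / tm
    return x * factor, factor


# ---------------------------------------------------------------------------
# Whole-dataset normalization
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probeset-by-sample MAS5 signals with detection statistics.

    ``signals`` are on the linear scale after per-array trimmed-mean
    scaling to ``target``; ``scale_factors`` holds the per-sample factor
    that was applied.
    """

    signals: pd.DataFrame
    pvalues: pd.DataFrame
    calls: pd.DataFrame
    scale_factors: pd.Series
    target: float

    def __post_init__(self) -> None:
        for other in (self.pvalues, self.calls):
            if not (other.index.equals(self.signals.index)
                    and other.columns.equals(self.signals.columns)):
                raise ValueError("signals, pvalues and calls must be aligned")
        if not self.scale_factors.index.equals(self.signals.columns):
            raise ValueError("scale_factors must cover every sample")

    @property
    def samples(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def probesets(self) -> list[str]:
        return list(self.signals.index)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.signals[samples], self.pvalues[samples],
                                self.calls[samples], self.scale_factors[samples],
                                self.target)


_LAYOUT_COLUMNS = ("probe_id", "probeset_id", "pair_index", "role")


def normalize_dataset(intensities: pd.DataFrame, layout,
                      params: Mas5Params | None = None) -> ExpressionMatrix:
    """Summarize a probe-level intensity matrix to probeset signals,
    detection p-values and P/M/A calls, then scale each array.

    ``intensities`` is probes x samples; ``layout`` maps each probe row to
    (probeset, pair index, PM/MM role) and may be a :class:`ChipLayout`
    or a bare DataFrame.
    """
    p = params or Mas5Params()
    table = layout.table if hasattr(layout, "table") else layout
    missing_cols = [c for c in _LAYOUT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"layout is missing columns: {missing_cols}")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicated probe_id in layout: {dup!r}")
    if table.duplicated(subset=["probeset_id", "pair_index", "role"]).any():
        raise ValueError("duplicated (probeset, pair, role) entry in layout")
    bad_roles = set(table["role"]) - {"PM", "MM"}
    if bad_roles:
        raise ValueError(f"unknown probe roles: {sorted(bad_roles)}")
    missing = set(table["probe_id"]) - set(intensities.index)
    if missing:
        examples = sorted(missing)[:3]
        raise ValueError(
            f"{len(missing)} layout probes missing from the intensity "
            f"matrix, e.g. {examples}")

    pm_t = table[table["role"] == "PM"].sort_values(
        ["probeset_id", "pair_index"], kind="mergesort")
    mm_t = table[table["role"] == "MM"].sort_values(
        ["probeset_id", "pair_index"], kind="mergesort")
    if (len(pm_t) != len(mm_t)
            or not np.array_equal(pm_t[["probeset_id", "pair_index"]].to_numpy(),
                                  mm_t[["probeset_id", "pair_index"]].to_numpy())):
        raise ValueError("every (probeset, pair) must have both a PM and a MM probe")

    x = intensities.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("intensity matrix contains non-finite values")
    if np.any(x < 0):
        raise ValueError("intensity matrix contains negative values")
    samples = list(intensities.columns)
    n_samples = len(samples)
    pm_rows = intensities.index.get_indexer(pm_t["probe_id"])
    mm_rows = intensities.index.get_indexer(mm_t["probe_id"])

    # integer codes per probeset (pm_t is sorted, so codes appear in order)
    codes, probeset_order = pd.factorize(pm_t["probeset_id"].to_numpy())
    counts = np.bincount(codes)

    sig_blocks, pv_blocks, id_blocks = [], [], []
    for n_pairs in np.unique(counts):
        set_codes = np.nonzero(counts == n_pairs)[0]
        ids = probeset_order[set_codes]
        mask = np.isin(codes, set_codes)
        n_sets = len(ids)
        pm3 = x[pm_rows[mask]].reshape(n_sets, n_pairs, n_samples)
        mm3 = x[mm_rows[mask]].reshape(n_sets, n_pairs, n_samples)
        tot = pm3 + mm3
        if np.any(tot <= 0):
            raise ValueError("pm + mm must be positive for every pair")
        lr = np.log2(np.maximum(pm3, _LOG_CLIP) / np.maximum(mm3, _LOG_CLIP))
        sb = tukey_biweight(lr, c=p.biweight_c, epsilon=p.biweight_epsilon,
                            axis=1)[:, None, :]
        im = _im_formula(pm3, mm3, sb, p.contrast_tau, p.scale_tau)
        v = np.maximum(pm3 - im, p.delta_floor)
        sig = 2.0 ** tukey_biweight(np.log2(v), c=p.biweight_c,
                                    epsilon=p.biweight_epsilon, axis=1)
        d = (pm3 - mm3) / tot - p.tau
        flat = np.moveaxis(d, 1, 2).reshape(-1, n_pairs)
        pv = _detection_pvalues(flat, p.exact_limit).reshape(n_sets, n_samples)
        sig_blocks.append(sig)
        pv_blocks.append(pv)
        id_blocks.append(np.asarray(ids))

    all_ids = np.concatenate(id_blocks)
    sig_df = pd.DataFrame(np.vstack(sig_blocks), index=all_ids,
                          columns=samples).loc[probeset_order]
    pv_df = pd.DataFrame(np.vstack(pv_blocks), index=all_ids,
                         columns=samples).loc[probeset_order]
    sig_df.index.name = pv_df.index.name = "probeset_id"
    calls_df = pd.DataFrame(detection_call(pv_df.to_numpy(), p.alpha1, p.alpha2),
                            index=sig_df.index, columns=samples)

    factors = pd.Series(
        {s: p.scale_target / trimmed_mean(sig_df[s].to_numpy(), p.trim)
         for s in samples}, name="scale_factor")
    factors.index = sig_df.columns
    scaled = sig_df * factors

    return ExpressionMatrix(signals=scaled, pvalues=pv_df, calls=calls_df,
                            scale_factors=factors, target=p.scale_target)
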