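"""Quantitative proteome / phosphoproteome stage.

Pipeline order is fixed: variance-stabilizing normalization, nearest-
neighbor imputation, empirical-Bayes variance moderation, moderated t-test,
Benjamini-Hochberg FDR, significance classification. Phosphosite operations
(localization-probability filtering, S/T/Y residue tally) live here too.

Normalization is a median-ratio per-sample calibration against a
geometric-mean pseudo-reference followed by the generalized logarithm

    glog2(x; lam) = log2((x + sqrt(x^2 + lam^2)) / 2),

which reduces to log2 at lam = 0 and damps the additive low-intensity noise
of label-free data. Variance moderation follows the standard hierarchical
model in which per-feature residual variances s_g^2 are shrunk toward a
prior (d0, s0^2) estimated by moments on log s_g^2; the moderated statistic
is referred to a t distribution on d0 + df degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .omics_io import IntensityMatrix

logger = logging.getLogger(__name__)


class DiffExprError(ValueError):
    pass


# --------------------------------------------------------------------------
# normalization

def glog2(x, lam: float):
    """Generalized log2; identical to log2 when lam = 0."""
    x = np.asarray(x, dtype=float)
    if lam < 0:
        raise DiffExprError("glog parameter must be non-negative")
    if lam == 0:
        return np.log2(x)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def vsn_normalize(m: IntensityMatrix, lam: float | None = None
                  ) -> IntensityMatrix:
    """Median-ratio calibration per sample, then glog2.

    Each sample is scaled so its median ratio against the geometric-mean
    pseudo-reference feature profile is one; ``lam`` defaults to the 5th
    percentile of the positive calibrated intensities. Missing cells stay
    missing; the output matrix is flagged transformed.
    """
    if m.transformed:
        raise DiffExprError("matrix is already transformed")
    x = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    if (obs.sum(axis=0) < 3).any():
        bad = [s for s, n in zip(m.sample_ids, obs.sum(axis=0)) if n < 3]
        raise DiffExprError(f"samples with <3 observed values: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # all-zero rows have no usable ratio; they drop out of the median
        warnings.simplefilter("ignore", RuntimeWarning)
        logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        logx = np.where(obs, logx, np.nan)
        ref = np.nanmean(logx, axis=1, keepdims=True)  # geometric-mean profile
        log_ratio = ref - logx
        factors = np.exp(np.nanmedian(log_ratio, axis=0))
    calibrated = x * factors[np.newaxis, :]
    if lam is None:
        pos = calibrated[obs & (calibrated > 0)]
        lam = float(np.percentile(pos, 5)) if pos.size else 0.0
    out = np.full_like(x, np.nan)
    out[obs] = glog2(calibrated[obs], lam)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.copy_with(values, transformed=True)


# --------------------------------------------------------------------------
# imputation

def knn_impute(m: IntensityMatrix, k: int = 10) -> IntensityMatrix:
    """Feature-wise k-nearest-neighbor imputation on the transformed scale.

    For each missing cell the k most similar features (RMS distance over
    mutually observed samples, at least two required, neighbor observed at
    the target sample) supply the imputed mean. Fallbacks: the feature's own
    observed mean when no neighbor is eligible; the global half-minimum when
    a feature has no observed value at all. Neighbor ties are broken by
    lexicographic feature id.
    """
    if not m.transformed:
        raise DiffExprError("impute after normalization (transformed matrix)")
    if k < 1:
        raise DiffExprError("k must be >= 1")
    x = m.values.to_numpy(dtype=float).copy()
    if not np.isnan(x).any():
        return m.copy_with(m.values.copy())
    obs = ~np.isnan(x)
    a = np.where(obs, x, 0.0)
    mask = obs.astype(float)
    sq = a * a
    # D2[i, j] = sum over mutually observed samples of (x_i - x_j)^2
    s1 = sq @ mask.T
    d2 = s1 + s1.T - 2.0 * (a @ a.T)
    counts = mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(np.maximum(d2, 0.0) / counts)
    feature_order = np.argsort(m.values.index.to_numpy())  # lexicographic
    lex_rank = np.empty(len(feature_order), dtype=np.intp)
    lex_rank[feature_order] = np.arange(len(feature_order))
    row_means = np.where(obs.any(axis=1),
                         np.nanmean(np.where(obs, x, np.nan), axis=1), np.nan)
    global_half_min = np.nanmin(x) / 2.0 if obs.any() else 0.0
    filled = x.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        eligible = (counts[i] >= 2) & np.isfinite(rms[i])
        eligible[i] = False
        idx = np.flatnonzero(eligible)
        # stable order: distance, then lexicographic feature id
        idx = idx[np.lexsort((lex_rank[idx], rms[i, idx]))]
        for s in np.flatnonzero(~obs[i]):
            cand = idx[obs[idx, s]]
            if cand.size == 0:
                if np.isfinite(row_means[i]):
                    filled[i, s] = row_means[i]
                else:
                    filled[i, s] = global_half_min
                continue
            if cand.size < k:
                logger.warning(
                    "feature %s sample %s: only %d eligible neighbor(s) "
                    "(k=%d)", m.values.index[i], m.values.columns[s],
                    cand.size, k)
            filled[i, s] = x[cand[:k], s].mean()
        if not obs[i].any():
            filled[i, :] = global_half_min
    values = pd.DataFrame(filled, index=m.values.index,
                          columns=m.values.columns)
    return m.copy_with(values)


# --------------------------------------------------------------------------
# moderated t

@dataclass
class ModerationParams:
    """Prior degrees of freedom and variance of the variance hierarchy."""

    d0: float          # prior df; may be +inf
    s0_sq: float       # prior variance
    residual_df: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise DiffExprError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise DiffExprError("s0_sq must be > 0")


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100
                      ) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        raise DiffExprError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled-F variance model s2 ~ s0^2 * F(df, d0).

    Returns (d0, s0_sq); d0 = +inf when the moment estimate of the
    log-variance dispersion is non-positive. ``df`` may be +inf, in which
    case the draws are treated as coming from s0^2 * d0 / chi2_d0 directly.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise DiffExprError("variances must be positive to fit the prior")
    z = np.log(s2)
    emean = float(z.mean())
    evar = float(z.var(ddof=1)) if z.size > 1 else 0.0
    if np.isfinite(df):
        df_term = float(special.digamma(df / 2.0) - np.log(df / 2.0))
        evar -= float(special.polygamma(1, df / 2.0))
    else:
        df_term = 0.0
    if evar <= 0:
        # no excess dispersion: infinite prior df, prior variance the mean
        return np.inf, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(
        emean - df_term + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _group_arrays(m: IntensityMatrix) -> tuple[np.ndarray, np.ndarray]:
    case = m.samples_in_group("case")
    control = m.samples_in_group("control")
    if len(case) < 2 or len(control) < 2:
        raise DiffExprError("need >=2 samples per group")
    x = m.values
    return (x[case].to_numpy(dtype=float), x[control].to_numpy(dtype=float))


def _pooled_variances(xc: np.ndarray, xk: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    n1, n2 = xc.shape[1], xk.shape[1]
    df = n1 + n2 - 2
    v1 = xc.var(axis=1, ddof=1)
    v2 = xk.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    return s2, float(df)


def fit_moderation(m: IntensityMatrix, min_s2: float = 1e-12
                   ) -> ModerationParams:
    """Estimate the variance prior from a complete transformed matrix."""
    if m.values.isna().any().any():
        raise DiffExprError("fit moderation on a complete (imputed) matrix")
    if len(m.feature_ids) < 3:
        raise DiffExprError("need >=3 features to estimate the prior")
    xc, xk = _group_arrays(m)
    s2, df = _pooled_variances(xc, xk)
    d0, s0_sq = fit_f_dist(np.maximum(s2, min_s2), df)
    return ModerationParams(d0=d0, s0_sq=s0_sq, residual_df=df)


def moderated_t_test(m: IntensityMatrix, params: ModerationParams
                     ) -> pd.DataFrame:
    """Per-feature moderated t-test (case vs control) on a complete matrix.

    Returns a frame with columns feature_id, log2fc, fold_change, t_mod, p.
    d0 = 0 reduces exactly to the ordinary pooled two-sample t; d0 = +inf
    uses the prior variance alone and a normal reference.
    """
    if m.values.isna().any().any():
        raise DiffExprError("test requires a complete (imputed) matrix")
    xc, xk = _group_arrays(m)
    n1, n2 = xc.shape[1], xk.shape[1]
    s2, df = _pooled_variances(xc, xk)
    log2fc = xc.mean(axis=1) - xk.mean(axis=1)
    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        s_post = np.full_like(s2, s0)
        ref_df = np.inf
    else:
        s_post = (d0 * s0 + df * s2) / (d0 + df)
        ref_df = d0 + df
    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    if np.any(se == 0):
        zero = se == 0
        if np.any(log2fc[zero] != 0):
            feat = m.values.index[zero & (log2fc != 0)][0]
            raise DiffExprError(
                f"zero variance with zero prior but nonzero effect "
                f"(feature {feat!r})")
        t = np.zeros_like(log2fc)
        t[~zero] = log2fc[~zero] / se[~zero]
        p = np.ones_like(log2fc)
        if np.isfinite(ref_df):
            p[~zero] = 2.0 * stats.t.sf(np.abs(t[~zero]), ref_df)
        else:
            p[~zero] = 2.0 * stats.norm.sf(np.abs(t[~zero]))
    else:
        t = log2fc / se
        if np.isfinite(ref_df):
            p = 2.0 * stats.t.sf(np.abs(t), ref_df)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.minimum(p, 1.0)
    return pd.DataFrame({
        "feature_id": m.feature_ids,
        "log2fc": log2fc,
        "fold_change": np.exp2(log2fc),
        "t_mod": t,
        "p": p,
    })


# --------------------------------------------------------------------------
# multiple testing and classification

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DiffExprError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class DEcounts:
    n_sig: int
    n_up: int
    n_down: int


def classify_de(results: pd.DataFrame, alpha: float = 0.05,
                rule: str = "raw_p") -> tuple[DEcounts, pd.DataFrame]:
    """Label features up / down / ns under a raw-p or FDR significance rule.

    Adds ``q`` (BH) and ``direction`` columns; up requires significance and a
    positive log2 fold change, down a negative one.
    """
    if rule not in ("raw_p", "fdr"):
        raise DiffExprError(f"unknown rule {rule!r}")
    out = results.copy()
    if len(out) == 0:
        out["q"] = np.array([], dtype=float)
        out["direction"] = np.array([], dtype=object)
        return DEcounts(0, 0, 0), out
    out["q"] = bh_fdr(out["p"].to_numpy())
    crit = out["p"] if rule == "raw_p" else out["q"]
    sig = crit < alpha
    direction = np.where(~sig, "ns",
                         np.where(out["log2fc"] > 0, "up", "down"))
    # a zero fold change can never be called in either direction
    direction = np.where(sig & (out["log2fc"] == 0), "ns", direction)
    out["direction"] = direction
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    return DEcounts(n_sig=n_up + n_down, n_up=n_up, n_down=n_down), out


# --------------------------------------------------------------------------
# phosphosites

REQUIRED_SITE_COLUMNS = ("peptide_id", "residue", "localization_prob")


def _check_sites(sites: pd.DataFrame) -> None:
    for col in REQUIRED_SITE_COLUMNS:
        if col not in sites.columns:
            raise DiffExprError(f"site table lacks column {col!r}")
    bad = sites.loc[~sites["residue"].isin(("S", "T", "Y")), "residue"]
    if len(bad):
        raise DiffExprError(f"unknown residue {bad.iloc[0]!r}")
    prob = sites["localization_prob"]
    if ((prob < 0) | (prob > 1)).any():
        raise DiffExprError("localization probabilities must lie in [0, 1]")


def filter_localized(sites: pd.DataFrame, threshold: float = 0.5
                     ) -> pd.DataFrame:
    """Keep sites whose localization probability strictly exceeds the
    threshold (default 0.5, i.e. the >50% rule)."""
    _check_sites(sites)
    return sites.loc[sites["localization_prob"] > threshold].copy()


def tally_residues(sites: pd.DataFrame) -> pd.DataFrame:
    """Counts and one-decimal percentages of S, T and Y phosphosites."""
    _check_sites(sites)
    counts = {r: int((sites["residue"] == r).sum()) for r in ("S", "T", "Y")}
    total = sum(counts.values())
    pct = {r: round(100.0 * c / total, 1) if total else 0.0
           for r, c in counts.items()}
    return pd.DataFrame({
        "residue": ["S", "T", "Y"],
        "count": [counts[r] for r in ("S", "T", "Y")],
        "percent": [pct[r] for r in ("S", "T", "Y")],
    })


def run_de_pipeline(m: IntensityMatrix, *, k: int = 10, alpha: float = 0.05,
                    rule: str = "raw_p", lam: float | None = None
                    ) -> tuple[DEcounts, pd.DataFrame]:
    """Normalize -> impute -> fit prior -> moderated t -> FDR -> classify."""
    norm = vsn_normalize(m, lam=lam)
    complete = knn_impute(norm, k=k)
    params = fit_moderation(complete)
    results = moderated_t_test(complete, params)
    return classify_de(results, alpha=alpha, rule=rule)
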