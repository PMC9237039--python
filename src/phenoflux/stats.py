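"""Temperature-sensitivity estimation and comparative statistics.

The temperature sensitivity of spring phenology, S_T (days per degC), is
the slope of an ordinary least-squares regression of normalized season
start anomalies on normalized previous-growing-season temperature
anomalies, fitted per site, then back-transformed to days/degC by the
ratio of raw standard deviations.  Negative S_T means warming advances
spring.  The module also provides t-based confidence intervals of
site-level slopes, partial correlation with covariate control, and
one-way ANOVA with Tukey's HSD and a compact letter display.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import CollinearityError, ConfigError


@dataclass
class STEstimate:
    site_id: str
    species_or_pft: str
    slope_norm: float
    slope_days_per_C: float
    p_value: float
    n_years: int


@dataclass
class PartialCorr:
    pair: tuple
    controls: tuple
    r_partial: float
    p_value: float
    df: int


@dataclass
class GroupComparison:
    groups: list
    anova_F: float
    anova_p: float
    tukey_p: pd.DataFrame  # symmetric matrix of pairwise p-values
    letters: dict = field(default_factory=dict)


def st_regression(sos_anom, predictor_anom, sd_sos: float, sd_predictor: float,
                  site_id: str = "", species_or_pft: str = "") -> STEstimate:
    """Per-site sensitivity: OLS slope of SOS anomalies on predictor
    anomalies, with the days/degC back-transform slope * SD(SOS)/SD(T)."""
    x = np.asarray(predictor_anom, float)
    y = np.asarray(sos_anom, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ConfigError("need >= 3 complete pairs")
    if np.std(x) == 0:
        raise ConfigError("degenerate predictor variance")
    fit = sps.linregress(x, y)
    return STEstimate(site_id, species_or_pft,
                      slope_norm=float(fit.slope),
                      slope_days_per_C=float(fit.slope * sd_sos / sd_predictor),
                      p_value=float(fit.pvalue), n_years=int(x.size))


def slope_ci(slopes, alpha: float = 0.05) -> dict:
    """Mean of site-level slopes with a t-based confidence interval;
    the effect is significant when the interval excludes zero."""
    s = np.asarray(slopes, float)
    s = s[np.isfinite(s)]
    if s.size < 3:
        raise ConfigError("need >= 3 site-level slopes")
    mean = s.mean()
    sem = s.std(ddof=1) / np.sqrt(s.size)
    if sem == 0:
        lo = hi = mean
    else:
        tcrit = sps.t.ppf(1 - alpha / 2, s.size - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    return {"mean": float(mean), "ci_low": float(lo), "ci_high": float(hi),
            "n": int(s.size), "significant": bool(lo > 0 or hi < 0)}


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, controls=None, method: str = "residuals",
                        labels: tuple | None = None) -> PartialCorr:
    """Correlation of x and y after removing linear covariate effects.

    ``method='residuals'`` correlates the residuals of x and y regressed on
    the controls (plus intercept); ``method='invcorr'`` reads the partial
    correlation off the inverse correlation matrix.  Both routes agree to
    numerical precision; the two-sided p-value uses a t approximation with
    ``df = n - 2 - #controls``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = (np.empty((x.size, 0)) if controls is None
         else np.atleast_2d(np.asarray(controls, float)))
    if C.size and C.shape[0] != x.size:
        C = C.T
    n, k = x.size, C.shape[1]
    if n <= k + 2:
        raise ConfigError("need n > #controls + 2")
    labels = labels or tuple(f"c{i}" for i in range(k))
    if k:
        Zc = C - C.mean(axis=0)
        rank = np.linalg.matrix_rank(Zc)
        if rank < k:
            bad = [labels[i] for i in range(k)
                   if np.linalg.matrix_rank(np.delete(Zc, i, axis=1)) == rank]
            raise CollinearityError(
                f"rank-deficient controls: {bad}", columns=bad)
    if method == "residuals":
        Z = np.column_stack([np.ones(n), C])
        rx = _residualize(x, Z)
        ry = _residualize(y, Z)
        # a variable explained exactly by the controls has no residual
        # variation left: the partial correlation is zero by convention
        tol_x = 1e-12 * max(float(np.var(x) * n), 1e-30)
        tol_y = 1e-12 * max(float(np.var(y) * n), 1e-30)
        if (rx @ rx) <= tol_x or (ry @ ry) <= tol_y:
            r = 0.0
        else:
            r = float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
    elif method == "invcorr":
        M = np.column_stack([x, y, C])
        P = np.linalg.inv(np.corrcoef(M, rowvar=False))
        r = float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    else:
        raise ConfigError(f"unknown method {method!r}")
    df = n - 2 - k
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorr(("x", "y"), tuple(labels), r, p, int(df))


def _compact_letter_display(groups: list, sig: pd.DataFrame) -> dict:
    """Insert-and-absorb compact letter display.

    Start from one letter set containing all groups; for every significant
    pair split each set containing both; absorb subsets; letter groups in
    input order.
    """
    sets = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            if not sig.loc[gi, gj]:
                continue
            new_sets = []
            for s in sets:
                if gi in s and gj in s:
                    new_sets.extend([s - {gi}, s - {gj}])
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            sets = [s for s in new_sets
                    if s and not any(s < t for t in new_sets)]
            # deduplicate
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g] += letter
    return letters


def anova_tukey(values_by_group: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA followed by Tukey's honestly-significant-difference
    test; groups that are statistically indistinguishable share a letter."""
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    if len(groups) < 2 or any(a.size < 2 for a in arrays):
        raise ConfigError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        p_mat = pd.DataFrame(1.0, index=groups, columns=groups)
        return GroupComparison(groups, 0.0, 1.0, p_mat,
                               {g: "a" for g in groups})
    F, p = sps.f_oneway(*arrays)
    data = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    p_mat = pd.DataFrame(1.0, index=groups, columns=groups)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    for _, row in res.iterrows():
        g1, g2, padj = row["group1"], row["group2"], float(row["p-adj"])
        p_mat.loc[g1, g2] = p_mat.loc[g2, g1] = padj
    sig = p_mat < alpha
    letters = _compact_letter_display(groups, sig)
    return GroupComparison(groups, float(F), float(p), p_mat, letters)
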