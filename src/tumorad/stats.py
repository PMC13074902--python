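"""Permutation-based group statistics for radiomic feature ratios and kinetics.

The analysis unit for features is the per-subject ratio of endpoint to
baseline feature values (accounting for the repeated-measures design).
Between-group differences are tested per feature with a permutation t-test:
the observed two-sample t statistic is referred to an empirical null built
by shuffling group labels, with the (+1)-smoothed two-sided p value

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)

so p = 0 is unattainable and Benjamini–Hochberg FDR input contracts hold.
Doubling-time group comparisons use Kruskal–Wallis followed by pairwise
Wilcoxon rank-sum tests (exact for small tie-free samples, otherwise the
normal approximation with continuity correction) and multiplicity
correction.  Correlation significance uses the same permutation scheme on
Pearson's r.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "KineticsComparison",
    "feature_ratios",
    "permutation_t_test",
    "paired_permutation_test",
    "fdr_adjust",
    "screen_features",
    "permutation_correlation",
    "compare_doubling_times",
    "normality_screen",
    "pooled_t",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    feature: str
    t_obs: float
    n_perm: int
    p_raw: float
    p_fdr: float | None
    n_a: int
    n_b: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError(f"raw p must be in (0,1], got {self.p_raw}")
        if self.p_fdr is not None and self.p_fdr < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


@dataclass(frozen=True)
class KineticsComparison:
    kw_h: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adj, method
    correction: str


def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample pooled-variance t statistic.

    Degenerate case (zero pooled variance): 0 for equal means, signed
    infinity otherwise, so the permutation ordering stays well defined.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    denom = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if denom == 0:
        return 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
    return float((ma - mb) / denom)


def _t_matrix(perm_data: np.ndarray, na: int) -> np.ndarray:
    """Pooled t for each row of a (n_perm, na+nb) permuted-data matrix."""
    nb = perm_data.shape[1] - na
    ga, gb = perm_data[:, :na], perm_data[:, na:]
    ma, mb = ga.mean(axis=1), gb.mean(axis=1)
    va = ga.var(axis=1, ddof=1)
    vb = gb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    zero = denom == 0
    if zero.any():
        diff = (ma - mb)[zero]
        t[zero] = np.where(diff == 0, 0.0, np.copysign(np.inf, diff))
    return t


def permutation_t_test(
    a,
    b,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "shuffle",
) -> PermutationResult:
    """Two-sided permutation t-test on two independent samples.

    ``method='shuffle'`` draws ``n_perm`` random label permutations and uses
    the (+1)-smoothed p; ``method='exhaustive'`` enumerates all C(n, na)
    label splits and returns the exact proportion (the observed split is one
    of them).  Missing values are dropped before testing.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"each sample needs >= 2 finite values, got {na} and {nb}")
    t_obs = pooled_t(a, b)
    data = np.concatenate([a, b])
    if math.isinf(t_obs) or (t_obs == 0.0 and data.var() == 0):
        # fully degenerate data still get a conventionally valid p
        pass
    if method == "exhaustive":
        n = na + nb
        idx_all = np.arange(n)
        count = total = 0
        for comb in itertools.combinations(range(n), na):
            ga = data[list(comb)]
            gb = data[np.setdiff1d(idx_all, comb, assume_unique=True)]
            total += 1
            if abs(pooled_t(ga, gb)) >= abs(t_obs) - 1e-12:
                count += 1
        p = count / total
        return PermutationResult("", t_obs, total, p, None, na, nb, seed)
    if method != "shuffle":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    perm = np.tile(data, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    t_perm = _t_matrix(perm, na)
    n_extreme = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + n_extreme) / (n_perm + 1)
    return PermutationResult("", t_obs, n_perm, p, None, na, nb, seed)


def paired_permutation_test(
    diffs, n_perm: int = 10_000, seed: int | None = None
) -> PermutationResult:
    """Sign-flipping permutation test on paired differences (two-sided)."""
    d = np.asarray(diffs, dtype=np.float64)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 finite paired differences")
    sd = d.std(ddof=1)
    t_obs = 0.0 if sd == 0 else float(d.mean() / (sd / math.sqrt(n)))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs * d
    m = flipped.mean(axis=1)
    s = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m / (s / math.sqrt(n))
    t_perm[s == 0] = np.where(m[s == 0] == 0, 0.0, np.inf)
    n_extreme = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + n_extreme) / (n_perm + 1)
    return PermutationResult("paired", t_obs, n_perm, p, None, n, n, seed)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)]
        raise ValueError(f"p values must lie in (0, 1], offending values: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def feature_ratios(
    baseline: pd.DataFrame,
    endpoint: pd.DataFrame,
    tol: float = 1e-12,
) -> pd.DataFrame:
    """Elementwise endpoint/baseline feature ratios, aligned on subjects.

    Both tables must be indexed by subject with identical feature columns.
    Baseline values with |value| < ``tol`` produce NaN ratios (flagged
    missing, never ±inf), with a logged count.
    """
    if not baseline.index.equals(endpoint.index):
        if set(baseline.index) != set(endpoint.index):
            raise ValueError(
                "subject mismatch between baseline and endpoint tables: "
                f"{sorted(set(baseline.index) ^ set(endpoint.index))[:5]}"
            )
        endpoint = endpoint.loc[baseline.index]
    if list(baseline.columns) != list(endpoint.columns):
        raise ValueError("feature columns differ between baseline and endpoint tables")
    b = baseline.to_numpy(dtype=np.float64)
    e = endpoint.to_numpy(dtype=np.float64)
    near_zero = np.abs(b) < tol
    with np.errstate(divide="ignore", invalid="ignore"):
        r = e / np.where(near_zero, np.nan, b)
    n_flagged = int(near_zero.sum())
    if n_flagged:
        log.warning("feature_ratios: %d near-zero baseline value(s) flagged as missing", n_flagged)
    return pd.DataFrame(r, index=baseline.index, columns=baseline.columns)


def screen_features(
    ratios: pd.DataFrame,
    groups: pd.Series,
    control_label: str,
    treatment_label: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation t-test per feature (control vs one treatment) with FDR.

    ``ratios`` is a subjects × features table; ``groups`` the per-subject
    group label.  FDR is applied across the tested features of this single
    comparison (one contrast, one control-treatment pair).  Returns a tidy
    frame with one row per feature; features with fewer than two finite
    values in either group are reported as untested (NaN p).
    """
    groups = groups.loc[ratios.index]
    for lab in (control_label, treatment_label):
        if lab not in set(groups):
            raise ValueError(f"group {lab!r} not present in the ratio table")
    in_a = groups == treatment_label
    in_b = groups == control_label
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    feat_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(ratios.shape[1])]
    rows = []
    n_skipped = 0
    for (feat, col), fseed in zip(ratios.items(), feat_seeds):
        a = col[in_a].to_numpy(dtype=np.float64)
        b = col[in_b].to_numpy(dtype=np.float64)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            n_skipped += 1
            rows.append(
                {"feature": feat, "t_obs": np.nan, "p_raw": np.nan, "n_a": len(a),
                 "n_b": len(b), "n_perm": n_perm, "seed": fseed, "tested": False}
            )
            continue
        res = permutation_t_test(a, b, n_perm=n_perm, seed=fseed)
        rows.append(
            {"feature": feat, "t_obs": res.t_obs, "p_raw": res.p_raw, "n_a": res.n_a,
             "n_b": res.n_b, "n_perm": n_perm, "seed": fseed, "tested": True}
        )
    if n_skipped:
        log.warning("screen_features: %d feature(s) untested (fewer than 2 values per group)", n_skipped)
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy()
    p_fdr = np.full(len(out), np.nan)
    if tested.any():
        p_fdr[tested] = fdr_adjust(out.loc[tested, "p_raw"].to_numpy())
    out["p_fdr"] = p_fdr
    out["significant"] = out["p_fdr"] < alpha
    out["comparison"] = f"{control_label} vs {treatment_label}"
    return out


def permutation_correlation(
    x, y, n_perm: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Pearson r with a permutation p value (shuffles of y, two-sided on |r|)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), 1.0
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    ym = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    xc = x - x.mean()
    yc = ym - ym.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    r_perm = num / den
    n_extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p = (1 + n_extreme) / (n_perm + 1)
    return r_obs, p


def _pairwise_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Wilcoxon rank-sum p: exact for small tie-free samples, else normal
    approximation with continuity correction."""
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    if len(a) <= 10 and len(b) <= 10 and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "normal+cc"


def compare_doubling_times(
    dt: pd.Series,
    groups: pd.Series,
    correction: str = "fdr",
) -> KineticsComparison:
    """Kruskal–Wallis across groups plus corrected pairwise rank-sum tests.

    Non-finite doubling times (non-growing tumors) are excluded with a
    logged count.  ``correction`` is 'fdr' (Benjamini–Hochberg) or
    'bonferroni'.
    """
    if correction not in ("fdr", "bonferroni"):
        raise ValueError(f"correction must be 'fdr' or 'bonferroni', got {correction!r}")
    dt = pd.Series(np.asarray(dt, dtype=np.float64), index=dt.index)
    finite = np.isfinite(dt)
    if (~finite).any():
        log.warning("compare_doubling_times: excluding %d non-finite DT value(s)", int((~finite).sum()))
    dt, groups = dt[finite], groups.loc[dt.index][finite]
    labels = sorted(set(groups))
    samples = {lab: dt[groups == lab].to_numpy() for lab in labels}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 finite values")
    if len(labels) >= 3:
        kw = sps.kruskal(*samples.values())
        kw_h, kw_p = float(kw.statistic), float(kw.pvalue)
    else:
        kw_h, kw_p = float("nan"), float("nan")
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        stat, p, method = _pairwise_ranksum(samples[la], samples[lb])
        rows.append({"group_a": la, "group_b": lb, "statistic": stat, "p_raw": p, "method": method})
    pw = pd.DataFrame(rows)
    if correction == "fdr":
        pw["p_adj"] = fdr_adjust(np.clip(pw["p_raw"].to_numpy(), 1e-300, 1.0))
    else:
        pw["p_adj"] = np.minimum(pw["p_raw"].to_numpy() * len(pw), 1.0)
    return KineticsComparison(kw_h=kw_h, kw_p=kw_p, pairwise=pw, correction=correction)


def normality_screen(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test; gates the nonparametric path in reports.

    Constant input has an undefined W; it is reported as (NaN, 0.0) — a
    degenerate sample is certainly non-normal.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if not (3 <= len(v) <= 5000):
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={len(v)}")
    if np.ptp(v) == 0:
        return float("nan"), 0.0
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)
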