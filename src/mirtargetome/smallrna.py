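"""Differential small-RNA expression: RPM normalization, abundance filtering,
empirical-Bayes moderated t-test, and Benjamini-Hochberg correction.

The workflow mirrors a standard bulk small-RNA-seq comparison of two groups
(e.g. lymphoma cell lines versus sorted normal B cells): per-sample counts
are scaled to reads per million (RPM), miRNAs below a raw-count floor in any
sample are dropped, and per-miRNA two-sample t-tests on log2 RPM are
moderated by shrinking the residual variances toward a common prior
estimated from all miRNAs (a scaled inverse chi-square / scaled-F
empirical-Bayes model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class CountMatrix:
    """Raw miRNA read counts (miRNA x sample) with a group label per sample."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValueError("miRNA ids and sample ids must be unique")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """RPM values and log2(RPM + pseudocount), sample columns summing to 1e6."""

    rpm: pd.DataFrame
    log2_rpm: pd.DataFrame
    groups: pd.Series
    pseudocount: float


@dataclass
class EmpiricalBayesParams:
    """Prior for the variance shrinkage: s^2 ~ s0_sq * chi2_d0 / d0.

    d0 = 0 disables moderation (classical pooled t); d0 = inf fixes every
    posterior variance at s0_sq.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative (may be inf)")
        if not (self.s0_sq > 0 and np.isfinite(self.s0_sq)):
            raise ValueError("s0_sq must be positive and finite")


def normalize_to_rpm(cm: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Scale each sample to 1,000,000 reads and take log2 with a pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    totals = cm.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    rpm = cm.counts / totals * 1e6
    return NormalizedMatrix(
        rpm=rpm,
        log2_rpm=np.log2(rpm + pseudocount),
        groups=cm.groups.copy(),
        pseudocount=pseudocount,
    )


def filter_min_count(cm: CountMatrix, min_count: int = 50) -> CountMatrix:
    """Keep miRNAs with at least ``min_count`` raw reads in every sample."""
    keep = (cm.counts >= min_count).all(axis=1)
    return CountMatrix(counts=cm.counts.loc[keep].copy(), groups=cm.groups.copy())


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_eb_params(s_sq, df: float) -> EmpiricalBayesParams:
    """Method-of-moments fit of the variance prior on the log scale.

    Under the scaled-F model, z = log(s^2) has known mean/variance offsets in
    terms of digamma/trigamma of the residual and prior degrees of freedom;
    matching the sample moments of z yields (d0, s0_sq).  When the observed
    spread of the log variances does not exceed the sampling minimum, the
    prior is degenerate and d0 = +inf.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    if len(s_sq) < 2 or (s_sq <= 0).any():
        raise ValueError("need >=2 finite positive variances")
    if df <= 0:
        raise ValueError("residual df must be positive")
    if np.allclose(s_sq, s_sq[0], rtol=1e-12, atol=0.0):
        # literally identical variances: no sampling spread at all, so the
        # prior is degenerate at the common value (no digamma correction)
        return EmpiricalBayesParams(d0=np.inf, s0_sq=float(s_sq[0]))
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return EmpiricalBayesParams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    if not np.isfinite(half_d0):
        return EmpiricalBayesParams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    s0_sq = np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0))
    return EmpiricalBayesParams(d0=float(2 * half_d0), s0_sq=float(s0_sq))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fit_moderated_ttest(
    nm: NormalizedMatrix,
    eb: EmpiricalBayesParams | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA moderated two-sample t-test on log2 RPM with BH correction.

    The pooled (equal-variance) residual variance s^2 with d = n1 + n2 - 2 df
    is shrunk to s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); the moderated statistic
    (mean1 - mean2) / (s~ * sqrt(1/n1 + 1/n2)) is referred to a t distribution
    with d0 + d degrees of freedom.  ``log2fc`` is mean(group1) - mean(group2)
    in the order given by ``group_order`` (default: sorted labels).

    Passing ``eb`` overrides the empirical-Bayes estimate; ``d0=0`` is allowed
    there and recovers the classical pooled t-test exactly.
    """
    levels = list(pd.unique(nm.groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if group_order is None:
        group_order = tuple(sorted(levels))
    elif set(group_order) != set(levels):
        raise ValueError(f"group_order {group_order} does not match groups {levels}")
    g1, g2 = group_order
    x1 = nm.log2_rpm.loc[:, nm.groups == g1].to_numpy()
    x2 = nm.log2_rpm.loc[:, nm.groups == g2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >=2 samples")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d

    if eb is None:
        eb = estimate_eb_params(s_sq[s_sq > 0], df=d)
    d0, s0_sq = eb.d0, eb.s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = (m1 - m2) / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(np.isnan(t_mod), 1.0, p)
    res = pd.DataFrame(
        {
            f"mean_{g1}": m1,
            f"mean_{g2}": m2,
            "log2fc": m1 - m2,
            "s_sq": s_sq,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": bh_adjust(p),
        },
        index=nm.log2_rpm.index,
    )
    res.attrs["eb"] = eb
    res.attrs["groups"] = (g1, g2)
    return res


def top_abundance_share(nm: NormalizedMatrix, k: int = 10) -> pd.Series:
    """Per-group share of reads carried by the k most abundant miRNAs.

    The group-mean RPM profile is taken, and the sum of its k largest entries
    is divided by 1e6 (the per-sample total).
    """
    if k > nm.rpm.shape[0]:
        raise ValueError(f"k={k} exceeds the number of miRNAs ({nm.rpm.shape[0]})")
    shares = {}
    for g in pd.unique(nm.groups):
        profile = nm.rpm.loc[:, nm.groups == g].mean(axis=1)
        shares[g] = float(profile.nlargest(k).sum() / 1e6)
    return pd.Series(shares, name=f"top{k}_share")
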