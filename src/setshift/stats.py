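"""Repeated-measures statistical battery for set-shifting experiments.

Implements the split-plot (one between-subjects x one within-subjects factor)
ANOVA with Mauchly's sphericity test and Greenhouse-Geisser / Huynh-Feldt
epsilon-adjusted degrees of freedom, per-stage one-way ANOVAs with Fisher LSD
post-hoc comparisons, paired t-tests for the set-formation contrasts, and
Pearson correlations between stages.

Sums of squares, epsilons, Mauchly's W and the LSD construction are computed
here from first principles; only p-value lookups go through scipy's
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str  # between | within | interaction
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    epsilon_gg: float
    epsilon_hf: float
    correction_used: str  # none | GG | HF
    p_corrected: float


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_lsd: float


@dataclass(frozen=True)
class OneWayAnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    pairwise: tuple[PairwiseResult, ...]


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


# --------------------------------------------------------------------------
# sphericity
# --------------------------------------------------------------------------


def _gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-level covariance matrix."""
    k = S.shape[0]
    # double-centered covariance
    row = S.mean(axis=0)
    grand = S.mean()
    D = S - row[None, :] - row[:, None] + grand
    num = np.trace(D) ** 2
    den = (k - 1) * np.sum(D * D)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def sphericity_epsilons(
    within_matrix: np.ndarray,
) -> tuple[float, float]:
    """GG and HF epsilons for a subjects x within-levels score matrix.

    With fewer than 3 within levels sphericity holds trivially and (1, 1) is
    returned.  The Huynh-Feldt value uses the single-group small-sample
    correction and may exceed 1; it is capped at 1 when adjusting degrees of
    freedom but reported uncapped here (up to its natural range).
    """
    X = np.asarray(within_matrix, dtype=float)
    if X.ndim != 2:
        raise StatsError("within_matrix must be 2-D (subjects x levels)")
    if np.isnan(X).any():
        raise StatsError("missing cells are not supported")
    n, k = X.shape
    if k < 3:
        return 1.0, 1.0
    if n < 2:
        raise StatsError("need at least 2 subjects")
    S = np.cov(X, rowvar=False)
    eps_gg = _gg_epsilon(S)
    num = n * (k - 1) * eps_gg - 2.0
    den = (k - 1) * (n - 1 - (k - 1) * eps_gg)
    eps_hf = num / den if den > 0 else 1.0
    return eps_gg, float(max(eps_gg, eps_hf))


def mauchly_test(
    X: np.ndarray, groups: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Mauchly's sphericity test; returns (W, p).

    ``X`` is subjects x within-levels.  When ``groups`` is given, the
    covariance pools within-group deviations (df = N - g).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 3:
        return 1.0, 1.0
    if groups is None:
        resid = X - X.mean(axis=0)
        df = n - 1
        g = 1
    else:
        groups = np.asarray(groups)
        resid = X.copy()
        g = len(np.unique(groups))
        for lvl in np.unique(groups):
            m = groups == lvl
            resid[m] -= X[m].mean(axis=0)
        df = n - g
    S = resid.T @ resid / df
    # orthonormal contrasts of the k levels
    C = _orthonormal_contrasts(k)
    A = C @ S @ C.T
    eig = np.linalg.eigvalsh(A)
    eig = np.clip(eig, 1e-300, None)
    p_dim = k - 1
    W = float(np.prod(eig) / (eig.mean() ** p_dim))
    d = 1 - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim * df)
    chi2 = -df * d * np.log(max(W, 1e-300))
    ddof = p_dim * (p_dim + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, ddof))
    return W, p


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.sqrt((i + 1) * (i + 2))
    return H


# --------------------------------------------------------------------------
# mixed (split-plot) ANOVA
# --------------------------------------------------------------------------


def _mixed_anova_arrays(
    Y: np.ndarray, group_labels: np.ndarray, alpha_sphericity: float = 0.05
) -> list[RmAnovaResult]:
    """Split-plot ANOVA on a subjects x within-levels matrix."""
    Y = np.asarray(Y, dtype=float)
    n_subj, k = Y.shape
    levels, counts = np.unique(group_labels, return_counts=True)
    a = len(levels)
    if a > 1 and len(set(counts)) != 1:
        raise StatsError(
            f"unbalanced design: group sizes {dict(zip(levels, counts))}"
        )
    n = counts[0]
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    subj_means = Y.mean(axis=1)
    ss_between_subj = k * float(((subj_means - grand) ** 2).sum())

    group_means = np.array([Y[group_labels == g].mean() for g in levels])
    ss_A = k * n * float(((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_A

    level_means = Y.mean(axis=0)
    ss_B = n_subj * float(((level_means - grand) ** 2).sum())

    cell_means = np.array([Y[group_labels == g].mean(axis=0) for g in levels])
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_AB = ss_cells - ss_A - ss_B

    ss_err = ss_total - ss_between_subj - ss_B - ss_AB

    df_A = a - 1
    df_subj = a * (n - 1)
    df_B = k - 1
    df_AB = (a - 1) * (k - 1)
    df_err = (k - 1) * a * (n - 1)

    if df_subj <= 0 or df_err <= 0:
        raise StatsError("not enough subjects for a mixed ANOVA")
    if ss_err <= 0 or (a > 1 and ss_subj_within <= 0):
        raise StatsError("zero error variance: effects are not testable")

    # sphericity on the within-level scores (pooled within groups)
    if k >= 3:
        _, p_mauchly = mauchly_test(Y, group_labels if a > 1 else None)
        resid = Y.copy()
        for g in levels:
            m = group_labels == g
            resid[m] -= Y[m].mean(axis=0)
        S = resid.T @ resid / (n_subj - a)
        eps_gg = _gg_epsilon(S)
        hf_num = (n_subj - a + 1) * (k - 1) * eps_gg - 2.0
        hf_den = (k - 1) * (n_subj - a - (k - 1) * eps_gg)
        eps_hf = max(eps_gg, hf_num / hf_den) if hf_den > 0 else 1.0
    else:
        p_mauchly, eps_gg, eps_hf = 1.0, 1.0, 1.0

    if p_mauchly >= alpha_sphericity:
        correction, eps_used = "none", 1.0
    elif eps_gg < 0.75:
        correction, eps_used = "GG", eps_gg
    else:
        correction, eps_used = "HF", min(1.0, eps_hf)

    results = []

    def add(effect, ss_num, df_num, ss_den, df_den, corrected: bool):
        F = (ss_num / df_num) / (ss_den / df_den)
        p_unc = float(sps.f.sf(F, df_num, df_den))
        if corrected and correction != "none":
            p_cor = float(sps.f.sf(F, df_num * eps_used, df_den * eps_used))
            used = correction
        else:
            p_cor, used = p_unc, "none"
        results.append(
            RmAnovaResult(
                effect=effect,
                F=float(F),
                df_num=float(df_num),
                df_den=float(df_den),
                p_uncorrected=p_unc,
                epsilon_gg=float(eps_gg),
                epsilon_hf=float(eps_hf),
                correction_used=used,
                p_corrected=p_cor,
            )
        )

    if a > 1:
        add("between", ss_A, df_A, ss_subj_within, df_subj, corrected=False)
    add("within", ss_B, df_B, ss_err, df_err, corrected=True)
    if a > 1:
        add("interaction", ss_AB, df_AB, ss_err, df_err, corrected=True)
    return results


def mixed_rm_anova(
    long_table: pd.DataFrame,
    between_factor: str,
    within_factor: str,
    dv: str = "value",
    subject: str = "subject",
    alpha_sphericity: float = 0.05,
) -> list[RmAnovaResult]:
    """Mixed repeated-measures ANOVA from a long-format table.

    The design must be balanced: equal subjects per group, every within level
    observed exactly once per subject.  Sphericity is tested with Mauchly's
    test at ``alpha_sphericity``; if violated, the within and interaction
    p-values use Greenhouse-Geisser-adjusted degrees of freedom when
    epsilon_GG < 0.75 and Huynh-Feldt otherwise.
    """
    required = {between_factor, within_factor, dv, subject}
    missing = required - set(long_table.columns)
    if missing:
        raise StatsError(f"long table lacks columns: {sorted(missing)}")
    wide = long_table.pivot_table(
        index=subject, columns=within_factor, values=dv, aggfunc="mean", sort=False
    )
    if wide.isna().any().any():
        raise StatsError("unbalanced design: missing subject x level cells")
    counts = long_table.groupby([subject, within_factor]).size()
    if (counts != 1).any():
        raise StatsError("each subject must contribute exactly one value per level")
    grp = (
        long_table[[subject, between_factor]]
        .drop_duplicates()
        .set_index(subject)[between_factor]
    )
    if grp.index.duplicated().any():
        raise StatsError("a subject appears in more than one group")
    groups = grp.loc[wide.index].to_numpy()
    return _mixed_anova_arrays(
        wide.to_numpy(), groups, alpha_sphericity=alpha_sphericity
    )


# --------------------------------------------------------------------------
# one-way ANOVA + Fisher LSD
# --------------------------------------------------------------------------


def oneway_anova_lsd(
    values_by_group: dict[str, Sequence[float]]
) -> OneWayAnovaResult:
    """One-way ANOVA with Fisher LSD pairwise comparisons.

    LSD uses the pooled within-group mean square and its degrees of freedom,
    with no multiplicity adjustment (that is what LSD is).
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise StatsError("need at least 2 groups")
    if any(len(x) < 2 for x in arrays):
        raise StatsError("each group needs n >= 2")
    N = sum(len(x) for x in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in arrays)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within <= 0:
        raise StatsError("zero within-group variance in all groups")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[i].mean() - arrays[j].mean()
            se = np.sqrt(ms_w * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            t = diff / se
            p_lsd = float(2 * sps.t.sf(abs(t), df_w))
            pairs.append(PairwiseResult(names[i], names[j], float(diff), p_lsd))
    return OneWayAnovaResult(float(F), df_b, df_w, p, tuple(pairs))


# --------------------------------------------------------------------------
# paired t and correlation
# --------------------------------------------------------------------------


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise StatsError("x and y must be equal-length 1-D with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance of differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), n - 1, p, float(d.mean()))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StatsError("x and y must be equal-length 1-D with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))
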