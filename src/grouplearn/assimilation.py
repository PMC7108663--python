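"""Trial-resolved assimilation: how differentiated are the predictions for a
condition's agents over learning?

For each participant, condition and presentation index k (1..50), every
agent's cumulative prediction counts through its first k presentations are
smoothed into a distribution; the condition's mean distribution is their
unweighted average; and the dispersion is the mean Jeffreys (symmetric KL)
divergence of the four agent distributions from that mean, in bits.  Small
dispersion means the participant predicts the agents of that condition
alike — the signature of assimilation.  Because the final presentation's
cumulative distribution contains all preceding trials, the condition
contrast is tested at the last index with a paired Wilcoxon signed-rank
test, and the time course of the NoLogo - Logo difference is summarized by
a logarithmic regression on ln(k).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, LOGO, NOLOGO, N_VASES, AgentSpec, block1_agents

__all__ = [
    "assimilation_series",
    "last_trial_test",
    "wilcoxon_signed_rank",
    "condition_difference_series",
    "fit_log_regression",
    "kde_scott",
    "prediction_points",
    "WilcoxonResult",
    "LogRegressionResult",
]


def _cumulative_smoothed(
    sub: pd.DataFrame, agent_ids: list[str], n_pres: int, pseudocount: float
) -> np.ndarray:
    """(agents, k, vases) cumulative smoothed prediction distributions.

    Missed presentations contribute no count but still advance k.
    """
    out = np.empty((len(agent_ids), n_pres, N_VASES))
    for i, aid in enumerate(agent_ids):
        a = sub[(sub["agent_id"] == aid) & (sub["presentation_index"] <= n_pres)]
        counts = np.zeros((n_pres, N_VASES))
        ok = ~a["missed"].to_numpy(dtype=bool)
        ks = a["presentation_index"].to_numpy(dtype=int)[ok] - 1
        vs = a["predicted_vase"].to_numpy()[ok].astype(int)
        counts[ks, vs] = 1.0
        cum = np.cumsum(counts, axis=0)
        out[i] = (cum + pseudocount) / (
            cum.sum(axis=1, keepdims=True) + N_VASES * pseudocount
        )
    return out


def _jeffreys_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise Jeffreys divergence in bits for strictly positive inputs."""
    lg = np.log2(p / q)
    return np.sum((p - q) * lg, axis=-1)


def assimilation_series(
    records: pd.DataFrame,
    designs: dict[int, list[AgentSpec]],
    pseudocount: float = 1.0,
    ks: list[int] | None = None,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Per (participant, condition, k) dispersion of agent prediction
    distributions, in bits.

    ``ks`` restricts the presentation indices evaluated (default: all
    available, i.e. 1..50 for the standard design).  ``pairwise`` replaces
    the agent-vs-mean dispersion with the mean Jeffreys divergence over all
    agent pairs (an alternative differentiation statistic).
    """
    b1 = records[records["block"] == 1]
    rows = []
    for pid, sub in b1.groupby("participant_id"):
        pid = int(pid)
        agents = designs[pid]
        for cond in CONDITIONS:
            aids = [a.agent_id for a in block1_agents(agents, cond)]
            n_pres = int(sub[sub["agent_id"].isin(aids)]["presentation_index"].max())
            use_ks = range(1, n_pres + 1) if ks is None else ks
            if max(use_ks) > n_pres:
                raise ValueError(
                    f"k={max(use_ks)} exceeds the {n_pres} presentations available"
                )
            dists = _cumulative_smoothed(sub, aids, n_pres, pseudocount)
            if pairwise:
                pairs = list(combinations(range(len(aids)), 2))
                disp = np.mean(
                    [_jeffreys_rows(dists[i], dists[j]) for i, j in pairs], axis=0
                )
            else:
                mean_dist = dists.mean(axis=0)
                disp = _jeffreys_rows(dists, mean_dist[None, :, :]).mean(axis=0)
            for k in use_ks:
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "k": int(k),
                        "dispersion_bits": float(disp[k - 1]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class WilcoxonResult:
    median_logo: float
    median_nologo: float
    statistic: float  # W+: rank sum of positive differences
    z: float
    p: float
    n: int
    method: str
    degenerate: bool = False


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p by enumeration of all sign assignments.

    Dynamic program over the distribution of W+ when every rank is included
    with probability 1/2.  Requires untied (integer) ranks.
    """
    ranks = np.asarray(np.rint(ranks), dtype=int)
    total = int(ranks.sum())
    # counts[s] = number of subsets with rank sum s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks:
        counts[r:] += counts[:-r].copy() if r else counts.copy()
    counts /= counts.sum()
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    if alternative == "greater":
        return float(min(p_ge, 1.0))
    if alternative == "less":
        return float(min(p_le, 1.0))
    return float(min(2.0 * min(p_le, p_ge), 1.0))


def wilcoxon_signed_rank(
    diffs, method: str = "auto", alternative: str = "two-sided"
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are discarded (signed-rank zero-discard convention);
    tied absolute differences share mid-ranks.  ``method`` selects the exact
    enumeration of the null distribution (``"exact"``, requires no rank
    ties), the normal approximation with continuity and tie correction
    (``"approx"``), or automatic choice (exact for n <= 25 without ties).
    The z statistic is always reported from the approximation formula.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(np.nan, np.nan, np.nan, np.nan, np.nan, 0, "degenerate", True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(ranks)) < n

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if sigma2 <= 0:
        return WilcoxonResult(np.nan, np.nan, w_plus, np.nan, np.nan, n, "degenerate", True)
    # continuity correction toward the mean
    cc = 0.5 * np.sign(w_plus - mu) if w_plus != mu else 0.0
    z = (w_plus - mu - cc) / np.sqrt(sigma2)

    if method == "auto":
        method = "exact" if (n <= 25 and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires untied ranks")
        p = _exact_signed_rank_p(w_plus, ranks, alternative)
    elif method == "approx":
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(np.nan, np.nan, w_plus, float(z), min(p, 1.0), n, method)


def last_trial_test(
    series: pd.DataFrame, k: int | None = None, method: str = "auto"
) -> WilcoxonResult:
    """Condition contrast of the dispersion at the final presentation index.

    Tests NoLogo - Logo differences across participants with the paired
    Wilcoxon signed-rank test; positive differences mean stronger
    assimilation (lower dispersion) under the Logo condition.
    """
    if k is None:
        k = int(series["k"].max())
    at_k = series[series["k"] == k]
    wide = at_k.pivot_table(
        index="participant_id", columns="condition", values="dispersion_bits"
    )
    if LOGO not in wide.columns or NOLOGO not in wide.columns or wide.isna().any().any():
        raise ValueError(f"incomplete condition pairs at k={k}")
    diffs = (wide[NOLOGO] - wide[LOGO]).to_numpy()
    if np.all(diffs == 0):
        return WilcoxonResult(
            float(np.median(wide[LOGO])), float(np.median(wide[NOLOGO])),
            np.nan, np.nan, np.nan, 0, "degenerate", True,
        )
    res = wilcoxon_signed_rank(diffs, method=method)
    res.median_logo = float(np.median(wide[LOGO]))
    res.median_nologo = float(np.median(wide[NOLOGO]))
    return res


def condition_difference_series(series: pd.DataFrame) -> pd.DataFrame:
    """Per-k mean of (NoLogo - Logo) dispersion across participants."""
    wide = series.pivot_table(
        index=["participant_id", "k"], columns="condition", values="dispersion_bits"
    )
    diff = (wide[NOLOGO] - wide[LOGO]).groupby(level="k").mean()
    return pd.DataFrame({"k": diff.index.to_numpy(), "mean_diff_bits": diff.to_numpy()})


@dataclass
class LogRegressionResult:
    beta0: float
    beta1: float
    t_beta1: float
    F: float
    df_num: int
    df_den: int
    p: float
    r_sq: float


def fit_log_regression(diff_series: pd.DataFrame) -> LogRegressionResult:
    """OLS fit of the condition-difference time course on ln(k).

    A positive slope means the conditions' dispersions separate
    logarithmically over learning.
    """
    import statsmodels.api as sm

    k = diff_series["k"].to_numpy(dtype=float)
    y = diff_series["mean_diff_bits"].to_numpy(dtype=float)
    if len(k) < 3:
        raise ValueError("need at least 3 trial points")
    if np.any(k < 1):
        raise ValueError("trial indices must be >= 1")
    x = np.log(k)
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor: need at least 2 distinct k")
    if np.ptp(y) == 0:
        # constant response: flat fit, no explained variance
        return LogRegressionResult(
            beta0=float(y[0]), beta1=0.0, t_beta1=0.0, F=0.0,
            df_num=1, df_den=len(k) - 2, p=1.0, r_sq=0.0,
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LogRegressionResult(
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        t_beta1=float(model.tvalues[1]),
        F=float(model.fvalue),
        df_num=1,
        df_den=int(model.df_resid),
        p=float(model.f_pvalue),
        r_sq=float(model.rsquared),
    )


def kde_scott(samples: np.ndarray, grid_size: int = 100, pad: float = 3.0):
    """Gaussian kernel density estimate with Scott's bandwidth rule.

    ``samples`` is (n,) for a univariate or (n, 2) for a bivariate
    estimate.  The per-dimension bandwidth is n^(-1/(d+4)) * sigma_j.
    Returns ``(grid, density, bandwidths)`` where for d=2 the grid is a
    meshgrid pair and the density a (grid_size, grid_size) surface.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if d > 2:
        raise ValueError("only 1-D or 2-D densities are supported")
    sig = x.std(axis=0, ddof=1)
    if np.any(sig == 0):
        raise ValueError("zero variance along a dimension")
    kde = stats.gaussian_kde(x.T, bw_method="scott")
    bandwidths = n ** (-1.0 / (d + 4)) * sig
    axes = [
        np.linspace(x[:, j].min() - pad * sig[j], x[:, j].max() + pad * sig[j], grid_size)
        for j in range(d)
    ]
    if d == 1:
        dens = kde(axes[0])
        return axes[0], dens, bandwidths
    gx, gy = np.meshgrid(axes[0], axes[1])
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return (gx, gy), dens, bandwidths


def prediction_points(
    records: pd.DataFrame, designs: dict[int, list[AgentSpec]]
) -> pd.DataFrame:
    """Per (participant, agent) marginal prediction probabilities for KDE
    summaries: the smoothed Block-1 prediction distribution reduced to its
    color- and shape-phenotype-A marginals."""
    from .divergence import prediction_distribution

    rows = []
    b1 = records[records["block"] == 1]
    for pid, sub in b1.groupby("participant_id"):
        pid = int(pid)
        for agent in block1_agents(designs[pid]):
            pdist = prediction_distribution(
                sub, agent_id=agent.agent_id, smoothing_mode="always"
            )
            p = pdist.probs
            rows.append(
                {
                    "participant_id": pid,
                    "agent_id": agent.agent_id,
                    "condition": agent.condition,
                    "p_color": float(p[0] + p[1]),
                    "p_shape": float(p[0] + p[2]),
                }
            )
    return pd.DataFrame(rows)
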