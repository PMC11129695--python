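"""Group comparisons of display summaries and the bootstrap-fed mixed model.

Three comparisons are provided, matching a standard ethological workflow:

* an omnibus Kruskal–Wallis test over all groups, followed by all pairwise
  two-sample rank-sum (Mann–Whitney U) tests with Bonferroni adjustment over
  the pairwise family;
* a Spearman rank correlation of mean movement interval against water
  temperature;
* a linear mixed model of movement interval on lure group with a
  per-recording random intercept, fed by per-recording bootstrap resamples
  (default 1,000 values each) so that individuals contribute equally
  regardless of how many movements they displayed.  Fixed effects are tested
  with Satterthwaite-approximated denominator degrees of freedom.

The rank-sum statistic reported per pair is the U statistic of the first
group, which for tie-free samples equals the W that R's ``wilcox.test``
prints; complete separation with the first group shifted low gives W = 0.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DisplaySummary

logger = logging.getLogger("luregait")

METRICS = ("mean_interval", "interval_sd", "mean_duration", "proportion_sync")

#: Largest tie-free sample size for which the rank-sum test is run exactly.
EXACT_RANKSUM_MAX_N = 25


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float  # rank-sum U of group_a
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparisonResult:
    metric: str
    side: str
    h_statistic: float
    h_pvalue: float
    pairwise: list[PairwiseTest] = field(default_factory=list)
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"metric": self.metric, "group_a": t.group_a, "group_b": t.group_b,
              "W": t.statistic, "p_raw": t.p_raw, "p_adjusted": t.p_adjusted}
             for t in self.pairwise]
        )


def _collect(
    summaries: list[DisplaySummary],
    grouping: dict[str, str],
    metric: str,
    side: str,
) -> dict[str, np.ndarray]:
    values: dict[str, list[float]] = {}
    for s in summaries:
        group = grouping.get(s.recording_id)
        if group is None:
            continue
        v = s.metric(metric, side)
        values.setdefault(group, [])
        if v is not None:
            values[group].append(float(v))
    for group, vals in values.items():
        if not vals:
            raise ValueError(
                f"metric {metric!r} absent for every member of group {group!r}"
            )
    return {g: np.asarray(v) for g, v in values.items()}


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample rank-sum (Mann–Whitney U) test; U of ``x`` reported.

    Exact for tie-free samples up to :data:`EXACT_RANKSUM_MAX_N` per group,
    normal approximation with continuity correction otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.allclose(np.concatenate([x, y]), x[0]):
        return len(x) * len(y) / 2.0, 1.0  # all-tied degenerate case
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    exact = tie_free and max(len(x), len(y)) <= EXACT_RANKSUM_MAX_N
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    summaries: list[DisplaySummary],
    grouping: dict[str, str],
    metric: str,
    side: str = "left",
) -> GroupComparisonResult:
    """Kruskal–Wallis omnibus plus Bonferroni-adjusted pairwise rank-sum tests."""
    if metric not in METRICS:
        raise KeyError(f"metric must be one of {METRICS}, got {metric!r}")
    values = _collect(summaries, grouping, metric, side)
    if len(values) < 2:
        raise ValueError(f"need at least 2 groups, got {len(values)}")

    groups = sorted(values)
    samples = [values[g] for g in groups]
    if all(np.allclose(s, samples[0][0]) for s in samples):
        h, h_p = 0.0, 1.0  # all values identical: no signal by construction
    else:
        h, h_p = stats.kruskal(*samples)

    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for ga, gb in itertools.combinations(groups, 2):
        w, p = rank_sum_test(values[ga], values[gb])
        pairwise.append(
            PairwiseTest(ga, gb, w, p, min(1.0, p * n_pairs))
        )
    return GroupComparisonResult(
        metric=metric, side=side, h_statistic=float(h), h_pvalue=float(h_p),
        pairwise=pairwise, group_sizes={g: len(values[g]) for g in groups},
    )


def temperature_correlation(
    summaries: list[DisplaySummary],
    side: str = "left",
) -> tuple[float, float]:
    """Spearman correlation of water temperature with mean movement interval."""
    pairs = [
        (s.water_temp, s.metric("mean_interval", side))
        for s in summaries
        if s.water_temp is not None and s.metric("mean_interval", side) is not None
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need at least 3 summaries with temperature and interval, got {len(pairs)}"
        )
    temp, interval = zip(*pairs)
    rho, p = stats.spearmanr(temp, interval)
    return float(rho), float(p)


def bootstrap_movements(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n_boot`` values with replacement from one recording's intervals."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty value set")
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return rng.choice(values, size=n_boot, replace=True)


# ---------------------------------------------------------------------------
# Mixed model with Satterthwaite denominator degrees of freedom
# ---------------------------------------------------------------------------

@dataclass
class FixedEffectTest:
    """Satterthwaite t-test of one group's mean difference from the reference."""

    group: str
    estimate: float  # difference from reference group, seconds
    se: float
    df: float
    p: float


@dataclass
class MixedModelResult:
    group_means: dict[str, float]          # fitted mean interval per group (s)
    group_mean_se: dict[str, float]
    reference_group: str
    contrasts: list[FixedEffectTest]
    random_intercept_variance: float       # between-recording variance (s^2)
    residual_variance: float               # within-recording variance (s^2)
    n_boot: int
    seed: int
    singular: bool = False
    n_recordings: int = 0


def _profile_beta_cov(
    theta: np.ndarray,
    X_blocks: list[np.ndarray],
    y_blocks: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, float]:
    """GLS quantities for a random-intercept model at variance parameters theta.

    theta = (tau2, sigma2): between-recording and residual variances.  Each
    block is one recording, with covariance sigma2*I + tau2*J, whose inverse
    is (1/sigma2) (I - tau2/(sigma2 + n*tau2) J).  Returns (beta_hat,
    cov(beta_hat), restricted log-likelihood).
    """
    tau2, sigma2 = float(theta[0]), float(theta[1])
    p = X_blocks[0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v = 0.0
    for X, y in zip(X_blocks, y_blocks):
        n = len(y)
        shrink = tau2 / (sigma2 + n * tau2)
        Xs, ys = X.sum(axis=0), y.sum()
        xtvx += (X.T @ X - shrink * np.outer(Xs, Xs)) / sigma2
        xtvy += (X.T @ y - shrink * Xs * ys) / sigma2
        logdet_v += (n - 1) * np.log(sigma2) + np.log(sigma2 + n * tau2)
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ xtvy
    quad = 0.0
    for X, y in zip(X_blocks, y_blocks):
        n = len(y)
        shrink = tau2 / (sigma2 + n * tau2)
        r = y - X @ beta
        quad += (r @ r - shrink * r.sum() ** 2) / sigma2
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    reml = -0.5 * (logdet_v + logdet_xtvx + quad)
    return beta, cov_beta, reml


def _satterthwaite_df(
    contrast: np.ndarray,
    theta: np.ndarray,
    X_blocks: list[np.ndarray],
    y_blocks: list[np.ndarray],
) -> float:
    """Satterthwaite df for c' beta: 2 f^2 / Var(f), f = c' cov(beta) c.

    The gradient of f and the curvature of the restricted likelihood are
    taken numerically from the closed-form profile above.
    """
    theta = np.asarray(theta, float)
    h = np.maximum(1e-6, 1e-4 * np.maximum(theta, 1e-8))

    def f(th):
        _, cov, _ = _profile_beta_cov(th, X_blocks, y_blocks)
        return float(contrast @ cov @ contrast)

    def reml(th):
        return _profile_beta_cov(th, X_blocks, y_blocks)[2]

    grad = np.zeros(2)
    for k in range(2):
        e = np.zeros(2); e[k] = h[k]
        lo = np.maximum(theta - e, 1e-12)
        grad[k] = (f(theta + e) - f(lo)) / (theta[k] + e[k] - lo[k])

    hess = np.zeros((2, 2))
    for k in range(2):
        for l in range(k, 2):
            ek = np.zeros(2); ek[k] = h[k]
            el = np.zeros(2); el[l] = h[l]
            pp = reml(np.maximum(theta + ek + el, 1e-12))
            pm = reml(np.maximum(theta + ek - el, 1e-12))
            mp = reml(np.maximum(theta - ek + el, 1e-12))
            mm = reml(np.maximum(theta - ek - el, 1e-12))
            hess[k, l] = hess[l, k] = (pp - pm - mp + mm) / (4 * h[k] * h[l])
    try:
        cov_theta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return float("nan")
    var_f = float(grad @ cov_theta @ grad)
    f0 = f(theta)
    if var_f <= 0 or not np.isfinite(var_f):
        return float("nan")
    return 2.0 * f0 ** 2 / var_f


def fit_interval_mixed_model(
    bootstrapped: dict[str, np.ndarray],
    grouping: dict[str, str],
    seed: int = 0,
    n_boot: int | None = None,
) -> MixedModelResult:
    """REML random-intercept model of interval on lure group.

    ``bootstrapped`` maps recording_id to its resampled interval values (see
    :func:`bootstrap_movements`).  The model is interval ~ group with a random
    intercept per recording; the random intercept absorbs the bootstrap
    inflation of per-recording n, so group contrasts are driven by
    between-recording variation.  Contrast tests use Satterthwaite df.  A
    near-zero between-recording variance flags the fit as singular; estimates
    are still reported.
    """
    import statsmodels.formula.api as smf

    if not bootstrapped:
        raise ValueError("no bootstrap value sets supplied")
    groups_present = sorted({grouping[r] for r in bootstrapped})
    if len(groups_present) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups_present)}")

    rows = []
    for rid, vals in bootstrapped.items():
        vals = np.asarray(vals, float)
        if vals.size == 0:
            raise ValueError(f"recording {rid!r} has an empty bootstrap set")
        rows.append(pd.DataFrame(
            {"interval": vals, "recording_id": rid, "group": grouping[rid]}
        ))
    data = pd.concat(rows, ignore_index=True)
    reference = groups_present[0]
    data["group"] = pd.Categorical(
        data["group"], categories=groups_present, ordered=False
    )

    model = smf.mixedlm("interval ~ C(group)", data, groups=data["recording_id"])
    tau2 = sigma2 = float("nan")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        tau2 = float(np.asarray(fit.cov_re)[0, 0])
        sigma2 = float(fit.scale)
    except (np.linalg.LinAlgError, ValueError):
        pass
    if not (np.isfinite(tau2) and np.isfinite(sigma2) and sigma2 > 0):
        # Degenerate data (e.g. zero between-recording variance) can defeat
        # the REML optimizer; fall back to ANOVA moment estimators.
        within = data.groupby("recording_id")["interval"].var(ddof=1).fillna(0.0)
        sigma2 = float(max(within.mean(), 1e-12))
        means = data.groupby("recording_id")["interval"].mean()
        n_bar = float(data.groupby("recording_id").size().mean())
        tau2 = float(max(means.var(ddof=1) - sigma2 / n_bar, 0.0))
        logger.warning("mixed model: REML fit failed; using moment estimators")
    singular = tau2 < 1e-10 * max(sigma2, 1e-12)
    if singular:
        logger.warning("mixed model: between-recording variance ~ 0 (singular fit)")

    # Closed-form blocks (one per recording) for the Satterthwaite machinery.
    X_blocks, y_blocks = [], []
    design_cols = groups_present  # cell-means handled via treatment coding
    for rid, sub in data.groupby("recording_id", sort=True):
        X = np.ones((len(sub), len(design_cols)))
        for k, g in enumerate(groups_present[1:], start=1):
            X[:, k] = (sub["group"] == g).to_numpy(float)
        X_blocks.append(X)
        y_blocks.append(sub["interval"].to_numpy(float))

    theta = np.array([max(tau2, 0.0), sigma2])
    beta, cov_beta, _ = _profile_beta_cov(theta, X_blocks, y_blocks)

    group_means, group_se = {}, {}
    for k, g in enumerate(groups_present):
        c = np.zeros(len(groups_present)); c[0] = 1.0
        if k > 0:
            c[k] = 1.0
        group_means[g] = float(c @ beta)
        group_se[g] = float(np.sqrt(c @ cov_beta @ c))

    contrasts = []
    for k, g in enumerate(groups_present[1:], start=1):
        c = np.zeros(len(groups_present)); c[k] = 1.0
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov_beta @ c))
        df = _satterthwaite_df(c, theta, X_blocks, y_blocks)
        if np.isfinite(df) and df > 0:
            p = float(2 * stats.t.sf(abs(est) / se, df)) if se > 0 else 1.0
        else:
            p = float("nan")
        contrasts.append(FixedEffectTest(group=g, estimate=est, se=se, df=df, p=p))

    nb = n_boot if n_boot is not None else int(
        np.median([len(v) for v in bootstrapped.values()])
    )
    return MixedModelResult(
        group_means=group_means, group_mean_se=group_se,
        reference_group=reference, contrasts=contrasts,
        random_intercept_variance=max(tau2, 0.0), residual_variance=sigma2,
        n_boot=nb, seed=seed, singular=singular,
        n_recordings=len(bootstrapped),
    )


def bootstrap_and_fit(
    interval_sets: dict[str, np.ndarray],
    grouping: dict[str, str],
    n_boot: int = 1000,
    seed: int = 0,
) -> MixedModelResult:
    """Bootstrap each recording's intervals, then fit the mixed model.

    One child seed per recording is spawned deterministically from ``seed``
    (sorted recording order), so results are reproducible and independent of
    dict insertion order.
    """
    root = np.random.default_rng(seed)
    boot: dict[str, np.ndarray] = {}
    for rid in sorted(interval_sets):
        boot[rid] = bootstrap_movements(interval_sets[rid], n_boot, root)
    return fit_interval_mixed_model(boot, grouping, seed=seed, n_boot=n_boot)
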