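"""Per-cohort two-group differential expression with empirical-Bayes moderated t.

The model is the standard two-group linear model per gene: the effect is the
case-minus-control difference of means (a log2 fold change), the residual
variance s2_g is pooled within groups with d_g = n1 + n2 - 2 degrees of
freedom. Gene-wise variances are shrunk toward a common prior by fitting a
scaled inverse-chi-square prior (d0, s0^2) to the observed variances with the
closed-form moment method of Smyth (2004): the posterior variance

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

replaces s2_g in the t statistic, which then has d0 + d_g degrees of freedom.
With few samples per cohort (down to 2 vs 2 here) this moderation is what
makes per-cohort p-values usable at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ExpressionStudy

#: Stand-in for an infinite prior degrees of freedom.
D0_CAP = 1e6


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on gene-wise variances.

    ``d0`` is the prior degrees of freedom (capped at 1e6 to encode infinity),
    ``s0sq`` the prior variance scale.
    """

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0sq > 0:
            raise ValueError("s0sq must be positive")


def fit_group_stats(study: ExpressionStudy) -> pd.DataFrame:
    """Per-feature two-group statistics: effect, pooled variance, df, design variance.

    Returns a frame indexed by feature with columns ``beta`` (case - control
    mean difference), ``s2`` (pooled residual variance), ``d`` (residual df)
    and ``v`` (unscaled variance of beta, 1/n1 + 1/n2).
    """
    case = study.values[:, study.case_mask]
    ctrl = study.values[:, study.control_mask]
    n1, n2 = case.shape[1], ctrl.shape[1]
    beta = case.mean(axis=1) - ctrl.mean(axis=1)
    rss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss += ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = rss / d
    return pd.DataFrame(
        {"beta": beta, "s2": s2, "d": float(d), "v": 1.0 / n1 + 1.0 / n2},
        index=pd.Index(study.features, name="feature"),
    )


def trigamma_inverse(y: float, rel_tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing trigamma with the standard 1/x-scale Newton
    step; converges in a handful of iterations from x = 0.5 + 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    # asymptotic guards: psi'(x) ~ 1/x for large x, ~ 1/x^2 for small x
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < rel_tol:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: np.ndarray) -> VariancePrior:
    """Moment-method fit of the variance prior (d0, s0^2) from sample variances.

    Works on the log scale: e_g = ln s2_g - psi(d_g/2) + ln(d_g/2) is an
    unbiased estimate of ln sigma2_g; the excess variance of e over the
    trigamma term identifies d0, the corrected mean identifies s0^2. When the
    observed spread is no larger than sampling noise, d0 is capped (the prior
    is effectively a point mass).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    keep = s2 > 0
    if not keep.any():
        raise ValueError("degenerate variance distribution: all variances zero")
    s2, d = s2[keep], d[keep]
    G = s2.size
    if G < 10:
        raise ValueError(f"need >=10 positive variances to fit the prior, got {G}")

    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_bar = e.mean()
    target = np.mean((e - e_bar) ** 2 * G / (G - 1) - special.polygamma(1, d / 2.0))
    if target <= 0:
        return VariancePrior(d0=D0_CAP, s0sq=float(np.exp(e_bar)))
    half_d0 = trigamma_inverse(float(target))
    d0 = 2.0 * half_d0
    s0sq = float(np.exp(e_bar + special.digamma(half_d0) - np.log(half_d0)))
    return VariancePrior(d0=min(d0, D0_CAP), s0sq=s0sq)


def moderated_t(beta, s2, d, v, prior: VariancePrior):
    """Moderated t statistic, total df and two-sided p for each feature.

    The posterior variance is the df-weighted blend of prior and observed
    variance; the statistic is beta / sqrt(s~2 * v) on d0 + d df.
    """
    beta = np.asarray(beta, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    s2_post = (prior.d0 * prior.s0sq + d * s2) / (prior.d0 + d)
    t = beta / np.sqrt(s2_post * v)
    df = np.minimum(prior.d0 + d, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


class ModeratedTTest:
    """Two-group moderated-t differential expression model for one cohort.

    Examples
    --------
    >>> results = ModeratedTTest(study).fit()
    >>> results.table.head()
    """

    def __init__(self, study: ExpressionStudy):
        self.study = study

    def fit(self, prior: VariancePrior | None = None) -> "DEResults":
        """Estimate the variance prior (unless given) and moderate every gene."""
        from .meta import bh_adjust  # shared BH implementation

        base = fit_group_stats(self.study)
        if prior is None:
            prior = estimate_variance_prior(base["s2"].to_numpy(), base["d"].to_numpy())
        t, df, p = moderated_t(
            base["beta"].to_numpy(), base["s2"].to_numpy(),
            base["d"].to_numpy(), base["v"].to_numpy(), prior,
        )
        table = base.assign(t=t, df=df, p=p, q=bh_adjust(p))
        return DEResults(study_id=self.study.study_id, table=table, prior=prior,
                         feature_to_gene=self.study.feature_to_gene)


class DEResults:
    """Fitted per-cohort differential expression results.

    Attributes
    ----------
    table : DataFrame
        Indexed by feature; columns beta, s2, d, v, t, df, p, q.
    prior : VariancePrior
        The empirical-Bayes hyperparameters used for moderation.
    """

    def __init__(self, study_id: str, table: pd.DataFrame, prior: VariancePrior,
                 feature_to_gene: dict[str, str] | None = None):
        self.study_id = study_id
        self.table = table
        self.prior = prior
        self.feature_to_gene = feature_to_gene

    @property
    def n_features(self) -> int:
        return len(self.table)

    def significant(self, fdr_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr_max]

    def summary(self) -> str:
        n_sig = int((self.table["q"] < 0.05).sum())
        lines = [
            f"Moderated t-test results: {self.study_id}",
            f"  features:           {self.n_features}",
            f"  prior df (d0):      {self.prior.d0:.4g}",
            f"  prior scale (s0^2): {self.prior.s0sq:.4g}",
            f"  q < 0.05:           {n_sig}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def run_de(study: ExpressionStudy) -> DEResults:
    """Convenience wrapper: fit the moderated-t model with an estimated prior."""
    return ModeratedTTest(study).fit()
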