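"""Sample-size and power calculators for the trial design.

Two families of computation:

* Power for detecting a between-arm difference in the mean of several
  correlated follow-up depression scores (HDRS-17), with the baseline
  score used as an ANCOVA covariate and uniform loss to follow-up.
* Fisher-z power and minimum-detectable-effect calculations for
  correlations between imaging measures and symptom change.

Both use the normal approximation; a Student-t variant of the
repeated-follow-up power is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TrialDesign",
    "CorrelationPowerSpec",
    "power_mean_followups",
    "power_correlation",
    "required_correlation",
]


@dataclass
class TrialDesign:
    """Design parameters for the repeated-follow-up mean-difference power.

    Parameters
    ----------
    n_total:
        Total randomized sample size across both arms, before dropout.
    effect:
        Between-arm difference in the mean follow-up score (HDRS-17 points).
    sd:
        Common standard deviation of a single score (points).
    r_follow:
        Correlation between any two follow-up measurements.
    r_baseline:
        Correlation between the baseline score and each follow-up score.
    k_followups:
        Number of follow-up time points averaged into the outcome.
    dropout:
        Fraction of randomized participants lost to follow-up.
    alpha:
        Significance level.
    tails:
        1 or 2.
    """

    n_total: int
    effect: float = 3.0
    sd: float = 8.0
    r_follow: float = 0.7
    r_baseline: float = 0.27
    k_followups: int = 3
    dropout: float = 0.2
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self) -> None:
        if self.n_total < 4:
            raise ValueError("n_total must be at least 4")
        if not (0 <= self.r_follow < 1 and 0 <= self.r_baseline < 1):
            raise ValueError("correlations must lie in [0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.k_followups < 1:
            raise ValueError("k_followups must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class CorrelationPowerSpec:
    """Specification for Fisher-z correlation power (and its inversion)."""

    n: int
    rho0: float = 0.0
    rho1: float = 0.0
    alpha: float = 0.05
    tails: int = 2
    power: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n <= 3:
            raise ValueError("n must exceed 3 for the Fisher-z approximation")
        if not (abs(self.rho0) < 1 and abs(self.rho1) < 1):
            raise ValueError("correlations must have magnitude < 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def _adjusted_outcome_sd(design: TrialDesign) -> float:
    """SD of the baseline-adjusted mean of k correlated follow-ups.

    var(mean of k follow-ups) = sigma^2 (1 + (k-1) r_f) / k; the ANCOVA
    baseline adjustment multiplies it by (1 - r_bm^2) where r_bm is the
    correlation between baseline and the follow-up mean,
    r_bm = r_b * sqrt(k / (1 + (k-1) r_f)).
    """
    k = design.k_followups
    var_mean = design.sd**2 * (1 + (k - 1) * design.r_follow) / k
    r_bm = design.r_baseline * np.sqrt(k / (1 + (k - 1) * design.r_follow))
    return float(np.sqrt(var_mean * (1 - r_bm**2)))


def power_mean_followups(design: TrialDesign, use_t: bool = False) -> float:
    """Power to detect ``design.effect`` in the mean follow-up score.

    The per-arm analyzed sample size is ``round(n_total (1 - dropout) / 2)``
    (whole participants). With standard error
    ``se = sd_adj * sqrt(2 / n_arm)`` the normal-approximation power is
    ``Phi(delta/se - z_c) + Phi(-delta/se - z_c)`` where ``z_c`` is the
    upper alpha/tails normal quantile; for a null effect this reduces
    exactly to alpha. Set ``use_t`` for the noncentral-t variant with
    ``2 n_arm - 2`` degrees of freedom.
    """
    sd_adj = _adjusted_outcome_sd(design)
    n_arm = round(design.n_total * (1 - design.dropout) / 2)
    if n_arm < 2:
        raise ValueError("fewer than 2 participants per arm after dropout")
    se = sd_adj * np.sqrt(2.0 / n_arm)
    lam = design.effect / se
    if use_t:
        df = 2 * n_arm - 2
        tc = stats.t.ppf(1 - design.alpha / design.tails, df)
        upper = 1 - stats.nct.cdf(tc, df, lam)
        lower = stats.nct.cdf(-tc, df, lam) if design.tails == 2 else 0.0
        return float(upper + lower)
    zc = stats.norm.ppf(1 - design.alpha / design.tails)
    upper = stats.norm.cdf(lam - zc)
    lower = stats.norm.cdf(-lam - zc) if design.tails == 2 else 0.0
    return float(upper + lower)


def power_correlation(spec: CorrelationPowerSpec) -> float:
    """Power to distinguish ``rho1`` from ``rho0`` via the Fisher z test.

    Uses z(rho) = atanh(rho) with sampling SD 1/sqrt(n-3). Both rejection
    tails are counted for a two-sided test, so ``rho1 == rho0`` returns
    exactly alpha.
    """
    dz = abs(np.arctanh(spec.rho1) - np.arctanh(spec.rho0))
    lam = dz * np.sqrt(spec.n - 3)
    zc = stats.norm.ppf(1 - spec.alpha / spec.tails)
    upper = stats.norm.cdf(lam - zc)
    lower = stats.norm.cdf(-lam - zc) if spec.tails == 2 else 0.0
    return float(upper + lower)


def required_correlation(
    n: int,
    power: float,
    alpha: float = 0.05,
    tails: int = 1,
    rho0: float = 0.0,
) -> float:
    """Smallest correlation magnitude detectable with the given power.

    Inverts the dominant-tail Fisher-z power formula:
    ``|rho| = tanh( z(rho0) + (z_{1-alpha/tails} + z_power) / sqrt(n-3) )``.
    The result is exact (not rounded); round only for presentation.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not alpha < power < 1:
        raise ValueError("power must lie in (alpha, 1)")
    zc = stats.norm.ppf(1 - alpha / tails)
    zp = stats.norm.ppf(power)
    return float(np.tanh(np.arctanh(rho0) + (zc + zp) / np.sqrt(n - 3)))
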