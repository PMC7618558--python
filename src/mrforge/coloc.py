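"""Approximate-Bayes-factor colocalization over a cis region.

Under a single-causal-variant assumption per trait, each variant's evidence
for association is a Wakefield approximate Bayes factor computed from its
summary effect and standard error.  Summing Bayes factors over the possible
causal-variant assignments yields posterior probabilities for five
hypotheses:

* H0 - no causal variant for either trait;
* H1 - a causal variant for trait 1 only;
* H2 - a causal variant for trait 2 only;
* H3 - distinct causal variants for the two traits;
* H4 - one shared causal variant.

A conditional colocalization probability, PP(H4) / (PP(H3) + PP(H4)),
quantifies the evidence for sharing given that both traits have a causal
variant in the region.  All hypothesis arithmetic is done in log space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Default per-variant prior probabilities: causal for trait 1 only (p1),
#: trait 2 only (p2), both (p12).
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: Default prior standard deviation of a true effect (per trait); 0.2 on the
#: SD scale for quantitative traits, 0.2 on the log-odds scale for
#: case-control traits.
DEFAULT_PRIOR_SD = 0.2


class NotEvaluable(enum.Enum):
    """Typed outcome for a quantity whose defining ratio has a zero denominator."""

    token = "not-evaluable"


NOT_EVALUABLE = NotEvaluable.token


@dataclass
class RegionalPair:
    """Per-variant summary effects of two traits over one region.

    ``df`` columns: variant_id, beta_t1, se_t1, beta_t2, se_t2.
    """

    df: pd.DataFrame
    trait_types: tuple[str, str] = ("quantitative", "case_control")
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    prior_sd: tuple[float, float] = (DEFAULT_PRIOR_SD, DEFAULT_PRIOR_SD)

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("region must contain at least one variant")
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        for t in self.trait_types:
            if t not in ("quantitative", "case_control"):
                raise ValueError(f"unknown trait type {t!r}")
        if not ((self.df["se_t1"] > 0).all() and (self.df["se_t2"] > 0).all()):
            raise ValueError("all standard errors must be > 0")


@dataclass
class ColocResult:
    """Posterior probabilities of the five hypotheses plus the conditional one."""

    pp: np.ndarray  # H0..H4, sums to 1
    conditional_h4: float | NotEvaluable
    n_variants: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.pp)) - 1.0) > 1e-9:
            raise ValueError("posteriors must sum to 1")


def wakefield_log_abf(beta, se, W: float) -> np.ndarray:
    """Log approximate Bayes factor for association at one variant.

    With z = beta/se and shrinkage r = W / (W + se^2):
    log ABF = 0.5 * (log(1 - r) + r * z^2).  W is the prior variance of a
    true effect.  Vectorized over ``beta``/``se``.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0) or W <= 0:
        raise ValueError("se and W must be positive")
    r = W / (W + se**2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def conditional_h4(pp: np.ndarray) -> float | NotEvaluable:
    """PP(H4) / (PP(H3) + PP(H4)); not-evaluable when the denominator is 0."""
    denom = pp[3] + pp[4]
    if denom == 0:
        return NOT_EVALUABLE
    return float(pp[4] / denom)


def coloc_posteriors(region: RegionalPair) -> ColocResult:
    """Posterior hypothesis probabilities for a regional trait pair.

    With per-variant Bayes factors BF1_j, BF2_j:

    * H0 is proportional to 1
    * H1 to p1 * sum_j BF1_j
    * H2 to p2 * sum_j BF2_j
    * H3 to p1 * p2 * (sum_j BF1_j * sum_k BF2_k - sum_j BF1_j * BF2_j)
    * H4 to p12 * sum_j BF1_j * BF2_j

    Sums are evaluated with log-sum-exp; a single-variant region has an
    exactly zero H3 term.
    """
    df = region.df
    W1, W2 = (sd**2 for sd in region.prior_sd)
    l1 = wakefield_log_abf(df["beta_t1"], df["se_t1"], W1)
    l2 = wakefield_log_abf(df["beta_t2"], df["se_t2"], W2)

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)

    lh = np.full(5, -np.inf)
    lh[0] = 0.0
    lh[1] = np.log(region.p1) + ls1
    lh[2] = np.log(region.p2) + ls2
    # H3: cross terms = S1*S2 - S12, computed as a signed log-sum-exp
    diff, sign = logsumexp([ls1 + ls2, ls12], b=[1.0, -1.0], return_sign=True)
    if sign > 0 and np.isfinite(diff):
        lh[3] = np.log(region.p1) + np.log(region.p2) + diff
    lh[4] = np.log(region.p12) + ls12

    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(pp, conditional_h4(pp), len(df))
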