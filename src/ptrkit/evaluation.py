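"""Policy-value evaluation of a treatment rule.

Under 1:pi randomisation the mean outcome the population would attain if
everyone followed a rule is estimated without bias by weighting the subjects
who actually received their recommended arm by the inverse probability of
that assignment:

    mu{PTR} = (1/n) sum_i [ (A_i + 1/2)(PTR_i + 1/2) / pi * Y_i
                          + (1/2 - A_i)(1/2 - PTR_i) / (1 - pi) * Y_i ]

With the +/-1/2 effect coding the products of shifted codes are literal 0/1
indicators of "treated and recommended treatment" and "control and
recommended control".  The same weighting with the rule replaced by the
constant policies gives mu{A=+1/2} and mu{A=-1/2}, and the contrasts

    theta_T = mu{PTR} - mu{A=+1/2},    theta_C = mu{PTR} - mu{A=-1/2}

are the expected change in outcome under the rule relative to treating or
withholding treatment from everybody.  By construction
theta_T - theta_C = mu{A=-1/2} - mu{A=+1/2} exactly.

In simulations, where each subject's optimal arm is known from the stored
potential outcomes, the misclassification rate of a rule is the fraction of
subjects whose recommendation conflicts with their optimal arm.

Inference for a theta contrast uses a nonparametric bootstrap over the
evaluation sample with the rule held fixed, with a normal approximation for
the confidence interval and p-value.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .errors import DataError
from .methods import PTRRule
from .trial import TrialData


@dataclasses.dataclass
class EvaluationResult:
    """IPW value of a rule and its contrasts against constant policies."""

    mu_ptr: float
    mu_treat: float
    mu_control: float
    theta_T: float
    theta_C: float
    n: int
    n_followed: int
    misclassification: float | None = None


def _ipw_components(Y: np.ndarray, A: np.ndarray, rec: np.ndarray,
                    pi: float) -> tuple[float, float, float]:
    treat_follow = (A + 0.5) * (rec + 0.5) / pi
    ctrl_follow = (0.5 - A) * (0.5 - rec) / (1.0 - pi)
    mu_ptr = float(np.mean(treat_follow * Y + ctrl_follow * Y))
    mu_treat = float(np.mean((A + 0.5) / pi * Y))
    mu_control = float(np.mean((0.5 - A) / (1.0 - pi) * Y))
    return mu_ptr, mu_treat, mu_control


def _recommendations(data: TrialData, rule) -> np.ndarray:
    if isinstance(rule, PTRRule):
        return rule.recommend(data)
    rec = np.asarray(rule, dtype=float)
    if rec.shape != data.Y.shape:
        raise DataError("recommendation vector length does not match the data")
    if not np.all(np.isin(rec, (-0.5, 0.5))):
        raise DataError("recommendations must be coded -1/2 or +1/2")
    return rec


def ipw_value(data: TrialData, rule) -> EvaluationResult:
    """Inverse-probability-weighted value of a rule on one dataset.

    ``rule`` is a :class:`PTRRule` or a precomputed +/-1/2 recommendation
    vector.  Uses the design randomisation probability ``data.pi``.
    """
    rec = _recommendations(data, rule)
    mu_ptr, mu_treat, mu_control = _ipw_components(data.Y, data.A, rec, data.pi)
    return EvaluationResult(
        mu_ptr=mu_ptr,
        mu_treat=mu_treat,
        mu_control=mu_control,
        theta_T=mu_ptr - mu_treat,
        theta_C=mu_ptr - mu_control,
        n=data.n,
        n_followed=int(np.sum(rec == data.A)),
    )


def misclassification_rate(rule, optimal, data: TrialData | None = None) -> float:
    """Fraction of subjects whose recommendation conflicts with the optimal arm.

    ``rule`` is a :class:`PTRRule` (then ``data`` is required) or a
    precomputed +/-1/2 recommendation vector; ``optimal`` is the per-subject
    optimal arm in +/-1/2 coding (known in simulation only).
    """
    if isinstance(rule, PTRRule):
        if data is None:
            raise DataError("a TrialData is required to evaluate a PTRRule")
        rec = rule.recommend(data)
    else:
        rec = np.asarray(rule, dtype=float)
    opt = np.asarray(optimal, dtype=float)
    if rec.shape != opt.shape:
        raise DataError("recommendation and optimal vectors differ in length")
    return float(np.mean(rec != opt))


@dataclasses.dataclass
class BootstrapTheta:
    """Bootstrap inference for a theta contrast with a fixed rule."""

    contrast: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    B: int
    n: int


_MAX_REDRAWS = 1000


def bootstrap_theta(data: TrialData, rule, contrast: str = "theta_T",
                    B: int = 1000, seed=None,
                    one_sided: bool = False) -> BootstrapTheta:
    """Resample the evaluation data with replacement, rule held fixed.

    The rule must have been fitted on independent (training) data.  Resamples
    that lose an entire arm are redrawn (the contrast is undefined without
    both arms), up to a retry cap.  SE is the bootstrap standard deviation;
    the 95% CI and p-value use the normal approximation.
    """
    if contrast not in ("theta_T", "theta_C"):
        raise ValueError("contrast must be 'theta_T' or 'theta_C'")
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    rec = _recommendations(data, rule)
    Y, A, pi, n = data.Y, data.A, data.pi, data.n

    def _theta(idx: np.ndarray) -> float:
        mu_ptr, mu_treat, mu_control = _ipw_components(Y[idx], A[idx], rec[idx], pi)
        return mu_ptr - (mu_treat if contrast == "theta_T" else mu_control)

    estimate = _theta(np.arange(n))
    boot = np.empty(B)
    for b in range(B):
        for _ in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, n)
            if (A[idx] > 0).any() and (A[idx] < 0).any():
                break
        else:
            raise DataError("could not draw a bootstrap resample with both arms")
        boot[b] = _theta(idx)
    se = float(np.std(boot, ddof=1))
    if se > 0:
        z = estimate / se
        p = float(stats.norm.sf(z) if one_sided else 2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if estimate == 0.0 else 0.0
    half = 1.959963984540054 * se
    return BootstrapTheta(contrast=contrast, estimate=float(estimate), se=se,
                          ci_low=float(estimate - half),
                          ci_high=float(estimate + half),
                          p_value=p, B=B, n=n)
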