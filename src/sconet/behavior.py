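"""Hyperbolic delay-discounting model: subjective value, softmax choice rule,
per-subject maximum-likelihood estimation of (k, beta), and median-split
group assignment.

The model: an option paying amount ``A`` after delay ``D`` days has subjective
value ``SV = A / (1 + k*D)`` where ``k`` (per day) is the subject's discount
rate.  On each trial the probability of choosing the delayed option is a
logistic function of the subjective-value difference,
``P = 1 / (1 + exp(-beta * (SV_delayed - SV_immediate)))``, with ``beta`` an
inverse-temperature scaling fitted per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "ChoiceTrial",
    "ChoiceSet",
    "DiscountFit",
    "GroupAssignment",
    "FitConfig",
    "subjective_value",
    "choice_probability",
    "fit_discounting",
    "median_split",
    "AmbiguousMedianError",
]


@dataclass(frozen=True)
class ChoiceTrial:
    """One intertemporal choice: immediate amount now vs. delayed amount later."""

    immediate_amount: float
    delayed_amount: float
    delay: float  # days
    chose_delayed: bool

    def __post_init__(self) -> None:
        if self.immediate_amount <= 0:
            raise ValueError("immediate_amount must be positive")
        if self.delayed_amount < self.immediate_amount:
            raise ValueError("delayed_amount must be >= immediate_amount")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass
class ChoiceSet:
    """All trials of one subject, held as aligned arrays for vectorized fits."""

    subject_id: str
    immediate_amount: np.ndarray
    delayed_amount: np.ndarray
    delay: np.ndarray
    chose_delayed: np.ndarray

    def __post_init__(self) -> None:
        self.immediate_amount = np.asarray(self.immediate_amount, dtype=float)
        self.delayed_amount = np.asarray(self.delayed_amount, dtype=float)
        self.delay = np.asarray(self.delay, dtype=float)
        self.chose_delayed = np.asarray(self.chose_delayed, dtype=float)
        n = len(self.immediate_amount)
        if n == 0:
            raise ValueError(f"subject {self.subject_id}: empty choice set")
        for name in ("delayed_amount", "delay", "chose_delayed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"subject {self.subject_id}: ragged trial arrays")

    @classmethod
    def from_trials(cls, subject_id: str, trials: list[ChoiceTrial]) -> "ChoiceSet":
        return cls(
            subject_id=subject_id,
            immediate_amount=np.array([t.immediate_amount for t in trials]),
            delayed_amount=np.array([t.delayed_amount for t in trials]),
            delay=np.array([t.delay for t in trials]),
            chose_delayed=np.array([float(t.chose_delayed) for t in trials]),
        )

    @property
    def n_trials(self) -> int:
        return len(self.chose_delayed)


@dataclass
class DiscountFit:
    """Result of fitting the discounting model to one subject."""

    subject_id: str
    k: float
    beta: float
    log_k: float
    neg_log_lik: float
    degenerate: bool = False
    converged: bool = True
    n_trials: int = 0

    @property
    def log10_k(self) -> float:
        return self.log_k / np.log(10.0)


@dataclass
class GroupAssignment:
    """Median-split assignment of subjects to high/low discounting groups."""

    high_group: set = field(default_factory=set)
    low_group: set = field(default_factory=set)
    excluded: set = field(default_factory=set)

    def label(self, subject_id: str) -> str:
        if subject_id in self.high_group:
            return "high"
        if subject_id in self.low_group:
            return "low"
        return "none"


class AmbiguousMedianError(ValueError):
    """More than one subject sits exactly at the median discount rate."""


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_discounting`.

    The likelihood is maximized over (log k, log beta) so positivity holds
    without constrained steps; a small multi-start grid guards against the
    flat/multi-modal regions that one-sided choosers induce.
    """

    k_bounds: tuple[float, float] = (1e-6, 10.0)
    beta_bounds: tuple[float, float] = (1e-8, 10.0)
    k_starts_log10: tuple[float, ...] = (-4.0, -3.0, -2.0, -1.0)
    beta_starts_log10: tuple[float, ...] = (-4.0, -3.0, -2.0)


def subjective_value(amount, delay, k):
    """Hyperbolically discounted value ``A / (1 + k*D)``.

    Equals ``amount`` when either the delay or the discount rate is zero and
    decreases strictly with delay for ``k > 0``.
    """
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(amount <= 0):
        raise ValueError("amount must be positive")
    if np.any(delay < 0):
        raise ValueError("delay must be non-negative")
    if np.any(k < 0):
        raise ValueError("discount rate k must be non-negative")
    out = amount / (1.0 + k * delay)
    return float(out) if out.ndim == 0 else out


def choice_probability(sv_delayed, sv_immediate, beta):
    """Probability of choosing the delayed option under the logistic rule.

    ``P = 1 / (1 + exp(-beta * (sv_delayed - sv_immediate)))``; numerically
    stable for arbitrarily large ``|beta * dSV|``.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")
    x = beta * (np.asarray(sv_delayed, dtype=float) - np.asarray(sv_immediate, dtype=float))
    out = expit(x)
    return float(out) if out.ndim == 0 else out


def _neg_log_lik(log_k: float, log_beta: float, choices: ChoiceSet) -> float:
    k = np.exp(log_k)
    beta = np.exp(log_beta)
    dsv = subjective_value(choices.delayed_amount, choices.delay, k) - choices.immediate_amount
    x = beta * dsv
    y = choices.chose_delayed
    # -sum[y*log p + (1-y)*log(1-p)] via the stable log-sigmoid
    return float(-np.sum(y * log_expit(x) + (1.0 - y) * log_expit(-x)))


def fit_discounting(choices: ChoiceSet, config: FitConfig | None = None) -> DiscountFit:
    """Maximum-likelihood fit of (k, beta) for one subject.

    Runs L-BFGS-B on (log k, log beta) from every point of the start grid and
    keeps the best optimum.  A subject who chose the same option on every
    trial carries no information about the indifference point: the fit is
    flagged ``degenerate`` with ``k`` pinned at the search bound (lower bound
    for an always-delayed chooser, upper bound for always-immediate).
    """
    cfg = config or FitConfig()
    if choices.n_trials < 2:
        raise ValueError(f"subject {choices.subject_id}: need at least 2 trials")
    pairs = set(zip(choices.delayed_amount.tolist(), choices.delay.tolist()))
    if len(pairs) < 2:
        raise ValueError(
            f"subject {choices.subject_id}: trials must span more than one "
            "(amount, delay) pair for identifiability"
        )

    y = choices.chose_delayed
    if np.all(y == 1.0) or np.all(y == 0.0):
        k_pin = cfg.k_bounds[0] if y[0] == 1.0 else cfg.k_bounds[1]
        log_k = np.log(k_pin)
        res = minimize(
            lambda lb: _neg_log_lik(log_k, lb[0], choices),
            x0=[np.log(1e-3)],
            bounds=[tuple(np.log(cfg.beta_bounds))],
            method="L-BFGS-B",
        )
        return DiscountFit(
            subject_id=choices.subject_id,
            k=k_pin,
            beta=float(np.exp(res.x[0])),
            log_k=float(log_k),
            neg_log_lik=float(res.fun),
            degenerate=True,
            converged=bool(res.success),
            n_trials=choices.n_trials,
        )

    bounds = [tuple(np.log(cfg.k_bounds)), tuple(np.log(cfg.beta_bounds))]
    best = None
    any_converged = False
    for lk10 in cfg.k_starts_log10:
        for lb10 in cfg.beta_starts_log10:
            x0 = [lk10 * np.log(10.0), lb10 * np.log(10.0)]
            res = minimize(
                lambda x: _neg_log_lik(x[0], x[1], choices),
                x0=x0,
                bounds=bounds,
                method="L-BFGS-B",
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
    log_k, log_beta = best.x
    return DiscountFit(
        subject_id=choices.subject_id,
        k=float(np.exp(log_k)),
        beta=float(np.exp(log_beta)),
        log_k=float(log_k),
        neg_log_lik=float(best.fun),
        degenerate=False,
        converged=any_converged,
        n_trials=choices.n_trials,
    )


def median_split(fits: list[DiscountFit]) -> GroupAssignment:
    """Split subjects at the median k: above -> high group, below -> low.

    With an odd cohort the unique subject at the median is excluded so the
    groups stay balanced; more than one subject exactly at the median is
    ambiguous and raises :class:`AmbiguousMedianError`.
    """
    if len(fits) < 2:
        raise ValueError("median split requires at least 2 fitted subjects")
    ks = np.array([f.k for f in fits])
    ids = [f.subject_id for f in fits]
    med = float(np.median(ks))
    high = {i for i, k in zip(ids, ks) if k > med}
    low = {i for i, k in zip(ids, ks) if k < med}
    at = {i for i, k in zip(ids, ks) if k == med}
    n = len(fits)
    if n % 2 == 1:
        if len(at) != 1:
            raise AmbiguousMedianError(
                f"odd cohort of {n}: expected exactly one subject at the median, found {len(at)}"
            )
        return GroupAssignment(high_group=high, low_group=low, excluded=at)
    if at:
        raise AmbiguousMedianError(
            f"even cohort of {n}: {len(at)} subject(s) exactly at the median make the split ambiguous"
        )
    return GroupAssignment(high_group=high, low_group=low, excluded=set())
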