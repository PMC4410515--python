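"""Bayesian conditioning and probabilistic abduction on finite partitions.

A hypothesis space is a finite set {H_1, ..., H_n} of mutually exclusive,
jointly exhaustive hypotheses carrying a prior credence vector.  Learning
evidence E with per-hypothesis likelihoods Pr(E|H_i) either

* conditions in the Bayesian way,
      Pr_t2(H_i) = Pr_t1(H_i) Pr(E|H_i) / sum_j Pr_t1(H_j) Pr(E|H_j),
  or
* updates abductively, adding an explanatory bonus c >= 0 to the numerator of
  the hypothesis that best explains E before renormalising:
      Pr_t2(H_i) = (Pr_t1(H_i) Pr(E|H_i) + E_i) / sum_j (...),
  with E_i = c for the unique best explainer and 0 otherwise.  With c = 0 the
  abductive rule coincides with Bayesian conditioning exactly (same floating
  point operations, hence bit-identical results).

The best explainer is the unique argmax of a pluggable explanatory-power
measure; ties (within tolerance) award no bonus, which preserves symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidBonusError, ZeroProbabilityEvidenceError
from .measures import PROB_TOL, MeasureSpec, power_from_model

TIE_TOL = 1e-12


@dataclass(frozen=True)
class HypothesisSpace:
    """A finite exhaustive partition of hypotheses with prior credences."""

    labels: Tuple[str, ...]
    priors: np.ndarray

    def __init__(self, labels: Sequence[str], priors: Sequence[float]):
        labels = tuple(labels)
        priors = np.asarray(priors, dtype=float)
        if len(labels) < 2:
            raise ValueError("a hypothesis space needs at least 2 hypotheses")
        if len(set(labels)) != len(labels):
            raise ValueError("hypothesis labels must be unique")
        if priors.shape != (len(labels),):
            raise ValueError("priors must align with labels")
        if (priors < 0).any():
            raise ValueError("priors must be nonnegative")
        if abs(priors.sum() - 1.0) > PROB_TOL:
            raise ValueError(f"priors sum to {priors.sum()}, not 1")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "priors", priors)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class CredenceState:
    """A credence distribution over a labelled partition, tagged by stage."""

    labels: Tuple[str, ...]
    values: np.ndarray
    stage: str = "t1"

    def __init__(self, labels: Sequence[str], values: Sequence[float], stage: str = "t1"):
        labels = tuple(labels)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels),):
            raise ValueError("values must align with labels")
        if (values < -PROB_TOL).any() or abs(values.sum() - 1.0) > PROB_TOL:
            raise ValueError("credences must be a probability distribution")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stage", stage)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def as_space(self) -> HypothesisSpace:
        return HypothesisSpace(self.labels, self.values)


@dataclass(frozen=True)
class EvidenceModel:
    """Per-hypothesis likelihoods Pr(E | H_i) for one piece of evidence."""

    likelihoods: np.ndarray

    def __init__(self, likelihoods: Sequence[float]):
        lik = np.asarray(likelihoods, dtype=float)
        if (lik < 0).any() or (lik > 1 + PROB_TOL).any():
            raise ValueError("likelihoods must lie in [0, 1]")
        object.__setattr__(self, "likelihoods", lik)

    def marginal(self, priors: np.ndarray) -> float:
        """Pr(E) = sum_i prior_i * Pr(E | H_i)."""
        return float(np.dot(np.asarray(priors, dtype=float), self.likelihoods))


@dataclass(frozen=True)
class BonusPolicy:
    """How the abductive rule rewards the best explainer.

    ``c`` is the flat bonus added to the best explainer's numerator;
    ``selector`` is the explanatory-power measure used to rank hypotheses
    (``None`` ranks by likelihood, which agrees with every implemented
    measure at equal priors).  Ties receive no bonus.
    """

    c: float = 0.1
    selector: Optional[MeasureSpec] = None
    tie_rule: str = field(default="no-bonus-on-tie")

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"bonus magnitude must be nonnegative, got {self.c}")
        if self.tie_rule != "no-bonus-on-tie":
            raise ValueError("only the no-bonus-on-tie rule is supported")

    @classmethod
    def from_config(cls, obj) -> "BonusPolicy":
        if isinstance(obj, BonusPolicy):
            return obj
        sel = obj.get("selector")
        return cls(c=float(obj.get("c", 0.1)),
                   selector=None if sel is None else MeasureSpec.from_config(sel))

    def to_config(self) -> dict:
        return {"c": self.c,
                "selector": None if self.selector is None else self.selector.to_config()}


def best_explainer(space: HypothesisSpace, evidence: EvidenceModel,
                   selector: Optional[MeasureSpec] = None) -> Optional[str]:
    """The unique hypothesis scoring highest under the selector, or ``None``.

    With ``selector=None`` hypotheses are ranked by their likelihood for the
    evidence.  A tie for the top score (within ``TIE_TOL``) returns ``None``.
    """
    if selector is None:
        scores = evidence.likelihoods
    else:
        scores = np.array([
            power_from_model(selector, space, evidence, h).value for h in space.labels
        ])
    top = np.max(scores)
    winners = np.flatnonzero(scores >= top - TIE_TOL)
    if len(winners) != 1:
        return None
    return space.labels[int(winners[0])]


def bayes_update(credences: CredenceState, evidence: EvidenceModel) -> CredenceState:
    """Condition the credence state on the evidence."""
    numer = credences.values * evidence.likelihoods
    denom = numer.sum()
    if denom <= 0.0:
        raise ZeroProbabilityEvidenceError("Pr(E) = 0: cannot condition")
    return CredenceState(credences.labels, numer / denom, stage="t2")


def abductive_update(credences: CredenceState, evidence: EvidenceModel,
                     bonus: BonusPolicy,
                     best: Optional[str] = "auto") -> CredenceState:
    """Update by probabilistic abduction.

    The best explainer's numerator receives the flat bonus ``bonus.c`` before
    renormalisation.  ``best`` may name the winning hypothesis directly (as a
    label, or ``None`` for an explicit tie); the default ``"auto"`` determines
    it from the current credences via ``bonus.selector``.
    """
    numer = credences.values * evidence.likelihoods
    if numer.sum() <= 0.0:
        raise ZeroProbabilityEvidenceError("Pr(E) = 0: cannot update")
    if bonus.c > 0.0:
        if best == "auto":
            best = best_explainer(credences.as_space(), evidence, bonus.selector)
        if best is not None:
            numer = numer.copy()
            numer[credences.labels.index(best)] += bonus.c
    if (numer < 0).any():
        raise InvalidBonusError("bonus produced a negative numerator")
    return CredenceState(credences.labels, numer / numer.sum(), stage="t2")


#: Update rules by name, each with signature (credences, evidence, policy).
RULES = {
    "bayes": lambda credences, evidence, policy=None: bayes_update(credences, evidence),
    "abduction": abductive_update,
}
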