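"""Probabilistic measures of explanatory power.

A measure of explanatory power scores how well a hypothesis H accounts for
evidence E, as a function of probabilities relating H and E.  All measures
implemented here share the "neutral point" convention: when H and E are
probabilistically independent the score is 0.  The measures are

``simple``
    Pr(E | H) - Pr(E), range [-1, 1].
``popper``
    (Pr(E | H) - Pr(E)) / (Pr(E | H) + Pr(E)), range [-1, 1].
``good``
    ln(Pr(E | H) / Pr(E)), range (-inf, inf).
``good_rescaled``
    L_alpha applied to the ``good`` score, where
    L_alpha(x) = sign(x) * (1 - exp(-x^2 / (2 alpha^2))), range [-1, 1].
    The presets G1, G2, G3 name L_0.5, L_1 and L_2.
``schupbach_sprenger``
    (Pr(H | E) - Pr(H | not-E)) / (Pr(H | E) + Pr(H | not-E)), range [-1, 1].

Scores can be computed either from raw conditional probabilities
(:func:`power_from_conditionals`, :func:`power_ss`) or from a full
hypothesis-space model (:func:`power_from_model`), which assembles the needed
conditionals by Bayes's theorem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from .errors import DegenerateMarginalError, UndefinedScoreError

if TYPE_CHECKING:  # pragma: no cover
    from .updating import EvidenceModel, HypothesisSpace

MEASURE_IDS = ("simple", "popper", "good", "good_rescaled", "schupbach_sprenger")

#: Named presets for the rescaled-Good family: G1 = L_0.5, G2 = L_1, G3 = L_2.
ALPHA_PRESETS = {"G1": 0.5, "G2": 1.0, "G3": 2.0}

#: Absolute tolerance for probability-sum and tie checks.
PROB_TOL = 1e-9


def study_measures() -> dict:
    """The five bounded measures used in the urn-experiment regressions.

    Keys follow the study's subscript convention: ``P`` (Popper), ``G1``,
    ``G2``, ``G3`` (rescaled Good with alpha = 0.5, 1, 2) and ``SS``
    (Schupbach-Sprenger).
    """
    return {
        "P": MeasureSpec("popper"),
        "G1": MeasureSpec("good_rescaled", 0.5),
        "G2": MeasureSpec("good_rescaled", 1.0),
        "G3": MeasureSpec("good_rescaled", 2.0),
        "SS": MeasureSpec("schupbach_sprenger"),
    }


@dataclass(frozen=True)
class MeasureSpec:
    """Identifies a measure of explanatory power.

    Parameters
    ----------
    id
        One of :data:`MEASURE_IDS`.
    alpha
        Shape parameter of the L_alpha rescaling; required iff
        ``id == "good_rescaled"`` and must be positive.
    """

    id: str
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.id not in MEASURE_IDS:
            raise ValueError(f"unknown measure id {self.id!r}; expected one of {MEASURE_IDS}")
        if self.id == "good_rescaled":
            if self.alpha is None:
                raise ValueError("good_rescaled requires alpha")
            if not self.alpha > 0:
                raise ValueError(f"alpha must be positive, got {self.alpha}")
        elif self.alpha is not None:
            raise ValueError(f"alpha is only meaningful for good_rescaled, not {self.id!r}")

    @classmethod
    def from_config(cls, obj) -> "MeasureSpec":
        """Build a spec from a config value.

        Accepts a preset name (``"G1"``, ``"G2"``, ``"G3"``), a plain measure
        id string, or a mapping ``{"id": ..., "alpha": ...}`` (whose ``id``
        may itself be a preset name).
        """
        if isinstance(obj, MeasureSpec):
            return obj
        if isinstance(obj, str):
            if obj in ALPHA_PRESETS:
                return cls("good_rescaled", ALPHA_PRESETS[obj])
            return cls(obj)
        if isinstance(obj, dict):
            ident = obj.get("id")
            if ident in ALPHA_PRESETS:
                if obj.get("alpha") is not None and obj["alpha"] != ALPHA_PRESETS[ident]:
                    raise ValueError(f"preset {ident} fixes alpha={ALPHA_PRESETS[ident]}")
                return cls("good_rescaled", ALPHA_PRESETS[ident])
            return cls(ident, obj.get("alpha"))
        raise TypeError(f"cannot build MeasureSpec from {type(obj).__name__}")

    def to_config(self) -> dict:
        out = {"id": self.id}
        if self.alpha is not None:
            out["alpha"] = self.alpha
        return out

    @property
    def bounded(self) -> bool:
        """Whether the measure's range is [-1, 1] (all but raw ``good``)."""
        return self.id != "good"


@dataclass(frozen=True)
class PowerInputs:
    """The conditional probabilities a measure may consume.

    Only the fields a given measure needs must be populated; all populated
    fields must lie in [0, 1].
    """

    p_e_given_h: Optional[float] = None
    p_e: Optional[float] = None
    p_h_given_e: Optional[float] = None
    p_h_given_not_e: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p_e_given_h", "p_e", "p_h_given_e", "p_h_given_not_e"):
            v = getattr(self, name)
            if v is not None and not (-PROB_TOL <= v <= 1 + PROB_TOL):
                raise ValueError(f"{name}={v} is not a probability")


@dataclass(frozen=True)
class PowerScore:
    """A measure together with its value for some hypothesis/evidence pair."""

    measure: MeasureSpec
    value: float


def rescale_good(x: float, alpha: float) -> PowerScore:
    """Compress an unbounded Good score into [-1, 1] via the L_alpha schema.

    L_alpha(x) = 1 - exp(-x^2 / (2 alpha^2)) for x >= 0 and its odd reflection
    for x < 0.  The map is strictly increasing and odd, fixes 0, and sends
    +/-inf to +/-1, so the rescaled-Good family keeps Good's hypothesis
    ordering while sharing the [-1, 1] scale of the other bounded measures.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    spec = MeasureSpec("good_rescaled", alpha)
    if math.isinf(x):
        return PowerScore(spec, math.copysign(1.0, x))
    mag = 1.0 - math.exp(-(x * x) / (2.0 * alpha * alpha))
    return PowerScore(spec, math.copysign(mag, x) if x != 0 else 0.0)


def power_from_conditionals(measure: MeasureSpec, inputs: PowerInputs,
                            zero_likelihood: str = "sentinel") -> PowerScore:
    """Evaluate a likelihood-based measure from Pr(E|H) and Pr(E).

    Parameters
    ----------
    measure
        ``simple``, ``popper``, ``good`` or ``good_rescaled``; the
        posterior-based ``schupbach_sprenger`` measure is dispatched to
        :func:`power_ss`.
    inputs
        Must populate ``p_e_given_h`` and ``p_e`` (or the posterior fields for
        ``schupbach_sprenger``).
    zero_likelihood
        Good's measure is -inf at Pr(E|H) = 0.  ``"sentinel"`` returns the
        -inf sentinel (which L_alpha maps to -1); ``"error"`` raises instead.
    """
    if measure.id == "schupbach_sprenger":
        return power_ss(inputs)
    peh, pe = inputs.p_e_given_h, inputs.p_e
    if peh is None or pe is None:
        raise ValueError(f"{measure.id} needs p_e_given_h and p_e")
    if not (0.0 < pe < 1.0):
        raise DegenerateMarginalError(f"Pr(E)={pe} must lie strictly inside (0, 1)")
    if measure.id == "simple":
        return PowerScore(measure, peh - pe)
    if measure.id == "popper":
        return PowerScore(measure, (peh - pe) / (peh + pe))
    # good / good_rescaled
    if peh <= 0.0:
        if zero_likelihood == "error":
            raise UndefinedScoreError("Good's measure diverges at Pr(E|H) = 0")
        good = float("-inf")
    else:
        good = math.log(peh / pe)
    if measure.id == "good":
        return PowerScore(measure, good)
    return rescale_good(good, measure.alpha)


def power_ss(inputs: PowerInputs) -> PowerScore:
    """Posterior-ratio measure: (Pr(H|E) - Pr(H|~E)) / (Pr(H|E) + Pr(H|~E))."""
    phe, phn = inputs.p_h_given_e, inputs.p_h_given_not_e
    if phe is None or phn is None:
        raise ValueError("schupbach_sprenger needs p_h_given_e and p_h_given_not_e")
    if phe + phn <= 0.0:
        raise UndefinedScoreError("Pr(H|E) and Pr(H|not-E) are both zero")
    return PowerScore(MeasureSpec("schupbach_sprenger"), (phe - phn) / (phe + phn))


def power_from_model(measure: MeasureSpec, space: "HypothesisSpace",
                     evidence: "EvidenceModel", h: str,
                     zero_likelihood: str = "sentinel") -> PowerScore:
    """Score hypothesis ``h`` against the evidence of a full partition model.

    Assembles the conditional probabilities the measure needs from the priors
    and per-hypothesis likelihoods:  Pr(E) by total probability,
    Pr(H|E) by Bayes's theorem, and Pr(H|~E) = Pr(H)(1 - Pr(E|H)) / (1 - Pr(E)).
    """
    idx = space.index(h)
    prior = float(space.priors[idx])
    lik = float(evidence.likelihoods[idx])
    pe = float(evidence.marginal(space.priors))
    if pe <= 0.0:
        raise DegenerateMarginalError("Pr(E) = 0: evidence impossible under every hypothesis")
    if measure.id == "schupbach_sprenger":
        if pe >= 1.0:
            raise DegenerateMarginalError("Pr(E) = 1: Pr(H | not-E) is undefined")
        inputs = PowerInputs(p_h_given_e=prior * lik / pe,
                             p_h_given_not_e=prior * (1.0 - lik) / (1.0 - pe))
        return power_ss(inputs)
    if pe >= 1.0:
        raise DegenerateMarginalError(f"Pr(E)={pe} must lie strictly inside (0, 1)")
    inputs = PowerInputs(p_e_given_h=lik, p_e=pe)
    return power_from_conditionals(measure, inputs, zero_likelihood=zero_likelihood)
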