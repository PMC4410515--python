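"""The two-urn drawing experiment.

An urn is selected by a fair coin toss: urn A holds 30 black and 10 white
balls, urn B holds 15 black and 25 white.  Ten balls are then drawn from the
selected urn without replacement.  After each draw k the objective posterior

    O_k = Pr(H_A | first k draws)

is well defined from the urn compositions alone, and each measure of
explanatory power yields per-step scores for H_A and H_B against the
cumulative evidence (the draws so far).

Likelihoods use ordered-sequence probabilities: the probability of a colour
sequence is the product over steps of (remaining balls of that colour) /
(remaining balls).  Since every ordering of the same colour counts has the
same probability, the posterior depends only on the counts (exchangeability);
this equals the hypergeometric count likelihood up to a common binomial
factor that cancels in the posterior.

Scalar operations (:func:`sequence_likelihood`, :func:`posterior_trajectory`,
:func:`trial_scores`) are the readable reference path; the array functions
(:func:`simulate_trials`, :func:`score_features`) vectorise whole batches of
trials for the synthetic-participant generator and simulation studies, and
are tested for agreement with the scalar path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateMarginalError
from .measures import MeasureSpec, power_from_model, study_measures
from .updating import EvidenceModel, HypothesisSpace

BLACK, WHITE = "B", "W"

DrawSequence = Tuple[str, ...]


@dataclass(frozen=True)
class UrnSpec:
    """Urn compositions and the selection prior over urns."""

    labels: Tuple[str, ...] = ("A", "B")
    counts: Tuple[Tuple[int, int], ...] = ((30, 10), (15, 25))  # (black, white)
    priors: Tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts) or len(self.labels) != len(self.priors):
            raise ValueError("labels, counts and priors must align")
        for black, white in self.counts:
            if black < 0 or white < 0:
                raise ValueError("ball counts must be nonnegative")
        if abs(sum(self.priors) - 1.0) > 1e-9 or any(p < 0 for p in self.priors):
            raise ValueError("selection priors must be a probability distribution")

    def total(self, i: int) -> int:
        return self.counts[i][0] + self.counts[i][1]

    def space(self) -> HypothesisSpace:
        return HypothesisSpace([f"H_{l}" for l in self.labels], list(self.priors))


def _validate_draws(draws: Sequence[str]) -> DrawSequence:
    draws = tuple(draws)
    for d in draws:
        if d not in (BLACK, WHITE):
            raise ValueError(f"draw colours must be {BLACK!r} or {WHITE!r}, got {d!r}")
    return draws


def sequence_likelihood(counts: Tuple[int, int], draws: Sequence[str]) -> float:
    """Probability of an ordered colour sequence drawn without replacement.

    Returns 0 for sequences that exhaust a colour's stock.
    """
    draws = _validate_draws(draws)
    black, white = counts
    prob = 1.0
    for d in draws:
        total = black + white
        if total == 0:
            return 0.0
        if d == BLACK:
            if black == 0:
                return 0.0
            prob *= black / total
            black -= 1
        else:
            if white == 0:
                return 0.0
            prob *= white / total
            white -= 1
    return prob


def posterior_trajectory(spec: UrnSpec, draws: Sequence[str]) -> np.ndarray:
    """O_k = Pr(urn A | first k draws) for k = 0..len(draws).

    O_0 is the selection prior of the first urn (urn A by default).
    """
    draws = _validate_draws(draws)
    out = [float(spec.priors[0])]
    for k in range(1, len(draws) + 1):
        liks = [sequence_likelihood(c, draws[:k]) for c in spec.counts]
        joint = [p * l for p, l in zip(spec.priors, liks)]
        tot = sum(joint)
        if tot <= 0.0:
            raise DegenerateMarginalError("draw sequence impossible under every urn")
        out.append(joint[0] / tot)
    return np.asarray(out)


def trial_scores(spec: UrnSpec, draws: Sequence[str], measure: MeasureSpec,
                 evidence_unit: str = "cumulative") -> pd.DataFrame:
    """Per-step objective posterior and explanatory-power scores.

    One row per draw with columns ``step`` (1-based), ``color``, ``O``,
    ``score_A`` and ``score_B``.  With ``evidence_unit="cumulative"``
    (default) step k scores each urn hypothesis against the whole sequence of
    the first k draws from the selection priors; with ``"latest"`` the
    evidence is the k-th draw alone and the priors are the step-(k-1)
    posteriors.
    """
    draws = _validate_draws(draws)
    if evidence_unit not in ("cumulative", "latest"):
        raise ValueError(f"unknown evidence_unit {evidence_unit!r}")
    traj = posterior_trajectory(spec, draws)
    rows = []
    labels = [f"H_{l}" for l in spec.labels]
    for k in range(1, len(draws) + 1):
        if evidence_unit == "cumulative":
            priors = list(spec.priors)
            liks = [sequence_likelihood(c, draws[:k]) for c in spec.counts]
        else:
            priors = [traj[k - 1], 1.0 - traj[k - 1]]
            liks = []
            for c in spec.counts:
                prev = sequence_likelihood(c, draws[:k - 1])
                liks.append(sequence_likelihood(c, draws[:k]) / prev if prev > 0 else 0.0)
        space = HypothesisSpace(labels, priors)
        ev = EvidenceModel(liks)
        rows.append({
            "step": k,
            "color": draws[k - 1],
            "O": traj[k],
            "score_A": power_from_model(measure, space, ev, labels[0]).value,
            "score_B": power_from_model(measure, space, ev, labels[1]).value,
        })
    return pd.DataFrame(rows, columns=["step", "color", "O", "score_A", "score_B"])


def simulate_trial(spec: UrnSpec, n_draws: int,
                   seed=None) -> Tuple[str, DrawSequence]:
    """Select an urn by the selection prior and draw without replacement."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if any(n_draws > spec.total(i) for i in range(len(spec.labels))):
        raise ValueError(f"cannot draw {n_draws} balls from every urn")
    urn = int(rng.choice(len(spec.labels), p=spec.priors))
    black, white = spec.counts[urn]
    draws = []
    for _ in range(n_draws):
        if rng.random() < black / (black + white):
            draws.append(BLACK)
            black -= 1
        else:
            draws.append(WHITE)
            white -= 1
    return spec.labels[urn], tuple(draws)


def enumerate_sequences(spec: UrnSpec, n: int) -> List[Tuple[DrawSequence, float]]:
    """All colour sequences of length ``n`` with their joint probabilities.

    Brute-force oracle: the probabilities sum to 1 by total probability.
    Intended for small ``n`` (the sequence count is 2^n).
    """
    out = []
    for seq in product((BLACK, WHITE), repeat=n):
        prob = sum(p * sequence_likelihood(c, seq)
                   for p, c in zip(spec.priors, spec.counts))
        out.append((seq, prob))
    return out


# ---------------------------------------------------------------------------
# Vectorised batch path


def simulate_trials(spec: UrnSpec, n_trials: int, n_draws: int,
                    rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate many independent trials at once.

    Returns ``(urns, blacks)`` where ``urns`` is the selected urn index per
    trial and ``blacks`` is a boolean (n_trials, n_draws) array, True where
    the draw was black.  A without-replacement sequence is realised as the
    first ``n_draws`` entries of a shuffled arrangement of the urn's balls.
    """
    if any(n_draws > spec.total(i) for i in range(len(spec.labels))):
        raise ValueError(f"cannot draw {n_draws} balls from every urn")
    urns = rng.choice(len(spec.labels), size=n_trials, p=np.asarray(spec.priors))
    blacks = np.zeros((n_trials, n_draws), dtype=bool)
    for i, (black, _white) in enumerate(spec.counts):
        members = np.flatnonzero(urns == i)
        if len(members) == 0:
            continue
        pool = np.zeros((len(members), spec.total(i)), dtype=bool)
        pool[:, :black] = True
        pool = rng.permuted(pool, axis=1)
        blacks[members] = pool[:, :n_draws]
    return urns, blacks


def _cumulative_loglik(counts: Tuple[int, int], blacks: np.ndarray) -> np.ndarray:
    """log Pr(first k draws | urn) for k = 1..n_draws, per trial.

    ``blacks`` is boolean (n_trials, n_draws).  Ordered-sequence likelihood:
    step t contributes (B - b_prev)/(N - t + 1) on black and
    (W - w_prev)/(N - t + 1) on white.
    """
    black0, white0 = counts
    n_trials, n_draws = blacks.shape
    steps = np.arange(1, n_draws + 1)
    cum_black = np.cumsum(blacks, axis=1)
    b_prev = cum_black - blacks  # blacks before each step
    w_prev = (steps - 1) - b_prev
    remain_black = black0 - b_prev
    remain_white = white0 - w_prev
    numer = np.where(blacks, remain_black, remain_white).astype(float)
    with np.errstate(divide="ignore"):
        log_terms = np.where(numer > 0, np.log(np.maximum(numer, 1e-300)), -np.inf) \
            - np.log(black0 + white0 - (steps - 1.0))
    return np.cumsum(log_terms, axis=1)


def score_features(spec: UrnSpec, blacks: np.ndarray,
                   measures: Optional[Dict[str, MeasureSpec]] = None,
                   evidence_unit: str = "cumulative") -> Dict[str, np.ndarray]:
    """Objective posteriors and per-measure scores for a batch of trials.

    Returns a dict with ``"O"`` (n_trials, n_draws + 1; column 0 is the
    selection prior) and, for each measure key X, arrays ``"A_X"`` and
    ``"B_X"`` of per-step scores of the two urn hypotheses (n_trials,
    n_draws).  Only two-urn specs are supported on this path.
    """
    if len(spec.labels) != 2:
        raise ValueError("the batch path supports exactly two urns")
    if evidence_unit not in ("cumulative", "latest"):
        raise ValueError(f"unknown evidence_unit {evidence_unit!r}")
    measures = study_measures() if measures is None else measures
    blacks = np.asarray(blacks, dtype=bool)
    ll_a = _cumulative_loglik(spec.counts[0], blacks)
    ll_b = _cumulative_loglik(spec.counts[1], blacks)
    pa, pb = float(spec.priors[0]), float(spec.priors[1])
    joint_a, joint_b = pa * np.exp(ll_a), pb * np.exp(ll_b)
    marg = joint_a + joint_b
    O = np.concatenate([np.full((blacks.shape[0], 1), pa), joint_a / marg], axis=1)

    if evidence_unit == "cumulative":
        prior_a, prior_b = pa, pb
        lik_a, lik_b = np.exp(ll_a), np.exp(ll_b)
    else:
        prior_a = O[:, :-1]
        prior_b = 1.0 - prior_a
        lik_a = np.exp(np.diff(np.concatenate(
            [np.zeros((blacks.shape[0], 1)), ll_a], axis=1), axis=1))
        lik_b = np.exp(np.diff(np.concatenate(
            [np.zeros((blacks.shape[0], 1)), ll_b], axis=1), axis=1))
    pe = prior_a * lik_a + prior_b * lik_b

    out: Dict[str, np.ndarray] = {"O": O}
    for key, m in measures.items():
        for side, prior, lik in (("A", prior_a, lik_a), ("B", prior_b, lik_b)):
            if m.id == "simple":
                sc = lik - pe
            elif m.id == "popper":
                sc = (lik - pe) / (lik + pe)
            elif m.id in ("good", "good_rescaled"):
                with np.errstate(divide="ignore"):
                    good = np.log(lik) - np.log(pe)
                if m.id == "good":
                    sc = good
                else:
                    sc = np.sign(good) * (1.0 - np.exp(-good ** 2 / (2.0 * m.alpha ** 2)))
                    sc = np.where(np.isinf(good), np.sign(good), sc)
            elif m.id == "schupbach_sprenger":
                ph_e = prior * lik / pe
                ph_ne = prior * (1.0 - lik) / (1.0 - pe)
                sc = (ph_e - ph_ne) / (ph_e + ph_ne)
            else:  # pragma: no cover
                raise ValueError(f"unknown measure {m.id!r}")
            out[f"{side}_{key}"] = sc
    return out
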