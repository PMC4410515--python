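"""Synthetic credence data with the urn-study's regression structure.

The original interview data (26 participants, each watching 10 draws from a
coin-selected urn) are not public.  This module generates stand-in datasets
with the statistical structure the regression analysis assumes: for every
participant a fresh urn trial is simulated, the objective posterior O and the
per-hypothesis explanatory-power scores are computed from the urn model, and
the reported credence is

    S = b0 + bO * O + bA * A + bB * B + eps,    eps ~ Normal(0, sigma^2),

truncated to [0, 1] by resampling eps (not clipping, which would pile mass on
the boundaries and break the linear-Gaussian likelihood the analysis
assumes).  The default coefficients (0.33, 0.40, 0.24, -0.13) are the
published estimates for the best explanationist model, with scores computed
under the L_2 rescaling of Good's measure (G3); sigma defaults to 0.08, which
places the generating model's R^2 near the published 0.84-0.86 band.

Human judgments of explanatory goodness are emulated as the computed scores
plus clipped Gaussian noise (the original study found computed degrees to
track judgments closely).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .measures import MeasureSpec, study_measures
from .urn import UrnSpec, score_features, simulate_trials

#: Published coefficient estimates (intercept, O, A_G3, B_G3) used as defaults.
DEFAULT_COEFFICIENTS = (0.33, 0.40, 0.24, -0.13)

SCORE_COLUMNS = [f"{side}_{key}" for key in ("P", "G1", "G2", "G3", "SS")
                 for side in ("A", "B")]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one synthetic dataset.

    ``coefficients`` are (intercept, slope on O, slope on the A-score, slope
    on the B-score); ``noise_sd`` is the credence noise sigma; ``measure``
    selects which score family feeds the generating model (default G3 = L_2);
    ``judgment_noise_sd`` controls how far emulated judgments stray from
    computed scores.  ``participant_sd`` > 0 adds Normal participant-level
    intercepts (off by default: the analysis pools observations).
    """

    n_participants: int = 26
    n_draws: int = 10
    coefficients: Tuple[float, float, float, float] = DEFAULT_COEFFICIENTS
    noise_sd: float = 0.08
    measure: MeasureSpec = field(default_factory=lambda: MeasureSpec("good_rescaled", 2.0))
    judgment_noise_sd: float = 0.05
    participant_sd: float = 0.0
    evidence_unit: str = "cumulative"
    urns: UrnSpec = field(default_factory=UrnSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.noise_sd < 0 or self.judgment_noise_sd < 0 or self.participant_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    @classmethod
    def from_dict(cls, obj: dict) -> "GeneratorConfig":
        kwargs = dict(obj)
        if "measure" in kwargs:
            kwargs["measure"] = MeasureSpec.from_config(kwargs["measure"])
        if "coefficients" in kwargs:
            kwargs["coefficients"] = tuple(kwargs["coefficients"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_draws": self.n_draws,
            "coefficients": list(self.coefficients),
            "noise_sd": self.noise_sd,
            "measure": self.measure.to_config(),
            "judgment_noise_sd": self.judgment_noise_sd,
            "participant_sd": self.participant_sd,
            "evidence_unit": self.evidence_unit,
            "seed": self.seed,
        }


def _generating_scores(config: GeneratorConfig, feats: dict,
                       spec_measures: dict) -> Tuple[np.ndarray, np.ndarray]:
    """Score arrays of the generating measure, reusing study columns if possible."""
    for key, m in spec_measures.items():
        if m == config.measure:
            return feats[f"A_{key}"], feats[f"B_{key}"]
    extra = score_features(config.urns,
                           feats["_blacks"], measures={"GEN": config.measure},
                           evidence_unit=config.evidence_unit)
    return extra["A_GEN"], extra["B_GEN"]


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate one synthetic study.

    Returns a tidy table with one row per participant and draw step:
    ``participant_id``, ``step``, ``color``, the objective posterior ``O``,
    score columns ``A_X``/``B_X`` for every study measure X in
    {P, G1, G2, G3, SS}, the generating measure's ``score_A``/``score_B``,
    noisy ``judged_A``/``judged_B``, and the credence ``S``.  The result is a
    pure function of the config (byte-identical CSV on regeneration); the
    config echo and the truncation rate are stored in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_participants, config.n_draws
    urns, blacks = simulate_trials(config.urns, n, k, rng)
    spec_measures = study_measures()
    feats = score_features(config.urns, blacks, measures=spec_measures,
                           evidence_unit=config.evidence_unit)
    feats["_blacks"] = blacks
    score_a, score_b = _generating_scores(config, feats, spec_measures)

    b0, b_o, b_a, b_b = config.coefficients
    O = feats["O"][:, 1:]  # objective posterior after each draw
    mean = b0 + b_o * O + b_a * score_a + b_b * score_b
    if config.participant_sd > 0:
        mean = mean + rng.normal(0.0, config.participant_sd, size=(n, 1))

    s = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    truncated = 0
    if config.noise_sd > 0:
        bad = (s < 0.0) | (s > 1.0)
        truncated = int(bad.sum())
        for _ in range(1000):
            if not bad.any():
                break
            s[bad] = mean[bad] + rng.normal(0.0, config.noise_sd, size=int(bad.sum()))
            bad = (s < 0.0) | (s > 1.0)
        else:  # pragma: no cover - would need a pathological config
            raise RuntimeError("credence resampling failed to land in [0, 1]")
    else:
        s = np.clip(s, 0.0, 1.0)

    rate = truncated / s.size
    if rate >= 0.05:
        warnings.warn(f"credence truncation rate {rate:.1%} exceeds 5%; "
                      "the linear-Gaussian assumption is strained", stacklevel=2)

    df = pd.DataFrame({
        "participant_id": np.repeat(np.arange(1, n + 1), k),
        "step": np.tile(np.arange(1, k + 1), n),
        "color": np.where(blacks.ravel(), "B", "W"),
        "O": O.ravel(),
    })
    for col in SCORE_COLUMNS:
        df[col] = feats[col].ravel()
    df["score_A"] = score_a.ravel()
    df["score_B"] = score_b.ravel()
    df = add_judgment_noise(df, config.judgment_noise_sd, rng,
                            bounded=config.measure.bounded)
    df["S"] = s.ravel()
    df.attrs["config"] = config.to_dict()
    df.attrs["truncation_rate"] = rate
    df.attrs["selected_urns"] = [config.urns.labels[i] for i in urns]
    return df


def add_judgment_noise(table: pd.DataFrame, sd: float, seed,
                       bounded: bool = True) -> pd.DataFrame:
    """Emulate judged explanatory goodness as noisy computed scores.

    ``judged_A``/``judged_B`` = ``score_A``/``score_B`` plus Normal(0, sd^2)
    noise, clipped to [-1, 1] when the generating measure is bounded.
    """
    if sd < 0:
        raise ValueError("judgment noise sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    for side in ("A", "B"):
        judged = out[f"score_{side}"].to_numpy(dtype=float)
        if sd > 0:
            judged = judged + rng.normal(0.0, sd, size=judged.shape)
        if bounded:
            judged = np.clip(judged, -1.0, 1.0)
        out[f"judged_{side}"] = judged
    return out


def write_trials(table: pd.DataFrame, path, measure: Optional[MeasureSpec] = None,
                 float_format: Optional[str] = None) -> None:
    """Write a trial table as RFC-4180 CSV with the measure in a comment line."""
    if measure is None:
        cfg = table.attrs.get("config")
        measure = MeasureSpec.from_config(cfg["measure"]) if cfg else None
    buf = io.StringIO()
    if measure is not None:
        alpha = "" if measure.alpha is None else f" alpha={measure.alpha}"
        buf.write(f"# measure={measure.id}{alpha}\n")
    table.to_csv(buf, index=False, lineterminator="\n", float_format=float_format)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    return pd.read_csv(path, comment="#")


def resample_config(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """The same study conditions under a different random seed."""
    return replace(config, seed=seed)
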