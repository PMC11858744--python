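"""Synthetic 2AFC observers and trial-level dataset generation.

The simulated observer judges perceived rather than physical viscosity: each
appearance carries a multiplicative gain beta, so an opaque reference of
viscosity r is perceived as beta_opaque * r.  With gains below 1 for
transparent liquids the model reproduces an appearance-driven bias in which a
transparent test must be physically thicker than an opaque reference to be
perceived as equal (the free-p fit then recovers
PSE = (beta_ref / beta_test) * r analytically).  An additive-shift variant
is available for sensitivity analysis.  Optional lapse mixes in stimulus-
independent guessing, and log-normal per-subject scatter on w and beta lets
pooled population curves flatten relative to individual ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import presets
from .data import (
    ExperimentDesign,
    PairSpec,
    TrialRecord,
    ValidationError,
    build_group_designs,
    builtin_stimuli,
    enumerate_unique_pairs,
)
from .psychometric import PsychometricParams, predict


@dataclass(frozen=True)
class ObserverSpec:
    """Generative observer: group-wise Weber fractions, appearance gains,
    lapse rate and per-subject heterogeneity (log-normal SDs)."""

    w_by_group: Mapping[str, float]
    appearance_gain: Mapping[str, float] = field(
        default_factory=lambda: {"transparent": 1.0, "opaque": 1.0}
    )
    lapse: float = 0.0
    subject_sd_logw: float = 0.0
    subject_sd_logbeta: float = 0.0
    bias_model: str = "multiplicative"  # or "additive" (gains become cP offsets)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.w_by_group.values()):
            raise ValidationError("all Weber fractions must be positive")
        if self.bias_model not in ("multiplicative", "additive"):
            raise ValidationError(f"unknown bias_model {self.bias_model!r}")
        if self.bias_model == "multiplicative" and any(
            b <= 0 for b in self.appearance_gain.values()
        ):
            raise ValidationError("multiplicative gains must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValidationError("lapse must be in [0, 0.1]")
        if self.subject_sd_logw < 0 or self.subject_sd_logbeta < 0:
            raise ValidationError("heterogeneity SDs must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    design: ExperimentDesign
    n_subjects: int
    seed: int
    observer: ObserverSpec
    side_labels: tuple[str, str] = ("left", "right")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


def _perceived(viscosity: float, appearance: str, gains: Mapping[str, float],
               bias_model: str) -> float:
    gain = gains.get(appearance, 1.0 if bias_model == "multiplicative" else 0.0)
    if bias_model == "multiplicative":
        return viscosity * gain
    return viscosity + gain


def response_probability(
    pair: PairSpec,
    w: float,
    appearance_gain: Mapping[str, float] | None = None,
    lapse: float = 0.0,
    bias_model: str = "multiplicative",
) -> float:
    """P('test thicker') for one pair under realized observer parameters:
    lapse/2 + (1-lapse) * f(perceived test; p=perceived reference, w)."""
    gains = appearance_gain or {}
    p_ref = _perceived(pair.reference.viscosity, pair.reference.appearance,
                       gains, bias_model)
    eta = _perceived(pair.test.viscosity, pair.test.appearance, gains, bias_model)
    if p_ref <= 0 or eta <= 0:
        raise ValidationError("perceived viscosities must stay positive")
    base = predict(eta, PsychometricParams(w, p_ref))
    return lapse / 2.0 + (1.0 - lapse) * float(base)


def simulate_experiment(config: SimulationConfig) -> list[TrialRecord]:
    """Draw one Bernoulli response per subject per pair; deterministic per seed.

    Per-subject parameters are log-normal perturbations of the observer's
    group Weber fractions and appearance gains; the shared boundary pairs use
    their home group's w.  Presentation side is randomized uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    obs = config.observer
    records: list[TrialRecord] = []
    side_a, side_b = config.side_labels
    appearances = sorted(set(obs.appearance_gain))
    for s in range(config.n_subjects):
        pid = f"S{s + 1:03d}"
        w_subj = {
            g: w * float(np.exp(obs.subject_sd_logw * rng.standard_normal()))
            for g, w in obs.w_by_group.items()
        }
        gains_subj = {
            a: obs.appearance_gain[a]
            * float(np.exp(obs.subject_sd_logbeta * rng.standard_normal()))
            if obs.bias_model == "multiplicative"
            else obs.appearance_gain[a]
            for a in appearances
        }
        for pair in config.design.pairs:
            group = pair.home_group
            if group not in w_subj:
                raise ValidationError(f"observer has no Weber fraction for group {group}")
            prob = response_probability(
                pair, w_subj[group], gains_subj, obs.lapse, obs.bias_model
            )
            thicker = bool(rng.random() < prob)
            ref_side = side_a if rng.random() < 0.5 else side_b
            records.append(
                TrialRecord(
                    participant_id=pid,
                    task_id=config.design.task_id,
                    group_label=group,
                    reference_viscosity=pair.reference.viscosity,
                    test_viscosity=pair.test.viscosity,
                    reference_appearance=pair.reference.appearance,
                    test_appearance=pair.test.appearance,
                    reference_side=ref_side,
                    response_test_thicker=thicker,
                )
            )
    return records


def scenario(name: str, n_subjects: int | None = None, seed: int = 0) -> SimulationConfig:
    """Preset simulation matching one of the bundled task layouts.

    Known names: task1a, task1b, task1c, task2, task3a, task3b.  Cohort
    sizes, appearance pairings and Weber-fraction magnitudes echo the studies
    the package was written for; ``n_subjects`` overrides the preset size.
    """
    if name not in presets.TASK_PRESETS:
        raise ValidationError(
            f"unknown scenario {name!r}; known: {sorted(presets.TASK_PRESETS)}"
        )
    preset = presets.TASK_PRESETS[name]
    ref_stim = builtin_stimuli(preset.reference_appearance)
    test_stim = builtin_stimuli(preset.test_appearance)
    groups = build_group_designs(ref_stim, test_stimuli=test_stim)
    dedup = (
        "within_appearance"
        if preset.reference_appearance == preset.test_appearance
        else "none"
    )
    design = enumerate_unique_pairs(
        groups, include_equal_pair=True, dedup_policy=dedup, task_id=name
    )
    observer = ObserverSpec(
        w_by_group=dict(preset.w_by_group),
        appearance_gain=dict(preset.appearance_gain),
    )
    sides = ("first", "second") if preset.modality == "haptic" else ("left", "right")
    return SimulationConfig(
        design=design,
        n_subjects=n_subjects if n_subjects is not None else preset.n_subjects,
        seed=seed,
        observer=observer,
        side_labels=sides,
    )
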