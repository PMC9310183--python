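"""Synthetic interaction tables and object-choice trials.

No coded chimpanzee interaction dataset is publicly deposited, so the
evaluation pipeline is exercised on synthetic tables that carry the
statistical structure the model assumes: each communicative event draws a
(gesture, facial, context, dominance) combination from a frequency table
and a Bernoulli reaction whose avoidant probability is the model posterior
for that combination. Real interaction data are messier — individuals are
not exchangeable, dyads repeat, coders disagree — and none of that is
modelled here; records are exchangeable given their combination.

The default combination frequencies are deliberately skewed toward the
negative social context (85% of events), mirroring field data in which
only negative-context combinations accumulate enough observations to clear
the minimum-count filter, while keeping the positive context testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import CueParameters, SocialSetting, Utterance, infer_intention
from .errors import DomainError, ParseError
from .evaluation import InteractionRecord
from .pragmatics import (
    RSAScenario,
    literal_receiver,
    pointed_target,
    pragmatic_receiver,
)
from .registry import AFFILIATIVE, AVOIDANT, DEFAULT_REGISTRY, SignalRegistry

__all__ = [
    "CombinationFrequencies",
    "TrialOutcome",
    "default_parameters",
    "default_frequencies",
    "generate_records",
    "generate_object_choice_trials",
]


def default_parameters(registry: SignalRegistry = DEFAULT_REGISTRY) -> CueParameters:
    """The reference cue weights for the coded chimpanzee categories.

    Stretched-arm is weakly avoidant (0.53), bent-arm weakly affiliative
    (0.47); the neutral face is neutral (0.5), bared-teeth weakly avoidant
    (0.6), funneled-lip strongly avoidant (0.9); a negative context leans
    avoidant (0.7) and a positive one affiliative (0.3); a dominant sender
    predicts an affiliative outcome (0.25) and a subordinate sender an
    avoidant one (0.75).
    """
    return CueParameters(
        gesture={"stretched_arm": 0.53, "bent_arm": 0.47},
        facial={"neutral": 0.5, "bared_teeth": 0.6, "funneled_lip": 0.9},
        context={"negative": 0.7, "positive": 0.3},
        dominance={"dominant_sender": 0.25, "subordinate_sender": 0.75},
        registry=registry,
    )


@dataclass(frozen=True)
class CombinationFrequencies:
    """A probability distribution over cue combinations."""

    probabilities: Mapping[tuple[str, str, str, str], float]
    registry: SignalRegistry = DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        valid = set(self.registry.combinations())
        unknown = set(probs) - valid
        if unknown:
            raise DomainError(f"unknown combinations: {sorted(unknown)[:3]}...")
        values = np.array(list(probs.values()), dtype=float)
        if np.any(values < 0) or abs(values.sum() - 1.0) > 1e-9:
            raise DomainError(
                "combination frequencies must be nonnegative and sum to 1"
            )
        object.__setattr__(self, "probabilities", probs)

    def as_arrays(self) -> tuple[list[tuple[str, str, str, str]], np.ndarray]:
        combos = list(self.probabilities)
        return combos, np.array(
            [self.probabilities[c] for c in combos], dtype=float
        )

    def to_json(self, path: str | Path) -> None:
        payload = {"|".join(c): p for c, p in self.probabilities.items()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(
        cls, path: str | Path, registry: SignalRegistry = DEFAULT_REGISTRY
    ) -> "CombinationFrequencies":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid frequency file {path}: {exc}") from exc
        probs = {}
        for key, p in payload.items():
            parts = tuple(key.split("|"))
            if len(parts) != 4:
                raise ParseError(f"bad combination key {key!r}")
            probs[parts] = float(p)
        return cls(probabilities=probs, registry=registry)


def default_frequencies(
    registry: SignalRegistry = DEFAULT_REGISTRY, negative_share: float = 0.85
) -> CombinationFrequencies:
    """Negative-context-skewed frequencies: ``negative_share`` of the mass
    on the negative context, uniform over combinations within context."""
    if not 0.0 <= negative_share <= 1.0:
        raise DomainError(f"negative_share must lie in [0, 1]")
    combos = list(registry.combinations())
    by_context = {"negative": [], "positive": []}
    for combo in combos:
        by_context[combo[2]].append(combo)
    probs: dict[tuple[str, str, str, str], float] = {}
    for context, share in (
        ("negative", negative_share),
        ("positive", 1.0 - negative_share),
    ):
        cell = share / len(by_context[context])
        for combo in by_context[context]:
            probs[combo] = cell
    return CombinationFrequencies(probabilities=probs, registry=registry)


def generate_records(
    params: CueParameters,
    freqs: CombinationFrequencies | None = None,
    n: int = 1000,
    seed: int | None = 0,
) -> list[InteractionRecord]:
    """Draw ``n`` synthetic interaction records.

    Each record's combination is drawn from ``freqs`` and its reaction is
    Bernoulli with the model's posterior avoidant probability for that
    combination. Deterministic given ``seed``.
    """
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    freqs = freqs or default_frequencies(params.registry)
    combos, probs = freqs.as_arrays()
    p_avoid = np.array(
        [
            infer_intention(
                Utterance(g, f), SocialSetting(c, s), params
            ).p_avoidant
            for g, f, c, s in combos
        ]
    )
    rng = np.random.default_rng(seed)
    combo_idx = rng.choice(len(combos), size=n, p=probs)
    avoidant = rng.random(n) < p_avoid[combo_idx]
    return [
        InteractionRecord(
            *combos[i], reaction=AVOIDANT if a else AFFILIATIVE
        )
        for i, a in zip(combo_idx, avoidant)
    ]


@dataclass(frozen=True)
class TrialOutcome:
    """One synthetic object-choice trial."""

    scenario_id: str
    receiver: str  # "literal" or "pragmatic"
    target: str
    chosen: str
    correct: bool


def generate_object_choice_trials(
    scenario: RSAScenario,
    receiver: str,
    n: int = 1000,
    seed: int | None = 0,
    scenario_id: str = "scenario",
) -> list[TrialOutcome]:
    """Simulate ``n`` object-choice trials.

    Each trial picks a target referent uniformly, the sender produces the
    utterance whose semantics points at that target, and the receiver
    samples a choice from PR0 (``receiver="literal"``) or PR1
    (``receiver="pragmatic"``). The long-run correct rate therefore tracks
    PR0(target | point) or PR1(target | point) respectively.
    """
    if receiver not in ("literal", "pragmatic"):
        raise DomainError(
            f"receiver must be 'literal' or 'pragmatic', got {receiver!r}"
        )
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    interpret = literal_receiver if receiver == "literal" else pragmatic_receiver
    # sender picks the utterance most strongly associated with the target
    # (argmax of the semantics column; first utterance on ties)
    point_for = {
        target: scenario.utterances[
            int(np.argmax(scenario.semantics[:, ri]))
        ]
        for ri, target in enumerate(scenario.referents)
    }
    dists = {
        target: interpret(point_for[target], scenario).to_numpy()
        for target in scenario.referents
    }
    rng = np.random.default_rng(seed)
    targets = rng.choice(len(scenario.referents), size=n)
    trials = []
    for t_idx in targets:
        target = scenario.referents[t_idx]
        chosen = scenario.referents[
            rng.choice(len(scenario.referents), p=dists[target])
        ]
        trials.append(
            TrialOutcome(
                scenario_id=scenario_id,
                receiver=receiver,
                target=target,
                chosen=chosen,
                correct=chosen == target,
            )
        )
    return trials
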