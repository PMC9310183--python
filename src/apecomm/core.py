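"""Bayesian integration of multimodal cues into an intention posterior.

The receiver is modelled as a Bayesian observer: an utterance ``u = (g, f)``
(a manual gesture plus a facial expression) is interpreted in a social
setting ``(c, s)`` (context valence plus dominance relation), yielding a
posterior over the binary intention ``i``::

    P(i | u) ∝ P(u | i) P(i)
    P(u | i) = L(g, i | θ_g) · L(f, i | θ_f)
    P(i)     = P(i | c, s) = ρ_c · ρ_s

Every cue carries a *soft semantics*: a single weight θ ∈ [0, 1] giving its
unnormalized multiplicative weight toward the avoidant intention (and 1 − θ
toward the affiliative one). θ = 0.5 is informationally neutral; values
below 0.5 lean affiliative, values above lean avoidant. Because the two
intention weights are θ and 1 − θ, each cue contributes log(θ / (1 − θ)) to
the posterior log-odds, making the model additive on the logit scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePosteriorError,
    DomainError,
    InfiniteLogitError,
    ParseError,
    RegistryError,
)
from .registry import (
    AFFILIATIVE,
    AVOIDANT,
    COMPONENTS,
    DEFAULT_REGISTRY,
    Intention,
    SignalRegistry,
)

__all__ = [
    "CueParameters",
    "Utterance",
    "SocialSetting",
    "IntentionPosterior",
    "cue_weight",
    "utterance_likelihood",
    "intention_prior",
    "infer_intention",
    "posterior_log_odds",
    "prediction_grid",
    "reduced_parameters",
    "GRID_COLUMNS",
]

GRID_COLUMNS = ["gesture", "facial", "context", "dominance", "p_avoidant"]


def _check_unit_interval(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class Utterance:
    """A multimodal communicative act: one gesture plus one facial
    expression (an absent facial expression is coded ``neutral``)."""

    gesture: str
    facial: str


@dataclass(frozen=True)
class SocialSetting:
    """The contextual side of an interaction: context valence and the
    dominance relation of the sender relative to the receiver."""

    context: str
    dominance: str


@dataclass(frozen=True)
class IntentionPosterior:
    """Normalized belief over the two intentions."""

    p_affiliative: float
    p_avoidant: float

    def __post_init__(self) -> None:
        _check_unit_interval("p_affiliative", self.p_affiliative)
        _check_unit_interval("p_avoidant", self.p_avoidant)
        if abs(self.p_affiliative + self.p_avoidant - 1.0) > 1e-9:
            raise DomainError(
                "posterior must sum to 1, got "
                f"{self.p_affiliative} + {self.p_avoidant}"
            )

    def __getitem__(self, intention: Intention | str) -> float:
        intention = Intention(intention)
        return self.p_avoidant if intention is AVOIDANT else self.p_affiliative


class CueParameters:
    """Soft-semantics weight for every registry label.

    Each label in each of the four component groups carries one weight in
    [0, 1], read as the unnormalized weight of the *avoidant* intention.
    Instances are immutable; derive variants with :meth:`replace`.

    Parameters
    ----------
    gesture, facial, context, dominance
        Mappings from label to weight, covering the registry exactly.
    registry
        The registry the parameters must cover (default: the coded
        chimpanzee categories).
    """

    def __init__(
        self,
        gesture: Mapping[str, float],
        facial: Mapping[str, float],
        context: Mapping[str, float],
        dominance: Mapping[str, float],
        registry: SignalRegistry = DEFAULT_REGISTRY,
    ) -> None:
        self.registry = registry
        given = {
            "gesture": dict(gesture),
            "facial": dict(facial),
            "context": dict(context),
            "dominance": dict(dominance),
        }
        self._weights: dict[str, dict[str, float]] = {}
        for component, table in given.items():
            expected = set(registry.labels(component))
            if set(table) != expected:
                missing = expected - set(table)
                extra = set(table) - expected
                raise RegistryError(
                    f"{component} parameters must cover the registry exactly; "
                    f"missing={sorted(missing)} unexpected={sorted(extra)}"
                )
            self._weights[component] = {
                label: _check_unit_interval(f"{component}.{label}", theta)
                for label, theta in table.items()
            }

    def weight(self, component: str, label: str) -> float:
        """The avoidant-leaning weight θ for one registry label."""
        self.registry.require(component, label)
        return self._weights[component][label]

    def component(self, component: str) -> dict[str, float]:
        if component not in COMPONENTS:
            raise RegistryError(
                f"unknown component {component!r}; expected one of {COMPONENTS}"
            )
        return dict(self._weights[component])

    def replace(self, **components: Mapping[str, float]) -> "CueParameters":
        """Return a copy with whole component tables replaced."""
        tables = {c: dict(self._weights[c]) for c in COMPONENTS}
        for component, table in components.items():
            if component not in COMPONENTS:
                raise RegistryError(f"unknown component {component!r}")
            tables[component] = dict(table)
        return CueParameters(registry=self.registry, **tables)

    # -- flat key-value serialization: "gesture.<label>": theta ------------

    def to_flat_dict(self) -> dict[str, float]:
        return {
            f"{component}.{label}": theta
            for component in COMPONENTS
            for label, theta in self._weights[component].items()
        }

    @classmethod
    def from_flat_dict(
        cls, flat: Mapping[str, float], registry: SignalRegistry = DEFAULT_REGISTRY
    ) -> "CueParameters":
        tables: dict[str, dict[str, float]] = {c: {} for c in COMPONENTS}
        for key, value in flat.items():
            component, sep, label = str(key).partition(".")
            if not sep or component not in COMPONENTS:
                raise ParseError(f"unknown parameter key {key!r}")
            registry.require(component, label)
            tables[component][label] = value
        return cls(registry=registry, **tables)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_flat_dict(), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(
        cls, path: str | Path, registry: SignalRegistry = DEFAULT_REGISTRY
    ) -> "CueParameters":
        try:
            flat = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid parameter file {path}: {exc}") from exc
        if not isinstance(flat, dict):
            raise ParseError(f"parameter file {path} must hold a JSON object")
        return cls.from_flat_dict(flat, registry=registry)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CueParameters):
            return NotImplemented
        return self._weights == other._weights and self.registry == other.registry

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{k}={v:.3g}" for k, v in sorted(self.to_flat_dict().items())
        )
        return f"CueParameters({parts})"


def cue_weight(theta: float, intention: Intention | str) -> float:
    """Unnormalized weight a single cue assigns to ``intention``.

    ``theta`` is the cue's avoidant-leaning weight; the affiliative weight
    is its complement ``1 - theta``.
    """
    theta = _check_unit_interval("theta", theta)
    return theta if Intention(intention) is AVOIDANT else 1.0 - theta


def utterance_likelihood(
    u: Utterance, intention: Intention | str, params: CueParameters
) -> float:
    """P(u | i): product of the gesture's and facial's cue weights."""
    g = params.weight("gesture", u.gesture)
    f = params.weight("facial", u.facial)
    return cue_weight(g, intention) * cue_weight(f, intention)


def intention_prior(
    setting: SocialSetting, intention: Intention | str, params: CueParameters
) -> float:
    """P(i | c, s): product of the context and dominance cue weights."""
    c = params.weight("context", setting.context)
    s = params.weight("dominance", setting.dominance)
    return cue_weight(c, intention) * cue_weight(s, intention)


def infer_intention(
    u: Utterance, setting: SocialSetting, params: CueParameters
) -> IntentionPosterior:
    """Posterior over intentions given the full multimodal observation.

    Raises
    ------
    DegeneratePosteriorError
        If both intentions receive exactly zero weight (possible only with
        hard 0/1 cue weights pulling in opposite directions).
    """
    w_avoid = utterance_likelihood(u, AVOIDANT, params) * intention_prior(
        setting, AVOIDANT, params
    )
    w_affil = utterance_likelihood(u, AFFILIATIVE, params) * intention_prior(
        setting, AFFILIATIVE, params
    )
    total = w_avoid + w_affil
    if total == 0.0:
        raise DegeneratePosteriorError(
            f"both intention weights are zero for {u}, {setting}: "
            "conflicting hard (0/1) cue weights"
        )
    return IntentionPosterior(
        p_affiliative=w_affil / total, p_avoidant=w_avoid / total
    )


def posterior_log_odds(
    u: Utterance, setting: SocialSetting, params: CueParameters
) -> float:
    """Log-odds of avoidant vs affiliative: Σ log(θ / (1 − θ)) over the four
    active cues. ``sigmoid`` of the result equals ``infer_intention``'s
    p_avoidant; used as an algebraic cross-check of the product form.

    Raises
    ------
    InfiniteLogitError
        If any involved cue weight is exactly 0 or 1.
    """
    thetas = (
        params.weight("gesture", u.gesture),
        params.weight("facial", u.facial),
        params.weight("context", setting.context),
        params.weight("dominance", setting.dominance),
    )
    total = 0.0
    for theta in thetas:
        if theta in (0.0, 1.0):
            raise InfiniteLogitError(
                f"cue weight {theta} has infinite log-odds"
            )
        total += math.log(theta / (1.0 - theta))
    return total


def prediction_grid(
    params: CueParameters, registry: SignalRegistry | None = None
) -> pd.DataFrame:
    """Posterior avoidant probability for every registry combination.

    Returns a DataFrame with columns ``gesture, facial, context, dominance,
    p_avoidant``, one row per (g, f, c, s) combination in registry order
    (24 rows under the default registry).
    """
    registry = registry or params.registry
    if registry is not params.registry:
        # params may carry a different but compatible registry; re-validate
        for component in COMPONENTS:
            if set(registry.labels(component)) - set(
                params.registry.labels(component)
            ):
                raise RegistryError(
                    f"parameters do not cover registry component {component!r}"
                )
    rows = []
    for g, f, c, s in registry.combinations():
        post = infer_intention(Utterance(g, f), SocialSetting(c, s), params)
        rows.append((g, f, c, s, post.p_avoidant))
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def write_grid(grid: pd.DataFrame, path: str | Path) -> None:
    """Serialize a prediction grid as RFC 4180 CSV."""
    grid.to_csv(path, index=False, lineterminator="\r\n")


def read_grid(path: str | Path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    if list(grid.columns) != GRID_COLUMNS:
        raise ParseError(
            f"grid file {path} must have columns {GRID_COLUMNS}, "
            f"got {list(grid.columns)}"
        )
    return grid


def reduced_parameters(params: CueParameters, keep: str) -> CueParameters:
    """Single-component reduction: every weight outside the ``keep``
    component is set to the neutral value 0.5, so the posterior reflects
    that component alone."""
    if keep not in COMPONENTS:
        raise DomainError(
            f"keep must be one of {COMPONENTS}, got {keep!r}"
        )
    neutral = {
        component: {label: 0.5 for label in params.registry.labels(component)}
        for component in COMPONENTS
        if component != keep
    }
    return params.replace(**neutral)
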