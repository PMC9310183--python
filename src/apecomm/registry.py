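"""Signal registries and the binary intention space.

The intention space is fixed at two levels — ``affiliative`` and
``avoidant`` — because the receiver's inferred state is operationalized as a
binary reaction. Signal categories (gestures, facial expressions, social
contexts, dominance relations) are open data: the default registry carries
the categories used in coded chimpanzee interaction tables, but new labels
(e.g. vocalizations as a third utterance component are out of scope, yet
additional gestures are not) can be registered without touching code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

from .errors import RegistryError

__all__ = ["Intention", "AFFILIATIVE", "AVOIDANT", "SignalRegistry", "COMPONENTS"]

#: The four cue component groups, in canonical order.
COMPONENTS = ("gesture", "facial", "context", "dominance")


class Intention(str, enum.Enum):
    """One of the two intention levels a receiver can infer."""

    AFFILIATIVE = "affiliative"
    AVOIDANT = "avoidant"

    @property
    def complement(self) -> "Intention":
        return AVOIDANT if self is AFFILIATIVE else AFFILIATIVE

    def __str__(self) -> str:
        return self.value


AFFILIATIVE = Intention.AFFILIATIVE
AVOIDANT = Intention.AVOIDANT


def _check_unique(name: str, labels: tuple[str, ...]) -> None:
    if len(set(labels)) != len(labels):
        raise RegistryError(f"duplicate {name} labels: {labels!r}")
    if not labels:
        raise RegistryError(f"registry component {name!r} has no labels")


@dataclass(frozen=True)
class SignalRegistry:
    """The set of valid labels for each cue component.

    Parameters
    ----------
    gestures, facials, contexts, dominances
        Unique lowercase snake_case labels for each component group.
    """

    gestures: tuple[str, ...] = ("stretched_arm", "bent_arm")
    facials: tuple[str, ...] = ("neutral", "bared_teeth", "funneled_lip")
    contexts: tuple[str, ...] = ("positive", "negative")
    dominances: tuple[str, ...] = ("dominant_sender", "subordinate_sender")

    def __post_init__(self) -> None:
        object.__setattr__(self, "gestures", tuple(self.gestures))
        object.__setattr__(self, "facials", tuple(self.facials))
        object.__setattr__(self, "contexts", tuple(self.contexts))
        object.__setattr__(self, "dominances", tuple(self.dominances))
        for name in COMPONENTS:
            _check_unique(name, self.labels(name))

    def labels(self, component: str) -> tuple[str, ...]:
        """Labels for one component group (``gesture``/``facial``/...)."""
        try:
            return {
                "gesture": self.gestures,
                "facial": self.facials,
                "context": self.contexts,
                "dominance": self.dominances,
            }[component]
        except KeyError:
            raise RegistryError(
                f"unknown component {component!r}; expected one of {COMPONENTS}"
            ) from None

    def require(self, component: str, label: str) -> str:
        """Validate ``label`` against ``component``, returning it unchanged."""
        if label not in self.labels(component):
            raise RegistryError(
                f"unknown {component} label {label!r}; "
                f"registry has {self.labels(component)}"
            )
        return label

    def combinations(self) -> Iterator[tuple[str, str, str, str]]:
        """All (gesture, facial, context, dominance) combinations, in
        registry order (row-major: gesture slowest)."""
        for g in self.gestures:
            for f in self.facials:
                for c in self.contexts:
                    for s in self.dominances:
                        yield (g, f, c, s)

    @property
    def n_combinations(self) -> int:
        return (
            len(self.gestures)
            * len(self.facials)
            * len(self.contexts)
            * len(self.dominances)
        )


#: Registry of the coded chimpanzee interaction categories.
DEFAULT_REGISTRY = SignalRegistry()
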