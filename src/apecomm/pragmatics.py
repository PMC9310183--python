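"""Rational Speech Act (RSA) recursion over object-choice scenarios.

One level of pragmatic recursion sits on top of the literal semantics:

* the **literal receiver** PR0 interprets an utterance in proportion to its
  raw semantic association with each referent,
  ``PR0(i | u) ∝ L(u, i | θ_u)``;
* the **pragmatic sender** PS1 chooses utterances to be informative for
  that literal receiver, with rationality α ≥ 0,
  ``PS1(u | i) ∝ PR0(i | u)^α``;
* the **pragmatic receiver** PR1 inverts the sender through Bayes' rule,
  ``PR1(i | u) ∝ PS1(u | i) P(i)``.

The central qualitative phenomenon is *amplification*: a vague semantics
(θ_u barely above 0.5) is sharpened by the recursion as α grows, so a
pointing gesture that literally favours its target at only 0.53 is
interpreted far more decisively by a pragmatic receiver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .errors import DegeneratePosteriorError, DomainError, ParseError

__all__ = [
    "RSAScenario",
    "symmetric_point_scenario",
    "literal_receiver",
    "pragmatic_sender",
    "pragmatic_receiver",
    "amplification_curve",
]


@dataclass(frozen=True)
class RSAScenario:
    """An object-choice scenario: referents, utterances, soft semantics.

    Parameters
    ----------
    referents
        Labels of the objects/locations the receiver can choose.
    utterances
        Labels of the signals the sender can produce.
    semantics
        Association strengths ``L(u, i)`` in [0, 1]; rows are utterances,
        columns referents. Rows need not normalize — they are strengths,
        not distributions (normalization happens inside PR0).
    prior
        Receiver's prior over referents (defaults to uniform).
    alpha
        Sender rationality, any real ≥ 0.
    """

    referents: tuple[str, ...]
    utterances: tuple[str, ...]
    semantics: np.ndarray
    prior: np.ndarray | None = None
    alpha: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "referents", tuple(self.referents))
        object.__setattr__(self, "utterances", tuple(self.utterances))
        sem = np.asarray(self.semantics, dtype=float)
        if sem.shape != (len(self.utterances), len(self.referents)):
            raise DomainError(
                f"semantics must be {len(self.utterances)}×{len(self.referents)} "
                f"(utterances × referents), got {sem.shape}"
            )
        if np.any((sem < 0) | (sem > 1)) or np.any(np.isnan(sem)):
            raise DomainError("semantics entries must lie in [0, 1]")
        object.__setattr__(self, "semantics", sem)
        prior = self.prior
        if prior is None:
            prior = np.full(len(self.referents), 1.0 / len(self.referents))
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (len(self.referents),):
            raise DomainError("prior must have one entry per referent")
        if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-9:
            raise DomainError("prior must be a probability vector over referents")
        object.__setattr__(self, "prior", prior)
        if not (self.alpha >= 0):
            raise DomainError(f"alpha must be >= 0, got {self.alpha!r}")
        if len(set(self.referents)) != len(self.referents):
            raise DomainError("referent labels must be unique")
        if len(set(self.utterances)) != len(self.utterances):
            raise DomainError("utterance labels must be unique")

    def with_alpha(self, alpha: float) -> "RSAScenario":
        return RSAScenario(
            self.referents, self.utterances, self.semantics, self.prior, alpha
        )

    def utterance_index(self, u: str) -> int:
        try:
            return self.utterances.index(u)
        except ValueError:
            raise DomainError(f"unknown utterance {u!r}") from None

    def referent_index(self, i: str) -> int:
        try:
            return self.referents.index(i)
        except ValueError:
            raise DomainError(f"unknown referent {i!r}") from None

    # scenario files: JSON with referents/utterances/semantics/prior/alpha
    def to_json(self, path: str | Path) -> None:
        payload = {
            "referents": list(self.referents),
            "utterances": list(self.utterances),
            "semantics": self.semantics.tolist(),
            "prior": self.prior.tolist(),
            "alpha": self.alpha,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RSAScenario":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid scenario file {path}: {exc}") from exc
        try:
            return cls(
                referents=tuple(payload["referents"]),
                utterances=tuple(payload["utterances"]),
                semantics=np.asarray(payload["semantics"], dtype=float),
                prior=np.asarray(payload["prior"], dtype=float)
                if payload.get("prior") is not None
                else None,
                alpha=float(payload.get("alpha", 1.0)),
            )
        except KeyError as exc:
            raise ParseError(f"scenario file {path} missing key {exc}") from exc


def symmetric_point_scenario(
    theta_u: float, n_referents: int = 2, alpha: float = 1.0
) -> RSAScenario:
    """Two locations, two pointing gestures, symmetric vague semantics.

    ``L(point_x, x) = theta_u`` and ``L(point_x, y) = 1 − theta_u``, with a
    uniform prior. ``theta_u`` slightly above 0.5 models a vaguely
    meaningful point; ``theta_u = 1`` recovers truth-functional pointing.
    """
    if n_referents != 2:
        raise DomainError(
            "symmetric_point_scenario builds the two-location task only; "
            "construct RSAScenario directly for other shapes"
        )
    if not (0.0 <= theta_u <= 1.0):
        raise DomainError(f"theta_u must lie in [0, 1], got {theta_u!r}")
    return RSAScenario(
        referents=("left", "right"),
        utterances=("point_left", "point_right"),
        semantics=np.array(
            [[theta_u, 1.0 - theta_u], [1.0 - theta_u, theta_u]]
        ),
        alpha=alpha,
    )


def _normalize(weights: np.ndarray, what: str) -> np.ndarray:
    total = weights.sum()
    if total == 0.0:
        raise DegeneratePosteriorError(f"all weights zero in {what}")
    return weights / total


def literal_receiver(u: str, scenario: RSAScenario) -> pd.Series:
    """PR0(i | u) ∝ L(u, i): semantics row normalized over referents.

    The prior is *not* applied at this level; the literal receiver reads
    the raw semantics only.
    """
    row = scenario.semantics[scenario.utterance_index(u)]
    return pd.Series(
        _normalize(row, f"literal receiver for {u!r}"),
        index=list(scenario.referents),
        name=u,
    )


def _pr0_matrix(scenario: RSAScenario) -> np.ndarray:
    row_sums = scenario.semantics.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0.0):
        bad = scenario.utterances[int(np.argmin(row_sums))]
        raise DegeneratePosteriorError(f"all-zero semantics row for {bad!r}")
    return scenario.semantics / row_sums


def _power(base: np.ndarray, alpha: float) -> np.ndarray:
    # 0**0 := 1 (uniform-sender convention at alpha = 0)
    if alpha == 0.0:
        return np.ones_like(base)
    return base**alpha


def pragmatic_sender(i: str, scenario: RSAScenario) -> pd.Series:
    """PS1(u | i) ∝ PR0(i | u)^α: soft-max informative utterance choice."""
    col = _pr0_matrix(scenario)[:, scenario.referent_index(i)]
    return pd.Series(
        _normalize(_power(col, scenario.alpha), f"pragmatic sender for {i!r}"),
        index=list(scenario.utterances),
        name=i,
    )


def pragmatic_receiver(u: str, scenario: RSAScenario) -> pd.Series:
    """PR1(i | u) ∝ PS1(u | i) P(i): Bayesian inversion of the sender."""
    ui = scenario.utterance_index(u)
    pr0 = _pr0_matrix(scenario)
    # PS1 column-wise: for each referent, normalize over utterances
    sender_weights = _power(pr0, scenario.alpha)
    col_sums = sender_weights.sum(axis=0)
    if np.any(col_sums == 0.0):
        bad = scenario.referents[int(np.argmin(col_sums))]
        raise DegeneratePosteriorError(
            f"pragmatic sender degenerate for referent {bad!r}"
        )
    ps1 = sender_weights / col_sums
    weights = ps1[ui] * scenario.prior
    return pd.Series(
        _normalize(weights, f"pragmatic receiver for {u!r}"),
        index=list(scenario.referents),
        name=u,
    )


def pointed_target(scenario: RSAScenario, u: str) -> str:
    """The referent an utterance points at: argmax of its semantics row
    (first on ties)."""
    row = scenario.semantics[scenario.utterance_index(u)]
    return scenario.referents[int(np.argmax(row))]


def amplification_curve(
    scenario: RSAScenario, alphas: list[float]
) -> pd.DataFrame:
    """PR1 of the pointed-at referent as a function of α.

    Uses the scenario's first utterance and its semantic target; returns a
    DataFrame with columns ``alpha, p_target``.
    """
    if len(alphas) == 0:
        raise DomainError("alphas must be nonempty")
    u = scenario.utterances[0]
    target = pointed_target(scenario, u)
    rows = []
    for alpha in alphas:
        if alpha < 0:
            raise DomainError(f"alpha must be >= 0, got {alpha!r}")
        pr1 = pragmatic_receiver(u, scenario.with_alpha(alpha))
        rows.append((float(alpha), float(pr1[target])))
    return pd.DataFrame(rows, columns=["alpha", "p_target"])
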