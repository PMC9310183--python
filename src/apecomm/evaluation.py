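"""Confronting the cue-integration model with coded interaction tables.

The observable in a coded interaction table is the receiver's *reaction*
(affiliative or avoidant), which stands in one-to-one correspondence with
the interpreted intention. Evaluation therefore compares the model's
posterior avoidant probability per (gesture, facial, context, dominance)
combination directly against the observed avoidant-reaction proportion:

* :func:`summarize_reactions` aggregates records per combination, drops
  combinations with fewer than ``min_n`` observations (default 5), and
  attaches non-parametric bootstrap confidence intervals;
* :func:`correlate` computes the Pearson correlation between predicted and
  observed avoidant proportions, with zero-variance cases reported as an
  explicit undefined outcome rather than NaN;
* :func:`compare_models` runs that comparison for the full model and the
  four single-component reductions;
* :func:`fit_parameters` estimates cue weights by maximum likelihood in
  log-odds space. The model's log-odds are additive over the four
  component groups, so a constant can be shifted between groups without
  changing any posterior — a 3-dimensional unidentifiable subspace.
  Fitting therefore requires *anchors*: fixed weights for at least one
  level in at least three of the four groups.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .core import (
    CueParameters,
    SocialSetting,
    Utterance,
    infer_intention,
    prediction_grid,
    reduced_parameters,
)
from .errors import (
    DomainError,
    IdentifiabilityError,
    InsufficientDataError,
    ParseError,
    UndefinedCorrelationError,
)
from .registry import (
    AVOIDANT,
    COMPONENTS,
    DEFAULT_REGISTRY,
    Intention,
    SignalRegistry,
)

__all__ = [
    "InteractionRecord",
    "CombinationSummary",
    "ModelComparisonReport",
    "FitResult",
    "read_records",
    "write_records",
    "summarize_reactions",
    "bootstrap_ci",
    "correlate",
    "compare_models",
    "negative_log_likelihood",
    "fit_parameters",
]

RECORD_COLUMNS = ["gesture", "facial", "context", "dominance", "reaction"]


@dataclass(frozen=True)
class InteractionRecord:
    """One coded communicative event, including the receiver's reaction."""

    gesture: str
    facial: str
    context: str
    dominance: str
    reaction: Intention

    @property
    def combination(self) -> tuple[str, str, str, str]:
        return (self.gesture, self.facial, self.context, self.dominance)


@dataclass(frozen=True)
class CombinationSummary:
    """Reaction counts and bootstrap CI for one cue combination."""

    combination: tuple[str, str, str, str]
    n: int
    n_avoidant: int
    ci_low: float
    ci_high: float

    @property
    def proportion_avoidant(self) -> float:
        return self.n_avoidant / self.n


@dataclass(frozen=True)
class ModelResult:
    """Correlation outcome for one model; exactly one of ``correlation``
    and ``undefined_reason`` is set."""

    correlation: float | None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.correlation is not None


@dataclass(frozen=True)
class ModelComparisonReport:
    """Prediction–observation correlations for the full model and each
    single-component reduction, over the same filtered summaries."""

    results: dict[str, ModelResult]
    n_combinations: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                name,
                res.correlation if res.defined else "",
                res.undefined_reason or "",
                self.n_combinations,
            )
            for name, res in self.results.items()
        ]
        return pd.DataFrame(
            rows, columns=["model", "correlation", "undefined", "n_combinations"]
        )


# ---------------------------------------------------------------------------
# interaction CSV I/O (strict schema: lowercase snake_case labels)
# ---------------------------------------------------------------------------


def read_records(
    path: str | Path, registry: SignalRegistry = DEFAULT_REGISTRY
) -> list[InteractionRecord]:
    """Read an interaction table, validating every label against the
    registry. Errors name the offending row and field."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if header != RECORD_COLUMNS:
            raise ParseError(
                f"{path}: header must be {','.join(RECORD_COLUMNS)}, "
                f"got {','.join(header)}"
            )
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(RECORD_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(RECORD_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            fields = dict(zip(RECORD_COLUMNS, row))
            for component in COMPONENTS:
                label = fields[component]
                if label not in registry.labels(component):
                    raise ParseError(
                        f"{path}:{lineno}: unknown {component} label {label!r}"
                    )
            reaction = fields["reaction"]
            if reaction not in ("affiliative", "avoidant"):
                raise ParseError(
                    f"{path}:{lineno}: reaction must be affiliative or "
                    f"avoidant, got {reaction!r}"
                )
            records.append(
                InteractionRecord(
                    gesture=fields["gesture"],
                    facial=fields["facial"],
                    context=fields["context"],
                    dominance=fields["dominance"],
                    reaction=Intention(reaction),
                )
            )
    return records


def write_records(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(RECORD_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.gesture, rec.facial, rec.context, rec.dominance,
                 rec.reaction.value]
            )


def _count_table(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Per-combination totals: columns n, n_avoidant, indexed by combo."""
    if not records:
        return pd.DataFrame(columns=["n", "n_avoidant"])
    frame = pd.DataFrame(
        [(r.gesture, r.facial, r.context, r.dominance,
          int(r.reaction is AVOIDANT)) for r in records],
        columns=RECORD_COLUMNS[:4] + ["avoidant"],
    )
    grouped = frame.groupby(RECORD_COLUMNS[:4], sort=True)["avoidant"]
    return pd.DataFrame({"n": grouped.size(), "n_avoidant": grouped.sum()})


# ---------------------------------------------------------------------------
# summaries and the bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    n: int,
    n_avoidant: int,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a proportion.

    Resamples the ``n`` observed reactions with replacement ``B`` times
    (equivalently, draws Binomial(n, n_avoidant/n)) and returns the
    percentile interval of the resampled proportion. Deterministic for a
    given ``seed``.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if not 0 <= n_avoidant <= n:
        raise DomainError(f"need 0 <= n_avoidant <= n, got {n_avoidant}/{n}")
    if B < 1:
        raise DomainError(f"B must be >= 1, got {B}")
    if not 0.0 < level < 1.0:
        raise DomainError(f"level must lie in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    props = rng.binomial(n, n_avoidant / n, size=B) / n
    tail = (1.0 - level) / 2.0
    # inverted-CDF quantiles: min{x : F̂(x) >= q}, matching the discrete
    # resampling distribution's quantile function
    lo, hi = np.quantile(props, [tail, 1.0 - tail], method="inverted_cdf")
    return float(lo), float(hi)


def summarize_reactions(
    records: Sequence[InteractionRecord],
    min_n: int = 5,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> list[CombinationSummary]:
    """Per-combination avoidant proportions with bootstrap CIs.

    Combinations observed fewer than ``min_n`` times are excluded — sparse
    cells give unstable proportions. Each retained combination gets its own
    bootstrap stream derived from ``seed``.
    """
    if min_n < 1:
        raise DomainError(f"min_n must be >= 1, got {min_n}")
    counts = _count_table(records)
    seeds = np.random.SeedSequence(seed).spawn(len(counts)) if len(counts) else []
    summaries = []
    for (combo, row), sub_seed in zip(counts.iterrows(), seeds):
        n, k = int(row["n"]), int(row["n_avoidant"])
        if n < min_n:
            continue
        lo, hi = bootstrap_ci(
            n, k, B=B, level=level,
            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
        )
        summaries.append(
            CombinationSummary(
                combination=combo, n=n, n_avoidant=k, ci_low=lo, ci_high=hi
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[CombinationSummary]) -> pd.DataFrame:
    rows = [
        (*s.combination, s.n, s.n_avoidant, s.proportion_avoidant,
         s.ci_low, s.ci_high)
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=RECORD_COLUMNS[:4]
        + ["n", "n_avoidant", "proportion_avoidant", "ci_low", "ci_high"],
    )


# ---------------------------------------------------------------------------
# correlation and model comparison
# ---------------------------------------------------------------------------


def correlate(
    grid: pd.DataFrame,
    summaries: Sequence[CombinationSummary],
    weighted: bool = False,
) -> float:
    """Pearson correlation between predicted p_avoidant and observed
    avoidant proportions over the matched combinations.

    ``weighted=True`` weights each combination by its observation count
    (weighted Pearson); the default is unweighted.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 matched combinations.
    UndefinedCorrelationError
        Predictions or observations constant across the matched
        combinations (zero variance).
    """
    if len(summaries) < 3:
        raise InsufficientDataError(
            f"need >= 3 combinations for a correlation, got {len(summaries)}"
        )
    lookup = {
        tuple(row[:4]): row[4]
        for row in grid[["gesture", "facial", "context", "dominance",
                         "p_avoidant"]].itertuples(index=False)
    }
    try:
        predicted = np.array([lookup[s.combination] for s in summaries])
    except KeyError as exc:
        raise DomainError(
            f"combination {exc.args[0]!r} not present in prediction grid"
        ) from None
    observed = np.array([s.proportion_avoidant for s in summaries])
    if np.ptp(predicted) == 0.0:
        raise UndefinedCorrelationError(
            "constant predictions across matched combinations"
        )
    if np.ptp(observed) == 0.0:
        raise UndefinedCorrelationError(
            "constant observations across matched combinations"
        )
    w = (
        np.array([s.n for s in summaries], dtype=float)
        if weighted
        else np.ones(len(summaries))
    )
    w = w / w.sum()
    mx, my = w @ predicted, w @ observed
    cov = w @ ((predicted - mx) * (observed - my))
    vx = w @ (predicted - mx) ** 2
    vy = w @ (observed - my) ** 2
    return float(cov / math.sqrt(vx * vy))


def compare_models(
    records: Sequence[InteractionRecord],
    params: CueParameters,
    min_n: int = 5,
    weighted: bool = False,
    B: int = 10_000,
    seed: int | None = 0,
) -> ModelComparisonReport:
    """Correlate the full model and every single-component reduction with
    the same filtered summaries. Undefined correlations are reported per
    model, not raised."""
    summaries = summarize_reactions(records, min_n=min_n, B=B, seed=seed)
    if len(summaries) < 3:
        raise InsufficientDataError(
            f"need >= 3 combinations with n >= {min_n}, got {len(summaries)}"
        )
    models = {"full": params}
    for component in COMPONENTS:
        models[f"{component}_only"] = reduced_parameters(params, component)
    results: dict[str, ModelResult] = {}
    for name, model_params in models.items():
        grid = prediction_grid(model_params)
        try:
            results[name] = ModelResult(
                correlation=correlate(grid, summaries, weighted=weighted)
            )
        except UndefinedCorrelationError as exc:
            results[name] = ModelResult(
                correlation=None, undefined_reason=exc.reason
            )
    return ModelComparisonReport(results=results, n_combinations=len(summaries))


# ---------------------------------------------------------------------------
# likelihood and anchored maximum-likelihood fitting
# ---------------------------------------------------------------------------


def negative_log_likelihood(
    params: CueParameters, records: Sequence[InteractionRecord]
) -> float:
    """Σ over records of −log P(reaction | combination; params).

    Raises
    ------
    DomainError
        If any record's observed reaction has posterior probability
        exactly 0 (infinite likelihood penalty).
    """
    counts = _count_table(records)
    total = 0.0
    for combo, row in counts.iterrows():
        g, f, c, s = combo
        post = infer_intention(Utterance(g, f), SocialSetting(c, s), params)
        n, k = int(row["n"]), int(row["n_avoidant"])
        for count, p in ((k, post.p_avoidant), (n - k, post.p_affiliative)):
            if count and p == 0.0:
                raise DomainError(
                    f"observed reaction has zero probability at {combo}"
                )
            if count:
                total -= count * math.log(p)
    return total


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_parameters`."""

    params: CueParameters
    nll: float
    #: flat keys of free parameters never observed in the data; these stay
    #: at the neutral value 0.5 and should not be interpreted
    sparse_parameters: tuple[str, ...] = ()


def _check_anchors(
    anchors: Mapping[str, float], registry: SignalRegistry
) -> dict[str, float]:
    checked: dict[str, float] = {}
    anchored_components = set()
    for key, value in anchors.items():
        component, sep, label = str(key).partition(".")
        if not sep or component not in COMPONENTS:
            raise DomainError(f"unknown anchor key {key!r}")
        registry.require(component, label)
        if not 0.0 < float(value) < 1.0:
            raise DomainError(
                f"anchor {key} must lie strictly inside (0, 1), got {value}"
            )
        checked[f"{component}.{label}"] = float(value)
        anchored_components.add(component)
    if len(anchored_components) < 3:
        raise IdentifiabilityError(
            "anchors must fix at least one level in at least three of the "
            f"four component groups; got {sorted(anchored_components)}. "
            "The additive log-odds structure admits constant shifts between "
            "groups, so unanchored fits are not identifiable."
        )
    return checked


def fit_parameters(
    records: Sequence[InteractionRecord],
    anchors: Mapping[str, float],
    seed: int | None = 0,
    registry: SignalRegistry = DEFAULT_REGISTRY,
    n_restarts: int = 5,
    tol: float = 1e-8,
) -> FitResult:
    """Anchored maximum-likelihood estimation of cue weights.

    Free parameters are optimized in unconstrained log-odds coordinates
    with multi-start L-BFGS (``n_restarts`` seeded restarts); anchored
    parameters stay fixed at their given values. Free parameters whose
    label never occurs in the data cannot move and are flagged in
    ``sparse_parameters`` (left at 0.5). The fitted 24-cell prediction
    grid is always identifiable; individual weights are identified only
    relative to the anchors.
    """
    if not records:
        raise DomainError("records must be nonempty")
    anchors = _check_anchors(anchors, registry)
    counts = _count_table(records)
    free_keys = [
        f"{component}.{label}"
        for component in COMPONENTS
        for label in registry.labels(component)
        if f"{component}.{label}" not in anchors
    ]
    observed_labels = set()
    for combo in counts.index:
        for component, label in zip(COMPONENTS, combo):
            observed_labels.add(f"{component}.{label}")
    sparse = tuple(k for k in free_keys if k not in observed_labels)
    active_keys = [k for k in free_keys if k in observed_labels]
    key_pos = {k: j for j, k in enumerate(active_keys)}

    n_combos = len(counts)
    design = np.zeros((n_combos, len(active_keys)))
    offset = np.zeros(n_combos)
    n_vec = counts["n"].to_numpy(dtype=float)
    k_vec = counts["n_avoidant"].to_numpy(dtype=float)
    logit = lambda t: math.log(t / (1.0 - t))
    for row_idx, combo in enumerate(counts.index):
        for component, label in zip(COMPONENTS, combo):
            key = f"{component}.{label}"
            if key in anchors:
                offset[row_idx] += logit(anchors[key])
            else:
                design[row_idx, key_pos[key]] = 1.0

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        eta = design @ x + offset
        # NLL = Σ n·log(1 + e^eta) − k·eta, numerically stable via logaddexp
        nll = float(np.sum(n_vec * np.logaddexp(0.0, eta) - k_vec * eta))
        grad = design.T @ (n_vec * expit(eta) - k_vec)
        return nll, grad

    rng = np.random.default_rng(seed)
    best_x, best_nll = np.zeros(len(active_keys)), objective(
        np.zeros(len(active_keys))
    )[0]
    starts = [np.zeros(len(active_keys))] + [
        rng.normal(scale=1.0, size=len(active_keys)) for _ in range(n_restarts)
    ]
    for x0 in starts:
        res = minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 1000},
        )
        if res.fun < best_nll:
            best_nll, best_x = float(res.fun), res.x

    flat = dict(anchors)
    for key, value in zip(active_keys, best_x):
        flat[key] = float(expit(value))
    for key in sparse:
        flat[key] = 0.5
    fitted = CueParameters.from_flat_dict(flat, registry=registry)
    return FitResult(params=fitted, nll=best_nll, sparse_parameters=sparse)
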