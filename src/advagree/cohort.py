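"""Simulated nAFC observer cohorts.

Generates forced-choice response tables with the statistical structure the
agreement analyses assume: participants choosing one of *m* labels per trial
under a parameterised decision strategy (uniform guessing, similarity-driven
foil elimination, or machine mimicry), with lognormal response times and
per-participant randomisation of trial order and on-screen label order.

The canonical container for responses is a long-format :class:`pandas.DataFrame`
with one row per (participant, trial); see :data:`RESPONSE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_COLUMNS",
    "TrialSpec",
    "FeatureSpace",
    "ObserverStrategy",
    "ResponseRecord",
    "RTConfig",
    "choice_probabilities",
    "simulate_observer_response",
    "simulate_cohort",
    "make_feature_space",
    "exclude_fast_responders",
    "validate_response_table",
]

#: Column schema of a response table (long format, one row per response).
RESPONSE_COLUMNS = [
    "participant_id",
    "trial_index",
    "image_id",
    "condition",
    "alternatives",
    "machine_label",
    "chosen_label",
    "rt_ms",
]

ALTERNATIVES_SEP = "|"

STRATEGY_KINDS = ("blindfolded", "feature_guesser", "machine_mimic")


class StrategyError(ValueError):
    """Raised for unknown or invalid observer strategies."""


@dataclass(frozen=True)
class TrialSpec:
    """One forced-choice trial: a stimulus, its candidate labels and the machine label.

    Parameters
    ----------
    image_id : str
        Identifier of the stimulus image.
    alternatives : tuple of str
        The *m* >= 2 distinct response labels offered on this trial, in canonical
        order (presentation order is randomised separately per participant).
    machine_label : str
        The classifier's label for this image; must be one of ``alternatives``.
    condition : str
        Free-form condition tag (e.g. ``"random"``, ``"competitive"``).
    """

    image_id: str
    alternatives: tuple
    machine_label: str
    condition: str = ""

    def __post_init__(self):
        alts = tuple(self.alternatives)
        object.__setattr__(self, "alternatives", alts)
        if len(alts) < 2:
            raise ValueError(f"trial {self.image_id!r} needs >= 2 alternatives, got {len(alts)}")
        if len(set(alts)) != len(alts):
            raise ValueError(f"trial {self.image_id!r} has duplicate alternatives: {alts}")
        if self.machine_label not in alts:
            raise ValueError(
                f"machine_label {self.machine_label!r} not among alternatives of trial "
                f"{self.image_id!r}"
            )

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)


@dataclass
class FeatureSpace:
    """Feature loadings shared by images and labels, with a dot-product similarity.

    Operationalises the "superficial commonalities" account of educated guessing:
    an image loads on its target label's identity feature and, to a degree set by
    the overlap parameter of :func:`make_feature_space`, on features shared with a
    designated set of competitive foil labels.

    Attributes
    ----------
    image_features, label_features : dict
        Map image/label identifiers to equal-length vectors with entries in [0, 1].
    target_labels : dict
        Map each image to its matched (machine) label.
    designated_foils : dict
        Map each image to the labels sharing superficial features with it.
    """

    image_features: Mapping[str, np.ndarray]
    label_features: Mapping[str, np.ndarray]
    target_labels: Mapping[str, str] = field(default_factory=dict)
    designated_foils: Mapping[str, tuple] = field(default_factory=dict)

    def similarity(self, image_id: str, label: str) -> float:
        """Dot-product similarity between an image and a label."""
        return float(np.dot(self.image_features[image_id], self.label_features[label]))

    def similarities(self, image_id: str, labels: Sequence[str]) -> np.ndarray:
        x = self.image_features[image_id]
        return np.array([float(np.dot(x, self.label_features[lb])) for lb in labels])


@dataclass(frozen=True)
class ObserverStrategy:
    """Parameterised decision rule mapping a trial to a choice distribution.

    kind
        ``"blindfolded"`` — uniform over alternatives (the chance null);
        ``"feature_guesser"`` — softmax over image-label similarity / temperature;
        ``"machine_mimic"`` — machine label with probability ``mimic_prob``,
        otherwise uniform over the remaining alternatives.
    """

    kind: str
    temperature: float = 1.0
    mimic_prob: float = 1.0

    def __post_init__(self):
        if self.kind not in STRATEGY_KINDS:
            raise StrategyError(f"unknown strategy kind {self.kind!r}; expected one of {STRATEGY_KINDS}")
        if not self.temperature > 0:
            raise StrategyError(f"temperature must be > 0, got {self.temperature}")
        if not 0.0 <= self.mimic_prob <= 1.0:
            raise StrategyError(f"mimic_prob must lie in [0, 1], got {self.mimic_prob}")


@dataclass(frozen=True)
class RTConfig:
    """Lognormal response-time model: rt = median * exp(sigma * Z), Z ~ N(0,1).

    The literature this emulates reports only a 500 ms random-clicking exclusion
    rule, not an RT distribution; the defaults are explicit stand-ins.
    """

    median_ms: float = 1500.0
    sigma: float = 0.4

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return self.median_ms * np.exp(self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class ResponseRecord:
    """A single participant response on a single trial."""

    participant_id: str
    trial_index: int
    image_id: str
    alternatives: tuple
    chosen_label: str
    machine_label: str
    response_time_ms: float
    condition: str = ""

    def __post_init__(self):
        if self.chosen_label not in self.alternatives:
            raise ValueError(
                f"chosen_label {self.chosen_label!r} not among alternatives {self.alternatives}"
            )
        if not self.response_time_ms > 0:
            raise ValueError("response_time_ms must be positive")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


def choice_probabilities(
    trial: TrialSpec,
    strategy: ObserverStrategy,
    feature_space: FeatureSpace | None = None,
) -> np.ndarray:
    """Probability over ``trial.alternatives`` of each label being chosen.

    Blindfolded observers are uniform; feature guessers apply a softmax with the
    strategy's temperature to the similarity between the image and each offered
    label; machine mimics choose the machine label with ``mimic_prob`` and
    spread the rest uniformly over the remaining alternatives.
    """
    m = trial.n_alternatives
    if strategy.kind == "blindfolded":
        return np.full(m, 1.0 / m)
    if strategy.kind == "machine_mimic":
        p = np.full(m, (1.0 - strategy.mimic_prob) / (m - 1))
        p[trial.alternatives.index(trial.machine_label)] = strategy.mimic_prob
        return p
    # feature_guesser
    if feature_space is None:
        raise StrategyError("feature_guesser strategy requires a FeatureSpace")
    sims = feature_space.similarities(trial.image_id, trial.alternatives)
    z = sims / strategy.temperature
    z -= z.max()  # numerical stability; softmax is shift-invariant
    w = np.exp(z)
    return w / w.sum()


def simulate_observer_response(
    trial: TrialSpec,
    strategy: ObserverStrategy,
    feature_space: FeatureSpace | None,
    rng: np.random.Generator,
    *,
    rt: RTConfig = RTConfig(),
    participant_id: str = "p000",
    trial_index: int = 0,
) -> ResponseRecord:
    """Simulate one response to one trial under the given strategy.

    The on-screen order of alternatives is randomised and stored in the record;
    the response time is drawn from the lognormal model in ``rt``.
    """
    probs = choice_probabilities(trial, strategy, feature_space)
    order = rng.permutation(trial.n_alternatives)
    presented = tuple(trial.alternatives[i] for i in order)
    chosen = trial.alternatives[rng.choice(trial.n_alternatives, p=probs)]
    return ResponseRecord(
        participant_id=participant_id,
        trial_index=trial_index,
        image_id=trial.image_id,
        alternatives=presented,
        chosen_label=chosen,
        machine_label=trial.machine_label,
        response_time_ms=float(rt.sample(rng)),
        condition=trial.condition,
    )


def _normalize_mixture(strategy_mixture) -> tuple[list, np.ndarray]:
    if isinstance(strategy_mixture, ObserverStrategy):
        strategy_mixture = [(strategy_mixture, 1.0)]
    strategies = [s for s, _ in strategy_mixture]
    weights = np.asarray([w for _, w in strategy_mixture], dtype=float)
    if len(strategies) == 0:
        raise StrategyError("strategy mixture is empty")
    if not np.isclose(weights.sum(), 1.0):
        raise StrategyError(f"mixture weights must sum to 1, got {weights.sum():g}")
    return strategies, weights


def simulate_cohort(
    experiment: Sequence[TrialSpec],
    n_participants: int,
    strategy_mixture,
    feature_space: FeatureSpace | None = None,
    rng: np.random.Generator | None = None,
    *,
    rt: RTConfig = RTConfig(),
    participant_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate a cohort of participants over a fixed list of trials.

    Each participant is assigned a strategy by a weighted draw from
    ``strategy_mixture`` (a list of ``(ObserverStrategy, weight)`` pairs or a
    single strategy), then responds to every trial, with trial order and
    alternative presentation order independently randomised per participant.

    Returns a long-format response table (:data:`RESPONSE_COLUMNS`); sampling is
    vectorised, so cohorts of 10,000+ participants are cheap.

    Notes
    -----
    ``trial_index`` records the position of the trial in the participant's own
    randomised order; ``alternatives`` records the on-screen order.
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    trials = list(experiment)
    if len(trials) == 0:
        raise ValueError("experiment must contain at least one trial")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    strategies, weights = _normalize_mixture(strategy_mixture)

    n, T = n_participants, len(trials)
    pad = max(3, len(str(n - 1)))
    pids = np.array([f"{participant_prefix}{i:0{pad}d}" for i in range(n)])

    strat_idx = rng.choice(len(strategies), size=n, p=weights)
    # random trial order per participant: argsort of iid uniforms is a uniform permutation
    trial_order = np.argsort(rng.random((n, T)), axis=1)  # position -> canonical trial
    rts = rt.sample(rng, size=(n, T))

    # chosen label and presented order per (participant, canonical trial)
    chosen = np.empty((n, T), dtype=object)
    presented = np.empty((n, T), dtype=object)
    for t, trial in enumerate(trials):
        m = trial.n_alternatives
        alts = np.array(trial.alternatives, dtype=object)
        # per-strategy choice sampling via inverse CDF
        u = rng.random(n)
        idx = np.empty(n, dtype=int)
        for s, strat in enumerate(strategies):
            mask = strat_idx == s
            if not mask.any():
                continue
            cdf = np.cumsum(choice_probabilities(trial, strat, feature_space))
            cdf[-1] = 1.0
            idx[mask] = np.searchsorted(cdf, u[mask], side="left")
        chosen[:, t] = alts[idx]
        perms = np.argsort(rng.random((n, m)), axis=1)
        joined = np.array(
            [ALTERNATIVES_SEP.join(alts[p]) for p in perms], dtype=object
        )
        presented[:, t] = joined

    rows_pid = np.repeat(pids, T)
    canon = trial_order.reshape(-1)  # canonical trial shown at each position
    trial_index = np.tile(np.arange(T), n)
    image_ids = np.array([tr.image_id for tr in trials], dtype=object)[canon]
    conditions = np.array([tr.condition for tr in trials], dtype=object)[canon]
    machine = np.array([tr.machine_label for tr in trials], dtype=object)[canon]
    part_rows = np.repeat(np.arange(n), T)
    chosen_flat = chosen[part_rows, canon]
    presented_flat = presented[part_rows, canon]
    rt_flat = rts.reshape(-1)

    return pd.DataFrame(
        {
            "participant_id": rows_pid,
            "trial_index": trial_index,
            "image_id": image_ids,
            "condition": conditions,
            "alternatives": presented_flat,
            "machine_label": machine,
            "chosen_label": chosen_flat,
            "rt_ms": rt_flat,
        }
    )


def make_feature_space(
    n_images: int,
    labels: Sequence[str],
    overlap: float,
    dim: int = 2,
    rng: np.random.Generator | None = None,
    *,
    n_designated_foils: int = 3,
) -> FeatureSpace:
    """Build a feature space controlling foil-target superficial-feature overlap.

    Every label gets a one-hot identity feature. Each image loads 1.0 on its
    target label's identity feature and ``overlap`` on the identity features of a
    designated set of competitive foil labels (drawn at random per image), plus
    ``dim`` label-irrelevant nuisance dimensions in [0, 1]. Consequences:

    * ``overlap = 0``: the matched label's similarity strictly exceeds every
      foil's for every image.
    * ``overlap = 1``: the target and its designated foils are indistinguishable
      by similarity (the "superficial commonality" regime).
    * A feature-guessing observer's agreement with the machine label is
      non-increasing in ``overlap`` when foils share features with the target.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    labels = list(labels)
    L = len(labels)
    if L < 2:
        raise ValueError("need at least 2 labels")
    n_foils = min(n_designated_foils, L - 1)

    label_features = {
        lb: np.concatenate([np.eye(L)[j], np.zeros(dim)]) for j, lb in enumerate(labels)
    }
    image_features: dict[str, np.ndarray] = {}
    target_labels: dict[str, str] = {}
    designated: dict[str, tuple] = {}
    pad = max(3, len(str(n_images - 1)))
    for i in range(n_images):
        t = i % L
        others = [j for j in range(L) if j != t]
        foil_idx = rng.choice(others, size=n_foils, replace=False)
        vec = np.zeros(L)
        vec[t] = 1.0
        vec[foil_idx] = overlap
        image_id = f"img{i:0{pad}d}"
        image_features[image_id] = np.concatenate([vec, rng.random(dim)])
        target_labels[image_id] = labels[t]
        designated[image_id] = tuple(labels[j] for j in sorted(foil_idx))
    return FeatureSpace(
        image_features=image_features,
        label_features=label_features,
        target_labels=target_labels,
        designated_foils=designated,
    )


def validate_response_table(table: pd.DataFrame) -> None:
    """Check the response-table schema and per-row label consistency."""
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    if len(table) == 0:
        return
    # delimiter-padded substring check; avoids splitting every row
    sep = ALTERNATIVES_SEP
    ok = [
        f"{sep}{c}{sep}" in f"{sep}{a}{sep}"
        for c, a in zip(table["chosen_label"], table["alternatives"])
    ]
    if not all(ok):
        bad = int(np.argmin(ok))
        raise ValueError(f"row {bad}: chosen_label not among alternatives")


def exclude_fast_responders(
    table: pd.DataFrame, threshold_ms: float = 500.0
) -> tuple[pd.DataFrame, list]:
    """Drop participants whose *mean* response time is below ``threshold_ms``.

    Mirrors the random-clicking exclusion rule used in online nAFC studies:
    exclusion is by participant, never by trial, and a participant whose mean RT
    equals the threshold exactly is retained.

    Returns the retained table and the sorted list of excluded participant ids.
    """
    if not threshold_ms > 0:
        raise ValueError("threshold_ms must be positive")
    if len(table) == 0:
        raise ValueError("response table is empty")
    means = table.groupby("participant_id")["rt_ms"].mean()
    excluded = sorted(means.index[means < threshold_ms])
    kept = table[~table["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, list(excluded)
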