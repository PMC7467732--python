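"""Experiment assembly: foil selection, stimulus selection, trial construction.

Builds nAFC trial lists under the designs used to probe human-classifier
agreement on fooling images:

* *random foils* — alternatives drawn uniformly from a label pool;
* *competitive foils* — alternatives chosen to share superficial visual
  features with the stimulus, operationalised here via feature-space
  similarity ranking (human experimenters chose them by eye);
* *fixed label set* — the same m labels on every trial (digit-style designs);
* *identification trials* — pick which of several generated images belongs to
  a named target class (one target-class fooling image among foil-class
  fooling images).

Also selects best/worst-case representative stimuli from most-like/least-like
pre-study counts, and crosses conditions for 2 x 2 within-participant designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from advagree.cohort import FeatureSpace, TrialSpec

__all__ = [
    "ExperimentDesign",
    "build_trials",
    "select_best_worst",
    "build_identification_trials",
    "crossed_conditions",
]

DESIGN_MODES = ("random_foils", "competitive_foils", "pick_one_of_three", "fixed_ten_labels")


@dataclass(frozen=True)
class ExperimentDesign:
    """How response alternatives are chosen for each stimulus.

    ``exclusion_pairs`` lists label pairs judged semantically or functionally
    overlapping (e.g. *baseball*/*basketball*); when one member is the target,
    the other is never offered as a foil. Such judgments are inputs, not
    derivable.
    """

    mode: str
    n_alternatives: int
    label_pool: tuple
    exclusion_pairs: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in DESIGN_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {DESIGN_MODES}")
        object.__setattr__(self, "label_pool", tuple(self.label_pool))
        object.__setattr__(
            self, "exclusion_pairs", tuple(frozenset(p) for p in self.exclusion_pairs)
        )
        if self.n_alternatives > len(self.label_pool):
            raise ValueError("n_alternatives exceeds label pool size")
        if self.n_alternatives < 2:
            raise ValueError("n_alternatives must be >= 2")

    def excluded_for(self, target: str) -> set:
        return {lb for pair in self.exclusion_pairs if target in pair for lb in pair} - {target}


def build_trials(
    images: Mapping[str, str],
    design: ExperimentDesign,
    feature_space: FeatureSpace | None = None,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
) -> list[TrialSpec]:
    """Build one trial per image under the design's foil-selection regime.

    Parameters
    ----------
    images : mapping
        image id -> machine (target) label; every target must be in the pool.
    design : ExperimentDesign
        ``random_foils`` draws m-1 foils uniformly without replacement from the
        pool minus the target and its exclusions. ``competitive_foils`` takes
        the m-1 non-excluded pool labels most similar to the image in
        ``feature_space`` (deterministic given the space; ties break by label
        order). ``fixed_ten_labels`` offers the whole pool, which must have
        exactly ``n_alternatives`` labels.
    condition : str, optional
        Condition tag stored on each trial; defaults to the design mode.

    The on-screen alternative order within each TrialSpec is randomised with
    ``rng``; foil *composition* in competitive mode does not depend on the rng.
    """
    if design.mode == "pick_one_of_three":
        raise ValueError(
            "mode 'pick_one_of_three' builds trials over images, not labels; "
            "use build_identification_trials"
        )
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    condition = design.mode if condition is None else condition
    m = design.n_alternatives
    trials = []
    for image_id, target in images.items():
        if target not in design.label_pool:
            raise ValueError(f"machine label {target!r} of {image_id!r} not in label pool")
        candidates = [
            lb for lb in design.label_pool
            if lb != target and lb not in design.excluded_for(target)
        ]
        if design.mode == "fixed_ten_labels":
            if len(design.label_pool) != m:
                raise ValueError("fixed label set requires len(label_pool) == n_alternatives")
            alts = list(design.label_pool)
        elif len(candidates) < m - 1:
            raise ValueError(
                f"label pool too small after exclusions for target {target!r}: "
                f"{len(candidates)} candidates, need {m - 1}"
            )
        elif design.mode == "random_foils":
            foils = list(rng.choice(candidates, size=m - 1, replace=False))
            alts = [target] + foils
        else:  # competitive_foils
            if feature_space is None:
                raise ValueError("competitive_foils mode requires a FeatureSpace")
            sims = feature_space.similarities(image_id, candidates)
            # stable sort on -similarity: ties keep label-pool order (seed-invariant)
            order = np.argsort(-sims, kind="stable")[: m - 1]
            alts = [target] + [candidates[i] for i in order]
        presented = [alts[i] for i in rng.permutation(len(alts))]
        trials.append(
            TrialSpec(
                image_id=image_id,
                alternatives=tuple(presented),
                machine_label=target,
                condition=condition,
            )
        )
    return trials


def select_best_worst(prestudy: pd.DataFrame) -> pd.DataFrame:
    """Pick best/worst-case representative stimuli per category from a pre-study.

    ``prestudy`` has columns ``category``, ``candidate``, ``most_like_count``,
    ``least_like_count``. The best-case image is the candidate most often
    marked "most like" the category; the worst-case the one most often marked
    "least like". Ties break toward the earliest candidate row (deterministic).
    Returns one row per category with ``best_image``, ``worst_image`` and a
    ``coincide`` flag set when one image maximises both counts.
    """
    required = {"category", "candidate", "most_like_count", "least_like_count"}
    missing = required - set(prestudy.columns)
    if missing:
        raise ValueError(f"prestudy table missing columns: {sorted(missing)}")
    rows = []
    for category, grp in prestudy.groupby("category", sort=True):
        if len(grp) < 2:
            raise ValueError(f"category {category!r} needs >= 2 candidate images")
        grp = grp.reset_index(drop=True)
        best = grp.loc[grp["most_like_count"].idxmax(), "candidate"]
        worst = grp.loc[grp["least_like_count"].idxmax(), "candidate"]
        rows.append(
            {
                "category": category,
                "best_image": best,
                "worst_image": worst,
                "coincide": best == worst,
            }
        )
    return pd.DataFrame(rows)


def build_identification_trials(
    attack_images_by_class: Mapping[str, Sequence[str]],
    n_foil_images: int = 2,
    rng: np.random.Generator | None = None,
    condition: str = "pick_one_of_three",
) -> list[TrialSpec]:
    """Trials where the observer must match a generated image to a target class.

    For each class with at least one generated image, one trial shows a
    target-class fooling image alongside ``n_foil_images`` fooling images
    generated for *other* classes, in random order; the correct (machine)
    answer is the target-class image. Chance is ``1 / (n_foil_images + 1)``.

    The TrialSpec's ``image_id`` is the target class; its alternatives are
    image identifiers.
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    if n_foil_images < 1:
        raise ValueError("n_foil_images must be >= 1")
    classes = [c for c in attack_images_by_class if len(attack_images_by_class[c]) > 0]
    trials = []
    for target_class in classes:
        target_img = attack_images_by_class[target_class][
            rng.integers(len(attack_images_by_class[target_class]))
        ]
        other_imgs = [
            img for c in classes if c != target_class for img in attack_images_by_class[c]
        ]
        if len(other_imgs) < n_foil_images:
            raise ValueError(
                f"not enough foil images for target class {target_class!r}: "
                f"{len(other_imgs)} < {n_foil_images}"
            )
        foils = list(rng.choice(np.asarray(other_imgs, dtype=object), size=n_foil_images, replace=False))
        alts = [target_img] + foils
        presented = [alts[i] for i in rng.permutation(len(alts))]
        trials.append(
            TrialSpec(
                image_id=str(target_class),
                alternatives=tuple(presented),
                machine_label=target_img,
                condition=condition,
            )
        )
    return trials


def crossed_conditions(factors: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Complete crossing of within-participant factors (e.g. dataset x encoding).

    Returns one row per cell with a ``condition`` tag ``"level1:level2"``,
    the scaffold for 2 x 2 repeated-measures designs in which every participant
    completes every cell.
    """
    names = list(factors)
    grids = np.meshgrid(*[np.asarray(v, dtype=object) for v in factors.values()], indexing="ij")
    df = pd.DataFrame({n: g.ravel() for n, g in zip(names, grids)})
    df["condition"] = df[names].agg(":".join, axis=1)
    return df
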