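"""Desk-scale fooling-image generation.

Trains small classifiers on a synthetic labelled shape dataset and attacks
them with (a) an iterative gradient-sign attack and (b) a direct-encoding
evolutionary attack whose genome is the raw pixel grid, then filters the
resulting candidates by ensemble transferability. Also provides the standard
centre-crop + per-channel normalisation preprocessing contract used with
ImageNet-pretrained networks.

The classifier behind :func:`train_classifier` is a multinomial logistic
(softmax) model fitted with scikit-learn; class probabilities and input
gradients are computed analytically from the fitted weights, so the gradient
contract is exact rather than autograd-dependent. Any object satisfying
:class:`ClassifierHandle` (including a wrapped pretrained deep network) can be
attacked through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression

__all__ = [
    "LabelledImageSet",
    "ClassifierHandle",
    "ArchConfig",
    "AttackConfig",
    "EAConfig",
    "AttackResult",
    "TransferFilterResult",
    "PreprocessSpec",
    "make_shape_dataset",
    "class_templates",
    "train_classifier",
    "iterative_gradient_attack",
    "direct_encoding_ea_attack",
    "ensemble_transfer_filter",
    "preprocess_centre_crop_normalize",
]


# ---------------------------------------------------------------------------
# datasets


@dataclass
class LabelledImageSet:
    """A stack of same-shape images in [0, 1] with integer class labels."""

    images: np.ndarray  # (n, H, W) or (n, H, W, 3)
    labels: np.ndarray  # (n,) ints in [0, n_classes)
    class_names: list

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        n_classes = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= n_classes):
            raise ValueError("labels out of range")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_shape(self) -> tuple:
        return self.images.shape[1:]


def _tpl_h_bar(s):
    g = np.zeros((s, s)); g[s // 2 - s // 8 : s // 2 + s // 8 + 1, :] = 1.0; return g


def _tpl_v_bar(s):
    return _tpl_h_bar(s).T


def _tpl_disk(s):
    y, x = np.mgrid[:s, :s]
    c = (s - 1) / 2
    return ((y - c) ** 2 + (x - c) ** 2 <= (s / 3.2) ** 2).astype(float)


def _tpl_ring(s):
    y, x = np.mgrid[:s, :s]
    c = (s - 1) / 2
    r = np.sqrt((y - c) ** 2 + (x - c) ** 2)
    return ((r <= s / 2.6) & (r >= s / 4.5)).astype(float)


def _tpl_cross(s):
    g = np.zeros((s, s))
    w = max(1, s // 8)
    g[s // 2 - w : s // 2 + w + 1, :] = 1.0
    g[:, s // 2 - w : s // 2 + w + 1] = 1.0
    return g


def _tpl_diag(s):
    y, x = np.mgrid[:s, :s]
    return (np.abs(y - x) <= max(1, s // 8)).astype(float)


def _tpl_anti_diag(s):
    return _tpl_diag(s)[::-1].copy()


def _tpl_checker(s):
    y, x = np.mgrid[:s, :s]
    b = max(2, s // 4)
    return (((y // b) + (x // b)) % 2).astype(float)


def _tpl_h_grating(s):
    y = np.arange(s)
    return np.tile((0.5 + 0.5 * np.sin(2 * np.pi * y * 3 / s))[:, None], (1, s))


def _tpl_v_grating(s):
    return _tpl_h_grating(s).T.copy()


def _tpl_frame(s):
    g = np.zeros((s, s))
    w = max(1, s // 8)
    g[:w, :] = g[-w:, :] = g[:, :w] = g[:, -w:] = 1.0
    return g


def _tpl_square(s):
    g = np.zeros((s, s))
    q = s // 4
    g[q : s - q, q : s - q] = 1.0
    return g


_PATTERN_FAMILY: list[tuple[str, Callable]] = [
    ("h_bar", _tpl_h_bar),
    ("v_bar", _tpl_v_bar),
    ("disk", _tpl_disk),
    ("ring", _tpl_ring),
    ("cross", _tpl_cross),
    ("diag", _tpl_diag),
    ("anti_diag", _tpl_anti_diag),
    ("checker", _tpl_checker),
    ("h_grating", _tpl_h_grating),
    ("v_grating", _tpl_v_grating),
    ("frame", _tpl_frame),
    ("square", _tpl_square),
]


def class_templates(n_classes: int, image_size: int) -> tuple[list, np.ndarray]:
    """Noise-free template image per class; `(names, (n_classes, s, s) array)`."""
    if n_classes > len(_PATTERN_FAMILY):
        raise ValueError(
            f"n_classes={n_classes} exceeds available pattern families ({len(_PATTERN_FAMILY)})"
        )
    names = [name for name, _ in _PATTERN_FAMILY[:n_classes]]
    tpls = np.stack([f(image_size) for _, f in _PATTERN_FAMILY[:n_classes]])
    return names, tpls


def make_shape_dataset(
    n_classes: int = 10,
    n_per_class: int = 100,
    image_size: int = 32,
    noise_sd: float = 0.15,
    rng: np.random.Generator | None = None,
) -> LabelledImageSet:
    """Synthetic grayscale shape dataset: one parametric pattern per class + noise.

    Classes are distinct geometric patterns (bars, disk, ring, cross, diagonals,
    checkerboard, gratings, frame, square) on an ``image_size`` x ``image_size``
    grid, each instance perturbed by iid Gaussian pixel noise of SD ``noise_sd``
    and clipped to [0, 1]. At ``noise_sd = 0`` the classes are exactly their
    templates and hence trivially separable.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    names, tpls = class_templates(n_classes, image_size)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    images = tpls[labels]
    if noise_sd > 0:
        images = images + noise_sd * rng.standard_normal(images.shape)
    images = np.clip(images, 0.0, 1.0)
    return LabelledImageSet(images=images, labels=labels, class_names=names)


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierHandle:
    """Contract for an attackable image classifier.

    ``predict_proba(image) -> (n_classes,)`` probabilities summing to 1;
    ``input_gradient(image, target_class)`` is the gradient of the log
    probability of ``target_class`` with respect to the input pixels, with the
    same shape as the image.
    """

    n_classes: int
    predict_proba: Callable[[np.ndarray], np.ndarray]
    input_gradient: Callable[[np.ndarray, int], np.ndarray]
    name: str = "classifier"
    input_shape: tuple = ()
    metadata: dict = field(default_factory=dict)

    def predict(self, image: np.ndarray) -> int:
        return int(np.argmax(self.predict_proba(image)))


@dataclass(frozen=True)
class ArchConfig:
    """Softmax-classifier fit settings (scikit-learn multinomial logistic)."""

    C: float = 1.0
    max_iter: int = 300


def train_classifier(
    dataset: LabelledImageSet,
    arch_config: ArchConfig = ArchConfig(),
    rng: np.random.Generator | None = None,
) -> ClassifierHandle:
    """Fit a softmax classifier on flattened pixels and wrap it as a handle.

    Probabilities are ``softmax(W x + b)`` and the input gradient of the
    log-probability of class *t* is the exact expression
    ``w_t - sum_c p_c w_c``, reshaped to the image. Non-convergence of the
    optimiser within ``arch_config.max_iter`` iterations is flagged in
    ``metadata["converged"]`` rather than raised.
    """
    if dataset.n_classes < 2:
        raise ValueError("need >= 2 classes")
    counts = np.bincount(dataset.labels, minlength=dataset.n_classes)
    if counts.min() < 10:
        raise ValueError("need >= 10 images per class")
    if rng is None:
        rng = np.random.default_rng(0)
    shape = dataset.image_shape
    n = len(dataset.labels)
    order = rng.permutation(n)
    X = dataset.images[order].reshape(n, -1)
    y = dataset.labels[order]
    clf = LogisticRegression(C=arch_config.C, max_iter=arch_config.max_iter)
    clf.fit(X, y)
    # express the decision function as softmax(W x + b) over classes 0..K-1
    W = np.zeros((dataset.n_classes, X.shape[1]))
    b = np.zeros(dataset.n_classes)
    if clf.coef_.shape[0] == 1:  # binary: sklearn stores the positive-class row
        W[clf.classes_[1]] = clf.coef_[0]
        b[clf.classes_[1]] = clf.intercept_[0]
    else:
        W[clf.classes_] = clf.coef_
        b[clf.classes_] = clf.intercept_

    def predict_proba(image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float).reshape(-1)
        return softmax(W @ x + b)

    def input_gradient(image: np.ndarray, target_class: int) -> np.ndarray:
        x = np.asarray(image, dtype=float).reshape(-1)
        p = softmax(W @ x + b)
        g = W[target_class] - p @ W
        return g.reshape(shape)

    converged = bool(np.all(clf.n_iter_ < arch_config.max_iter))
    return ClassifierHandle(
        n_classes=dataset.n_classes,
        predict_proba=predict_proba,
        input_gradient=input_gradient,
        name="softmax",
        input_shape=shape,
        metadata={"converged": converged, "n_iter": int(np.max(clf.n_iter_))},
    )


# ---------------------------------------------------------------------------
# attacks


@dataclass(frozen=True)
class AttackConfig:
    """Iterative gradient-sign attack settings.

    The attack succeeds once the classifier assigns the target class a
    probability of at least ``confidence_threshold`` (default 0.99, the
    customary ">99% confidence" criterion for fooling images).
    """

    confidence_threshold: float = 0.99
    max_iterations: int = 500
    step_size: float = 1.0 / 255.0
    pixel_bounds: tuple = (0.0, 1.0)
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.step_size > 0:
            raise ValueError("step_size must be positive")


@dataclass(frozen=True)
class EAConfig:
    """Direct-encoding evolutionary attack settings (genome = raw pixel grid)."""

    population_size: int = 20
    mutation_rate: float = 0.01
    mutation_sd: float = 0.1
    elitism: int = 1
    max_generations: int = 200
    confidence_threshold: float = 0.99
    pixel_bounds: tuple = (0.0, 1.0)

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in (0, 1]")
        if self.elitism < 1 or self.elitism >= self.population_size:
            raise ValueError("elitism must lie in [1, population_size)")


@dataclass
class AttackResult:
    """Outcome of an adversarial attack on one classifier/target pair."""

    image: np.ndarray
    target_class: int
    final_confidence: float
    iterations_used: int
    success: bool
    method: str
    confidence_threshold: float = 0.99
    history: list = field(default_factory=list)


def iterative_gradient_attack(
    classifier: ClassifierHandle,
    target_class: int,
    config: AttackConfig = AttackConfig(),
    rng: np.random.Generator | None = None,
) -> AttackResult:
    """Synthesise a fooling image by the iterative gradient-sign method.

    Starts from an image whose pixels are independently sampled Uniform[0, 1]
    and repeatedly steps by ``step_size * sign(grad log p(target))``, clipping to
    the pixel bounds, until the classifier's target-class probability reaches
    the confidence threshold or the iteration budget is spent. The returned
    ``final_confidence`` is recomputed by a fresh forward pass on the returned
    image.
    """
    if not 0 <= target_class < classifier.n_classes:
        raise ValueError(f"target_class {target_class} out of range [0, {classifier.n_classes})")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.pixel_bounds
    x = rng.uniform(lo, hi, size=classifier.input_shape)
    history = []
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        conf = float(classifier.predict_proba(x)[target_class])
        history.append(conf)
        if conf >= config.confidence_threshold:
            iterations -= 1  # no step taken this round
            break
        g = classifier.input_gradient(x, target_class)
        x = np.clip(x + config.step_size * np.sign(g), lo, hi)
    final = float(classifier.predict_proba(x)[target_class])
    return AttackResult(
        image=x,
        target_class=target_class,
        final_confidence=final,
        iterations_used=iterations,
        success=final >= config.confidence_threshold,
        method="gradient",
        confidence_threshold=config.confidence_threshold,
        history=history,
    )


def direct_encoding_ea_attack(
    classifier: ClassifierHandle,
    target_class: int,
    ea_config: EAConfig = EAConfig(),
    rng: np.random.Generator | None = None,
) -> AttackResult:
    """Evolve a fooling image with a direct-encoding (raw-pixel genome) EA.

    A population of pixel grids is evolved by per-pixel Gaussian mutation with
    elitist selection on the classifier's target-class confidence. Elitism makes
    the best-of-generation fitness non-decreasing; that trajectory is returned
    in ``history``. Direct encoding characteristically yields noise-like images
    rather than regular patterns.
    """
    if not 0 <= target_class < classifier.n_classes:
        raise ValueError(f"target_class {target_class} out of range [0, {classifier.n_classes})")
    if rng is None:
        rng = np.random.default_rng(0)
    cfg = ea_config
    lo, hi = cfg.pixel_bounds
    shape = classifier.input_shape
    pop = rng.uniform(lo, hi, size=(cfg.population_size,) + shape)
    fitness = np.array([classifier.predict_proba(g)[target_class] for g in pop])
    history = []
    gens = 0
    for gens in range(1, cfg.max_generations + 1):
        order = np.argsort(fitness)[::-1]
        pop, fitness = pop[order], fitness[order]
        history.append(float(fitness[0]))
        if fitness[0] >= cfg.confidence_threshold:
            gens -= 1
            break
        n_children = cfg.population_size - cfg.elitism
        parents = pop[rng.integers(0, max(2, cfg.population_size // 2), size=n_children)]
        mask = rng.random(parents.shape) < cfg.mutation_rate
        children = np.clip(
            parents + mask * (cfg.mutation_sd * rng.standard_normal(parents.shape)), lo, hi
        )
        pop = np.concatenate([pop[: cfg.elitism], children])
        child_fit = np.array([classifier.predict_proba(g)[target_class] for g in children])
        fitness = np.concatenate([fitness[: cfg.elitism], child_fit])
    best = pop[int(np.argmax(fitness))]
    final = float(classifier.predict_proba(best)[target_class])
    return AttackResult(
        image=best,
        target_class=target_class,
        final_confidence=final,
        iterations_used=gens,
        success=final >= cfg.confidence_threshold,
        method="ea_direct",
        confidence_threshold=cfg.confidence_threshold,
        history=history,
    )


# ---------------------------------------------------------------------------
# transferability


@dataclass
class TransferFilterResult:
    """Outcome of the ensemble transferability filter."""

    retained: list  # AttackResults passing the k_min rule
    agreement_counts: list  # per input candidate, # classifiers agreeing
    median_confidence: float  # over agreeing (classifier, image) pairs of retained


def ensemble_transfer_filter(
    candidates: Sequence[AttackResult],
    classifiers: Sequence[ClassifierHandle],
    k_min: int,
    conf_min: float = 0.0,
) -> TransferFilterResult:
    """Keep candidates whose fooling label transfers to >= ``k_min`` classifiers.

    A classifier *agrees* with a candidate when its argmax label equals the
    candidate's target class and its target-class confidence is at least
    ``conf_min`` (``conf_min = 0`` reduces agreement to the pure argmax rule).
    The reported median confidence is taken over the agreeing
    (classifier, image) pairs of the retained candidates only, mirroring how
    transferable stimulus sets report their "median confidence".
    """
    if len(classifiers) == 0:
        raise ValueError("classifier list is empty")
    if k_min > len(classifiers):
        raise ValueError("k_min exceeds the number of classifiers")
    retained = []
    counts = []
    agreeing_confs = []
    for cand in candidates:
        probs = [clf.predict_proba(cand.image) for clf in classifiers]
        agree = [
            p for p in probs
            if int(np.argmax(p)) == cand.target_class and p[cand.target_class] >= conf_min
        ]
        counts.append(len(agree))
        if len(agree) >= k_min:
            retained.append(cand)
            agreeing_confs.extend(float(p[cand.target_class]) for p in agree)
    med = float(np.median(agreeing_confs)) if agreeing_confs else float("nan")
    return TransferFilterResult(retained=retained, agreement_counts=counts, median_confidence=med)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass(frozen=True)
class PreprocessSpec:
    """Centre-crop + per-channel normalisation contract.

    Defaults are the standard ImageNet deployment constants: 224 x 224 centre
    crop, mean = [0.485, 0.456, 0.406], std = [0.229, 0.224, 0.225].
    """

    crop_size: int = 224
    channel_means: tuple = (0.485, 0.456, 0.406)
    channel_stds: tuple = (0.229, 0.224, 0.225)

    def __post_init__(self):
        if self.crop_size <= 0:
            raise ValueError("crop_size must be positive")
        if any(s <= 0 for s in self.channel_stds):
            raise ValueError("channel_stds must be strictly positive")


def preprocess_centre_crop_normalize(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Centre-crop to ``spec.crop_size`` and normalise per channel.

    The crop window is centred; for odd margins the extra pixel is dropped from
    the bottom/right (ties break toward the top-left). Output is
    ``(pixel - mean) / std`` per channel. Grayscale (H, W) images use the first
    mean/std entry.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape[:2]
    c = spec.crop_size
    if H < c or W < c:
        raise ValueError(f"image {(H, W)} smaller than crop size {c}")
    top, left = (H - c) // 2, (W - c) // 2
    crop = img[top : top + c, left : left + c]
    means = np.asarray(spec.channel_means, dtype=float)
    stds = np.asarray(spec.channel_stds, dtype=float)
    if crop.ndim == 2:
        return (crop - means[0]) / stds[0]
    n_ch = crop.shape[2]
    if len(means) < n_ch or len(stds) < n_ch:
        raise ValueError("spec does not cover all image channels")
    return (crop - means[:n_ch]) / stds[:n_ch]
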