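"""End-to-end training-performance forecasting with the Markov-threshold DHNN.

The pipeline turns a table of scored sessions into a fitted attractor
classifier and its evaluation:

1. encode each 7-score row as a bipolar pattern (score ≥ 5 → +1);
2. split rows 60/20/20 into train / test / validation (seeded shuffle,
   largest-remainder rounding);
3. on the training rows, build the Markov transition matrix from the raw
   score matrix, power it to m steps and read the per-neuron activation
   thresholds off its row maxima;
4. store one prototype pattern per class (elementwise sign of the class
   mean pattern) with Hebbian weights;
5. predict a row by running its encoded pattern to an attractor and
   assigning the class of the Hamming-nearest prototype;
6. report accuracy, precision, recall, F1 and G-score (the geometric mean
   of precision and recall) on each split.

A Hopfield network is an associative memory, not a classifier; the
per-class-prototype storage plus nearest-attractor assignment used here is
the minimal standard bridge between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FittingError, ScoreValidationError
from .hopfield import FitConfig, hebbian_weights, run_to_convergence
from .markov import first_step_matrix, step_matrix, thresholds
from .scoring import INDICATORS, LEVEL_SETS
from .synth import SessionTable

__all__ = [
    "encode",
    "label",
    "split",
    "SplitIndices",
    "Metrics",
    "FittedModel",
    "ConvergenceSummary",
    "fit",
    "predict",
    "decision_margin",
    "evaluate",
    "save_model",
    "load_model",
    "PipelineReport",
    "run_pipeline",
]

_LEVELS_BY_POS = [LEVEL_SETS[key] for key in INDICATORS]


def _as_score_rows(scores) -> np.ndarray:
    rows = np.asarray(scores)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.ndim != 2 or rows.shape[1] != len(INDICATORS):
        raise ScoreValidationError(
            f"expected rows of {len(INDICATORS)} indicator scores, got shape {rows.shape}"
        )
    for k, allowed in enumerate(_LEVELS_BY_POS):
        bad = ~np.isin(rows[:, k], allowed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ScoreValidationError(
                f"row {i}, indicator {INDICATORS[k]}: score {rows[i, k]!r} "
                f"not in allowed levels {allowed}"
            )
    return rows.astype(int)


def encode(scores) -> np.ndarray:
    """Bipolar encoding of score rows: +1 for at least partial completion.

    Accepts a single 7-score row or a V×7 matrix; entry k is +1 when
    score_k ≥ 5 and −1 otherwise.  Returns the same shape as the input.
    """
    single = np.asarray(scores).ndim == 1
    rows = _as_score_rows(scores)
    patterns = np.where(rows >= 5, 1, -1)
    return patterns[0] if single else patterns


def label(scores, cutoff: float = 40.0):
    """Binary training-performance class: total score ≥ cutoff (0–70 scale)."""
    if not 0 <= cutoff <= 70:
        raise ValueError("cutoff must lie in [0, 70]")
    single = np.asarray(scores).ndim == 1
    rows = _as_score_rows(scores)
    labels = (rows.sum(axis=1) >= cutoff).astype(int)
    return int(labels[0]) if single else labels


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint row-index sets covering a table."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    fractions: tuple[float, float, float]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.test), len(self.validation))


def split(table, fractions=(0.6, 0.2, 0.2), seed: int | None = 0) -> SplitIndices:
    """Shuffle rows with a seeded RNG and partition by largest-remainder rounding.

    ``table`` may be a :class:`SessionTable` or a plain row count.
    """
    n = len(table) if not isinstance(table, (int, np.integer)) else int(table)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("need three non-negative fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    exact = np.asarray(fractions) * n
    sizes = np.floor(exact).astype(int)
    remainder = int(n - sizes.sum())
    for idx in np.argsort(-(exact - sizes), kind="stable")[:remainder]:
        sizes[idx] += 1
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum(sizes)[:2]
    train, test, validation = np.split(perm, bounds)
    return SplitIndices(train, test, validation, fractions)


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived forecast metrics.

    ``degenerate`` lists metrics whose denominator was zero (reported as 0).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    g_score: float
    degenerate: tuple[str, ...] = ()


def evaluate(predictions, truths, positive_label: int = 1) -> Metrics:
    """Confusion counts plus accuracy, precision, recall, F1 and G-score."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape or predictions.ndim != 1:
        raise ValueError("predictions and truths must be equal-length 1-D sequences")
    if predictions.size == 0:
        raise ValueError("cannot evaluate an empty prediction list")
    pos_pred = predictions == positive_label
    pos_true = truths == positive_label
    tp = int(np.sum(pos_pred & pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))

    degenerate = []

    def _ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / predictions.size
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    g_score = float(np.sqrt(precision * recall))
    if degenerate:
        warnings.warn(
            f"degenerate denominators for: {', '.join(degenerate)}; reported as 0",
            stacklevel=2,
        )
    return Metrics(tp, fp, fn, tn, accuracy, precision, recall, f1, g_score,
                   tuple(degenerate))


@dataclass(frozen=True)
class ConvergenceSummary:
    """How the training patterns behaved under the fitted dynamics."""

    n_patterns: int
    n_converged: int
    mean_sweeps: float
    max_sweeps: int

    @property
    def converged(self) -> bool:
        return self.n_converged == self.n_patterns


@dataclass(frozen=True)
class FittedModel:
    """A trained Markov-threshold DHNN classifier."""

    weights: np.ndarray
    thresholds: np.ndarray
    classes: tuple[int, ...]
    prototypes: dict[int, np.ndarray]
    config: FitConfig
    markov_mode: str
    markov_branch: str
    convergence: ConvergenceSummary

    @property
    def n_neurons(self) -> int:
        return self.thresholds.size


def fit(scores, labels, config: FitConfig | None = None,
        markov_mode: str = "indicator_space") -> FittedModel:
    """Fit the classifier on training rows.

    Thresholds come from the Markov construction on the raw score matrix
    (one-step matrix → m-step power with m = neuron count → row maxima);
    prototypes are the per-class sign of the mean encoded pattern (ties
    break to +1); weights store the prototypes by the Hebbian rule.
    """
    config = config or FitConfig()
    rows = _as_score_rows(scores)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (rows.shape[0],):
        raise ValueError("labels must match the number of score rows")
    if rows.shape[0] == 0:
        raise FittingError("training slice is empty")
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) < 2:
        present = classes[0]
        missing = 1 - present if present in (0, 1) else "the second class"
        raise FittingError(
            f"training slice contains only class {present}; class {missing} is missing"
        )

    P1 = first_step_matrix(rows.astype(float), mode=markov_mode)
    Pm = step_matrix(P1, P1.m)
    T = thresholds(Pm)

    patterns = encode(rows)
    prototypes = {}
    for c in classes:
        mean = patterns[labels == c].mean(axis=0)
        prototypes[c] = np.where(mean >= 0, 1, -1).astype(int)
    W = hebbian_weights(np.stack([prototypes[c] for c in classes]))

    # Run every training pattern to an attractor under the fitted dynamics.
    rng_seeds = _per_row_seeds(config.seed, rows.shape[0])
    sweeps_by_pattern: dict[tuple, tuple[int, bool]] = {}
    total_sweeps = 0
    n_converged = 0
    max_sweeps = 0
    for i, pattern in enumerate(patterns):
        key = tuple(pattern)
        if config.update_mode == "deterministic" and key in sweeps_by_pattern:
            sweeps, ok = sweeps_by_pattern[key]
        else:
            row_config = FitConfig(
                j_max=config.j_max,
                update_mode=config.update_mode,
                threshold_scale=config.threshold_scale,
                seed=int(rng_seeds[i]),
                neuron_order=config.neuron_order,
            )
            result = run_to_convergence(W, pattern, T, row_config)
            sweeps, ok = result.sweeps, result.converged
            sweeps_by_pattern[key] = (sweeps, ok)
        total_sweeps += sweeps
        max_sweeps = max(max_sweeps, sweeps)
        n_converged += int(ok)
    summary = ConvergenceSummary(
        n_patterns=rows.shape[0],
        n_converged=n_converged,
        mean_sweeps=total_sweeps / rows.shape[0],
        max_sweeps=max_sweeps,
    )
    return FittedModel(W, T, classes, prototypes, config, markov_mode, P1.branch, summary)


def _per_row_seeds(seed, n) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _final_states(model: FittedModel, rows: np.ndarray) -> np.ndarray:
    patterns = encode(rows)
    seeds = _per_row_seeds(model.config.seed, rows.shape[0])
    finals = np.empty_like(patterns)
    cache: dict[tuple, np.ndarray] = {}
    deterministic = model.config.update_mode == "deterministic"
    for i, pattern in enumerate(patterns):
        key = tuple(pattern)
        if deterministic and key in cache:
            finals[i] = cache[key]
            continue
        row_config = FitConfig(
            j_max=model.config.j_max,
            update_mode=model.config.update_mode,
            threshold_scale=model.config.threshold_scale,
            seed=int(seeds[i]),
            neuron_order=model.config.neuron_order,
        )
        result = run_to_convergence(model.weights, pattern, model.thresholds, row_config)
        finals[i] = result.state
        if deterministic:
            cache[key] = result.state
    return finals


def predict(model: FittedModel, scores):
    """Classify rows by nearest prototype (Hamming) after attractor dynamics.

    Ties in Hamming distance break toward the first (sorted) class label.
    Accepts one row or a matrix; returns an int or an int array accordingly.
    """
    single = np.asarray(scores).ndim == 1
    rows = _as_score_rows(scores)
    finals = _final_states(model, rows)
    protos = np.stack([model.prototypes[c] for c in model.classes])
    # Hamming distance = (n - dot)/2; argmin takes the first class on ties.
    dists = (protos.shape[1] - finals @ protos.T) // 2
    preds = np.asarray(model.classes)[np.argmin(dists, axis=1)]
    return int(preds[0]) if single else preds


def decision_margin(model: FittedModel, scores) -> np.ndarray:
    """Signed continuous forecast: positive means closer to the higher class.

    For binary classes (c0 < c1) the margin is (d(x*, proto_c0) −
    d(x*, proto_c1)) / n, where x* is the attractor reached from the row's
    encoding and d is Hamming distance.  Used as the continuous outcome for
    the indicator-correlation analysis.
    """
    rows = _as_score_rows(scores)
    finals = _final_states(model, rows)
    protos = np.stack([model.prototypes[c] for c in model.classes])
    dists = (protos.shape[1] - finals @ protos.T) / 2
    return (dists[:, 0] - dists[:, -1]) / model.n_neurons


def save_model(model: FittedModel, destination) -> None:
    """Serialise a fitted model as JSON (weights, thresholds, prototypes, config)."""
    import json

    payload = {
        "weights": model.weights.tolist(),
        "thresholds": model.thresholds.tolist(),
        "classes": list(model.classes),
        "prototypes": {str(c): model.prototypes[c].tolist() for c in model.classes},
        "config": {
            "j_max": model.config.j_max,
            "update_mode": model.config.update_mode,
            "threshold_scale": model.config.threshold_scale,
            "seed": model.config.seed,
            "neuron_order": model.config.neuron_order,
        },
        "markov_mode": model.markov_mode,
        "markov_branch": model.markov_branch,
        "convergence": {
            "n_patterns": model.convergence.n_patterns,
            "n_converged": model.convergence.n_converged,
            "mean_sweeps": model.convergence.mean_sweeps,
            "max_sweeps": model.convergence.max_sweeps,
        },
    }
    with open(destination, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)


def load_model(source) -> FittedModel:
    """Load a model written by :func:`save_model`."""
    import json

    with open(source, encoding="utf-8") as handle:
        payload = json.load(handle)
    classes = tuple(int(c) for c in payload["classes"])
    return FittedModel(
        weights=np.asarray(payload["weights"], dtype=float),
        thresholds=np.asarray(payload["thresholds"], dtype=float),
        classes=classes,
        prototypes={c: np.asarray(payload["prototypes"][str(c)], dtype=int) for c in classes},
        config=FitConfig(**payload["config"]),
        markov_mode=payload["markov_mode"],
        markov_branch=payload["markov_branch"],
        convergence=ConvergenceSummary(**payload["convergence"]),
    )


@dataclass(frozen=True)
class PipelineReport:
    """Everything the end-to-end run produced."""

    model: FittedModel
    splits: SplitIndices
    metrics: dict[str, Metrics]
    seed: int | None
    label_cutoff: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def training_accuracy(self) -> float:
        return self.metrics["train"].accuracy

    @property
    def testing_accuracy(self) -> float:
        return self.metrics["test"].accuracy

    @property
    def predicted_accuracy(self) -> float:
        """Accuracy on the validation split — the headline forecast accuracy."""
        return self.metrics["validation"].accuracy

    def summary(self) -> str:
        lines = [
            f"Markov-threshold DHNN forecast report (seed={self.seed})",
            f"  neurons: {self.model.n_neurons}  markov: {self.model.markov_mode} "
            f"[{self.model.markov_branch}]",
            f"  split sizes (train/test/validation): "
            f"{'/'.join(str(s) for s in self.splits.sizes)}",
            f"  thresholds: {np.array2string(self.model.thresholds, precision=4)}",
            f"  training convergence: {self.model.convergence.n_converged}/"
            f"{self.model.convergence.n_patterns} patterns, "
            f"mean {self.model.convergence.mean_sweeps:.2f} sweeps",
        ]
        for name in ("train", "test", "validation"):
            m = self.metrics[name]
            lines.append(
                f"  {name:>10}: accuracy={m.accuracy:.3f} precision={m.precision:.3f} "
                f"recall={m.recall:.3f} f1={m.f1:.3f} g={m.g_score:.3f}"
            )
        return "\n".join(lines)


def run_pipeline(table: SessionTable, *, fractions=(0.6, 0.2, 0.2),
                 seed: int | None = 0, config: FitConfig | None = None,
                 markov_mode: str = "indicator_space",
                 label_cutoff: float = 40.0) -> PipelineReport:
    """Split → fit on train → evaluate on train, test and validation.

    The table's own ``label`` column is used when present; otherwise labels
    are derived from the total score at ``label_cutoff``.
    """
    config = config or FitConfig()
    rows = table.scores
    labels = table.labels
    used_cutoff = None
    if labels is None:
        labels = label(rows, cutoff=label_cutoff)
        used_cutoff = label_cutoff
    parts = split(len(table), fractions, seed)
    model = fit(rows[parts.train], labels[parts.train], config, markov_mode)
    metrics = {}
    for name, idx in (("train", parts.train), ("test", parts.test),
                      ("validation", parts.validation)):
        preds = predict(model, rows[idx])
        metrics[name] = evaluate(preds, labels[idx])
    return PipelineReport(model, parts, metrics, seed, used_cutoff)
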