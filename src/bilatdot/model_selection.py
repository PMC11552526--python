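"""Split protocol, linear-SVM training, and representation selection.

The selection protocol mirrors small-sample clinical ML practice: the cohort
is first split once into a *model selection* set (80%) and a held-back *final
test* set (20%), stratified by label.  All representation and hyperparameter
search happens inside the model-selection set via repeated (overlapping)
stratified shuffle splits, each holding out 20% for validation.  The winning
(representation, C) pair is then retrained on the whole model-selection set
and scored exactly once on the test set.

Units are breasts in *unilateral* mode (both breasts of a subject enter as
independent records, the tumour-bearing breast labelled positive and the
contralateral breast negative) and subjects in *bilateral* mode.  Held-out
sizes use the floor rule ``floor(frac * n)``; for a 63-subject cohort this
yields the canonical counts 126 -> 101/25 breasts and 81/20 per shuffle
split, and 63 -> 51/12 subjects with 41/10 per split.

The classifier is a maximum-margin linear SVM (hinge loss, inverse
regularization ``C``).  Features enter exactly as built — the normalizations
under study are the only rescaling applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVC

from ._errors import DegenerateDataError, StratificationError, ValidationError
from .core import Cohort, SubjectRecord
from .evaluation import ROCResult, roc_auc
from .representations import RepresentationSpec, build_bilateral, build_unilateral

Mode = Literal["unilateral", "bilateral"]

#: Default hyperparameter grid: 7 values log-spaced over 1e-3 .. 1e3.
DEFAULT_C_GRID: tuple[float, ...] = tuple(float(10.0 ** k) for k in range(-3, 4))


@dataclass(frozen=True)
class LabeledSample:
    """One classification unit: a breast (unilateral) or a subject (bilateral)."""

    features: np.ndarray
    label: int
    unit_id: str


@dataclass(frozen=True)
class SplitPlan:
    """Frozen unit-level split indices for one selection run."""

    model_selection_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    shuffle_splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, validation)
    mode: Mode
    seed: int


@dataclass(frozen=True)
class SelectionResult:
    """Winner of the cross-validated representation and hyperparameter search."""

    best_spec: RepresentationSpec
    best_C: float
    validation_auc_mean: float
    validation_auc_sd: float
    per_spec_table: tuple[tuple[RepresentationSpec, float, float], ...]  # (spec, C, mean val AUC)


def unit_ids_and_labels(cohort: Cohort, mode: Mode) -> tuple[list[str], dict[str, int]]:
    """Ordered unit ids and their binary labels for a cohort and mode."""
    ids: list[str] = []
    labels: dict[str, int] = {}
    for rec in cohort:
        if mode == "bilateral":
            ids.append(rec.subject_id)
            labels[rec.subject_id] = int(rec.cancer_positive)
        elif mode == "unilateral":
            for side in ("left", "right"):
                uid = f"{rec.subject_id}/{side}"
                ids.append(uid)
                labels[uid] = int(rec.tumor_side == side)
        else:
            raise ValidationError(f"mode must be 'unilateral' or 'bilateral', got {mode!r}")
    return ids, labels


def _stratified_holdout(ids: Sequence[str], labels: dict[str, int], n_hold: int,
                        rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Draw a stratified held-out set of exactly ``n_hold`` units.

    Per-class allocations follow largest-remainder rounding of
    ``n_hold * n_class / n``, which keeps label ratios within one unit of
    proportionality.  Order of the returned lists follows the input order.
    """
    n = len(ids)
    if not 0 < n_hold < n:
        raise StratificationError(f"cannot hold out {n_hold} of {n} units")
    by_class: dict[int, list[str]] = {}
    for uid in ids:
        by_class.setdefault(labels[uid], []).append(uid)
    quotas = {c: n_hold * len(members) / n for c, members in by_class.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    remainder = n_hold - sum(alloc.values())
    for c in sorted(quotas, key=lambda c: (-(quotas[c] - alloc[c]), c))[:remainder]:
        alloc[c] += 1
    for c, k in alloc.items():
        if k > len(by_class[c]):
            raise StratificationError(
                f"class {c} has {len(by_class[c])} units, cannot hold out {k}"
            )
    held = set()
    for c, members in sorted(by_class.items()):
        take = alloc[c]
        chosen = rng.choice(len(members), size=take, replace=False)
        held.update(members[j] for j in chosen)
    holdout = [uid for uid in ids if uid in held]
    rest = [uid for uid in ids if uid not in held]
    return rest, holdout


def make_split_plan(cohort: Cohort, mode: Mode, test_frac: float = 0.2,
                    val_frac: float = 0.2, n_splits: int = 20, seed: int = 0) -> SplitPlan:
    """Build the model-selection/test split and the shuffle splits within it.

    The test set holds ``floor(test_frac * n_units)`` units, stratified by
    label; each of the ``n_splits`` shuffle splits independently holds out
    ``floor(val_frac * n_model_selection)`` units for validation, stratified,
    drawn (with overlap across splits) from the seeded stream.
    """
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValidationError("test_frac and val_frac must lie in (0, 1)")
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    ids, labels = unit_ids_and_labels(cohort, mode)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n_test = int(math.floor(test_frac * len(ids)))
    model_ids, test_ids = _stratified_holdout(ids, labels, n_test, rng)
    n_val = int(math.floor(val_frac * len(model_ids)))
    splits = []
    for _ in range(n_splits):
        train, val = _stratified_holdout(model_ids, labels, n_val, rng)
        splits.append((tuple(train), tuple(val)))
    return SplitPlan(
        model_selection_ids=tuple(model_ids), test_ids=tuple(test_ids),
        shuffle_splits=tuple(splits), mode=mode, seed=seed,
    )


def build_samples(cohort: Cohort, spec: RepresentationSpec, mode: Mode) -> dict[str, LabeledSample]:
    """Featurize every unit of a cohort under one representation spec."""
    samples: dict[str, LabeledSample] = {}
    for rec in cohort:
        if mode == "bilateral":
            vec = build_bilateral(rec, spec).values
            samples[rec.subject_id] = LabeledSample(
                features=vec, label=int(rec.cancer_positive), unit_id=rec.subject_id,
            )
        else:
            for side in ("left", "right"):
                uid = f"{rec.subject_id}/{side}"
                vec = build_unilateral(rec, side, spec).values
                samples[uid] = LabeledSample(
                    features=vec, label=int(rec.tumor_side == side), unit_id=uid,
                )
    return samples


def train_linear_classifier(samples: Sequence[LabeledSample], C: float):
    """Fit a maximum-margin linear SVM and return its decision scorer.

    Higher scores mean more cancer-like.  Training is deterministic given the
    samples and ``C``.

    Raises
    ------
    DegenerateDataError
        If only one class is present or all feature vectors are identical.
    """
    if C <= 0:
        raise ValidationError(f"C must be positive, got {C}")
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples])
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set contains a single class")
    if np.all(X == X[0]):
        raise DegenerateDataError("all training feature vectors are identical")
    model = SVC(kernel="linear", C=C)
    model.fit(X, y)

    def scorer(features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return model.decision_function(features)

    scorer.model = model  # expose for inspection
    return scorer


def _spec_dimension(spec: RepresentationSpec, cohort: Cohort, mode: Mode) -> int:
    r, t = cohort.records[0].shape
    if mode == "bilateral":
        return spec.n_parts
    return spec.unilateral_length(r, t)


def select_model(cohort: Cohort, candidate_specs: Sequence[RepresentationSpec],
                 plan: SplitPlan, mode: Mode | None = None,
                 C_grid: Sequence[float] | None = None) -> SelectionResult:
    """Cross-validated search over representations and the SVM hyperparameter.

    Every (spec, C) candidate is trained on each shuffle split's training set
    and scored on its validation set; the pair with the highest mean
    validation AUC wins.  Ties break toward the smaller feature dimension,
    then the earlier spec in the candidate order, then the smaller C.
    """
    mode = mode or plan.mode
    if mode != plan.mode:
        raise ValidationError(f"mode {mode!r} disagrees with plan mode {plan.mode!r}")
    if not candidate_specs:
        raise ValidationError("candidate_specs must be non-empty")
    C_values = tuple(C_grid) if C_grid is not None else DEFAULT_C_GRID

    table: list[tuple[RepresentationSpec, float, float]] = []
    best = None  # (-(mean auc), dim, spec_pos, C) ordering key
    best_row: tuple[RepresentationSpec, float, float, float] | None = None
    for spec_pos, spec in enumerate(candidate_specs):
        samples = build_samples(cohort, spec, mode)
        dim = _spec_dimension(spec, cohort, mode)
        for C in C_values:
            aucs = []
            for split_idx, (train_ids, val_ids) in enumerate(plan.shuffle_splits):
                try:
                    scorer = train_linear_classifier([samples[u] for u in train_ids], C)
                    X_val = np.vstack([samples[u].features for u in val_ids])
                    y_val = [samples[u].label for u in val_ids]
                    aucs.append(roc_auc(scorer(X_val), y_val).auc)
                except DegenerateDataError as exc:
                    exc.add_note(f"spec {spec.label()!r}, C={C}, shuffle split {split_idx}")
                    raise
            mean_auc = float(np.mean(aucs))
            sd_auc = float(np.std(aucs))
            table.append((spec, float(C), mean_auc))
            key = (-mean_auc, dim, spec_pos, float(C))
            if best is None or key < best:
                best = key
                best_row = (spec, float(C), mean_auc, sd_auc)
    assert best_row is not None
    spec, C, mean_auc, sd_auc = best_row
    return SelectionResult(
        best_spec=spec, best_C=C,
        validation_auc_mean=mean_auc, validation_auc_sd=sd_auc,
        per_spec_table=tuple(table),
    )


def final_evaluate(cohort: Cohort, result: SelectionResult, plan: SplitPlan,
                   mode: Mode | None = None) -> ROCResult:
    """Retrain the winner on all model-selection units and score the test set once."""
    mode = mode or plan.mode
    samples = build_samples(cohort, result.best_spec, mode)
    scorer = train_linear_classifier(
        [samples[u] for u in plan.model_selection_ids], result.best_C,
    )
    X_test = np.vstack([samples[u].features for u in plan.test_ids])
    y_test = [samples[u].label for u in plan.test_ids]
    return roc_auc(scorer(X_test), y_test)
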