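"""Per-patient algorithm training.

Labels epochs as pre-ictal / interictal (with a post-ictal exclusion zone),
builds contiguous block-wise cross-validation folds (no temporal leakage),
searches the feature catalog by forward selection followed by backward
elimination (at most 16 features), and fits a regularized linear
discriminant that outputs a seizure likelihood in [0, 1] per epoch.

Selection scoring is the mean cross-validated balanced accuracy of a
shrinkage LDA, ``Sigma_reg = (1 - s) Sigma + s (tr(Sigma)/p) I`` — the same
regularization sklearn's ``LinearDiscriminantAnalysis(solver="lsqr",
shrinkage=s)`` applies.  Inside the search the discriminant is evaluated in
closed form (pooled per-block sufficient statistics, leave-one-block-out by
subtraction) so that the thousands of candidate fits per search cost
milliseconds; the final model is the sklearn estimator itself.

Tie-break everywhere: the lowest feature id wins.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

INTERICTAL, PREICTAL, EXCLUDED = 0, 1, -1

DEFAULT_HORIZON = 1800.0              # s, pre-ictal labeling window
DEFAULT_POSTICTAL_EXCLUSION = 3600.0  # s
DEFAULT_TOLERANCE = 0.002             # CV-score improvement tolerance
DEFAULT_SHRINKAGE = 0.1
MAX_SELECTED = 16


# ---------------------------------------------------------------------------
# Labeling


def label_epochs(epoch_starts: np.ndarray, epoch_length: float,
                 events: np.ndarray, horizon: float = DEFAULT_HORIZON,
                 postictal_exclusion: float = DEFAULT_POSTICTAL_EXCLUSION,
                 span: float | None = None) -> np.ndarray:
    """Label each epoch; exclusion (ictal/post-ictal) takes precedence.

    An epoch ``[s, s+L)`` is pre-ictal if it lies fully inside ``[onset -
    horizon, onset]`` for some onset (a 30-min horizon at 13.8-s epochs
    yields floor(1800/13.8) = 130 pre-ictal epochs before the onset epoch),
    and excluded if it intersects ``[onset, onset + postictal_exclusion)``;
    otherwise interictal.  Overlapping windows merge naturally.  Events
    outside the record span are ignored with a warning.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    starts = np.asarray(epoch_starts, dtype=float)
    labels = np.full(len(starts), INTERICTAL, dtype=int)
    if span is None:
        span = float(starts[-1] + epoch_length) if len(starts) else 0.0
    events = np.asarray(events, dtype=float)
    inside = (events >= 0) & (events < span)
    if np.any(~inside):
        warnings.warn(f"{int((~inside).sum())} event(s) outside the record "
                      "span ignored")
        events = events[inside]
    ends = starts + epoch_length
    for onset in events:
        pre = (starts >= onset - horizon) & (ends <= onset)
        labels[pre & (labels == INTERICTAL)] = PREICTAL
    for onset in events:
        exc = (starts < onset + postictal_exclusion) & (ends > onset)
        labels[exc] = EXCLUDED
    return labels


@dataclass
class LabeledDataset:
    values: np.ndarray            # (n_epochs, n_features); catalog order
    labels: np.ndarray            # INTERICTAL / PREICTAL / EXCLUDED
    feature_ids: np.ndarray       # column -> catalog feature id
    epoch_starts: np.ndarray
    epoch_length: float
    horizon: float = DEFAULT_HORIZON
    postictal_exclusion: float = DEFAULT_POSTICTAL_EXCLUSION

    def __post_init__(self) -> None:
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must align one-to-one with epochs")

    @property
    def usable_mask(self) -> np.ndarray:
        return self.labels != EXCLUDED

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()[:16]


def make_dataset(matrix, events: np.ndarray,
                 horizon: float = DEFAULT_HORIZON,
                 postictal_exclusion: float = DEFAULT_POSTICTAL_EXCLUSION,
                 feature_ids: np.ndarray | None = None) -> LabeledDataset:
    """Label a FeatureMatrix; unusable epochs are excluded from training."""
    labels = label_epochs(matrix.epoch_starts, matrix.epoch_length, events,
                          horizon, postictal_exclusion)
    labels = np.where(matrix.usable, labels, EXCLUDED)
    if feature_ids is None:
        feature_ids = np.array([e.id for e in matrix.catalog.entries])
        values = matrix.values
    else:
        all_ids = np.array([e.id for e in matrix.catalog.entries])
        cols = np.searchsorted(all_ids, feature_ids)
        values = matrix.values[:, cols]
    return LabeledDataset(values=values, labels=labels,
                          feature_ids=np.asarray(feature_ids),
                          epoch_starts=matrix.epoch_starts,
                          epoch_length=matrix.epoch_length,
                          horizon=horizon,
                          postictal_exclusion=postictal_exclusion)


# ---------------------------------------------------------------------------
# Folds


def blockwise_folds(n_epochs: int, k: int = 10) -> np.ndarray:
    """k contiguous, disjoint, exhaustive time blocks; sizes differ by <= 1.

    The earliest blocks absorb the remainder.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_epochs < k:
        raise ValueError(f"cannot split {n_epochs} epochs into {k} blocks")
    base, rem = divmod(n_epochs, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    return np.repeat(np.arange(k), sizes)


# ---------------------------------------------------------------------------
# Closed-form shrinkage LDA over candidate subsets


class _FoldStats:
    """Leave-one-block-out class means and pooled covariance by subtraction."""

    def __init__(self, X: np.ndarray, y: np.ndarray, folds: np.ndarray):
        self.k = int(folds.max()) + 1
        p = X.shape[1]
        self.p = p
        self.block_n = np.zeros((self.k, 2))
        self.block_sum = np.zeros((self.k, 2, p))
        self.block_ss = np.zeros((self.k, 2, p, p))
        for b in range(self.k):
            for c in (0, 1):
                Xb = X[(folds == b) & (y == c)]
                self.block_n[b, c] = len(Xb)
                if len(Xb):
                    self.block_sum[b, c] = Xb.sum(axis=0)
                    self.block_ss[b, c] = Xb.T @ Xb
        self.tot_n = self.block_n.sum(axis=0)
        self.tot_sum = self.block_sum.sum(axis=0)
        self.tot_ss = self.block_ss.sum(axis=0)

    def train_stats(self, b: int):
        """(n_c, mu_c, pooled covariance) for training data excluding block b."""
        n = self.tot_n - self.block_n[b]
        if np.any(n < 1):
            return None
        s = self.tot_sum - self.block_sum[b]
        ss = self.tot_ss - self.block_ss[b]
        mu = s / n[:, None]
        scatter = sum(ss[c] - np.outer(mu[c], s[c]) for c in (0, 1))
        cov = scatter / max(n.sum() - 2, 1)
        return n, mu, cov


def _regularize(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    p = cov.shape[0]
    return (1 - shrinkage) * cov + shrinkage * (np.trace(cov) / p) * np.eye(p)


def _balanced_accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    pred = scores > 0
    pos = y == 1
    if pos.all() or (~pos).all():
        return np.nan
    tpr = pred[pos].mean()
    tnr = (~pred[~pos]).mean()
    return 0.5 * (tpr + tnr)


def _cv_scores_for_candidates(X, y, folds, stats: _FoldStats,
                              selected: list[int], candidates: np.ndarray,
                              shrinkage: float) -> np.ndarray:
    """Mean CV balanced accuracy of LDA on selected+[j] for each candidate j.

    Folds whose training union misses a class are skipped with a warning;
    a candidate column equal to one already selected scores nan.
    """
    scores = np.zeros((len(candidates),))
    counts = np.zeros(len(candidates))
    skipped = 0
    for b in range(stats.k):
        tr = stats.train_stats(b)
        if tr is None:
            skipped += 1
            continue
        n, mu, cov = tr
        test = folds == b
        yt = y[test]
        if yt.size == 0 or (yt == 1).all() or (yt == 0).all():
            skipped += 1
            continue
        Xt = X[test]
        for ji, j in enumerate(candidates):
            A = selected + [int(j)]
            covA = _regularize(cov[np.ix_(A, A)], shrinkage)
            d = mu[1, A] - mu[0, A]
            try:
                w = np.linalg.solve(covA, d)
            except np.linalg.LinAlgError:
                scores[ji] = np.nan
                continue
            c = w @ (mu[0, A] + mu[1, A]) / 2.0
            bacc = _balanced_accuracy(Xt[:, A] @ w - c, yt)
            if not np.isnan(bacc):
                scores[ji] += bacc
                counts[ji] += 1
    if skipped == stats.k:
        raise ValueError("every fold misses a class; cannot cross-validate")
    if skipped:
        warnings.warn(f"{skipped} fold(s) skipped (class missing)")
    with np.errstate(invalid="ignore"):
        return scores / np.where(counts > 0, counts, np.nan)


def _cv_score_for_subsets(X, y, folds, stats, subsets, shrinkage) -> np.ndarray:
    """Mean CV balanced accuracy for each explicit column subset."""
    out = np.zeros(len(subsets))
    counts = np.zeros(len(subsets))
    for b in range(stats.k):
        tr = stats.train_stats(b)
        if tr is None:
            continue
        n, mu, cov = tr
        test = folds == b
        yt = y[test]
        if yt.size == 0 or (yt == 1).all() or (yt == 0).all():
            continue
        Xt = X[test]
        for si, A in enumerate(subsets):
            A = list(A)
            covA = _regularize(cov[np.ix_(A, A)], shrinkage)
            w = np.linalg.solve(covA, mu[1, A] - mu[0, A])
            c = w @ (mu[0, A] + mu[1, A]) / 2.0
            bacc = _balanced_accuracy(Xt[:, A] @ w - c, yt)
            if not np.isnan(bacc):
                out[si] += bacc
                counts[si] += 1
    with np.errstate(invalid="ignore"):
        return out / np.where(counts > 0, counts, np.nan)


# ---------------------------------------------------------------------------
# Selection


@dataclass
class SelectionResult:
    feature_ids: list[int]            # catalog ids, in selection order
    step_scores: list[float]          # CV score after each accepted step
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.feature_ids) > MAX_SELECTED:
            raise ValueError(f"selection exceeds {MAX_SELECTED} features")


def _training_arrays(dataset: LabeledDataset, folds: np.ndarray):
    mask = dataset.usable_mask
    X = dataset.values[mask]
    y = (dataset.labels[mask] == PREICTAL).astype(int)
    f = folds[mask]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("dataset must contain both classes")
    return X, y, f


def forward_select(dataset: LabeledDataset, folds: np.ndarray,
                   max_size: int = MAX_SELECTED,
                   tolerance: float = DEFAULT_TOLERANCE,
                   shrinkage: float = DEFAULT_SHRINKAGE) -> SelectionResult:
    """Greedy forward selection under block-wise CV balanced accuracy.

    The first feature is always accepted (the result is never empty);
    afterwards a step must improve the score by more than ``tolerance``.
    Ties go to the lowest feature id.
    """
    max_size = min(max_size, MAX_SELECTED)
    X, y, f = _training_arrays(dataset, folds)
    stats = _FoldStats(X, y, f)
    ids = dataset.feature_ids
    selected: list[int] = []
    scores: list[float] = []
    log: list[str] = []
    current = 0.5
    remaining = list(range(X.shape[1]))
    while remaining and len(selected) < max_size:
        cand = np.array(remaining)
        cs = _cv_scores_for_candidates(X, y, f, stats, selected, cand, shrinkage)
        cs = np.where(np.isnan(cs), -np.inf, cs)
        best = int(cand[np.argmax(cs)])        # argmax -> first, lowest id
        best_score = float(np.max(cs))
        if selected and best_score - current <= tolerance:
            log.append(f"stop: best addition f{ids[best]} improves by "
                       f"{best_score - current:+.4f} <= tol")
            break
        selected.append(best)
        remaining.remove(best)
        current = max(current, best_score) if selected[:-1] else best_score
        scores.append(current)
        log.append(f"add f{ids[best]} -> CV score {current:.4f}")
    return SelectionResult(feature_ids=[int(ids[j]) for j in selected],
                           step_scores=scores, log=log)


def backward_eliminate(selection: SelectionResult, dataset: LabeledDataset,
                       folds: np.ndarray,
                       tolerance: float = DEFAULT_TOLERANCE,
                       shrinkage: float = DEFAULT_SHRINKAGE) -> SelectionResult:
    """Drop features whose removal does not cost more than ``tolerance``.

    At least one feature is always retained.  Among removals with equal
    scores the highest feature id is dropped (keeps the lowest ids).
    """
    if not selection.feature_ids:
        raise ValueError("selection must be non-empty")
    X, y, f = _training_arrays(dataset, folds)
    stats = _FoldStats(X, y, f)
    id_to_col = {int(fid): i for i, fid in enumerate(dataset.feature_ids)}
    current_ids = list(selection.feature_ids)
    cols = [id_to_col[i] for i in current_ids]
    current = float(_cv_score_for_subsets(X, y, f, stats, [cols], shrinkage)[0])
    log = list(selection.log)
    scores = list(selection.step_scores)
    while len(current_ids) > 1:
        subsets = [[c for j, c in enumerate(cols) if j != i]
                   for i in range(len(cols))]
        sub_scores = _cv_score_for_subsets(X, y, f, stats, subsets, shrinkage)
        order = sorted(range(len(cols)),
                       key=lambda i: (-sub_scores[i], -current_ids[i]))
        i = order[0]
        if current - sub_scores[i] > tolerance:
            log.append("stop elimination: every removal costs more than tol")
            break
        log.append(f"drop f{current_ids[i]} -> CV score {sub_scores[i]:.4f}")
        current = float(sub_scores[i])
        del current_ids[i], cols[i]
        scores.append(current)
    return SelectionResult(feature_ids=current_ids, step_scores=scores, log=log)


# ---------------------------------------------------------------------------
# Classifier


@dataclass
class PatientAlgorithm:
    """Selected features + linear discriminant + advisory thresholds."""

    selection: SelectionResult
    coef: np.ndarray
    intercept: float
    theta_high: float
    theta_low: float
    shrinkage: float
    fingerprint: str
    version: int = 1
    red_target: float = 0.25      # time-fraction targets behind the thresholds
    blue_target: float = 0.45
    red_hold: int = 0             # epochs a raised warning persists

    def __post_init__(self) -> None:
        if not self.theta_high > self.theta_low:
            raise ValueError("theta_high must exceed theta_low")

    def likelihood(self, dataset: LabeledDataset) -> np.ndarray:
        """Seizure likelihood in [0, 1] for every epoch of the dataset."""
        cols = _columns_for(dataset, self.selection.feature_ids)
        z = dataset.values[:, cols] @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def to_json(self) -> str:
        return json.dumps({
            "feature_ids": self.selection.feature_ids,
            "step_scores": self.selection.step_scores,
            "coef": list(map(float, self.coef)),
            "intercept": self.intercept,
            "theta_high": self.theta_high,
            "theta_low": self.theta_low,
            "shrinkage": self.shrinkage,
            "fingerprint": self.fingerprint,
            "version": self.version,
            "red_target": self.red_target,
            "blue_target": self.blue_target,
            "red_hold": self.red_hold,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PatientAlgorithm":
        d = json.loads(text)
        sel = SelectionResult(feature_ids=d["feature_ids"],
                              step_scores=d["step_scores"])
        return cls(selection=sel, coef=np.array(d["coef"]),
                   intercept=d["intercept"], theta_high=d["theta_high"],
                   theta_low=d["theta_low"], shrinkage=d["shrinkage"],
                   fingerprint=d["fingerprint"], version=d["version"],
                   red_target=d["red_target"], blue_target=d["blue_target"],
                   red_hold=d.get("red_hold", 0))


def _columns_for(dataset: LabeledDataset, feature_ids: list[int]) -> list[int]:
    id_to_col = {int(fid): i for i, fid in enumerate(dataset.feature_ids)}
    return [id_to_col[i] for i in feature_ids]


def _fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    model.fit(X, y)
    return model


def _held_red_fraction(lik: np.ndarray, theta: float, red_hold: int) -> float:
    from .advisory import hold_red_mask

    return float(hold_red_mask(lik >= theta, red_hold).mean())


def _calibrate_theta_high(lik: np.ndarray, red_target: float,
                          red_hold: int) -> float:
    """Threshold whose *held* red time fraction is closest to red_target.

    With ``red_hold`` epochs of warning persistence the fraction of red
    time exceeds the fraction of supra-threshold epochs, so the per-epoch
    quantile level is found by bisection on the held fraction.
    """
    if red_hold <= 0:
        return float(np.quantile(lik, 1.0 - red_target))
    lo, hi = 0.0, red_target        # per-epoch crossing-rate bracket
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        theta = float(np.quantile(lik, 1.0 - mid))
        if _held_red_fraction(lik, theta, red_hold) > red_target:
            hi = mid
        else:
            lo = mid
    return float(np.quantile(lik, 1.0 - 0.5 * (lo + hi)))


def train_classifier(dataset: LabeledDataset, selection: SelectionResult,
                     shrinkage: float = DEFAULT_SHRINKAGE,
                     red_target: float = 0.25,
                     blue_target: float = 0.45,
                     red_hold: int = 0,
                     version: int = 1) -> PatientAlgorithm:
    """Fit the shrinkage LDA on the selected features.

    Likelihood thresholds are set from the training-set score distribution
    so that about ``red_target`` of the time is spent red (accounting for
    ``red_hold`` epochs of warning persistence) and about ``blue_target``
    of the scores fall below theta_low.
    """
    if not selection.feature_ids:
        raise ValueError("selection must be non-empty")
    cols = _columns_for(dataset, selection.feature_ids)
    mask = dataset.usable_mask
    X = dataset.values[np.ix_(mask, cols)]
    y = (dataset.labels[mask] == PREICTAL).astype(int)
    if (y == 1).sum() == 0:
        raise ValueError("no pre-ictal epochs in training data")
    if (y == 0).sum() == 0:
        raise ValueError("no interictal epochs in training data")
    model = _fit_lda(X, y, shrinkage)
    coef = model.coef_.ravel()
    intercept = float(model.intercept_[0])
    z = X @ coef + intercept
    lik = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    theta_high = _calibrate_theta_high(lik, red_target, red_hold)
    theta_low = float(np.quantile(lik, blue_target))
    if not theta_high > theta_low:                       # degenerate spread
        eps = 1e-9
        theta_high = theta_low + eps
        warnings.warn("degenerate likelihood spread; thresholds floored")
    return PatientAlgorithm(selection=selection, coef=coef,
                            intercept=intercept, theta_high=theta_high,
                            theta_low=theta_low, shrinkage=shrinkage,
                            fingerprint=dataset.fingerprint(),
                            version=version, red_target=red_target,
                            blue_target=blue_target, red_hold=red_hold)


def cross_validated_likelihood(dataset: LabeledDataset, folds: np.ndarray,
                               selection: SelectionResult,
                               shrinkage: float = DEFAULT_SHRINKAGE,
                               ) -> np.ndarray:
    """Out-of-fold likelihood: each epoch scored by a model trained on the
    other blocks.  Excluded epochs are scored too (prediction needs no
    label); blocks whose complement misses a class fall back to 0.5."""
    cols = _columns_for(dataset, selection.feature_ids)
    lik = np.full(len(dataset.labels), 0.5)
    mask = dataset.usable_mask
    y_all = (dataset.labels == PREICTAL).astype(int)
    for b in np.unique(folds):
        train = mask & (folds != b)
        ytr = y_all[train]
        if (ytr == 1).sum() == 0 or (ytr == 0).sum() == 0:
            warnings.warn(f"fold {b}: training complement misses a class")
            continue
        model = _fit_lda(dataset.values[np.ix_(train, cols)], ytr, shrinkage)
        test = folds == b
        z = dataset.values[np.ix_(test, cols)] @ model.coef_.ravel() \
            + float(model.intercept_[0])
        lik[test] = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return lik


def develop_algorithm(dataset: LabeledDataset, k_folds: int = 10,
                      max_size: int = MAX_SELECTED,
                      tolerance: float = DEFAULT_TOLERANCE,
                      shrinkage: float = DEFAULT_SHRINKAGE,
                      red_target: float = 0.25, blue_target: float = 0.45,
                      red_hold: int = 0, version: int = 1,
                      ) -> tuple[PatientAlgorithm, np.ndarray]:
    """Selection + fit + out-of-fold likelihood series, in one call."""
    folds = blockwise_folds(len(dataset.labels), k_folds)
    sel = forward_select(dataset, folds, max_size, tolerance, shrinkage)
    sel = backward_eliminate(sel, dataset, folds, tolerance, shrinkage)
    algo = train_classifier(dataset, sel, shrinkage, red_target, blue_target,
                            red_hold=red_hold, version=version)
    oof = cross_validated_likelihood(dataset, folds, sel, shrinkage)
    return algo, oof


def retrain(algorithm: PatientAlgorithm, new_dataset: LabeledDataset,
            k_folds: int = 10, max_size: int = MAX_SELECTED,
            tolerance: float = DEFAULT_TOLERANCE) -> PatientAlgorithm:
    """Re-run selection and fitting on a new window; version increments.

    The old and new selections are diffed in the new selection log.
    """
    if new_dataset.values.size == 0:
        raise ValueError("new dataset is empty")
    folds = blockwise_folds(len(new_dataset.labels), k_folds)
    sel = forward_select(new_dataset, folds, max_size, tolerance,
                         algorithm.shrinkage)
    sel = backward_eliminate(sel, new_dataset, folds, tolerance,
                             algorithm.shrinkage)
    old = set(algorithm.selection.feature_ids)
    new = set(sel.feature_ids)
    sel.log.append(f"retrain diff: kept {sorted(old & new)}, "
                   f"dropped {sorted(old - new)}, added {sorted(new - old)}")
    return train_classifier(new_dataset, sel, algorithm.shrinkage,
                            algorithm.red_target, algorithm.blue_target,
                            red_hold=algorithm.red_hold,
                            version=algorithm.version + 1)
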