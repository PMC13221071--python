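"""Population decoding of behavioral stage and learning block.

Each labelled epoch is cut into consecutive non-overlapping 400-ms windows;
within a window, every neuron's spikes are counted in 20-ms bins and
converted to rates, giving a feature vector of length n_neurons x 20 per
sample.  Classes are balanced by random subsampling to the smallest class,
features are z-scored with training-fold statistics only, and a Gaussian
naive Bayes classifier is evaluated with leave-one-trial-out
cross-validation, so no window of a held-out trial ever appears in training.
Held-out class posteriors are pooled over folds and summarized as the
micro-average ROC-AUC of the flattened one-hot label / posterior matrices
(chance 0.5 for the four-class problems used here).

The fixed-N replacement control holds the decoding population size constant
while a fraction of one region's neurons is swapped for neurons of the other
region (n = 200 resamples per fraction), separating the effect of mixing
regional codes from that of simply adding neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Session

WINDOW_S = 0.4
BIN_S = 0.02
N_BINS = int(round(WINDOW_S / BIN_S))
N_RESAMPLES = 200

STAGE_CLASSES = ("Navigation1", "Goal1", "Navigation2", "Goal2")


@dataclass
class DecodingSamples:
    """Samples as (n_samples, n_units, 20) rate tensors plus labels and trials."""

    features: np.ndarray
    labels: np.ndarray
    trials: np.ndarray
    unit_ids: list[str]
    unit_regions: list[str]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def matrix(self, unit_idx: np.ndarray | None = None) -> np.ndarray:
        """Flattened (n_samples, n_selected_units * 20) feature matrix."""
        feats = self.features if unit_idx is None else self.features[:, unit_idx, :]
        return feats.reshape(self.n_samples, -1)


def _window_features(
    units_spikes: list[np.ndarray], start: float, n_windows: int
) -> np.ndarray:
    """Rates (n_windows, n_units, 20) for consecutive 400-ms windows."""
    edges = start + BIN_S * np.arange(n_windows * N_BINS + 1)
    out = np.empty((n_windows, len(units_spikes), N_BINS))
    for ui, st in enumerate(units_spikes):
        counts = np.diff(np.searchsorted(st, edges))
        out[:, ui, :] = counts.reshape(n_windows, N_BINS) / BIN_S
    return out


def build_samples(
    session: Session,
    task: str,
    rng: np.random.Generator,
    balance: bool = True,
) -> DecodingSamples:
    """Windowed, labelled, class-balanced samples for one decoding task.

    ``task`` is ``stage`` (four stage classes, final learning block only),
    ``block_goal`` or ``block_nav`` (four block classes from Goal-only or
    Navigation-only epochs).  Windows that do not fit wholly inside an epoch
    are dropped.
    """
    if session.epochs is None:
        raise ValueError("session has no segmented epochs")
    if task not in ("stage", "block_goal", "block_nav"):
        raise ValueError(f"unknown task {task!r}")

    spikes = [u.spike_times for u in session.units]
    final_block = max(ep.block for ep in session.epochs)
    feats, labels, trials = [], [], []
    for ep in session.epochs:
        if task == "stage":
            if ep.block != final_block:
                continue
            label = ep.label
        elif task == "block_goal":
            if not ep.label.startswith("Goal"):
                continue
            label = f"Block{ep.block}"
        else:
            if not ep.label.startswith("Navigation"):
                continue
            label = f"Block{ep.block}"
        n_win = int((ep.end_s - ep.start_s) / WINDOW_S)
        if n_win < 1:
            continue
        feats.append(_window_features(spikes, ep.start_s, n_win))
        labels.extend([label] * n_win)
        trials.extend([ep.trial] * n_win)

    if not feats:
        raise ValueError(f"no samples for task {task!r}")
    features = np.concatenate(feats, axis=0)
    labels = np.asarray(labels)
    trials = np.asarray(trials)

    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"task {task!r}: only one class present")
    if balance:
        n_min = counts.min()
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(labels == c), size=n_min, replace=False) for c in classes]
        )
        keep.sort()
        features, labels, trials = features[keep], labels[keep], trials[keep]

    return DecodingSamples(
        features,
        labels,
        trials,
        [u.unit_id for u in session.units],
        [u.region for u in session.units],
    )


def loto_cv(trials: np.ndarray):
    """Leave-one-trial-out folds as (train_mask, test_mask) pairs."""
    distinct = np.unique(trials)
    if distinct.size < 2:
        raise ValueError("leave-one-trial-out needs at least 2 trials")
    for trial in distinct:
        test = trials == trial
        yield ~test, test


def gnb_fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    var_floor: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Train-fold z-scoring plus Gaussian naive Bayes posteriors.

    Returns (posterior matrix for x_test, class order).  Feature standard
    deviations of zero are floored so constant features stay uninformative
    rather than degenerate.
    """
    from sklearn.naive_bayes import GaussianNB

    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd < var_floor, 1.0, sd)
    clf = GaussianNB()
    clf.fit((x_train - mu) / sd, y_train)
    return clf.predict_proba((x_test - mu) / sd), clf.classes_


def micro_roc_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Micro-average ROC-AUC of flattened one-hot labels vs posteriors."""
    from sklearn.metrics import roc_auc_score

    onehot = (np.asarray(y_true)[:, None] == np.asarray(classes)[None, :]).astype(int)
    if onehot.sum(axis=0).min() == onehot.shape[0] or len(np.unique(y_true)) < 2:
        raise ValueError("micro ROC-AUC undefined with a single class")
    return float(roc_auc_score(onehot.ravel(), proba.ravel()))


def decode(samples: DecodingSamples, unit_idx: np.ndarray | None = None) -> float:
    """Full leave-one-trial-out decode; pooled held-out micro ROC-AUC."""
    x = samples.matrix(unit_idx)
    y = samples.labels
    classes = np.unique(y)
    proba = np.zeros((samples.n_samples, classes.size))
    for train, test in loto_cv(samples.trials):
        if np.unique(y[train]).size < classes.size:
            # a fold missing a class cannot score it; posteriors stay 0 there
            pass
        p, fold_classes = gnb_fit_predict(x[train], y[train], x[test])
        col = np.searchsorted(classes, fold_classes)
        proba[np.ix_(np.flatnonzero(test), col)] = p
    return micro_roc_auc(y, proba, classes)


def fixed_n_replacement(
    samples: DecodingSamples,
    source_region: str,
    donor_region: str,
    fraction: float,
    rng: np.random.Generator,
    n_resamples: int = N_RESAMPLES,
) -> float:
    """Mean AUC over resampled mixed populations of fixed size.

    Starts from all ``source_region`` neurons and replaces
    floor(fraction * N) of them, chosen at random, with randomly chosen
    ``donor_region`` neurons; the population size never changes.  With
    fraction 0 this is exactly the single-region decode.
    """
    regions = np.asarray(samples.unit_regions)
    source_idx = np.flatnonzero(regions == source_region)
    donor_idx = np.flatnonzero(regions == donor_region)
    n = source_idx.size
    k = int(np.floor(fraction * n))
    if k == 0:
        return decode(samples, source_idx)
    if k > donor_idx.size:
        raise ValueError(
            f"fraction {fraction} needs {k} donor neurons, only {donor_idx.size} available"
        )
    aucs = []
    for _ in range(n_resamples):
        drop = rng.choice(n, size=k, replace=False)
        keep = np.delete(source_idx, drop)
        donors = rng.choice(donor_idx, size=k, replace=False)
        pop = np.concatenate([keep, donors])
        assert pop.size == n  # fixed-N contract
        aucs.append(decode(samples, pop))
    return float(np.mean(aucs))
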