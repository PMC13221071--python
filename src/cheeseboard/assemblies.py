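"""Cell-assembly detection by Marchenko-Pastur-thresholded PCA plus ICA.

Spike trains are binned at 20 ms (ripple periods and the following 100 ms
excluded) and z-scored per neuron.  The number of co-activation patterns is
the number of eigenvalues of the neuron-by-neuron correlation matrix that
exceed the Marchenko-Pastur upper edge (1 + sqrt(n/T))^2 - the largest
eigenvalue expected from independent unit-variance neurons.  FastICA run in
the significant principal subspace yields one weight vector per pattern
(unit length, sign fixed so the largest-magnitude weight is positive).

Pattern expression over time is the quadratic form S_i(t) = z(t)' P_i z(t)
with P_i the outer product of the weight vector with its main diagonal set to
zero, so a single neuron spiking alone contributes nothing.  Activation
events are local peaks of S_i exceeding 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

ASSEMBLY_BIN_S = 0.02
EVENT_THRESHOLD = 5.0
SWR_PAD_S = 0.1


@dataclass
class AssemblyPattern:
    weights: np.ndarray  # unit-length over neurons
    activation: np.ndarray | None = None
    events: np.ndarray | None = None

    @property
    def projection(self) -> np.ndarray:
        p = np.outer(self.weights, self.weights)
        np.fill_diagonal(p, 0.0)
        return p


def bin_and_zscore(
    spike_times_by_neuron: list[np.ndarray],
    t0: float,
    t1: float,
    bin_s: float = ASSEMBLY_BIN_S,
    swr_intervals: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-scored 20-ms binned counts; SWR-contaminated bins removed.

    A bin is dropped when it intersects a detected ripple event or the 100 ms
    that follows it.  Neurons with zero count variance over the kept bins are
    dropped with a warning.  Returns (z, kept_bin_indices, kept_neuron_indices)
    where z is (n_neurons x n_bins).
    """
    edges = np.arange(t0, t1 + bin_s / 2, bin_s)
    n_bins = edges.size - 1
    counts = np.stack(
        [np.histogram(np.asarray(st, float), bins=edges)[0] for st in spike_times_by_neuron]
    ).astype(float)

    keep = np.ones(n_bins, dtype=bool)
    if swr_intervals:
        for a, b in swr_intervals:
            lo = np.searchsorted(edges, a, side="right") - 1
            hi = np.searchsorted(edges, b + SWR_PAD_S, side="left")
            keep[max(lo, 0) : min(hi, n_bins)] = False
    counts = counts[:, keep]
    if counts.shape[1] < 100:
        raise ValueError("fewer than 100 usable bins after SWR exclusion")

    sd = counts.std(axis=1)
    neuron_keep = sd > 0
    if not neuron_keep.all():
        warnings.warn(
            f"dropping {int((~neuron_keep).sum())} zero-variance neurons from assembly analysis"
        )
    counts = counts[neuron_keep]
    z = (counts - counts.mean(axis=1, keepdims=True)) / counts.std(axis=1, keepdims=True)
    return z, np.flatnonzero(keep), np.flatnonzero(neuron_keep)


def marchenko_pastur_threshold(n_neurons: int, n_bins: int) -> float:
    """Upper edge (1 + sqrt(n/T))^2 of the eigenvalue spectrum of noise."""
    return (1.0 + np.sqrt(n_neurons / n_bins)) ** 2


def mp_significant_components(z: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """Eigenvalues above the Marchenko-Pastur edge and their eigenvectors.

    Returns (count, eigenvalues descending, eigenvectors as columns aligned
    with the eigenvalues).
    """
    n, t = z.shape
    corr = np.corrcoef(z)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix (constant neuron?)")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_sig = int(np.sum(evals > marchenko_pastur_threshold(n, t)))
    return n_sig, evals, evecs


def extract_assemblies(
    z: np.ndarray, n_components: int, seed: int = 0, max_retries: int = 3
) -> list[AssemblyPattern]:
    """ICA weight vectors for the significant co-activation patterns.

    FastICA runs on the data projected into the significant principal
    subspace; each resulting direction is mapped back to neuron space,
    normalized to unit length, and sign-fixed so its largest-magnitude weight
    is positive.  Non-convergence retries with a new seed before raising.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if n_components == 0:
        return []
    _, _, evecs = mp_significant_components(z)
    v = evecs[:, :n_components]  # n_neurons x k
    projected = v.T @ z  # k x T

    last_err: Exception | None = None
    for attempt in range(max_retries):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                ica = FastICA(
                    n_components=n_components,
                    random_state=seed + attempt,
                    max_iter=1000,
                )
                ica.fit(projected.T)
            break
        except ConvergenceWarning as exc:  # retry with a fresh seed
            last_err = exc
    else:
        raise RuntimeError(f"FastICA failed to converge after {max_retries} seeds: {last_err}")

    # rows of the unmixing matrix define directions in the PCA subspace
    patterns = []
    for row in ica.components_:
        w = v @ row
        w = w / np.linalg.norm(w)
        if np.abs(w).max() > 0 and w[np.argmax(np.abs(w))] < 0:
            w = -w
        patterns.append(AssemblyPattern(weights=w))
    return patterns


def activation_strength(pattern: AssemblyPattern, z: np.ndarray) -> np.ndarray:
    """S_i(t) = z(t)' P_i z(t) per bin, with the zero-diagonal projector.

    Computed as (w.z)^2 - sum_j w_j^2 z_j^2, which equals the quadratic form
    with the diagonal removed.
    """
    w = pattern.weights
    wz = w @ z
    return wz**2 - (w**2) @ (z**2)


def activation_events(
    pattern: AssemblyPattern, z: np.ndarray, threshold: float = EVENT_THRESHOLD
) -> AssemblyPattern:
    """Mark activation events: local peaks of S_i above the threshold.

    A local peak is strictly greater than the preceding value and at least as
    large as the following one; on a plateau only its first bin counts.
    """
    s = activation_strength(pattern, z)
    if s.size < 3:
        events = np.empty(0, dtype=int)
    else:
        rising = s[1:-1] > s[:-2]
        not_falling_into = s[1:-1] >= s[2:]
        peaks = np.flatnonzero(rising & not_falling_into) + 1
        events = peaks[s[peaks] > threshold]
    pattern.activation = s
    pattern.events = events
    return pattern
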