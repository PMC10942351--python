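"""Trial-to-trial noise covariance, noise modes, and their geometry.

Within the visually-evoked (PLS) subspace, the noise covariance matrix C
is estimated per stimulus class from mean-subtracted trial features and
averaged across classes; its eigendecomposition C = sum_a lambda_a e_a
e_a^T yields the noise modes.  The angle of each mode to the optimal
decoding direction, cos(theta_a) = (w . e_a) / (|w| |e_a|), quantifies
whether trial-to-trial variability can limit stimulus decoding (0 deg =
maximally information-limiting, 90 deg = harmless).  Significant
contributors to a population vector are neurons whose |coefficient|
exceeds the shuffle mean by three shuffle standard deviations; behavioral
relevance of a mode is tested against a circular-shift null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encoding import PLSModel, TrialFeatures
from .errors import AnalysisError, ConfigurationError
from .preprocessing import ActivityMatrix

log = logging.getLogger("popnoise.geometry")


@dataclass
class NoiseGeometry:
    C: np.ndarray
    classes_used: np.ndarray
    eigvals: np.ndarray | None = None
    var_fractions: np.ndarray | None = None
    modes_latent: np.ndarray | None = None  # columns are eigenvectors e_a
    modes_neurons: np.ndarray | None = None  # loadings-mapped, unit columns
    angles_deg: np.ndarray | None = None


def noise_covariance(features: TrialFeatures, model: PLSModel, min_trials: int = 3) -> NoiseGeometry:
    """Mean within-class covariance of latent-space trial features.

    Features are projected into the PLS latent space, the per-class mean
    is subtracted, and the unbiased (n-1) covariance is computed per class
    and averaged (unweighted) across classes with at least ``min_trials``
    trials.
    """
    Z = model.project(features.X)
    covs, used = [], []
    for c in np.unique(features.labels):
        zc = Z[features.labels == c]
        if zc.shape[0] < min_trials:
            log.info("class %s has %d trials; excluded from the noise average", c, zc.shape[0])
            continue
        covs.append(np.cov(zc, rowvar=False, ddof=1))
        used.append(c)
    if not covs:
        raise AnalysisError("no stimulus class has enough trials for a noise covariance")
    C = np.mean(np.stack([np.atleast_2d(c) for c in covs]), axis=0)
    return NoiseGeometry(C=C, classes_used=np.asarray(used))


def noise_modes(geometry: NoiseGeometry, model: PLSModel | None = None) -> NoiseGeometry:
    """Eigendecomposition of C; eigenvalues descending, deterministic signs.

    Each eigenvector's sign is fixed by making its largest-magnitude entry
    positive.  If a PLS model is supplied, modes are also mapped to neuron
    space through the subspace loadings.
    """
    C = np.atleast_2d(geometry.C)
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    total = vals.sum()
    fractions = vals / total if total > 0 else np.full_like(vals, 1.0 / vals.size)
    modes_neurons = None
    if model is not None:
        # loadings are orthonormal, so this is the subspace direction of
        # each latent mode expressed over neurons
        mapped = model.loadings @ vecs
        norms = np.linalg.norm(mapped, axis=0)
        modes_neurons = mapped / np.where(norms > 0, norms, 1.0)
    return NoiseGeometry(
        C=geometry.C,
        classes_used=geometry.classes_used,
        eigvals=vals,
        var_fractions=fractions,
        modes_latent=vecs,
        modes_neurons=modes_neurons,
    )


def mode_angles(w_opt: np.ndarray, geometry: NoiseGeometry, space: str = "latent") -> np.ndarray:
    """Angle (degrees, folded to [0, 90]) between each noise mode and w_opt.

    ``space='latent'`` compares against the latent-space eigenvectors
    (pass ``model.w_opt_latent``); ``space='neurons'`` uses the
    loadings-mapped modes (pass ``model.w_opt``).  Folding reflects the
    arbitrary sign of eigenvectors.
    """
    w = np.asarray(w_opt, dtype=float)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise AnalysisError("w_opt is the zero vector")
    modes = geometry.modes_latent if space == "latent" else geometry.modes_neurons
    if modes is None:
        raise AnalysisError(f"geometry has no {space}-space modes; run noise_modes first")
    angles = []
    for j in range(modes.shape[1]):
        e = modes[:, j]
        ne = np.linalg.norm(e)
        if ne == 0:
            raise AnalysisError(f"noise mode {j} is the zero vector")
        cos = abs(float(w @ e) / (nw * ne))
        angles.append(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))
    return np.asarray(angles)


def shuffle_significance(coef_vector: np.ndarray, shuffled_coef_vectors) -> np.ndarray:
    """Neurons whose |coef| exceeds the shuffle mean + 3 shuffle SDs.

    With zero shuffle SD for a neuron, significance degenerates to
    |coef| > shuffle mean (warned).
    """
    w = np.abs(np.asarray(coef_vector, dtype=float))
    S = np.abs(np.asarray(list(shuffled_coef_vectors), dtype=float))
    if S.ndim != 2 or S.shape[0] < 2:
        raise ConfigurationError("need at least 2 shuffled coefficient vectors")
    mu = S.mean(axis=0)
    sd = S.std(axis=0, ddof=1)
    degenerate = sd == 0
    if np.any(degenerate):
        log.warning("%d neurons have zero shuffle SD; using mean-only rule", int(degenerate.sum()))
    return np.where(degenerate, w > mu, w > mu + 3.0 * sd)


def mode_behavior_correlation(
    mode_projection: np.ndarray,
    behavior_series: np.ndarray,
    n_shifts: int = 1000,
    seed: int = 0,
    rate_hz: float = 5.0,
    min_shift_s: float = 30.0,
):
    """Pearson r against a circular-shift null of the behavioral series.

    The null applies ``n_shifts`` random circular permutations (shift at
    least ``min_shift_s``) to the behavioral series, preserving its
    autocorrelation.  p = (1 + #{|null| >= |r|}) / (n_shifts + 1).
    """
    x = np.asarray(mode_projection, dtype=float)
    y = np.asarray(behavior_series, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("constant series: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    min_shift = max(1, int(round(min_shift_s * rate_hz)))
    if x.size <= 2 * min_shift:
        raise AnalysisError("series too short for the requested minimum circular shift")
    shifts = rng.integers(min_shift, x.size - min_shift, n_shifts)
    null = np.array([np.corrcoef(x, np.roll(y, int(s)))[0, 1] for s in shifts])
    p = (1.0 + np.sum(np.abs(null) >= abs(r))) / (n_shifts + 1.0)
    return r, null, float(p)


def whole_brain_pc1(activity: ActivityMatrix, vigor: np.ndarray | None = None):
    """First principal component of the neurons x time matrix.

    Returns (timeseries, loadings).  The sign is oriented so the
    timeseries correlates non-negatively with the tail vigor when
    supplied, otherwise so the largest-magnitude loading is positive.
    """
    X = activity.values - activity.values.mean(axis=1, keepdims=True)
    cov = (X @ X.T) / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    loadings = vecs[:, -1]
    series = loadings @ X
    if vigor is not None:
        v = np.asarray(vigor, dtype=float)[: series.size]
        if np.std(v) > 0 and np.corrcoef(series[: v.size], v)[0, 1] < 0:
            loadings, series = -loadings, -series
    elif loadings[np.argmax(np.abs(loadings))] < 0:
        loadings, series = -loadings, -series
    return series, loadings


def overlap_percentage(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """100 * |a AND b| / |a| (percentage of a's neurons also in b)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigurationError("masks must have equal length")
    na = int(a.sum())
    if na == 0:
        raise AnalysisError("reference mask is empty: overlap undefined")
    return 100.0 * int((a & b).sum()) / na
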