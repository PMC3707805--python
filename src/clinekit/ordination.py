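"""Classical multidimensional scaling with additive-constant correction,
Procrustes comparison with a permutation test (protest), and Gaussian-mixture
clustering of ordination coordinates with BIC model selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from sklearn.mixture import GaussianMixture

from .core import PairMatrix


@dataclass
class MDSResult:
    """Embedding of a distance matrix.

    ``eigenvalues`` is the full corrected spectrum (decreasing);
    ``constant_added`` is the Cailliez additive constant (0 when no
    correction was needed); ``variance_fractions`` are per-axis fractions of
    the positive spectrum.
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    constant_added: float
    variance_fractions: np.ndarray


def _double_centre(D2: np.ndarray) -> np.ndarray:
    row = D2.mean(axis=1)
    return -(D2 - row[:, None] - row[None, :] + D2.mean()) / 2.0


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant c making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    F1 = _double_centre(D * D)
    F2 = _double_centre(D)
    block = np.block(
        [[np.zeros((n, n)), 2.0 * F1], [-np.eye(n), -4.0 * F2]]
    )
    ev = np.linalg.eigvals(block)
    return float(max(0.0, np.max(ev.real)))


def classical_mds(D: PairMatrix, k: int = 2, correct: bool = True) -> MDSResult:
    """Classical (metric) MDS of a distance matrix.

    Eigendecomposes the double-centred squared distances. When ``correct``
    is set and negative eigenvalues are present, the Cailliez additive
    constant is added to the off-diagonal dissimilarities first so the
    corrected configuration is Euclidean.
    """
    if D.has_missing():
        raise ValueError(
            "distance matrix has missing cells; run QC / filter pairs first"
        )
    v = D.values.copy()
    constant = 0.0
    B = _double_centre(v * v)
    ev = np.linalg.eigvalsh(B)
    if correct and ev.min() < -1e-9 * max(1.0, abs(ev).max()):
        constant = cailliez_constant(v)
        v = v + constant
        np.fill_diagonal(v, 0.0)
        B = _double_centre(v * v)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    k = min(k, (pos > 0).sum() or 1)
    coords = evecs[:, :k] * np.sqrt(pos[:k])
    total = pos.sum()
    fractions = pos[:k] / total if total > 0 else np.zeros(k)
    return MDSResult(
        labels=list(D.labels),
        coordinates=coords,
        eigenvalues=evals,
        constant_added=constant,
        variance_fractions=fractions,
    )


@dataclass
class ProcrustesResult:
    r: float
    p_value: float
    n_permutations: int
    m2: float  # minimized symmetric Procrustes residual


def _procrustes_r(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Procrustes correlation (reflections allowed)."""
    _, _, m2 = _scipy_procrustes(X, Y)
    return float(np.sqrt(max(0.0, 1.0 - m2)))


def procrustes_protest(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes rotation with a row-permutation test.

    Both configurations are centred and scaled to unit sum of squares;
    ``r = sqrt(1 - m^2)``. The p-value permutes the rows of ``Y`` and is
    ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if X.shape[0] < X.shape[1] or Y.shape[0] < Y.shape[1]:
        raise ValueError("fewer rows than columns")
    r_obs = _procrustes_r(X, Y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        if _procrustes_r(X, Y[perm]) >= r_obs - 1e-12:
            exceed += 1
    m2 = 1.0 - r_obs**2
    return ProcrustesResult(
        r=r_obs, p_value=(1 + exceed) / (n_perm + 1), n_permutations=n_perm, m2=m2
    )


@dataclass
class GMMClusterResult:
    labels: np.ndarray
    k: int
    covariance_type: str
    bic: float
    bic_table: dict  # (k, covariance_type) -> BIC


def gmm_cluster(
    coords: np.ndarray,
    k_range=range(1, 7),
    seed: int = 0,
    covariance_types=("full", "tied", "diag", "spherical"),
) -> GMMClusterResult:
    """Gaussian-mixture clustering with BIC model selection.

    Fits every (k, covariance parameterization) combination and returns the
    hard assignment of the best-BIC model.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if max(k_range) > coords.shape[0]:
        raise ValueError("k_range exceeds the number of observations")
    best = None
    table = {}
    for k in k_range:
        for ct in covariance_types:
            gmm = GaussianMixture(
                n_components=k,
                covariance_type=ct,
                random_state=seed,
                n_init=3,
                reg_covar=1e-9,
            ).fit(coords)
            bic = gmm.bic(coords)
            table[(k, ct)] = bic
            if best is None or bic < best[0]:
                best = (bic, k, ct, gmm)
    bic, k, ct, gmm = best
    return GMMClusterResult(
        labels=gmm.predict(coords), k=k, covariance_type=ct, bic=bic, bic_table=table
    )
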