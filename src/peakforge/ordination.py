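"""Count normalization and sample ordination (non-metric MDS, PCA).

Raw counts are normalized as log2(count / library size * 1e8 + 1)
before a Manhattan distance matrix is built between samples. The
non-metric MDS follows Kruskal: a configuration is sought whose
inter-point distances are, as nearly as possible, a monotone function
of the input dissimilarities; fit quality is Kruskal stress-1,

    stress = sqrt( sum_(i<j) (D_ij - dhat_ij)^2 / sum_(i<j) D_ij^2 )

where D are configuration distances and dhat the isotonic (monotone)
regression of D on the input dissimilarity order. The configuration is
initialized from classical (Torgerson) scaling and improved by
alternating the isotonic fit with a Guttman-transform update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.isotonic import IsotonicRegression

from .intervals import CountMatrix

__all__ = [
    "normalize_counts",
    "manhattan_distance",
    "nmds",
    "NMDSResult",
    "pca",
    "PCAResult",
]


def normalize_counts(m: CountMatrix, scale: float = 1.0e8) -> pd.DataFrame:
    """log2(raw / library size * scale + 1), elementwise.

    Monotone in the raw count and zero for a zero count; library sizes
    must be positive (enforced by :class:`CountMatrix`).
    """
    if (m.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    frac = m.counts.div(m.library_sizes, axis="columns")
    return np.log2(frac * scale + 1.0)


def manhattan_distance(normalized: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Manhattan (city-block) distance over features."""
    if normalized.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = normalized.to_numpy().T  # samples x features
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=normalized.columns, columns=normalized.columns)


# ---------------------------------------------------------------------------
# Non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coordinates: np.ndarray  # samples x k
    stress: float
    stress_history: list[float]
    n_iterations: int
    converged: bool
    sample_ids: list | None = None

    def frame(self) -> pd.DataFrame:
        cols = [f"MDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(config_d: np.ndarray, disparities: np.ndarray) -> float:
    denom = (config_d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((config_d - disparities) ** 2).sum() / denom))


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NMDSResult:
    """Kruskal non-metric MDS of a dissimilarity matrix.

    Starts from the classical-scaling configuration (with a tiny seeded
    jitter only if that configuration is degenerate) and alternates
    isotonic regression of configuration distances on the dissimilarity
    order with Guttman-transform updates until the stress-1 decrease
    falls below ``tol``. The recorded stress sequence is non-increasing:
    an update that would raise stress is discarded and iteration stops.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    if (dm < 0).any():
        raise ValueError("distances must be non-negative")
    n = dm.shape[0]
    if n <= k:
        raise ValueError("need more points than dimensions")

    dv = squareform(dm, checks=False)  # condensed upper triangle
    x = _classical_mds(dm, k)
    if np.allclose(x, 0):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=1e-6, size=(n, k))

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    history: list[float] = []
    converged = False
    x_prev = x
    for _ in range(max_iter):
        cd = squareform(np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)),
                        checks=False)
        dhat = iso.fit_transform(dv, cd)
        stress = _stress1(cd, dhat)
        if history and stress > history[-1] + 1e-12:
            break  # keep the previous (better) configuration
        x_prev = x
        history.append(stress)
        if len(history) > 1 and history[-2] - history[-1] < tol:
            converged = True
            break
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cd > 0, dhat / cd, 0.0)
        b = -squareform(ratio, checks=False)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n

    coords = x_prev
    return NMDSResult(
        coordinates=coords,
        stress=history[-1] if history else 0.0,
        stress_history=history,
        n_iterations=len(history),
        converged=converged,
        sample_ids=list(index) if index is not None else None,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray
    components: np.ndarray  # loadings, components x features


def pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """SVD-based principal component analysis of a features x samples matrix.

    Samples are the observations; variance shares sum to one over the
    full decomposition.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    u, vt = u * signs, vt * signs[:, None]
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    var = s**2
    total = (x**2).sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        u * s, index=matrix.columns,
        columns=[f"PC{i+1}" for i in range(len(s))],
    )
    return PCAResult(scores=scores, variance_ratio=ratio, components=vt)
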