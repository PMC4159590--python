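"""Geometric morphometrics: GPA, sliding semi-landmarks, shape PCA.

Shapes are superimposed by generalized Procrustes analysis (centering,
scaling to unit centroid size, and least-squares rotation to an iteratively
re-estimated mean; reflections are disallowed).  Semi-landmarks slide along
tangents estimated from their curve neighbours so as to minimise the
thin-plate-spline bending energy of the deviation from the reference
(Bookstein's bending-energy criterion, Gunz-style chord tangents).  Shape
variation is summarised by PCA of the flattened Procrustes coordinates;
``pc_deformation`` renders the shape change along a component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import LandmarkDataset

log = logging.getLogger(__name__)


@dataclass
class ProcrustesFit:
    aligned: np.ndarray           # (n, k, 2), unit centroid size, centered
    mean_shape: np.ndarray        # (k, 2), unit centroid size
    centroid_sizes: np.ndarray    # (n,), pre-scaling sizes
    iterations: int
    converged: bool
    specimens: list[str] = field(default_factory=list)


@dataclass
class SlidingSpec:
    """Controls for bending-energy sliding."""
    max_iterations: int = 10
    tol: float = 1e-8             # convergence on summed bending energy


@dataclass
class ShapePCA:
    scores: np.ndarray            # (n, c)
    loadings: np.ndarray          # (c, 2k), orthonormal rows
    variance_explained: np.ndarray
    mean_shape: np.ndarray        # (k, 2)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances from the centroid."""
    cfg = np.asarray(config, dtype=float)
    if cfg.ndim != 2 or cfg.shape[1] != 2 or cfg.shape[0] < 3:
        raise ValueError("config must be (k, 2) with k >= 3")
    centered = cfg - cfg.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum()))


def _center_scale(cfg: np.ndarray) -> tuple[np.ndarray, float]:
    centered = cfg - cfg.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    return centered / cs, cs


def align_pair(config: np.ndarray, reference: np.ndarray
               ) -> tuple[np.ndarray, float]:
    """Rotate ``config`` onto ``reference`` (both centered, unit size).

    The optimal rotation comes from the SVD of the cross-product matrix;
    improper rotations (reflections) are forced out, so a mirrored
    configuration keeps a nonzero residual.  Returns the rotated
    configuration and the Procrustes distance to the reference.
    """
    A = np.asarray(config, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape:
        raise ValueError("configurations must share k")
    M = A.T @ B
    U, s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if s[-1] == 0:
        log.warning("degenerate (collinear) configuration; rotation is the "
                    "limit solution")
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    rotated = A @ R
    return rotated, float(np.linalg.norm(rotated - B))


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    """Proper rotation sending the mean's principal axis to x, sign-fixed."""
    _, V = np.linalg.eigh(mean.T @ mean)
    V = V[:, ::-1]                          # principal axis first
    if np.linalg.det(V) < 0:
        V[:, 1] = -V[:, 1]
    rotated = mean @ V
    j = int(np.argmax(np.abs(rotated[:, 0])))
    if rotated[j, 0] < 0:
        V = -V                              # 180-degree flip, still proper
    return V


def gpa(dataset: LandmarkDataset, tol: float = 1e-10,
        max_iter: int = 100) -> ProcrustesFit:
    """Generalized Procrustes analysis.

    All configurations are centered and scaled to unit centroid size, then
    iteratively rotated to the current mean, the mean re-estimated and
    re-normalised, until the mean moves less than ``tol``.
    """
    if dataset.n < 2:
        raise ValueError("GPA needs >= 2 specimens")
    scaled, sizes = [], []
    for cfg in dataset.coords:
        s, cs = _center_scale(cfg)
        scaled.append(s)
        sizes.append(cs)
    X = np.array(scaled)
    mean = X[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i], _ = align_pair(X[i], mean)
        new_mean, _ = _center_scale(X.mean(axis=0))
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            converged = True
            break
        mean = new_mean
    if not converged:
        log.warning("GPA did not converge in %d iterations", max_iter)
    # GPA is defined only up to a global rotation; fix a canonical
    # orientation (principal axis of the mean along x, deterministic sign)
    # so results do not depend on specimen order
    R = _canonical_rotation(mean)
    mean = mean @ R
    X = X @ R
    return ProcrustesFit(aligned=X, mean_shape=mean,
                         centroid_sizes=np.array(sizes), iterations=it,
                         converged=converged,
                         specimens=list(dataset.specimens))


# ---------------------------------------------------------------------------
# thin-plate-spline bending energy and sliding
# ---------------------------------------------------------------------------

def bending_energy(reference: np.ndarray) -> np.ndarray:
    """The k x k TPS bending-energy matrix of a reference configuration.

    Kernel U(r) = r^2 log r^2; the matrix is the upper-left block of the
    inverted bordered TPS system, so any affine displacement field lies in
    its null space.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=-1)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident points in reference")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Be = np.linalg.inv(L)[:k, :k]
    return (Be + Be.T) / 2.0


def slide_semilandmarks(dataset: LandmarkDataset, spec: SlidingSpec,
                        reference: np.ndarray) -> LandmarkDataset:
    """Slide semi-landmarks along chord tangents to minimise bending energy.

    Per specimen, the tangent at each semi-landmark is the (normalised)
    chord between its curve neighbours (one-sided at curve ends); the
    sliding amounts solve the normal equations of the bending-energy
    quadratic restricted to tangent directions.  Fixed landmarks never move
    and the energy never increases (the unslid state is feasible).
    """
    Be = bending_energy(reference)
    semis = list(dataset.curve_order)
    if not semis:
        return dataset
    new_coords = dataset.coords.copy()
    for si in range(dataset.n):
        X = new_coords[si]
        T = np.zeros((len(semis), 2))
        for idx, j in enumerate(semis):
            pos = semis.index(j)
            prev_pt = X[semis[pos - 1]] if pos > 0 else X[j]
            next_pt = X[semis[pos + 1]] if pos < len(semis) - 1 else X[j]
            chord = next_pt - prev_pt
            norm = np.linalg.norm(chord)
            T[idx] = chord / norm if norm > 0 else 0.0
        V0 = X - reference
        G = Be @ V0                                   # (k, 2)
        b = np.array([T[i] @ G[j] for i, j in enumerate(semis)])
        M = Be[np.ix_(semis, semis)] * (T @ T.T)
        try:
            alpha = np.linalg.solve(M, -b)
        except np.linalg.LinAlgError:
            log.warning("singular sliding system; adding ridge 1e-8")
            alpha = np.linalg.solve(M + 1e-8 * np.eye(len(semis)), -b)
        for i, j in enumerate(semis):
            X[j] = X[j] + alpha[i] * T[i]
    return LandmarkDataset(list(dataset.specimens), new_coords,
                           dataset.semi_flags.copy(),
                           list(dataset.curve_order), dict(dataset.groups))


def total_bending_energy(aligned: np.ndarray, mean: np.ndarray) -> float:
    """Sum over specimens of the TPS bending energy of (shape - mean)."""
    Be = bending_energy(mean)
    total = 0.0
    for X in aligned:
        V = X - mean
        total += float(np.trace(V.T @ Be @ V))
    return total


def gpa_with_sliding(dataset: LandmarkDataset,
                     spec: SlidingSpec | None = None) -> ProcrustesFit:
    """Alternate GPA and bending-energy sliding until the energy stabilises.

    With no semi-landmarks this is exactly :func:`gpa`.  The iteration trace
    of summed bending energies is attached as ``energy_trace`` and is
    non-increasing (the loop stops rather than accept an increase).
    """
    spec = spec or SlidingSpec()
    fit = gpa(dataset)
    if not dataset.semi_flags.any():
        fit.energy_trace = []           # type: ignore[attr-defined]
        return fit
    current = LandmarkDataset(list(dataset.specimens), fit.aligned.copy(),
                              dataset.semi_flags.copy(),
                              list(dataset.curve_order), dict(dataset.groups))
    trace = [total_bending_energy(fit.aligned, fit.mean_shape)]
    best = fit
    for _ in range(spec.max_iterations):
        slid = slide_semilandmarks(current, spec, best.mean_shape)
        fit2 = gpa(slid)
        e = total_bending_energy(fit2.aligned, fit2.mean_shape)
        if e > trace[-1] - spec.tol:
            if e <= trace[-1]:
                trace.append(e)
                best = fit2
            break
        trace.append(e)
        best = fit2
        current = LandmarkDataset(list(dataset.specimens),
                                  fit2.aligned.copy(),
                                  dataset.semi_flags.copy(),
                                  list(dataset.curve_order),
                                  dict(dataset.groups))
    best.centroid_sizes = fit.centroid_sizes
    best.energy_trace = trace           # type: ignore[attr-defined]
    return best


# ---------------------------------------------------------------------------
# shape PCA
# ---------------------------------------------------------------------------

def shape_pca(fit: ProcrustesFit) -> ShapePCA:
    """PCA of flattened Procrustes coordinates about the mean.

    Deterministic sign convention: the largest-magnitude element of each
    loading is positive.  ``variance_explained`` are the eigenvalues; their
    sum equals the total Procrustes variance.
    """
    n = fit.aligned.shape[0]
    if n < 3:
        raise ValueError("shape PCA needs >= 3 specimens")
    flat = fit.aligned.reshape(n, -1)
    center = flat.mean(axis=0)
    Xc = flat - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    keep = s > 1e-12 * max(s[0], 1e-300)
    Vt, s, var = Vt[keep], s[keep], var[keep]
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    scores = Xc @ Vt.T
    k = fit.aligned.shape[1]
    return ShapePCA(scores=scores, loadings=Vt, variance_explained=var,
                    mean_shape=center.reshape(k, 2))


def pc_deformation(pca: ShapePCA, component: int, score: float) -> np.ndarray:
    """Mean shape displaced by ``score`` units along one component."""
    if not (0 <= component < pca.loadings.shape[0]):
        raise ValueError(f"component {component} out of range")
    flat = pca.mean_shape.reshape(-1) + score * pca.loadings[component]
    return flat.reshape(pca.mean_shape.shape)
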