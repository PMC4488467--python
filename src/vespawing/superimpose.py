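"""Landmark superimposition for 2D wing configurations.

Implements the standard geometric-morphometrics chain: centroid size,
generalized Procrustes analysis (partial Procrustes: every configuration kept
at unit centroid size, rotations only -- all wings are right forewings, so
reflections are never fitted), orthogonal projection into the linear tangent
space at the consensus, Procrustes distances, and PCA of the tangent
coordinates.

Conventions
-----------
* A configuration is a ``(k, 2)`` float array of landmark coordinates
  (``k = 19`` for the wasp forewing, but nothing here assumes it).
* Aligned configurations are centered and scaled to centroid size 1.
* The consensus orientation is made reproducible by rotating its major
  principal axis onto the x axis and choosing, among the two remaining
  rotations, the one placing the first landmark at positive x.
* For ``k`` 2D landmarks the tangent space has dimension ``2k - 4``
  (translation, scale and rotation removed), hence 34 shape dimensions for
  the 19-landmark wing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "AlignedSample",
    "ShapePCA",
    "centroid_size",
    "gpa",
    "tangent_project",
    "procrustes_distance",
    "shape_pca",
]


@dataclass
class LandmarkConfiguration:
    """One digitized wing: ordered 2D landmarks plus provenance identifiers.

    Parameters
    ----------
    coords
        ``(k, 2)`` array of landmark coordinates, file/digitizer units.
    specimen_id, colony_id
        Identifiers carried through the pipeline.
    mounting, digitization
        Replicate indices for measurement-error studies (1-based; 0 means
        "only measurement").
    scale
        Optional digitizer scale factor (units per pixel), recorded but not
        applied here; see :mod:`vespawing.io_formats`.
    """

    coords: np.ndarray
    specimen_id: str = ""
    colony_id: str = ""
    mounting: int = 0
    digitization: int = 0
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"landmark coordinates must be (k, 2), got {self.coords.shape}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class AlignedSample:
    """Output of a generalized Procrustes analysis.

    ``consensus`` is the mean shape (centered, unit centroid size);
    ``aligned`` holds each configuration after centering, unit-size scaling
    and optimal rotation; ``tangent`` holds the ``(n, 2k)`` coordinates after
    orthogonal projection onto the tangent space at the consensus.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    log_centroid_sizes: np.ndarray
    tangent: np.ndarray
    iterations_used: int
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def n_configurations(self) -> int:
        return self.aligned.shape[0]


@dataclass
class ShapePCA:
    """PCA of tangent coordinates: retained scores, eigenvalues, loadings."""

    eigenvalues: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def _coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    x = np.asarray(config, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"landmark coordinates must be (k, 2), got {x.shape}")
    return x


def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    x = _coords(config)
    if x.shape[0] < 3:
        raise ValueError("centroid size requires at least 3 landmarks")
    centered = x - x.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    scale = float(np.abs(x).max())
    if cs <= 1e-12 * max(scale, 1.0):
        raise ValueError("degenerate configuration: all landmarks coincident")
    return cs


def _normalize(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and scale to unit centroid size; return (shape, centroid size)."""
    centered = x - x.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs <= 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / cs, float(cs)


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R in SO(2) minimizing ||target - source @ R||_F (no reflection)."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa(
    configs,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes analysis of a set of landmark configurations.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus; the consensus is recomputed,
    re-centered and re-scaled each sweep until its change (Frobenius norm)
    falls below ``tol``. The tangent coordinates (see
    :func:`tangent_project`) are filled in on the returned sample.

    Raises
    ------
    ValueError
        On landmark-count mismatch or non-convergence within ``max_iter``.
    """
    coords = [_coords(c) for c in configs]
    if len(coords) == 0:
        raise ValueError("gpa requires at least one configuration")
    k = coords[0].shape[0]
    for i, x in enumerate(coords):
        if x.shape[0] != k:
            raise ValueError(
                f"configuration {i} has {x.shape[0]} landmarks, expected {k}"
            )
    ids = [
        c.specimen_id if isinstance(c, LandmarkConfiguration) else str(i)
        for i, c in enumerate(configs)
    ]

    shapes = np.empty((len(coords), k, 2))
    sizes = np.empty(len(coords))
    for i, x in enumerate(coords):
        shapes[i], sizes[i] = _normalize(x)

    consensus = shapes[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus, _ = _normalize(shapes.mean(axis=0))
        change = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ValueError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})"
        )

    # Deterministic orientation: major principal axis of the consensus onto x,
    # 180-degree flip so the first landmark sits at positive x.
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot[:, 1] *= -1
    if (consensus @ rot)[0, 0] < 0:
        rot = rot @ np.array([[-1.0, 0.0], [0.0, -1.0]])
    consensus = consensus @ rot
    shapes = shapes @ rot
    # one final exact fit of every configuration to the oriented consensus
    for i in range(shapes.shape[0]):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)

    sample = AlignedSample(
        consensus=consensus,
        aligned=shapes,
        centroid_sizes=sizes,
        log_centroid_sizes=np.log(sizes),
        tangent=np.empty((len(coords), 2 * k)),
        iterations_used=iterations,
        specimen_ids=ids,
    )
    sample.tangent = tangent_project(sample)
    return sample


def tangent_project(sample: AlignedSample) -> np.ndarray:
    """Orthogonally project aligned coordinates onto the tangent space.

    The component of each flattened configuration along the (unit-norm)
    consensus vector is removed, so the consensus itself maps to the zero
    vector and every tangent vector is orthogonal to the consensus.
    """
    c = sample.consensus.ravel()
    c_hat = c / np.linalg.norm(c)
    flat = sample.aligned.reshape(sample.aligned.shape[0], -1)
    # consensus has unit norm (centroid size 1), so it projects to zero
    return flat - np.outer(flat @ c_hat, c_hat)


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    Both configurations are centered and scaled to unit centroid size, then
    ``b`` is rotated (no reflection) to best fit ``a``; the distance is the
    square root of the residual sum of squares.
    """
    xa = _coords(a)
    xb = _coords(b)
    if xa.shape != xb.shape:
        raise ValueError("configurations must share the landmark count")
    sa, _ = _normalize(xa)
    sb, _ = _normalize(xb)
    h = sb.T @ sa
    s = np.linalg.svd(h, compute_uv=False)
    trace = s[0] + np.sign(np.linalg.det(h)) * s[1]
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * trace)))


def shape_pca(tangent: np.ndarray, rtol: float = 1e-12) -> ShapePCA:
    """PCA of tangent coordinates about their mean.

    Components with eigenvalue above ``rtol`` times the largest eigenvalue
    are retained; for a generic sample of ``k`` 2D landmarks this yields
    ``2k - 4`` components. ``variance_fraction`` is each retained
    eigenvalue divided by the *total* tangent variance.
    """
    x = np.asarray(tangent, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("shape_pca requires an (n >= 2, d) tangent matrix")
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (x.shape[0] - 1)
    total = eigenvalues.sum()
    if total <= 0:
        keep = np.zeros(0, dtype=int)
    else:
        keep = np.flatnonzero(eigenvalues > rtol * eigenvalues[0])
    scores = (u * s)[:, keep]
    return ShapePCA(
        eigenvalues=eigenvalues[keep],
        scores=scores,
        loadings=vt[keep],
        variance_fraction=(eigenvalues[keep] / total) if total > 0 else eigenvalues[keep],
        mean=mean,
    )
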