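"""Landmark-based geometric morphometrics.

Reads landmark configurations from TPS files, superimposes them by
generalized Procrustes analysis (GPA), and extracts relative warps —
principal components of the aligned shapes in the tangent space at the
consensus — which serve as the shape variables of all downstream models.

The implementation works with two-dimensional landmarks.  Superimposition
is "full" Procrustes: every configuration is centred, scaled to unit
centroid size, and rotated to the running consensus; reflections are not
allowed by default since all specimens are photographed in the same
lateral orientation (a flag permits them for other datasets).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ShapeData",
    "RelativeWarps",
    "read_tps",
    "write_tps",
    "centroid_size",
    "procrustes_distance",
    "gpa",
    "tangent_coordinates",
    "relative_warps",
]


@dataclass
class ShapeData:
    """Landmark configurations for a set of specimens.

    ``coords`` holds the raw digitized coordinates, shape ``(n, k, 2)``
    for ``n`` specimens and ``k`` landmarks.  After :func:`gpa` the
    ``aligned`` array holds the superimposed configurations (centroid at
    the origin, unit centroid size), ``centroid_sizes`` the pre-scaling
    sizes, and ``consensus`` the mean aligned configuration.
    """

    specimen_ids: list[str]
    coords: np.ndarray
    metadata: pd.DataFrame | None = None
    aligned: np.ndarray | None = None
    centroid_sizes: np.ndarray | None = None
    consensus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (n, k, 2), got {self.coords.shape}"
            )
        if len(self.specimen_ids) != self.coords.shape[0]:
            raise ValueError("specimen_ids length does not match coords")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]


@dataclass
class RelativeWarps:
    """Principal components of aligned shapes (relative warps).

    ``scores`` and ``loadings`` are restricted to the retained axes;
    ``eigenvalues`` and ``variance_fractions`` cover every axis so the
    fractions sum to one.  ``mean`` is the mean tangent-space vector
    about which the decomposition was taken.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    mean: np.ndarray
    consensus: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Tangent-space coordinates rebuilt from the retained scores."""
        return self.scores @ self.loadings + self.mean

    def to_frame(self) -> pd.DataFrame:
        cols = [f"rw{i + 1}" for i in range(self.n_retained)]
        return pd.DataFrame(self.scores, index=self.specimen_ids, columns=cols)


# ---------------------------------------------------------------------------
# TPS input/output


def read_tps(path: str | Path) -> ShapeData:
    """Read a TPS landmark file (``LM=``, ``ID=``, ``SCALE=`` dialect).

    One specimen per ``LM=`` block.  ``SCALE`` lines are applied
    multiplicatively to the block's coordinates; ``ID`` (or ``IMAGE``)
    lines name the specimen.  A block whose coordinate-line count does
    not match its ``LM=`` count raises a parse error naming the block.
    """
    path = Path(path)
    ids: list[str] = []
    configs: list[np.ndarray] = []
    block: list[tuple[float, float]] | None = None
    expected = 0
    block_no = 0
    cur_id: str | None = None
    cur_scale = 1.0

    def close_block() -> None:
        nonlocal block, cur_id, cur_scale
        if block is None:
            return
        if len(block) != expected:
            raise ValueError(
                f"TPS block {block_no} (specimen "
                f"{cur_id or block_no - 1}): LM={expected} but "
                f"{len(block)} coordinate lines found"
            )
        configs.append(np.asarray(block, dtype=float) * cur_scale)
        ids.append(cur_id if cur_id is not None else f"specimen_{block_no - 1}")
        block, cur_id, cur_scale = None, None, 1.0

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            close_block()
            block_no += 1
            expected = int(line.split("=", 1)[1])
            block = []
        elif upper.startswith("ID="):
            cur_id = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            cur_scale = float(line.split("=", 1)[1])
        elif upper.startswith("IMAGE="):
            if cur_id is None:
                cur_id = line.split("=", 1)[1].strip()
        else:
            if block is None:
                raise ValueError(f"coordinate line outside LM block: {line!r}")
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"TPS block {block_no}: malformed coordinate line {line!r}"
                )
            block.append((float(parts[0]), float(parts[1])))
    close_block()
    if not configs:
        raise ValueError(f"no LM blocks found in {path}")
    k = {c.shape[0] for c in configs}
    if len(k) != 1:
        raise ValueError(f"inconsistent landmark counts across specimens: {sorted(k)}")
    return ShapeData(specimen_ids=ids, coords=np.stack(configs))


def write_tps(shapes: ShapeData, path: str | Path) -> None:
    """Write raw coordinates as a TPS file (one ``LM=`` block per specimen)."""
    lines: list[str] = []
    for sid, cfg in zip(shapes.specimen_ids, shapes.coords):
        lines.append(f"LM={cfg.shape[0]}")
        for x, y in cfg:
            lines.append(f"{x:.10f} {y:.10f}")
        lines.append(f"ID={sid}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superimposition


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def _normalize(config: np.ndarray) -> np.ndarray:
    centred = config - config.mean(axis=0)
    size = np.sqrt((centred**2).sum())
    if size <= 1e-300:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return centred / size


def _rotate_to(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally rotate each configuration in ``X`` (n, k, 2) to ``target``.

    Uses the closed-form two-dimensional solution: the optimal angle has
    cos/sin proportional to the cross-covariance sums.  Rotation only —
    determinant +1, no reflection.
    """
    a = np.einsum("nkd,kd->n", X, target)
    b = X[:, :, 0] @ target[:, 1] - X[:, :, 1] @ target[:, 0]
    norm = np.hypot(a, b)
    norm = np.where(norm == 0, 1.0, norm)
    c, s = a / norm, b / norm
    out = np.empty_like(X)
    out[:, :, 0] = c[:, None] * X[:, :, 0] - s[:, None] * X[:, :, 1]
    out[:, :, 1] = s[:, None] * X[:, :, 0] + c[:, None] * X[:, :, 1]
    return out


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = False
) -> float:
    """Procrustes distance between two configurations.

    Both are centred and scaled to unit centroid size, ``b`` is rotated
    optimally onto ``a``, and the root summed squared difference is
    returned.
    """
    an = _normalize(np.asarray(a, float))
    bn = _normalize(np.asarray(b, float))
    d = float(np.sqrt(((an - _rotate_to(bn[None], an)[0]) ** 2).sum()))
    if allow_reflection:
        br = bn.copy()
        br[:, 1] *= -1
        d2 = float(np.sqrt(((an - _rotate_to(br[None], an)[0]) ** 2).sum()))
        d = min(d, d2)
    return d


def gpa(
    shapes: ShapeData,
    tol: float = 1e-10,
    max_iter: int = 1000,
    allow_reflection: bool = False,
) -> ShapeData:
    """Generalized Procrustes superimposition.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated to the running consensus; the consensus is
    re-estimated (and renormalized to unit size) until it moves by less
    than ``tol``.  Centroid sizes are recorded before scaling.
    """
    if shapes.n_specimens < 2:
        raise ValueError("GPA requires at least 2 specimens")
    X = shapes.coords
    centred = X - X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if np.any(sizes <= 1e-300):
        bad = list(np.nonzero(sizes <= 1e-300)[0])
        raise ValueError(f"degenerate configuration(s) at index {bad}")
    Xn = centred / sizes[:, None, None]
    if allow_reflection:
        # resolve each specimen's chirality against the first specimen once
        ref = Xn[0]
        for i in range(1, Xn.shape[0]):
            direct = _rotate_to(Xn[i][None], ref)[0]
            mirrored = Xn[i].copy()
            mirrored[:, 1] *= -1
            mir = _rotate_to(mirrored[None], ref)[0]
            if ((ref - mir) ** 2).sum() < ((ref - direct) ** 2).sum():
                Xn[i] = mirrored
    consensus = Xn[0].copy()
    for _ in range(max_iter):
        Xr = _rotate_to(Xn, consensus)
        new = Xr.mean(axis=0)
        new = new - new.mean(axis=0)
        size = np.sqrt((new**2).sum())
        if size <= 1e-300:
            raise ValueError("consensus collapsed to a point")
        new /= size
        shift = float(np.sqrt(((new - consensus) ** 2).sum()))
        consensus = new
        if shift < tol:
            break
    aligned = _rotate_to(Xn, consensus)
    return dataclasses.replace(
        shapes,
        aligned=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
    )


# ---------------------------------------------------------------------------
# Relative warps (shape PCA)


def tangent_coordinates(shapes: ShapeData) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal projection of aligned shapes into the tangent space.

    Returns ``(X_t, c)`` where ``X_t`` is ``(n, 2k)`` and ``c`` the
    flattened (unit-norm) consensus.  The component of each flattened
    configuration along the consensus direction is removed; together
    with centring and the rotation-optimality constraint this leaves
    shapes in an exactly ``2k - 4`` dimensional subspace.
    """
    if shapes.aligned is None or shapes.consensus is None:
        raise ValueError("run gpa() before extracting tangent coordinates")
    n = shapes.n_specimens
    X = shapes.aligned.reshape(n, -1)
    c = shapes.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    Xt = X - np.outer(X @ c, c)
    return Xt, c


def relative_warps(shapes: ShapeData, n_keep: int = 7) -> RelativeWarps:
    """Principal components of Procrustes-aligned shapes.

    Uniform and non-uniform shape variation are decomposed together
    (equal landmark weighting, i.e. no bending-energy re-weighting).
    ``n_keep`` axes are retained; seven by default.  Eigenvalues and
    variance fractions are reported for every axis, so the fractions
    sum to one.  Each axis is oriented so its largest-magnitude loading
    coefficient is positive.
    """
    Xt, _ = tangent_coordinates(shapes)
    n, m = Xt.shape
    k = shapes.n_landmarks
    mean = Xt.mean(axis=0)
    Xc = Xt - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = S**2 / (n - 1)
    max_rank = min(n - 1, 2 * k - 4)
    rank = int(np.sum(eigenvalues > max(eigenvalues[0], 1e-300) * 1e-12))
    rank = min(rank, max_rank)
    if n_keep > max_rank:
        raise ValueError(
            f"n_keep={n_keep} exceeds the available shape-space rank {max_rank}"
        )
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else eigenvalues
    scores = U * S
    loadings = Vt
    # sign convention: largest-|coefficient| loading positive per axis
    for j in range(min(n_keep, loadings.shape[0])):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return RelativeWarps(
        scores=scores[:, :n_keep],
        eigenvalues=eigenvalues,
        loadings=loadings[:n_keep],
        variance_fractions=fractions,
        mean=mean,
        consensus=shapes.consensus.copy(),
        specimen_ids=list(shapes.specimen_ids),
    )
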