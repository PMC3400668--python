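"""Landmark-based geometric morphometrics.

Generalized Procrustes analysis (GPA) superimposes k-landmark 2-D
configurations by removing translation, scale (to unit centroid size) and
rotation, iterating the consensus to convergence.  Shape variation around the
consensus is decomposed, via the thin-plate-spline bending-energy matrix,
into 2(k-3) non-uniform partial-warp scores plus a 2-D uniform (affine)
component; together these span the shape tangent space, so squared scores sum
to the squared tangent-space Procrustes residual of each specimen.

Shape is related to a continuous covariate by a Goodall-style F statistic
(explained vs residual Procrustes sum of squares) whose tail probability is
obtained by permuting the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError


@dataclass
class LandmarkConfig:
    """One specimen's landmark configuration: k ordered (x, y) pairs."""

    specimen_id: str
    coords: np.ndarray  # (k, 2), image units

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise InvalidParameterError("coords must be a (k, 2) array")
        if self.coords.shape[0] < 4:
            raise InvalidParameterError("need at least 4 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidParameterError("landmark coordinates must be finite")
        # duplicated landmark positions make the TPS system singular
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        if np.any(dist == 0):
            raise InvalidParameterError(
                f"specimen {self.specimen_id!r} has duplicated landmark positions"
            )

    @property
    def k(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class AlignedShapes:
    """Result of a GPA: consensus, superimposed configurations, sizes."""

    consensus: np.ndarray  # (k, 2), centered, unit centroid size
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    ids: list[str]

    @property
    def n(self) -> int:
        return int(self.aligned.shape[0])

    @property
    def k(self) -> int:
        return int(self.consensus.shape[0])


@dataclass
class ShapeScores:
    """Tangent-space shape variables: non-uniform partial warps plus uniform part."""

    partial_warp_scores: np.ndarray  # (n, 2(k-3))
    uniform_component: np.ndarray  # (n, 2)
    ids: list[str]

    @property
    def matrix(self) -> np.ndarray:
        """All shape variables, (n, 2(k-3)+2)."""
        return np.hstack([self.partial_warp_scores, self.uniform_component])


@dataclass
class MorphoRatios:
    """The univariate body-shape ratios used alongside landmark analysis."""

    FR: float  # fitness ratio, body length / body depth
    AR: float  # caudal fin aspect ratio, fin height^2 / fin area
    CPH: float  # relative caudal peduncle height, % of body length
    CPD_BD: float  # caudal peduncle depth / body depth


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared deviations from the centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _preshape(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and scale to unit centroid size; returns (preshape, size)."""
    c = coords - coords.mean(axis=0)
    size = float(np.sqrt((c**2).sum()))
    if size == 0:
        raise DegenerateInputError("all landmarks coincident; shape undefined")
    return c / size, size


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||a @ R - b||."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def opa_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are reduced to preshape (centered, unit centroid size) and one is
    rotated onto the other; the distance is the residual norm,
    sqrt(2 - 2 cos rho) with rho the Procrustes angle.
    """
    a, _ = _preshape(np.asarray(c1, float))
    b, _ = _preshape(np.asarray(c2, float))
    r = _optimal_rotation(a, b)
    return float(np.linalg.norm(a @ r - b))


def gpa_align(
    configs: list[LandmarkConfig], tol: float = 1e-10, max_iter: int = 200
) -> AlignedShapes:
    """Generalized (partial) Procrustes superimposition of n configurations.

    Each configuration is centered, scaled to unit centroid size and rotated
    to the running consensus; the consensus (mean shape, re-standardized to
    unit size) is re-estimated until it moves by less than ``tol``.
    """
    if len(configs) < 2:
        raise InsufficientDataError("GPA needs at least 2 configurations")
    k = configs[0].k
    if any(c.k != k for c in configs):
        raise InvalidParameterError("all configurations must share the same landmark count")

    pre = np.empty((len(configs), k, 2))
    sizes = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        pre[i], sizes[i] = _preshape(cfg.coords)

    consensus = pre.mean(axis=0)
    norm = np.linalg.norm(consensus)
    if norm < 1e-12:
        consensus = pre[0].copy()
    else:
        consensus /= norm

    aligned = pre.copy()
    for _ in range(max_iter):
        for i in range(aligned.shape[0]):
            aligned[i] = pre[i] @ _optimal_rotation(pre[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.linalg.norm(new_consensus)
        if norm == 0:
            raise DegenerateInputError("degenerate consensus (all shapes cancel)")
        new_consensus /= norm
        # fix the rotational gauge: rotate candidate consensus onto the old one
        new_consensus = new_consensus @ _optimal_rotation(new_consensus, consensus)
        change = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if change < tol:
            break

    return AlignedShapes(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        ids=[c.specimen_id for c in configs],
    )


def bending_energy_matrix(consensus: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending-energy matrix of a reference configuration.

    Built from the TPS kernel U(r) = r^2 log r^2; the returned k x k matrix is
    symmetric positive semi-definite with a 3-dimensional null space spanned
    by the affine functions {1, x, y} of the reference landmarks.
    """
    pts = np.asarray(consensus, float)
    k = pts.shape[0]
    d = pts[:, None, :] - pts[None, :, :]
    r2 = d[..., 0] ** 2 + d[..., 1] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    p = np.column_stack([np.ones(k), pts])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    try:
        linv = np.linalg.inv(lmat)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular TPS system (collinear consensus?): {exc}") from exc
    be = linv[:k, :k]
    return (be + be.T) / 2.0


def _tangent_basis(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal bases (flattened, length-2k vectors) for the non-uniform
    and uniform subspaces of the shape tangent space at the consensus."""
    k = consensus.shape[0]
    be = bending_energy_matrix(consensus)
    evals, evecs = np.linalg.eigh(be)
    # the 3 smallest eigenvalues correspond to the affine null space
    order = np.argsort(evals)
    nonzero = evecs[:, order[3:]]  # (k, k-3) principal warps, orthonormal
    zero_col = np.zeros(k)
    nonuni = np.empty((2 * k, 2 * (k - 3)))
    for j in range(k - 3):
        nonuni[:, 2 * j] = np.concatenate([nonzero[:, j], zero_col])
        nonuni[:, 2 * j + 1] = np.concatenate([zero_col, nonzero[:, j]])

    cx, cy = consensus[:, 0], consensus[:, 1]
    s = np.concatenate([cx, cy])  # scaling direction (unit: consensus has unit size)
    q = np.concatenate([-cy, cx])
    q = q - (q @ s) * s
    q /= np.linalg.norm(q)  # rotation direction
    # affine displacement fields
    affine = np.column_stack(
        [
            np.concatenate([cx, zero_col]),
            np.concatenate([cy, zero_col]),
            np.concatenate([zero_col, cx]),
            np.concatenate([zero_col, cy]),
        ]
    )
    # remove the similarity (scale + rotation) directions, orthonormalize the rest
    proj = affine - np.outer(s, s @ affine) - np.outer(q, q @ affine)
    qmat, rmat = np.linalg.qr(proj)
    keep = np.abs(np.diag(rmat)) > 1e-9 * np.abs(np.diag(rmat)).max()
    uniform = qmat[:, keep][:, :2]
    if uniform.shape[1] != 2:
        raise DegenerateInputError("could not construct a 2-D uniform subspace")
    return nonuni, uniform


def tps_partial_warps(aligned: AlignedShapes) -> ShapeScores:
    """Partial-warp and uniform scores of each specimen's tangent residual.

    Residuals (aligned minus consensus) are projected into the tangent space
    (removing the residual scale and rotation directions) and expressed in the
    orthonormal principal-warp / uniform basis, giving 2(k-3) non-uniform and
    2 uniform scores per specimen whose squared sum equals the squared
    tangent residual norm.
    """
    if aligned.k < 4:
        raise InvalidParameterError("partial warps need at least 4 landmarks")
    consensus = aligned.consensus
    nonuni, uniform = _tangent_basis(consensus)
    k = aligned.k
    s = np.concatenate([consensus[:, 0], consensus[:, 1]])  # scaling direction
    q = np.concatenate([-consensus[:, 1], consensus[:, 0]])
    q = q - (q @ s) * s
    q /= np.linalg.norm(q)  # rotation direction

    n = aligned.n
    pw = np.empty((n, 2 * (k - 3)))
    uni = np.empty((n, 2))
    for i in range(n):
        resid = aligned.aligned[i] - consensus
        v = np.concatenate([resid[:, 0], resid[:, 1]])
        v = v - (v @ s) * s - (v @ q) * q  # tangent projection
        pw[i] = v @ nonuni
        uni[i] = v @ uniform
    return ShapeScores(partial_warp_scores=pw, uniform_component=uni, ids=list(aligned.ids))


@dataclass
class ShapeRegressionResult:
    F: float
    p: float
    df1: int
    df2: int
    n_perm: int


def shape_regression(
    scores: ShapeScores,
    covariate: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> ShapeRegressionResult:
    """Multivariate regression of shape scores on one covariate, permutation test.

    Uses a Goodall-style statistic on the pooled Procrustes sums of squares:
    F = (SS_explained / 1) / (SS_residual / (n - 2)), with the tail
    probability the proportion of covariate permutations (observed included)
    whose F is at least the observed one.
    """
    x = np.asarray(covariate, dtype=float)
    s = scores.matrix
    n = s.shape[0]
    if x.shape != (n,):
        raise InvalidParameterError("covariate must have one value per specimen")
    if n_perm < 99:
        raise InvalidParameterError("need at least 99 permutations")
    if np.ptp(x) == 0:
        raise InvalidParameterError("covariate is constant; regression undefined")

    s = s - s.mean(axis=0)
    rng = np.random.default_rng(seed)

    def goodall_f(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        ssx = xc @ xc
        ss_exp = float(((s.T @ xc) ** 2).sum()) / ssx
        ss_tot = float((s**2).sum())
        ss_res = max(ss_tot - ss_exp, 0.0)
        if ss_res == 0:
            return np.inf
        return ss_exp / (ss_res / (n - 2))

    f_obs = goodall_f(x)
    hits = 1  # the observed ordering counts
    for _ in range(n_perm):
        if goodall_f(rng.permutation(x)) >= f_obs:
            hits += 1
    return ShapeRegressionResult(
        F=f_obs, p=hits / (n_perm + 1), df1=1, df2=n - 2, n_perm=n_perm
    )


def morpho_ratios(
    body_length: float,
    body_depth: float,
    caudal_fin_height: float,
    caudal_fin_area: float,
    caudal_peduncle_depth: float,
) -> MorphoRatios:
    """The univariate shape ratios from direct body measurements.

    FR = body length / body depth; AR = caudal fin height^2 / caudal fin
    area; CPH = 100 * caudal peduncle depth / body length (%);
    CPD_BD = caudal peduncle depth / body depth.
    """
    vals = [body_length, body_depth, caudal_fin_height, caudal_fin_area, caudal_peduncle_depth]
    if any(v <= 0 for v in vals):
        raise InvalidParameterError("all body measurements must be positive")
    return MorphoRatios(
        FR=body_length / body_depth,
        AR=caudal_fin_height**2 / caudal_fin_area,
        CPH=100.0 * caudal_peduncle_depth / body_length,
        CPD_BD=caudal_peduncle_depth / body_depth,
    )
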