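"""Mass-univariate GLM and random-field-theory topological inference.

Each voxel of a stack of summary-statistic images is fit with the same
general linear model Y = X b + e; t and F contrast maps are formed from
the voxelwise estimates.  Because neighbouring voxels are correlated
(the maps are smooth by construction), a Bonferroni correction over
voxels would be needlessly severe; random field theory instead adjusts
p-values using the expected Euler characteristic of the excursion set
of a smooth field above a threshold,

    P(max Z >= u)  ~=  E[EC]  =  sum_d R_d * rho_d(u),

where R_d are the resel (resolution element) counts of the search
region — its intrinsic volumes measured in units of the field's FWHM —
and rho_d are the EC densities of the field type (Gaussian, t or F).
The field's FWHM is estimated from the variance of first differences of
the standardized GLM residuals.  Reported peak p-values take the
minimum of the RFT and Bonferroni corrections, so validity is preserved
even when the field is nearly unsmooth.

Cluster-extent inference uses the standard Gaussian-field approximation
for the distribution of suprathreshold cluster sizes; t and F maps are
probit-transformed to the Gaussian scale first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.special import gammaln

from topostat.image_export import StatImage

FOUR_LN2 = 4.0 * np.log(2.0)

#: Column order of the results table written by :func:`topological_report`.
RESULTS_COLUMNS = [
    "peak_x", "peak_y", "peak_z", "stat", "p_peak_corrected",
    "cluster_k", "p_cluster_corrected", "p_uncorrected", "significant",
]


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    X: np.ndarray
    column_labels: list[str]
    kind: str = "custom"

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if np.any(np.all(self.X == 0, axis=0)):
            raise ValueError("design matrix has an all-zero column")
        if self.X.shape[0] <= np.linalg.matrix_rank(self.X):
            raise ValueError("need more images than the design rank")

    @property
    def n_images(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    @property
    def dof(self) -> int:
        """Residual degrees of freedom."""
        return self.n_images - self.rank


@dataclass
class Contrast:
    """t (vector) or F (matrix) contrast over design columns."""

    c: np.ndarray
    kind: str = "t"

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if self.kind not in ("t", "F"):
            raise ValueError("contrast kind must be 't' or 'F'")
        if self.kind == "t":
            c = c.ravel()
        else:
            c = np.atleast_2d(c)
        if not np.any(c):
            raise ValueError("contrast is all zero")
        self.c = c


def build_design(
    kind: str,
    group_sizes: tuple[int, ...] | None = None,
    n_subjects: int | None = None,
) -> DesignMatrix:
    """Standard design encodings.

    one-sample: a column of ones over ``group_sizes[0]`` images.
    two-sample: two group-indicator columns.
    paired: two condition indicators plus one block indicator per
    subject (2 x ``n_subjects`` images, rank ``n_subjects + 1``).
    """
    if kind == "one-sample":
        (n,) = group_sizes
        if n < 2:
            raise ValueError("one-sample design needs >= 2 images")
        return DesignMatrix(np.ones((n, 1)), ["mean"], kind)
    if kind == "two-sample":
        n1, n2 = group_sizes
        if n1 < 1 or n2 < 1 or n1 + n2 < 3:
            raise ValueError("two-sample design needs >= 3 images total")
        X = np.zeros((n1 + n2, 2))
        X[:n1, 0] = 1.0
        X[n1:, 1] = 1.0
        return DesignMatrix(X, ["group1", "group2"], kind)
    if kind == "paired":
        n = int(n_subjects)
        if n < 2:
            raise ValueError("paired design needs >= 2 subjects")
        X = np.zeros((2 * n, 2 + n))
        X[:n, 0] = 1.0
        X[n:, 1] = 1.0
        for s in range(n):
            X[s, 2 + s] = 1.0
            X[n + s, 2 + s] = 1.0
        labels = ["cond1", "cond2"] + [f"subj{s + 1}" for s in range(n)]
        return DesignMatrix(X, labels, kind)
    raise ValueError(f"unknown design kind {kind!r}")


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMModel:
    beta: np.ndarray  # (p, *shape)
    sigma2: np.ndarray  # (*shape)
    residuals: np.ndarray  # (n, *shape)
    dof: int
    mask: np.ndarray  # (*shape) bool
    shape: tuple[int, ...] = None

    def __post_init__(self):
        if self.shape is None:
            self.shape = self.sigma2.shape


def _as_stack(images) -> tuple[np.ndarray, StatImage | None]:
    if isinstance(images, np.ndarray):
        return images, None
    first = images[0] if len(images) else None
    if isinstance(first, StatImage):
        shapes = {im.data.shape for im in images}
        if len(shapes) != 1:
            raise ValueError("images differ in shape")
        return np.stack([im.data for im in images]), first
    return np.stack([np.asarray(im, dtype=float) for im in images]), None


def fit_glm(images, design: DesignMatrix | np.ndarray) -> GLMModel:
    """Voxelwise least squares: beta = pinv(X) Y, sigma2 = RSS / dof.

    ``images`` is a stack ``(n, *shape)``, a list of arrays, or a list
    of :class:`StatImage`.  Voxels missing (NaN) in any image are masked
    out of every estimate.
    """
    Y, _ = _as_stack(images)
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"{Y.shape[0]} images but design has {X.shape[0]} rows"
        )
    shape = Y.shape[1:]
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    dof = n - rank
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    mask = np.all(np.isfinite(Y), axis=0)
    Yf = Y.reshape(n, -1)[:, mask.ravel()]
    pinv = np.linalg.pinv(X)
    beta_m = pinv @ Yf
    res_m = Yf - X @ beta_m
    sigma2_m = np.sum(res_m**2, axis=0) / dof
    beta = np.full((p,) + shape, np.nan)
    beta.reshape(p, -1)[:, mask.ravel()] = beta_m
    sigma2 = np.full(shape, np.nan)
    sigma2.ravel()[mask.ravel()] = sigma2_m
    residuals = np.full((n,) + shape, np.nan)
    residuals.reshape(n, -1)[:, mask.ravel()] = res_m
    return GLMModel(beta, sigma2, residuals, int(dof), mask, shape)


def compute_contrast(
    model: GLMModel,
    design: DesignMatrix | np.ndarray,
    contrast: Contrast | np.ndarray,
    template: StatImage | None = None,
) -> StatImage:
    """t or F statistic map for a contrast of GLM parameters.

    t = c'b / sqrt(sigma2 * c'(X'X)^- c); F is the equivalent quadratic
    form over the rows of a contrast matrix C, with (rank C, dof)
    degrees of freedom (extra-sum-of-squares between the full model and
    the model constrained to C'b = 0).
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if not isinstance(contrast, Contrast):
        contrast = Contrast(np.asarray(contrast))
    xtx = X.T @ X
    xtx_pinv = np.linalg.pinv(xtx)
    C = np.atleast_2d(contrast.c)
    # estimability: C rows must lie in the row space of X
    proj = xtx @ xtx_pinv
    if np.max(np.abs(C - C @ proj.T)) > 1e-8 * max(1.0, np.max(np.abs(C))):
        raise ValueError("contrast is not estimable under this design")
    p = model.beta.shape[0]
    shape = model.shape
    bm = model.beta.reshape(p, -1)[:, model.mask.ravel()]
    s2 = model.sigma2.ravel()[model.mask.ravel()]
    if contrast.kind == "t":
        c = contrast.c
        denom = float(c @ xtx_pinv @ c)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat_m = (c @ bm) / np.sqrt(s2 * denom)
        fieldtype, dof = "t", (float(model.dof),)
    else:
        M = C @ xtx_pinv @ C.T
        M_pinv = np.linalg.pinv(M)
        q = np.linalg.matrix_rank(M)
        cb = C @ bm  # (q_rows, n_voxels)
        num = np.einsum("iv,ij,jv->v", cb, M_pinv, cb) / q
        with np.errstate(invalid="ignore", divide="ignore"):
            stat_m = num / s2
        fieldtype, dof = "F", (float(q), float(model.dof))
    out = np.full(shape, np.nan)
    out.ravel()[model.mask.ravel()] = stat_m
    if template is not None:
        return StatImage(
            out, template.axis_units, template.axis_scales,
            template.axis_origins, field=fieldtype, dof=dof,
        )
    return StatImage(
        out, ("voxel",) * len(shape), (1.0,) * len(shape),
        field=fieldtype, dof=dof,
    )


# ---------------------------------------------------------------------------
# Smoothness and resels
# ---------------------------------------------------------------------------

@dataclass
class SmoothnessEstimate:
    """Per-dimension FWHM (voxels) and resel counts R_0..R_D of a mask."""

    fwhm: np.ndarray
    resels: np.ndarray
    n_voxels: int

    @property
    def resel_volume(self) -> float:
        """Voxels per resel: prod of the per-dimension FWHMs."""
        return float(np.prod(self.fwhm))


def resel_counts(mask: np.ndarray, fwhm: np.ndarray) -> np.ndarray:
    """Resel counts of a mask given the field FWHM per dimension.

    R_D is the mask volume in FWHM units; lower orders come from the
    bounding-box edge lengths L_j (in FWHM units): R_1 = sum L_j,
    R_2 = sum_{j<k} L_j L_k, which is exact for cuboid masks and a
    bounding-box approximation otherwise.
    """
    mask = np.asarray(mask, dtype=bool)
    D = mask.ndim
    fwhm = np.asarray(fwhm, dtype=float)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty mask")
    idx = np.nonzero(mask)
    extents = np.array([i.max() - i.min() + 1 for i in idx], dtype=float)
    L = extents / fwhm
    R = np.zeros(D + 1)
    R[0] = 1.0
    if D >= 1:
        R[1] = L.sum()
    if D >= 2:
        R[2] = sum(L[j] * L[k] for j, k in combinations(range(D), 2))
    R[D] = n_vox / np.prod(fwhm)
    return R


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray | None = None
) -> SmoothnessEstimate:
    """Estimate field FWHM from standardized GLM residuals.

    Residual images are standardized to unit sum of squares per voxel;
    lambda_j, the variance of their first differences along dimension j
    (summed over images, averaged over in-mask voxel pairs), gives
    FWHM_j = sqrt(4 ln 2 / lambda_j).  No small-sample bias correction
    is applied; estimates are reliable from roughly 20 residual images.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim < 2 or res.shape[0] < 2:
        raise ValueError("need at least 2 residual images")
    n = res.shape[0]
    shape = res.shape[1:]
    D = len(shape)
    if mask is None:
        mask = np.all(np.isfinite(res), axis=0)
    mask = np.asarray(mask, dtype=bool) & np.all(np.isfinite(res), axis=0)
    if not mask.any():
        raise ValueError("empty mask")
    rss = np.sum(np.where(mask, res, 0.0) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        std = np.where(mask & (rss > 0), res / np.sqrt(rss), np.nan)
    lam = np.empty(D)
    for j in range(D):
        sl_hi = [slice(None)] * D
        sl_lo = [slice(None)] * D
        sl_hi[j] = slice(1, None)
        sl_lo[j] = slice(None, -1)
        pair_ok = mask[tuple(sl_hi)] & mask[tuple(sl_lo)]
        if not pair_ok.any():
            raise ValueError(f"mask has no voxel pairs along dimension {j}")
        d = std[(slice(None),) + tuple(sl_hi)] - std[(slice(None),) + tuple(sl_lo)]
        d2 = np.nansum(d**2, axis=0)  # summed over images
        lam[j] = float(d2[pair_ok].mean())
    fwhm = np.sqrt(FOUR_LN2 / lam)
    return SmoothnessEstimate(fwhm, resel_counts(mask, fwhm), int(mask.sum()))


# ---------------------------------------------------------------------------
# EC densities and corrected p-values
# ---------------------------------------------------------------------------

def ec_density(u: float, d: int, fieldtype: str, dof: tuple[float, ...] = ()) -> float:
    """Euler characteristic density rho_d(u) for Gaussian, t and F fields."""
    u = float(u)
    a = FOUR_LN2 / (2.0 * np.pi)
    if fieldtype == "gaussian":
        if d == 0:
            return float(stats.norm.sf(u))
        g = np.exp(-(u**2) / 2.0)
        if d == 1:
            return float(np.sqrt(FOUR_LN2) / (2 * np.pi) * g)
        if d == 2:
            return float(FOUR_LN2 / (2 * np.pi) ** 1.5 * u * g)
        if d == 3:
            return float(FOUR_LN2**1.5 / (2 * np.pi) ** 2 * (u**2 - 1) * g)
    elif fieldtype == "t":
        (nu,) = dof
        if d == 0:
            return float(stats.t.sf(u, nu))
        core = (1.0 + u**2 / nu) ** (-(nu - 1) / 2.0)
        if d == 1:
            return float(np.sqrt(FOUR_LN2) / (2 * np.pi) * core)
        if d == 2:
            g = np.exp(gammaln((nu + 1) / 2) - gammaln(nu / 2)) / np.sqrt(nu / 2)
            return float(FOUR_LN2 / (2 * np.pi) ** 1.5 * g * u * core)
        if d == 3:
            return float(
                FOUR_LN2**1.5 / (2 * np.pi) ** 2
                * ((nu - 1) / nu * u**2 - 1) * core
            )
    elif fieldtype == "F":
        k, nu = dof
        if d == 0:
            return float(stats.f.sf(u, k, nu))
        if u <= 0:
            return np.inf
        lam = k * u / nu
        lb = np.log1p(lam)
        logb = gammaln(nu / 2) + gammaln(k / 2)

        def base(dd: float) -> float:
            return np.exp(
                gammaln((nu + k - dd) / 2) - logb
                + (k - dd) / 2 * np.log(lam) - (nu + k - 2) / 2 * lb
            )

        if d == 1:
            return float(a**0.5 * np.sqrt(2.0) * base(1))
        if d == 2:
            return float(a * base(2) * ((nu - 1) * lam - (k - 1)))
        if d == 3:
            poly = (
                (nu - 1) * (nu - 2) * lam**2
                - (2 * nu * k - nu - k - 1) * lam
                + (k - 1) * (k - 2)
            )
            return float(a**1.5 / np.sqrt(2.0) * base(3) * poly)
    else:
        raise ValueError(f"unknown field type {fieldtype!r}")
    raise ValueError("EC densities implemented for dimensions 0..3 only")


def _uncorrected_p(u: float, fieldtype: str, dof) -> float:
    return ec_density(u, 0, fieldtype, dof)


def rft_peak_p(
    u: float,
    fieldtype: str,
    dof: tuple[float, ...],
    resels: np.ndarray,
    n_voxels: int | None = None,
) -> float:
    """FWER-corrected peak p-value: min(expected EC, Bonferroni, 1).

    The RFT part is sum_d R_d rho_d(u); when ``n_voxels`` is given the
    Bonferroni bound over the mask provides a validity floor at low
    smoothness.
    """
    resels = np.asarray(resels, dtype=float)
    if np.any(resels < 0):
        raise ValueError("resel counts must be non-negative")
    if not np.isfinite(u):
        raise ValueError("threshold must be finite")
    # the EC expansion only approximates P(max >= u) in its decreasing
    # tail; below a Gaussian-equivalent threshold of 2.5 freeze it at
    # that point so the reported p is monotone in u
    p_unc = _uncorrected_p(u, fieldtype, dof)
    u_floor = stats.norm.sf(2.5)
    u_eval = u
    if p_unc > u_floor:
        if fieldtype == "gaussian":
            u_eval = 2.5
        elif fieldtype == "t":
            u_eval = float(stats.t.isf(u_floor, *dof))
        else:
            u_eval = float(stats.f.isf(u_floor, *dof))
    p = sum(
        R * ec_density(u_eval, d, fieldtype, dof)
        for d, R in enumerate(resels)
    )
    # the maximum exceeds u whenever any fixed point does, so the
    # corrected p can never drop below the uncorrected tail
    p = min(1.0, max(p, p_unc))
    if n_voxels is not None:
        p = min(p, min(1.0, n_voxels * p_unc))
    return float(p)


def rft_corrected_threshold(
    alpha: float,
    fieldtype: str,
    dof: tuple[float, ...],
    resels: np.ndarray,
    n_voxels: int | None = None,
) -> float:
    """Statistic value whose corrected peak p equals alpha.

    The root is bracketed between the uncorrected threshold (where the
    corrected p is >= alpha) and the Bonferroni threshold (where it is
    <= alpha), which always encloses the min(RFT, Bonferroni) solution.
    """

    def f(u):
        return rft_peak_p(u, fieldtype, dof, resels, n_voxels) - alpha

    if fieldtype == "gaussian":
        isf = stats.norm.isf
    elif fieldtype == "t":
        def isf(q):
            return stats.t.isf(q, *dof)
    elif fieldtype == "F":
        def isf(q):
            return stats.f.isf(q, *dof)
    else:
        raise ValueError(f"unknown field type {fieldtype!r}")
    lo = isf(min(alpha, 0.5))
    if n_voxels is not None:
        hi = isf(alpha / n_voxels)
    else:
        hi = max(2.0 * lo, lo + 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
    if f(lo) <= 0:  # point-domain limit: uncorrected threshold suffices
        return float(lo)
    if f(hi) > 0:  # float round-off at the Bonferroni endpoint
        return float(hi)
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def bonferroni_threshold(
    alpha: float, fieldtype: str, dof: tuple[float, ...], n_voxels: int
) -> float:
    q = alpha / n_voxels
    if fieldtype == "gaussian":
        return float(stats.norm.isf(q))
    if fieldtype == "t":
        return float(stats.t.isf(q, *dof))
    if fieldtype == "F":
        return float(stats.f.isf(q, *dof))
    raise ValueError(f"unknown field type {fieldtype!r}")


def rft_cluster_p(
    k_voxels: float,
    u_c: float,
    fieldtype: str,
    dof: tuple[float, ...],
    smoothness: SmoothnessEstimate,
) -> float:
    """Cluster-level corrected p for a cluster of ``k_voxels`` voxels.

    Uses the Gaussian-field extent approximation: with E[m] clusters
    expected above the cluster-forming threshold and E[n] expected
    suprathreshold volume, cluster extents are modelled as
    P(extent >= k) = exp(-beta k_resels^(2/D)); the corrected p is
    1 - exp(-E[m] P(extent >= k)).  t and F thresholds are probit-
    transformed to the Gaussian scale first.
    """
    if u_c <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    if k_voxels < 0:
        raise ValueError("cluster extent must be >= 0")
    resels = smoothness.resels
    D = len(resels) - 1
    if fieldtype == "gaussian":
        u_g = float(u_c)
    else:
        u_g = float(stats.norm.isf(_uncorrected_p(u_c, fieldtype, dof)))
    Em = sum(R * ec_density(u_g, d, "gaussian") for d, R in enumerate(resels))
    if Em <= 0:
        return 0.0
    En_resels = resels[D] * stats.norm.sf(u_g)  # expected volume, resel units
    if En_resels <= 0:
        return 0.0
    k_resels = k_voxels / smoothness.resel_volume
    from scipy.special import gamma as gamma_fn

    beta = (gamma_fn(D / 2.0 + 1.0) * Em / En_resels) ** (2.0 / D)
    p_ext = np.exp(-beta * k_resels ** (2.0 / D))
    return float(1.0 - np.exp(-Em * p_ext))


# ---------------------------------------------------------------------------
# Topological report
# ---------------------------------------------------------------------------

def _local_maxima(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Indices of in-mask local maxima under 8- (2D) / 18- (3D) connectivity."""
    D = data.ndim
    footprint = ndimage.generate_binary_structure(D, 2)
    arr = np.where(mask, data, -np.inf)
    mx = ndimage.maximum_filter(arr, footprint=footprint, mode="constant",
                                cval=-np.inf)
    is_peak = mask & (arr >= mx) & np.isfinite(arr)
    return np.argwhere(is_peak)


def topological_report(
    img: StatImage,
    smoothness: SmoothnessEstimate,
    alpha: float = 0.05,
    window_mask: np.ndarray | None = None,
    cluster_forming_p: float = 0.001,
    max_rows: int = 20,
) -> pd.DataFrame:
    """Peak- and cluster-level corrected inference on a statistic image.

    Local maxima (8-connectivity in 2D, 18 in 3D, ties kept in
    first-index order) are assigned RFT/Bonferroni-corrected peak
    p-values; suprathreshold clusters at the ``cluster_forming_p``
    uncorrected threshold are assigned cluster-extent p-values.  When a
    window mask is supplied the search — and the resel counts — are
    restricted to it.  Rows are sorted by corrected peak p ascending;
    ``significant`` flags rows at or below ``alpha``.
    """
    if img.field is None:
        raise ValueError("image lacks statistical field metadata")
    fieldtype = "gaussian" if img.field.lower() in ("gaussian", "z") else img.field
    dof = tuple(img.dof or ())
    data = img.data
    mask = np.isfinite(data)
    if window_mask is not None:
        window_mask = np.asarray(window_mask, dtype=bool)
        if window_mask.shape != data.shape:
            raise ValueError("window mask shape mismatch")
        if not (mask & window_mask).any():
            raise ValueError("window mask is disjoint from the analysis mask")
        mask = mask & window_mask
    resels = resel_counts(mask, smoothness.fwhm)
    n_vox = int(mask.sum())
    sm = SmoothnessEstimate(smoothness.fwhm, resels, n_vox)

    # cluster-forming threshold on the statistic's own scale
    if fieldtype == "gaussian":
        u_c = float(stats.norm.isf(cluster_forming_p))
    elif fieldtype == "t":
        u_c = float(stats.t.isf(cluster_forming_p, *dof))
    else:
        u_c = float(stats.f.isf(cluster_forming_p, *dof))
    structure = ndimage.generate_binary_structure(data.ndim, 2)
    supra = mask & (np.nan_to_num(data, nan=-np.inf) >= u_c)
    labels, _ = ndimage.label(supra, structure=structure)

    peaks = _local_maxima(data, mask)
    rows = []
    for idx in peaks:
        tidx = tuple(idx)
        u = float(data[tidx])
        p_unc = _uncorrected_p(u, fieldtype, dof)
        p_peak = rft_peak_p(u, fieldtype, dof, resels, n_vox)
        lab = labels[tidx]
        if lab > 0:
            k = int(np.sum(labels == lab))
            p_clu = rft_cluster_p(k, u_c, fieldtype, dof, sm)
        else:
            k, p_clu = 0, np.nan
        coords = [
            img.axis_origins[d] + idx[d] * img.axis_scales[d]
            for d in range(data.ndim)
        ]
        coords += [np.nan] * (3 - len(coords))
        rows.append(
            {
                "peak_x": coords[0], "peak_y": coords[1], "peak_z": coords[2],
                "stat": u, "p_peak_corrected": p_peak, "cluster_k": k,
                "p_cluster_corrected": p_clu, "p_uncorrected": p_unc,
                "significant": bool(p_peak <= alpha),
            }
        )
    table = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    table = table.sort_values(
        ["p_peak_corrected", "p_uncorrected"], kind="stable"
    ).reset_index(drop=True)
    if max_rows is not None:
        keep = table["significant"] | (np.arange(len(table)) < max_rows)
        table = table[keep].reset_index(drop=True)
    return table
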