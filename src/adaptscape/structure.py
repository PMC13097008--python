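"""Population structure diagnostics and genotype-environment association.

Covers PCA of the dosage matrix, Haversine geographic distances, Mantel /
partial Mantel tests (isolation by distance / by environment), redundancy
analysis (RDA) with optional conditioning (partial RDA), variance
partitioning of genetic variation into climate / geography / structure
components, and pRDA-based detection of candidate adaptive loci via
Mahalanobis distances of locus loadings on the significant constrained axes,
with genomic-inflation-factor recalibration and a Bonferroni threshold of
alpha = 0.01 / n_loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# PCA and distances


@dataclass
class PCAResult:
    scores: np.ndarray            # individuals x axes
    explained_fraction: np.ndarray
    loadings: np.ndarray          # loci x axes

    def __post_init__(self) -> None:
        ef = np.asarray(self.explained_fraction)
        if np.any(np.diff(ef) > 1e-10):
            raise ValueError("explained fractions must be non-increasing")
        if ef.sum() > 1 + 1e-8:
            raise ValueError("explained fractions sum above 1")


def pca_genotypes(dosages: np.ndarray, n_axes: int | None = None) -> PCAResult:
    """Column-centered PCA of an imputed dosage matrix (no missing values)."""
    Y = np.asarray(dosages, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("PCA requires an imputed matrix (no missing values)")
    Yc = Y - Y.mean(axis=0)
    U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
    total = (S ** 2).sum()
    if total == 0:
        raise ValueError("zero total variance")
    k = n_axes or len(S)
    return PCAResult(
        scores=U[:, :k] * S[:k],
        explained_fraction=(S[:k] ** 2) / total,
        loadings=Vt[:k].T,
    )


def haversine_matrix(coords: pd.DataFrame) -> np.ndarray:
    """Pairwise great-circle distances (km) from lon/lat columns in degrees."""
    lon = np.radians(coords["lon"].to_numpy(float))
    lat = np.radians(coords["lat"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# Mantel tests


@dataclass
class MantelResult:
    statistic: float
    n_perm: int
    p_value: float
    partial: bool = False

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.statistic <= 1 + 1e-9:
            raise ValueError("Mantel r outside [-1, 1]")
        if self.p_value < 1 / (self.n_perm + 1) - 1e-12:
            raise ValueError("p-value below permutation resolution")


def _check_square(*mats: np.ndarray) -> int:
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("distance matrices must be square and equally sized")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("distance matrices must be symmetric")
    return n


def _tril(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel(
    dA: np.ndarray,
    dB: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided Mantel test: Pearson r of lower triangles, permutation p.

    Rows/columns of ``dB`` are shuffled jointly; p = (#perm r >= observed + 1)
    / (n_perm + 1).
    """
    n = _check_square(np.asarray(dA, float), np.asarray(dB, float))
    a, b = _tril(np.asarray(dA, float)), _tril(np.asarray(dB, float))
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = _tril(np.asarray(dB, float)[np.ix_(perm, perm)])
        if np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        statistic=r_obs, n_perm=n_perm, p_value=(count + 1) / (n_perm + 1)
    )


def partial_mantel(
    dA: np.ndarray,
    dB: np.ndarray,
    dC: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel: correlation of dA and dB residuals after regressing
    each lower triangle on dC's; permutation shuffles dA's rows/columns."""
    n = _check_square(np.asarray(dA, float), np.asarray(dB, float), np.asarray(dC, float))
    c = _tril(np.asarray(dC, float))
    X = np.column_stack([np.ones_like(c), c])

    def resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ beta

    rb = resid(_tril(np.asarray(dB, float)))
    ra = resid(_tril(np.asarray(dA, float)))
    r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    A = np.asarray(dA, float)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rap = resid(_tril(A[np.ix_(perm, perm)]))
        if np.corrcoef(rap, rb)[0, 1] >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        statistic=r_obs, n_perm=n_perm, p_value=(count + 1) / (n_perm + 1),
        partial=True,
    )


# ---------------------------------------------------------------------------
# Redundancy analysis


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of (centered) M after least-squares regression on [1, Z]."""
    Z1 = np.column_stack([np.ones(len(M)), Z])
    beta, *_ = np.linalg.lstsq(Z1, M, rcond=None)
    return M - Z1 @ beta


@dataclass
class RDAResult:
    """Constrained ordination of a response matrix on predictors.

    ``axis_coefs`` maps a (centered, conditioned) predictor vector to axis
    scores: score_k = x . axis_coefs[:, k].  ``loadings`` are the response
    (locus) loadings on the constrained axes; ``eigenvalues`` the constrained
    axis variances.
    """

    eigenvalues: np.ndarray
    axis_coefs: np.ndarray        # predictors x axes
    loadings: np.ndarray          # loci x axes
    site_scores: np.ndarray       # samples x axes (linear constraints)
    total_variance: float
    constrained_variance: float
    x_mean: np.ndarray

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


def _predictor_basis(Xres: np.ndarray, scale_ref: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal basis of the effective predictor space.

    Directions whose singular value is negligible relative to the
    pre-conditioning predictor scale are dropped: they are numerical residue
    of the conditioning (e.g. Z identical to X) and must not absorb variance.
    """
    Ux, Sx, Vtx = np.linalg.svd(Xres, full_matrices=False)
    keep = Sx > 1e-9 * max(scale_ref, 1e-300)
    return Ux[:, keep], Sx[keep], Vtx[keep]


def rda_fit(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    tol: float = 1e-12,
) -> RDAResult:
    """(Partial) redundancy analysis of Y on X, conditioning on Z.

    Y is column-centered; with Z given, both Y and X are replaced by their
    residuals on Z before the constrained ordination.  Axes come from the SVD
    of the fitted values of the multivariate regression of Y on X (computed
    by orthogonal projection onto the effective predictor space, so predictor
    directions wiped out by the conditioning carry no variance).
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    if len(Y) != len(X) or (Z is not None and len(Z) != len(Y)):
        raise ValueError("Y, X and Z must have aligned rows")
    n = len(Y)
    Yc = _center(Y)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    scale_ref = float(np.linalg.norm(Xc, 2)) if Xc.size else 0.0
    if Z is not None and np.asarray(Z).size:
        Z = np.asarray(Z, float)
        Yc = _residualize(Yc, Z)
        Xc = _residualize(Xc, Z)

    Ux, Sx, Vtx = _predictor_basis(Xc, scale_ref)
    fitted = Ux @ (Ux.T @ Yc)
    # beta solves Xres beta = fitted in least squares
    beta = Vtx.T @ np.diag(1.0 / Sx) @ (Ux.T @ Yc) if len(Sx) else np.zeros((X.shape[1], Y.shape[1]))
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = S ** 2 / (n - 1)
    keep = eig > tol * max(eig.max(initial=0.0), 1.0)
    U, S, Vt, eig = U[:, keep], S[keep], Vt[keep], eig[keep]
    total = float((Yc ** 2).sum() / (n - 1))
    return RDAResult(
        eigenvalues=eig,
        axis_coefs=beta @ Vt.T,
        loadings=Vt.T,
        site_scores=U * S,
        total_variance=total,
        constrained_variance=float(eig.sum()),
        x_mean=x_mean,
    )


def _constrained_variance(
    Yres: np.ndarray, Xres: np.ndarray, scale_ref: float | None = None
) -> float:
    if scale_ref is None:
        scale_ref = float(np.linalg.norm(Xres, 2))
    Ux, *_ = _predictor_basis(Xres, scale_ref)
    fitted = Ux @ (Ux.T @ Yres)
    return float((fitted ** 2).sum() / (len(Yres) - 1))


def _permutation_p(
    Yres: np.ndarray,
    Xres: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    scale_ref: float | None = None,
) -> float:
    """Permutation p for the constrained variance of Yres ~ Xres."""
    obs = _constrained_variance(Yres, Xres, scale_ref)
    count = 0
    for _ in range(n_perm):
        Xp = Xres[rng.permutation(len(Xres))]
        if _constrained_variance(Yres, Xp, scale_ref) >= obs - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


@dataclass
class VariancePartition:
    """Fractions of total genetic variance by predictor group (Table-style)."""

    fractions: dict[str, float]
    p_values: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-6:
            raise ValueError("variance fractions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": k, "fraction": v, "p_value": self.p_values.get(k, np.nan)}
            for k, v in self.fractions.items()
        ]
        return pd.DataFrame(rows)


def geography_matrix(coords: pd.DataFrame) -> np.ndarray:
    """Geographic predictors: standardized lat, lon and their product."""
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    lat = (lat - lat.mean()) / lat.std()
    lon = (lon - lon.mean()) / lon.std()
    return np.column_stack([lat, lon, lat * lon])


def variance_partition(
    Y: np.ndarray,
    climate: np.ndarray,
    geography: np.ndarray,
    structure: np.ndarray,
    n_perm: int = 99,
    seed: int | None = None,
) -> VariancePartition:
    """Partition genetic variance into climate / geography / structure.

    Fits the full model on all predictor groups jointly, then each group's
    unique contribution as a partial RDA conditioned on the other two; the
    confounded (joint) fraction is the remainder of the explained variance.
    Permutation p-values test each constrained variance by row permutation of
    the (residualized) predictors.
    """
    Y = _center(np.asarray(Y, float))
    groups = {
        "climate": np.asarray(climate, float),
        "geography": np.asarray(geography, float),
        "structure": np.atleast_2d(np.asarray(structure, float).T).T,
    }
    rng = np.random.default_rng(seed)
    total = float((Y ** 2).sum() / (len(Y) - 1))
    X_full = np.column_stack(list(groups.values()))
    full = _constrained_variance(Y, _center(X_full))
    p_full = _permutation_p(Y, _center(X_full), n_perm, rng)

    fractions: dict[str, float] = {}
    p_values: dict[str, float] = {"full": p_full}
    for name, X in groups.items():
        others = np.column_stack([g for k, g in groups.items() if k != name])
        Xc = _center(X)
        scale_ref = float(np.linalg.norm(Xc, 2))
        Yres = _residualize(Y, others)
        Xres = _residualize(Xc, others)
        unique = _constrained_variance(Yres, Xres, scale_ref)
        fractions[name] = unique / total
        p_values[name] = _permutation_p(Yres, Xres, n_perm, rng, scale_ref)
    confounded = full / total - sum(fractions.values())
    fractions["confounded"] = confounded
    fractions["unexplained"] = 1.0 - full / total
    return VariancePartition(fractions=fractions, p_values=p_values)


# ---------------------------------------------------------------------------
# pRDA outlier detection


@dataclass
class OutlierResult:
    """Candidate adaptive loci from partial RDA loadings.

    p-values come from Mahalanobis distances of the (scaled) locus loadings
    on the retained constrained axes, recalibrated by the genomic inflation
    factor and referred to a chi-squared distribution with df = retained axes.
    """

    retained_axes: int
    locus_scores: np.ndarray
    mahalanobis_d2: np.ndarray
    gif: float
    p_values: np.ndarray
    alpha: float
    outlier_ids: list[str]
    axis_p_values: np.ndarray = field(default_factory=lambda: np.array([]))
    locus_ids: list[str] = field(default_factory=list)

    def to_frame(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "locus_id": self.locus_ids,
            "mahalanobis_d2": self.mahalanobis_d2,
            "p_value": self.p_values,
            "outlier": [l in set(self.outlier_ids) for l in self.locus_ids],
        })
        if variants is not None:
            df = df.merge(
                variants[["id", "chrom", "pos"]], left_on="locus_id", right_on="id",
                how="left",
            ).drop(columns="id")
        return df


def _axis_eigenvalues(Yres: np.ndarray, Xres: np.ndarray, k: int) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Xres, Yres, rcond=None)
    s = np.linalg.svd(Xres @ beta, compute_uv=False)
    eig = np.zeros(k)
    m = min(k, len(s))
    eig[:m] = s[:m] ** 2 / (len(Yres) - 1)
    return eig


def prda_outliers(
    Y: np.ndarray,
    climate: np.ndarray,
    condition: np.ndarray | None,
    locus_ids: Sequence[str] | None = None,
    alpha_scale: float = 0.01,
    n_axis_perm: int = 250,
    axis_test_subset: int = 100_000,
    axis_alpha: float = 0.05,
    max_axes: int | None = None,
    seed: int | None = None,
) -> OutlierResult:
    """Detect candidate adaptive SNPs with a partial RDA of Y on climate.

    Procedure: fit climate | condition pRDA; test each constrained axis by
    permutation (``n_axis_perm`` permutations on a random subset of at most
    ``axis_test_subset`` loci) and retain the leading axes significant at
    ``axis_alpha`` (optionally capped at ``max_axes``); z-scale each locus's
    loadings on the retained axes and
    take the Mahalanobis distance (sum of squared z-scores); divide by the
    genomic inflation factor (median d2 over the chi-squared median with
    df = retained axes); convert to chi-squared p-values.  Outliers are loci
    with p below the Bonferroni threshold ``alpha_scale / n_loci``.
    """
    Y = np.asarray(Y, float)
    if np.isnan(Y).any():
        raise ValueError("Y must be imputed (no missing values)")
    n, n_loci = Y.shape
    locus_ids = list(locus_ids) if locus_ids is not None else [f"locus_{j}" for j in range(n_loci)]
    rng = np.random.default_rng(seed)

    Yc = _center(Y)
    Xc = _center(np.asarray(climate, float))
    if condition is not None and np.asarray(condition).size:
        Z = np.asarray(condition, float)
        Yres = _residualize(Yc, Z)
        Xres = _residualize(Xc, Z)
    else:
        Yres, Xres = Yc, Xc

    # axis significance by permutation on a loci subset
    if n_loci > axis_test_subset:
        sub = rng.choice(n_loci, size=axis_test_subset, replace=False)
        Ysub = Yres[:, sub]
    else:
        Ysub = Yres
    k_max = min(Xres.shape[1], n - 1, Ysub.shape[1])
    obs_eig = _axis_eigenvalues(Ysub, Xres, k_max)
    exceed = np.zeros(k_max)
    for _ in range(n_axis_perm):
        Xp = Xres[rng.permutation(n)]
        exceed += _axis_eigenvalues(Ysub, Xp, k_max) >= obs_eig - 1e-15
    axis_p = (exceed + 1) / (n_axis_perm + 1)
    retained = 0
    for p in axis_p:  # leading run of significant axes
        if p < axis_alpha:
            retained += 1
        else:
            break
    if max_axes is not None:
        retained = min(retained, max_axes)

    alpha = alpha_scale / n_loci
    # with zero significant axes the outlier set is empty, but the Mahalanobis
    # machinery still runs on the leading axes as a calibration diagnostic
    k_score = retained if retained > 0 else min(max_axes or k_max, k_max)
    fit = rda_fit(Yres, Xres)
    k_score = min(k_score, fit.loadings.shape[1])
    V = fit.loadings[:, :k_score]
    z = (V - V.mean(axis=0)) / V.std(axis=0, ddof=1)
    d2 = (z ** 2).sum(axis=1)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, df=k_score))
    p_values = stats.chi2.sf(d2 / gif, df=k_score)
    if retained == 0:
        logger.warning("no significant constrained axes; returning empty outlier set")
        outliers: list[str] = []
        p_values = np.ones(n_loci)
    else:
        outliers = [locus_ids[j] for j in np.flatnonzero(p_values < alpha)]
    return OutlierResult(
        retained_axes=retained, locus_scores=V, mahalanobis_d2=d2, gif=gif,
        p_values=p_values, alpha=alpha, outlier_ids=outliers,
        axis_p_values=axis_p, locus_ids=locus_ids,
    )
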