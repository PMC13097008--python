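"""Genomic-offset engines: gradient forest, RDA adaptive index, and GDM.

Each engine is fitted on candidate adaptive loci against the standardized
climate at the sampled individuals (or sites), and exposes:

* ``embed(climate)``   — map a cells x variables table into the engine's
  adaptive-composition space;
* ``pair_offset(E1, E2)`` — offsets between two embedded sets of cells;
* ``offset(grid_now, grid_future)`` — the per-cell genomic offset between a
  cell's current and future climate, wrapped in an
  :class:`AdaptednessSurface` with adaptedness = -1 x offset.

The engines differ in how they build the climate -> composition map: gradient
forest aggregates split importances of per-locus random forests into monotone
cumulative-importance turnover curves; the RDA engine projects climate onto
the constrained-axis coefficients, weighting axes by their eigenvalue share;
GDM regresses pairwise genetic dissimilarity on I-spline-transformed climate
differences under a 1 - exp(-eta) link with non-negative coefficients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cdist

from .climate import ClimateGrid
from .structure import rda_fit

logger = logging.getLogger(__name__)


@dataclass
class AdaptednessSurface:
    """Per-cell offset and adaptedness for one (current, future) scenario pair.

    Adaptedness is defined as -1 x genomic offset: 0 is a perfect predicted
    match to future climate, more negative means more predicted maladaptation.
    """

    current: str
    future: str
    method: str
    table: pd.DataFrame  # index cell_id, columns offset, adaptedness

    def __post_init__(self) -> None:
        t = self.table
        if (t["offset"] < -1e-12).any():
            raise ValueError("offset must be non-negative")
        if not np.allclose(t["adaptedness"], -t["offset"], atol=1e-12):
            raise ValueError("adaptedness must equal -1 x offset")

    @classmethod
    def from_offsets(
        cls, cell_ids, offsets: np.ndarray, current: str, future: str, method: str
    ) -> "AdaptednessSurface":
        offsets = np.maximum(np.asarray(offsets, float), 0.0)
        table = pd.DataFrame(
            {"offset": offsets, "adaptedness": -offsets},
            index=pd.Index(cell_ids, name="cell_id"),
        )
        return cls(current=current, future=future, method=method, table=table)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, float_format="%.10g")
        return path


def _clamp_to_range(
    table: pd.DataFrame, lo: pd.Series, hi: pd.Series, method: str
) -> pd.DataFrame:
    clamped = table.clip(lower=lo, upper=hi, axis=1)
    n = int((clamped != table).to_numpy().sum())
    if n:
        logger.info("%s: clamped %d out-of-range climate values to the fitted range", method, n)
    return clamped


# ---------------------------------------------------------------------------
# Gradient forest


@dataclass
class GradientForestModel:
    """Monotone cumulative-importance turnover curves per climate variable.

    ``curves[v]`` is a pair (breakpoints, cumulative values): the cumulative
    R2-weighted, density-standardized split importance along variable v.  The
    curve is 0 at or below the variable's observed minimum and flat beyond its
    maximum; its total height is the variable's overall importance.
    """

    variables: tuple[str, ...]
    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    locus_r2: pd.Series
    retained_loci: list[str]
    importance: pd.Series
    params: dict = field(default_factory=dict)
    method: str = "gf"

    def __post_init__(self) -> None:
        for v, (bp, cum) in self.curves.items():
            if np.any(np.diff(cum) < -1e-12):
                raise ValueError(f"cumulative curve for {v} must be non-decreasing")

    def transform(self, climate: pd.DataFrame) -> pd.DataFrame:
        """Evaluate each variable's turnover curve at the input values.

        Left-continuous step evaluation: the value at x is the total binned
        importance of bins whose right edge is <= x; inputs beyond the fitted
        range clamp to the curve's end values.
        """
        out = {}
        for v in self.variables:
            bp, cum = self.curves[v]
            x = climate[v].to_numpy(float)
            idx = np.searchsorted(bp[1:], x, side="right")
            out[v] = np.concatenate([[0.0], cum])[np.clip(idx, 0, len(cum))]
        return pd.DataFrame(out, index=climate.index)

    def embed(self, climate: pd.DataFrame) -> np.ndarray:
        return self.transform(climate[list(self.variables)]).to_numpy()

    def pair_offset(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        return cdist(E1, E2, metric="euclidean")

    def offset(self, grid_now: ClimateGrid, grid_future: ClimateGrid) -> AdaptednessSurface:
        if not np.array_equal(grid_now.cell_ids, grid_future.cell_ids):
            raise ValueError("current and future grids must share cells")
        e1 = self.embed(grid_now.values())
        e2 = self.embed(grid_future.values())
        off = np.linalg.norm(e1 - e2, axis=1)
        return AdaptednessSurface.from_offsets(
            grid_now.cell_ids, off, grid_now.scenario.label,
            grid_future.scenario.label, self.method,
        )

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "method": self.method,
            "variables": list(self.variables),
            "curves": {
                v: {"breakpoints": bp.tolist(), "cumulative": cum.tolist()}
                for v, (bp, cum) in self.curves.items()
            },
            "importance": self.importance.to_dict(),
            "locus_r2": self.locus_r2.to_dict(),
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload))
        return Path(path)


def _tree_split_importances(tree, n_features: int) -> list[tuple[int, float, float]]:
    """(feature, threshold, impurity decrease) for each internal node."""
    t = tree.tree_
    out = []
    w = t.weighted_n_node_samples / t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        dec = w[node] * t.impurity[node] - w[left] * t.impurity[left] - w[right] * t.impurity[right]
        if dec > 0:
            out.append((int(t.feature[node]), float(t.threshold[node]), float(dec)))
    return out


def fit_gradient_forest(
    allele_data: pd.DataFrame,
    climate_at_samples: pd.DataFrame,
    n_trees: int = 500,
    n_bins: int = 101,
    density_floor: float = 1e-6,
    max_features: float | int | str | None = None,
    min_samples_leaf: int = 15,
    seed: int | None = None,
) -> GradientForestModel:
    """Fit per-locus regression forests and aggregate turnover curves.

    Parameters
    ----------
    allele_data
        Samples x loci dosages (or site x loci allele frequencies).
    climate_at_samples
        Samples x variables standardized climate, row-aligned.

    For every locus a random forest regresses the allele value on climate;
    loci with positive out-of-bag R2 contribute their split impurity
    reductions, normalized per locus and weighted by R2.  Per variable, split
    importances are binned along the observed range, standardized by the
    density of observed values (ratio capped by ``density_floor``, then
    rescaled to preserve the total), and accumulated into a monotone
    cumulative-importance curve.
    """
    from sklearn.ensemble import RandomForestRegressor

    X = climate_at_samples.to_numpy(float)
    variables = tuple(climate_at_samples.columns)
    if X.shape[1] < 2:
        raise ValueError("need at least two climate variables")
    if len(X) < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)

    r2: dict[str, float] = {}
    splits: dict[str, list[tuple[int, float, float]]] = {}
    for locus in allele_data.columns:
        y = allele_data[locus].to_numpy(float)
        if np.allclose(y, y[0]):
            r2[locus] = 0.0
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,  # dosages are noisy; small
            # leaves would spend split importance on binomial noise
            oob_score=True,
            bootstrap=True,
            random_state=int(rng.integers(2 ** 31 - 1)),
            n_jobs=1,
        )
        forest.fit(X, y)
        r2[locus] = float(forest.oob_score_)
        if r2[locus] > 0:
            locus_splits: list[tuple[int, float, float]] = []
            for tree in forest.estimators_:
                locus_splits.extend(_tree_split_importances(tree, X.shape[1]))
            splits[locus] = locus_splits

    locus_r2 = pd.Series(r2, name="oob_r2")
    retained = [l for l in allele_data.columns if r2[l] > 0]
    if not retained:
        raise ValueError("no predictive loci: all out-of-bag R2 <= 0")

    # R2-weighted aggregation of per-locus normalized split importances
    agg: dict[int, list[tuple[float, float]]] = {i: [] for i in range(len(variables))}
    for locus in retained:
        total = sum(d for _, _, d in splits[locus])
        if total <= 0:
            continue
        w = r2[locus] / total
        for feat, thr, dec in splits[locus]:
            agg[feat].append((thr, dec * w))

    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    importance: dict[str, float] = {}
    for i, v in enumerate(variables):
        lo, hi = float(X[:, i].min()), float(X[:, i].max())
        edges = np.linspace(lo, hi, n_bins + 1)
        imp = np.zeros(n_bins)
        if agg[i]:
            thr = np.array([t for t, _ in agg[i]])
            dec = np.array([d for _, d in agg[i]])
            bins = np.clip(np.searchsorted(edges, thr, side="right") - 1, 0, n_bins - 1)
            np.add.at(imp, bins, dec)
        total = imp.sum()
        if total > 0:
            dens, _ = np.histogram(X[:, i], bins=edges)
            dens = dens / dens.sum()
            ratio = imp / np.maximum(dens, density_floor)
            imp = ratio * (total / ratio.sum())
        curves[v] = (edges, np.cumsum(imp))
        importance[v] = float(total)

    return GradientForestModel(
        variables=variables,
        curves=curves,
        locus_r2=locus_r2,
        retained_loci=retained,
        importance=pd.Series(importance).sort_values(ascending=False),
        params={
            "n_trees": n_trees, "n_bins": n_bins, "max_features": max_features,
            "min_samples_leaf": min_samples_leaf,
            "density_floor": density_floor, "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# RDA adaptive index


@dataclass
class RDAOffsetModel:
    """Linear adaptive index from the constrained axes of an RDA.

    The index of a climate vector on axis k is its dot product with the
    axis-k climate coefficients; the offset between two climate vectors is
    the eigenvalue-weighted Euclidean distance between their index vectors.
    """

    variables: tuple[str, ...]
    axis_coefs: np.ndarray   # variables x retained axes
    weights: np.ndarray      # eigenvalue fractions over retained axes, sum 1
    x_mean: np.ndarray
    clamp_lo: pd.Series | None = None
    clamp_hi: pd.Series | None = None
    params: dict = field(default_factory=dict)
    method: str = "rda"

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("axis weights must be positive and sum to 1")

    def adaptive_index(self, climate: pd.DataFrame) -> np.ndarray:
        Xc = climate[list(self.variables)].to_numpy(float) - self.x_mean
        return Xc @ self.axis_coefs

    def embed(self, climate: pd.DataFrame) -> np.ndarray:
        # scaling by sqrt(weight) turns the weighted offset into Euclidean
        return self.adaptive_index(climate) * np.sqrt(self.weights)

    def pair_offset(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        return cdist(E1, E2, metric="euclidean")

    def offset(self, grid_now: ClimateGrid, grid_future: ClimateGrid) -> AdaptednessSurface:
        if not np.array_equal(grid_now.cell_ids, grid_future.cell_ids):
            raise ValueError("current and future grids must share cells")
        e1, e2 = self.embed(grid_now.values()), self.embed(grid_future.values())
        off = np.linalg.norm(e1 - e2, axis=1)
        return AdaptednessSurface.from_offsets(
            grid_now.cell_ids, off, grid_now.scenario.label,
            grid_future.scenario.label, self.method,
        )


def fit_rda_offset(
    allele_data: pd.DataFrame,
    climate_at_samples: pd.DataFrame,
    condition: np.ndarray | None = None,
    n_axes: int = 2,
) -> RDAOffsetModel:
    """RDA of candidate loci on climate; retain ``n_axes`` leading axes.

    The retained-axis count conventionally matches the number of constrained
    axes found significant during outlier detection (two in the analysis this
    package reproduces).
    """
    fit = rda_fit(
        allele_data.to_numpy(float), climate_at_samples.to_numpy(float), condition
    )
    k = min(n_axes, len(fit.eigenvalues))
    if k == 0:
        raise ValueError("RDA has no constrained axes")
    eig = fit.eigenvalues[:k]
    return RDAOffsetModel(
        variables=tuple(climate_at_samples.columns),
        axis_coefs=fit.axis_coefs[:, :k],
        weights=eig / eig.sum(),
        x_mean=fit.x_mean,
        params={"n_axes": k},
    )


# ---------------------------------------------------------------------------
# Generalized dissimilarity modelling


def _tent_integral(x: np.ndarray, l: float, p: float, r: float) -> np.ndarray:
    """Normalized integral of a tent density with support [l, r], peak p."""
    span = r - l
    out = np.zeros_like(x)
    if p > l:
        rising = (x > l) & (x <= p)
        out[rising] = (x[rising] - l) ** 2 / ((p - l) * span)
    if r > p:
        falling = (x > p) & (x < r)
        out[falling] = 1.0 - (r - x[falling]) ** 2 / ((r - p) * span)
    out[x >= r] = 1.0
    return out


def ispline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Monotone I-spline basis on [knots[0], knots[-1]], one column per knot.

    Order-2 I-splines: each basis function is the normalized integral of a
    tent (degree-1 M-spline) density peaking at its knot, so every column is
    piecewise quadratic, non-decreasing, 0 at the lower bound and 1 at the
    upper.  Values outside the knot span clamp to 0/1.
    """
    knots = np.asarray(knots, float)
    if len(knots) < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing, length >= 2")
    x = np.clip(np.asarray(x, float), knots[0], knots[-1])
    cols = []
    for i, p in enumerate(knots):
        l = knots[max(i - 1, 0)]
        r = knots[min(i + 1, len(knots) - 1)]
        cols.append(_tent_integral(x, float(l), float(p), float(r)))
    return np.column_stack(cols)


@dataclass
class GDMModel:
    """Generalized dissimilarity model with non-negative I-spline coefficients.

    Predicted dissimilarity between climates a and b is
    ``1 - exp(-(intercept?) - sum_b c_b |I_b(a) - I_b(b)|)``; the intercept
    captures between-site sampling turnover and is excluded from the
    within-cell current -> future offset prediction so that identical
    climates always give offset 0.
    """

    variables: tuple[str, ...]
    knots: dict[str, np.ndarray]
    coefs: dict[str, np.ndarray]
    intercept: float
    deviance_explained: float
    params: dict = field(default_factory=dict)
    method: str = "gdm"

    def __post_init__(self) -> None:
        if self.intercept < -1e-12:
            raise ValueError("intercept must be non-negative")
        for v, c in self.coefs.items():
            if np.any(np.asarray(c) < -1e-12):
                raise ValueError(f"negative spline coefficient for {v}")

    def _basis(self, climate: pd.DataFrame) -> np.ndarray:
        cols = []
        for v in self.variables:
            cols.append(ispline_basis(climate[v].to_numpy(float), self.knots[v]))
        return np.column_stack(cols)

    def _coef_vector(self) -> np.ndarray:
        return np.concatenate([self.coefs[v] for v in self.variables])

    def embed(self, climate: pd.DataFrame) -> np.ndarray:
        # coefficient-scaled basis: city-block distance then gives eta
        return self._basis(climate) * self._coef_vector()

    def pair_offset(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        eta = cdist(E1, E2, metric="cityblock")
        return 1.0 - np.exp(-eta)

    def predict_dissimilarity(
        self, climate_a: pd.DataFrame, climate_b: pd.DataFrame,
        include_intercept: bool = True,
    ) -> np.ndarray:
        """Row-wise predicted dissimilarity between two aligned climate tables."""
        eta = np.abs(self.embed(climate_a) - self.embed(climate_b)).sum(axis=1)
        if include_intercept:
            eta = eta + self.intercept
        return 1.0 - np.exp(-eta)

    def offset(self, grid_now: ClimateGrid, grid_future: ClimateGrid) -> AdaptednessSurface:
        if not np.array_equal(grid_now.cell_ids, grid_future.cell_ids):
            raise ValueError("current and future grids must share cells")
        off = self.predict_dissimilarity(
            grid_now.values(), grid_future.values(), include_intercept=False
        )
        return AdaptednessSurface.from_offsets(
            grid_now.cell_ids, off, grid_now.scenario.label,
            grid_future.scenario.label, self.method,
        )


def site_allele_frequencies(
    dosages: np.ndarray, sites: Sequence[str], locus_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-site alternate allele frequencies from (imputed) dosages."""
    df = pd.DataFrame(dosages, columns=list(locus_ids))
    df["site"] = list(sites)
    return df.groupby("site").mean() / 2.0


def genetic_dissimilarity(site_freqs: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distance between site allele-frequency rows,
    rescaled into [0, 1)."""
    F = site_freqs.to_numpy(float)
    d = cdist(F, F, metric="euclidean")
    mx = d.max()
    if mx > 0:
        d = d / (mx * (1 + 1e-9))
    return d


def fit_gdm(
    site_allele_freqs: pd.DataFrame,
    site_climate: pd.DataFrame,
    n_knots: int = 3,
    max_iter: int = 100,
    tol: float = 1e-10,
    response: np.ndarray | None = None,
) -> GDMModel:
    """Fit a GDM of pairwise genetic dissimilarity on climate differences.

    Knots sit at the min / interior quantiles / max of each variable over
    sites (3 knots: min, median, max).  The response is the pairwise
    Euclidean allele-frequency distance rescaled to [0, 1); the linear
    predictor is eta = intercept + sum of coefficient-weighted I-spline
    difference terms, with dissimilarity = 1 - exp(-eta).  Coefficients and
    intercept are constrained non-negative and estimated by iterated
    non-negative least squares on the working linearization of the link
    (Gauss-Newton); non-convergence raises with the deviance trace.
    """
    if len(site_allele_freqs) < 4:
        raise ValueError("GDM needs at least 4 sites")
    if not site_allele_freqs.index.equals(site_climate.index):
        site_climate = site_climate.loc[site_allele_freqs.index]
    variables = tuple(site_climate.columns)

    knots: dict[str, np.ndarray] = {}
    basis_cols: dict[str, np.ndarray] = {}
    for v in variables:
        vals = site_climate[v].to_numpy(float)
        qs = np.linspace(0, 1, n_knots)
        kn = np.quantile(vals, qs)
        kn = np.unique(kn)
        if len(kn) < 2:
            raise ValueError(f"variable {v} has no spread across sites")
        knots[v] = kn
        basis_cols[v] = ispline_basis(vals, kn)

    n_sites = len(site_allele_freqs)
    iu, ju = np.triu_indices(n_sites, k=1)
    if response is None:
        d = genetic_dissimilarity(site_allele_freqs)
    else:
        d = np.asarray(response, float)
        if d.shape != (n_sites, n_sites):
            raise ValueError("response must be a square site dissimilarity matrix")
    y = d[iu, ju]

    X = np.column_stack([
        np.abs(basis_cols[v][iu] - basis_cols[v][ju]) for v in variables
    ])
    n_coef_per_var = {v: basis_cols[v].shape[1] for v in variables}
    A = np.column_stack([np.ones(len(y)), X])

    # initialization: the link is linear in eta = -log(1 - y)
    z0 = -np.log(np.clip(1.0 - y, 1e-12, None))
    theta, _ = nnls(A, z0)
    trace = []
    converged = False
    for _ in range(max_iter):
        eta = A @ theta
        mu = 1.0 - np.exp(-eta)
        resid = y - mu
        trace.append(float((resid ** 2).sum()))
        g = np.exp(-eta)  # d mu / d eta
        w = np.clip(g, 1e-8, None)
        z = eta + resid / w
        sw = np.sqrt(w)
        theta_new, _ = nnls(A * sw[:, None], z * sw)
        if np.max(np.abs(theta_new - theta)) < tol:
            theta = theta_new
            converged = True
            break
        theta = theta_new
    if not converged:
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < 1e-12:
            converged = True
        else:
            raise RuntimeError(f"GDM did not converge; deviance trace: {trace}")

    eta = A @ theta
    mu = 1.0 - np.exp(-eta)
    rss = float(((y - mu) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    deviance_explained = 1.0 - rss / tss if tss > 0 else 1.0

    coefs: dict[str, np.ndarray] = {}
    pos = 1
    for v in variables:
        k = n_coef_per_var[v]
        coefs[v] = theta[pos:pos + k]
        pos += k
    return GDMModel(
        variables=variables, knots=knots, coefs=coefs,
        intercept=float(theta[0]), deviance_explained=deviance_explained,
        params={"n_knots": n_knots, "max_iter": max_iter},
    )


# ---------------------------------------------------------------------------
# Cross-engine helpers


def variable_importance(model) -> pd.Series:
    """Ranked per-variable importance for any engine, ties alphabetical.

    GF: total R2-weighted cumulative importance.  GDM: summed spline
    coefficients (total curve height).  RDA: eigenvalue-weighted squared
    climate coefficients across retained axes.
    """
    if isinstance(model, GradientForestModel):
        imp = {v: model.importance.get(v, 0.0) for v in model.variables}
    elif isinstance(model, GDMModel):
        imp = {v: float(np.sum(model.coefs[v])) for v in model.variables}
    elif isinstance(model, RDAOffsetModel):
        sq = model.axis_coefs ** 2 @ model.weights
        imp = dict(zip(model.variables, sq.astype(float)))
    else:
        raise TypeError(f"unknown engine type: {type(model).__name__}")
    s = pd.Series(imp)
    order = sorted(s.index, key=lambda v: (-s[v], v))
    return s.loc[order]


ENGINE_NAMES = ("gf", "rda", "gdm")


def fit_engine(
    name: str,
    allele_data: pd.DataFrame,
    climate_at_samples: pd.DataFrame,
    sites: Sequence[str] | None = None,
    seed: int | None = None,
    **kwargs,
):
    """Fit one engine by name.

    GF and RDA fit on individual dosages; GDM fits on site allele frequencies
    and site-mean climate (``sites`` labels required).
    """
    if name == "gf":
        return fit_gradient_forest(allele_data, climate_at_samples, seed=seed, **kwargs)
    if name == "rda":
        return fit_rda_offset(allele_data, climate_at_samples, **kwargs)
    if name == "gdm":
        if sites is None:
            raise ValueError("GDM requires per-sample site labels")
        freqs = site_allele_frequencies(
            allele_data.to_numpy(float), sites, allele_data.columns
        )
        clim = climate_at_samples.copy()
        clim["site"] = list(sites)
        site_clim = clim.groupby("site").mean()
        return fit_gdm(freqs, site_clim, **kwargs)
    raise ValueError(f"unknown engine {name!r}; expected one of {ENGINE_NAMES}")
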