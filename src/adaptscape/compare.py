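"""Cross-method concordance and the protection-status ANOVA.

The three offset engines live in different spaces, so their raw adaptedness
values are not directly comparable.  Two scale-free comparisons are provided:
Procrustes superimposition of PCA-reduced per-cell configurations (residuals
map the spatial disagreement), and Spearman rank correlations between per-cell
offset maps.  A nested fixed-effects ANOVA
(adaptedness ~ protection * model / RCP / year) with Tukey HSD tests whether
protected cells carry higher predicted adaptedness than unprotected ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes


@dataclass
class ProcrustesResult:
    residuals: pd.Series          # per-cell residual distance, >= 0
    ss_residual: float
    rotation: np.ndarray
    scale: float
    correlation: float            # configuration correlation in [0, 1]
    p_value: float | None = None
    n_perm: int = 0


def procrustes_residuals(
    configA: pd.DataFrame,
    configB: pd.DataFrame,
    n_perm: int = 0,
    seed: int | None = None,
) -> ProcrustesResult:
    """Orthogonal Procrustes superimposition of B onto A with per-cell residuals.

    Both configurations are centered and scaled to unit Frobenius norm; the
    optimal rotation (and scaling) of B onto A comes from the SVD.  The
    per-cell residual is the Euclidean distance after superimposition; the
    configuration correlation is sqrt(1 - m12^2) where m12^2 is the residual
    sum of squares.  An optional permutation test (PROTEST-style, shuffling
    B's rows) gives a p-value.
    """
    if len(configA) != len(configB) or configA.shape[1] == 0 or configB.shape[1] == 0:
        raise ValueError("configurations must share cells and have k >= 1 columns")
    if not configA.index.equals(configB.index):
        raise ValueError("configurations must be indexed by the same cells")
    # configurations of unequal dimension: pad the narrower with zero columns
    kA, kB = configA.shape[1], configB.shape[1]
    if kA != kB:
        k = max(kA, kB)

        def _pad(M: pd.DataFrame) -> pd.DataFrame:
            out = M.copy()
            for i in range(M.shape[1], k):
                out[f"_pad{i}"] = 0.0
            return out

        configA, configB = _pad(configA), _pad(configB)

    def _norm(M: pd.DataFrame) -> np.ndarray:
        X = M.to_numpy(float)
        X = X - X.mean(axis=0)
        nrm = np.linalg.norm(X)
        if nrm == 0:
            raise ValueError("degenerate configuration (zero variance)")
        return X / nrm

    def _stat(A: np.ndarray, B: np.ndarray):
        R, s = orthogonal_procrustes(B, A)  # minimizes ||B R - A||
        fitted = s * (B @ R)
        res = np.linalg.norm(A - fitted, axis=1)
        ss = float((res ** 2).sum())
        return R, float(s), res, ss

    A, B = _norm(configA), _norm(configB)
    R, s, res, ss = _stat(A, B)
    corr = float(np.sqrt(max(0.0, 1.0 - ss)))

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            Bp = B[rng.permutation(len(B))]
            *_, ss_p = _stat(A, Bp)
            corr_p = np.sqrt(max(0.0, 1.0 - ss_p))
            if corr_p >= corr - 1e-12:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return ProcrustesResult(
        residuals=pd.Series(res, index=configA.index, name="procrustes_residual"),
        ss_residual=ss, rotation=R, scale=s, correlation=corr,
        p_value=p_value, n_perm=n_perm,
    )


def reduce_for_procrustes(embedding: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """PCA-reduce a per-cell engine embedding to k components.

    Engines embed cells in spaces of different dimensionality (turnover-curve
    components, weighted RDA indices, coefficient-scaled splines); reducing
    each to its leading k principal components puts them on a common footing
    before Procrustes superimposition.
    """
    X = embedding.to_numpy(float)
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, len(S))
    return pd.DataFrame(
        U[:, :k] * S[:k], index=embedding.index,
        columns=[f"pc{i + 1}" for i in range(k)],
    )


def spearman_table(maps: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation table between per-cell offset maps."""
    names = list(maps)
    idx = None
    for name, m in maps.items():
        idx = m.index if idx is None else idx
        if not m.index.equals(idx):
            raise ValueError("offset maps must share cells")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = stats.spearmanr(maps[a].to_numpy(), maps[b].to_numpy()).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


@dataclass
class AnovaTable:
    """Nested fixed-effects ANOVA plus Tukey HSD pairwise comparisons."""

    anova: pd.DataFrame
    tukey: pd.DataFrame
    formula: str
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.n_obs:
            total_df = self.anova["df"].sum()
            if abs(total_df - (self.n_obs - 1)) > 1e-6:
                raise ValueError(
                    f"df sum {total_df} does not match N - 1 = {self.n_obs - 1}"
                )


def _interaction_dummies(df: pd.DataFrame, factors: Sequence[str]) -> np.ndarray:
    combo = df[list(factors)].astype(str).agg(":".join, axis=1)
    return pd.get_dummies(combo).to_numpy(float)


def protection_anova(
    values: pd.DataFrame,
    response: str = "adaptedness",
    tukey_on: str = "protection",
    tukey_alpha: float = 0.05,
) -> AnovaTable:
    """Fixed-effects nested ANOVA of adaptedness on protection and scenario.

    ``values`` must hold one row per (cell, scenario) observation with columns
    ``adaptedness, protection, model, rcp, year``.  The model is
    ``adaptedness ~ protection * model / rcp / year``: the nesting expands to
    model, model:rcp and model:rcp:year, each also crossed with protection.
    Sums of squares are sequential (Type I, as R's ``aov`` reports), with each
    term's degrees of freedom taken as the rank increment of the growing
    design matrix, so redundant nesting columns are never double-counted.
    Tukey HSD with studentized-range adjustment compares the levels of
    ``tukey_on`` (a factor column, or ``"cells"`` for the full interaction
    cells).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    required = {response, "protection", "model", "rcp", "year"}
    if not required.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    df = values.copy()
    for col in ("protection", "model", "rcp", "year"):
        df[col] = df[col].astype(str)
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    counts = df.groupby(["protection", "model", "rcp", "year"]).size()
    empty = [str(c) for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"empty factor cell(s): {empty}")

    # expansion of protection * model / rcp / year, ordered by interaction order
    terms: list[tuple[str, ...]] = [
        ("protection",),
        ("model",),
        ("protection", "model"),
        ("model", "rcp"),
        ("protection", "model", "rcp"),
        ("model", "rcp", "year"),
        ("protection", "model", "rcp", "year"),
    ]
    y = df[response].to_numpy(float)
    n = len(y)
    X = np.ones((n, 1))
    rank_prev = 1
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = tss <= 1e-12 * n  # constant response: every F is 0
    rss_prev = tss
    rows = []
    for term in terms:
        X = np.column_stack([X, _interaction_dummies(df, term)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rows.append({
            "term": ":".join(term),
            "df": rank - rank_prev,
            "sum_sq": max(rss_prev - rss, 0.0),
        })
        rank_prev, rss_prev = rank, rss
    df_resid = n - rank_prev
    ms_resid = rss_prev / df_resid if df_resid > 0 else np.nan
    for r in rows:
        if degenerate:
            r["F"], r["p_value"] = 0.0, np.nan
        elif r["df"] > 0 and df_resid > 0 and ms_resid > 0:
            r["F"] = (r["sum_sq"] / r["df"]) / ms_resid
            r["p_value"] = float(stats.f.sf(r["F"], r["df"], df_resid))
        else:
            r["F"], r["p_value"] = 0.0, np.nan
    rows.append({
        "term": "residual", "df": df_resid, "sum_sq": rss_prev,
        "F": np.nan, "p_value": np.nan,
    })
    anova = pd.DataFrame(rows).set_index("term")

    if tukey_on == "cells":
        labels = (
            df["protection"] + ":" + df["model"] + ":" + df["rcp"] + ":" + df["year"]
        )
    else:
        labels = df[tukey_on]
    tk = pairwise_tukeyhsd(df[response].to_numpy(), labels.to_numpy(), alpha=tukey_alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return AnovaTable(
        anova=anova, tukey=tukey,
        formula="adaptedness ~ protection * model / rcp / year",
        n_obs=len(df),
    )
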