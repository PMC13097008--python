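"""Climate grids: loading, point extraction, collinearity pruning, standardization.

A :class:`ClimateGrid` holds one climate scenario (e.g. the recent baseline, or a
future model x RCP x period combination) as a table of grid cells.  Cells are the
atomic unit of every downstream prediction: offsets and adaptedness are defined
per cell, so extraction is nearest-cell with no sub-cell interpolation.

Grids are stored as long-format CSV (``cell_id, x, y, variable, value``); x/y are
longitude/latitude in decimal degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six bioclimatic/hydrologic variables used throughout: climate water
#: deficit, recharge, runoff, soil water storage, min and max air temperature.
DEFAULT_VARIABLES = ("cwd", "rch", "run", "str", "tmn", "tmx")


@dataclass(frozen=True)
class ScenarioKey:
    """Identifies one climate scenario: a model, an emission pathway, a period.

    The recent/baseline scenario has ``rcp="none"``.
    """

    model: str
    rcp: str = "none"
    period: str = "recent"

    def __post_init__(self) -> None:
        if self.model == "recent" and self.rcp != "none":
            raise ValueError("the recent scenario must have rcp='none'")

    @property
    def label(self) -> str:
        if self.model == "recent":
            return "recent"
        return f"{self.model}_rcp{self.rcp}_{self.period}"

    @classmethod
    def recent(cls) -> "ScenarioKey":
        return cls(model="recent", rcp="none", period="recent")

    @classmethod
    def from_label(cls, label: str) -> "ScenarioKey":
        if label == "recent":
            return cls.recent()
        parts = label.split("_")
        if len(parts) != 3 or not parts[1].startswith("rcp"):
            raise ValueError(f"cannot parse scenario label {label!r}")
        return cls(model=parts[0], rcp=parts[1][3:], period=parts[2])


@dataclass
class ClimateGrid:
    """Cells x climate variables for one scenario.

    ``data`` is indexed by integer ``cell_id`` with columns ``x``, ``y`` followed
    by the climate variables, in a fixed order shared by every cell.
    """

    scenario: ScenarioKey
    data: pd.DataFrame
    variables: tuple[str, ...]
    cell_size_km: float
    crs: str = "lon/lat degrees (synthetic)"

    def __post_init__(self) -> None:
        missing = [v for v in self.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"grid missing variable columns: {missing}")
        if self.data[list(self.variables)].isna().any().any():
            raise ValueError("retained grid cells must not contain NaN")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def coords(self) -> pd.DataFrame:
        return self.data[["x", "y"]]

    def values(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Cells x variables table (no coordinates)."""
        return self.data[list(variables or self.variables)]

    def subset(self, cell_ids: Iterable[int]) -> "ClimateGrid":
        ids = list(cell_ids)
        return ClimateGrid(
            scenario=self.scenario,
            data=self.data.loc[ids].copy(),
            variables=self.variables,
            cell_size_km=self.cell_size_km,
            crs=self.crs,
        )

    def to_csv(self, path: str | Path) -> Path:
        """Write long-format CSV (cell_id, x, y, variable, value)."""
        path = Path(path)
        long = self.data.reset_index(names="cell_id").melt(
            id_vars=["cell_id", "x", "y"], var_name="variable", value_name="value"
        )
        long = long[long["variable"].isin(self.variables)]
        long.to_csv(path, index=False, float_format="%.10g")
        return path


def load_grid(
    paths: str | Path | Sequence[str | Path],
    scenario: ScenarioKey,
    cell_size_km: float = 0.27,
    variables: Sequence[str] | None = None,
) -> ClimateGrid:
    """Load a scenario grid from one or more long-format CSV files.

    Each file holds columns ``cell_id, x, y, variable, value``; multiple files
    (e.g. one per variable) must share cell geometry exactly.  Cells with any
    missing variable are dropped and logged.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        p = Path(p)
        try:
            df = pd.read_csv(p)
        except Exception as exc:  # pragma: no cover - I/O context
            raise IOError(f"failed to read grid file {p}: {exc}") from exc
        required = {"cell_id", "x", "y", "variable", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"{p}: grid CSV must have columns {sorted(required)}")
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)

    geom = long.groupby("cell_id")[["x", "y"]].nunique()
    if (geom > 1).any().any():
        raise ValueError("geometry mismatch: a cell_id maps to multiple coordinates")

    wide = long.pivot_table(
        index="cell_id", columns="variable", values="value", aggfunc="first"
    )
    coords = long.drop_duplicates("cell_id").set_index("cell_id")[["x", "y"]]
    if variables is None:
        seen: list[str] = []
        for v in long["variable"]:
            if v not in seen:
                seen.append(v)
        variables = seen
    variables = tuple(variables)
    missing_vars = [v for v in variables if v not in wide.columns]
    if missing_vars:
        raise ValueError(f"grid lacks variables {missing_vars}")

    wide = coords.join(wide[list(variables)].astype(float)).sort_index()
    bad = wide[list(variables)].isna().any(axis=1)
    if bad.any():
        logger.info(
            "dropping %d/%d cells with missing values in scenario %s",
            int(bad.sum()), len(wide), scenario.label,
        )
        wide = wide[~bad]
    return ClimateGrid(
        scenario=scenario,
        data=wide,
        variables=variables,
        cell_size_km=cell_size_km,
    )


def extract_at_points(grid: ClimateGrid, coords: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell climate for each sample point.

    Parameters
    ----------
    coords
        Table with columns ``sample_id, lon, lat`` (degrees).

    Returns
    -------
    DataFrame indexed by sample_id with the grid variables plus the ``cell_id``
    each sample maps to.  Equidistant ties go to the lowest cell_id.  Points
    outside the grid bounds (cell centers padded by half a cell spacing) raise.
    """
    cells = grid.data.sort_index()
    cx = cells["x"].to_numpy()
    cy = cells["y"].to_numpy()

    def _halfspacing(vals: np.ndarray) -> float:
        u = np.unique(vals)
        return float(np.min(np.diff(u)) / 2) if len(u) > 1 else np.inf

    pad_x, pad_y = _halfspacing(cx), _halfspacing(cy)
    px = coords["lon"].to_numpy(float)
    py = coords["lat"].to_numpy(float)
    out_of_bounds = (
        (px < cx.min() - pad_x) | (px > cx.max() + pad_x)
        | (py < cy.min() - pad_y) | (py > cy.max() + pad_y)
    )
    if out_of_bounds.any():
        bad = coords.loc[out_of_bounds, "sample_id"].tolist()
        raise ValueError(f"points outside grid bounds for samples: {bad}")

    d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
    # lowest cell_id wins on exact ties: cells are sorted by id and argmin
    # returns the first minimizing index
    idx = np.argmin(d2, axis=1)
    chosen = cells.iloc[idx]
    out = chosen[list(grid.variables)].copy()
    out.insert(0, "cell_id", chosen.index.to_numpy())
    out.index = pd.Index(coords["sample_id"], name="sample_id")
    return out


def prune_collinear(
    table: pd.DataFrame,
    r2_max: float = 0.7,
    keep_priority: Sequence[str] | None = None,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop one of each highly collinear variable pair.

    While any pair of variables has squared Pearson correlation > ``r2_max``
    over cells, the worst pair is resolved by removing its member ranked lower
    in ``keep_priority`` (variables absent from the priority list rank after
    all listed ones, alphabetically).  Returns the retained variables in input
    order plus a removal log.  The result does not depend on the column order
    of ``table`` for a fixed priority list.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables to prune")
    keep_priority = list(keep_priority or [])

    def rank(v: str) -> tuple:
        return (
            (keep_priority.index(v), "") if v in keep_priority
            else (len(keep_priority), v)
        )

    retained = sorted(cols)  # canonical working order; restored at the end
    log: list[dict] = []
    while True:
        sub = table[retained]
        r2 = sub.corr().to_numpy() ** 2
        np.fill_diagonal(r2, 0.0)
        worst_pair = None
        worst_key = (r2_max, "", "")
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                val = r2[i, j]
                key = (val, retained[i], retained[j])
                if val > r2_max and key > worst_key:
                    worst_key, worst_pair = key, (i, j)
        if worst_pair is None:
            break
        worst = worst_key[0]
        i, j = worst_pair
        a, b = retained[i], retained[j]
        drop = a if rank(a) > rank(b) else b
        keep = b if drop == a else a
        log.append({"removed": drop, "kept": keep, "r2": float(worst)})
        retained.remove(drop)
        if len(retained) == 1:
            break
    retained_in_order = [c for c in cols if c in retained]
    return retained_in_order, log


@dataclass
class ClimateStandardizer:
    """Standardize every scenario with statistics from the recent scenario.

    The offset engines are trained on current climate and predict on future
    climate, so the scaling must be learned once (on the recent grid) and then
    applied unchanged to every other scenario.
    """

    means: pd.Series = field(default_factory=pd.Series)
    sds: pd.Series = field(default_factory=pd.Series)

    def fit(self, recent: ClimateGrid | pd.DataFrame) -> "ClimateStandardizer":
        table = recent.values() if isinstance(recent, ClimateGrid) else recent
        self.means = table.mean()
        self.sds = table.std(ddof=1)
        zero = self.sds[self.sds == 0]
        if len(zero):
            raise ValueError(f"zero-variance variable(s): {list(zero.index)}")
        return self

    def transform(self, obj: ClimateGrid | pd.DataFrame) -> ClimateGrid | pd.DataFrame:
        if isinstance(obj, ClimateGrid):
            data = obj.data.copy()
            for v in self.means.index:
                data[v] = (data[v] - self.means[v]) / self.sds[v]
            return ClimateGrid(
                scenario=obj.scenario, data=data, variables=obj.variables,
                cell_size_km=obj.cell_size_km, crs=obj.crs,
            )
        return (obj - self.means) / self.sds

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table * self.sds + self.means


def standardize(
    grids: Mapping[str, ClimateGrid],
    stats_from: str = "recent",
) -> tuple[dict[str, ClimateGrid], ClimateStandardizer]:
    """Standardize all scenario grids using the recent scenario's mean/SD."""
    if stats_from not in grids:
        raise KeyError(f"reference scenario {stats_from!r} not in grids")
    std = ClimateStandardizer().fit(grids[stats_from])
    return {k: std.transform(g) for k, g in grids.items()}, std
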