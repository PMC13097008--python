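"""Donor-recipient seed-transfer analysis.

A donor cell contributes its *current* adaptive composition; a recipient cell
demands the composition its *future* climate requires.  The transfer offset of
a (donor, recipient) pair is the engine offset between those two quantities;
transfer adaptedness is its negative.  Averaging over recipients gives each
donor's reverse adaptedness (how good a seed source it is for a focal site);
averaging over donors gives each recipient's forward adaptedness (how good a
planting location it is for a focal site's seeds).  Seed-source priority is
the fraction of recipients a donor would strictly improve over their
no-transfer baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .offsets import AdaptednessSurface
from .structure import haversine_matrix


@dataclass
class TransferMatrix:
    """Dense donor x recipient transfer offsets for one engine and scenario pair."""

    donors: np.ndarray       # donor cell ids (current-scenario climate)
    recipients: np.ndarray   # recipient cell ids (future-scenario climate)
    offset: np.ndarray       # donors x recipients, >= 0
    method: str
    current: str
    future: str

    def __post_init__(self) -> None:
        if self.offset.shape != (len(self.donors), len(self.recipients)):
            raise ValueError("offset matrix shape mismatch")
        if (self.offset < -1e-12).any():
            raise ValueError("transfer offsets must be non-negative")

    @property
    def adaptedness(self) -> np.ndarray:
        return -self.offset

    def to_long_csv(self, path: str | Path) -> Path:
        path = Path(path)
        d, r = np.meshgrid(self.donors, self.recipients, indexing="ij")
        pd.DataFrame({
            "donor": d.ravel(), "recipient": r.ravel(),
            "offset": self.offset.ravel(),
        }).to_csv(path, index=False, float_format="%.10g")
        return path


@dataclass
class SeedPriorityMap:
    """Per-donor fraction of focal-site recipients strictly improved."""

    priority: pd.Series          # index donor cell_id, values in [0, 1]
    n_recipients: int
    mean_reverse_adaptedness: pd.Series

    def __post_init__(self) -> None:
        if ((self.priority < 0) | (self.priority > 1)).any():
            raise ValueError("priorities must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({
            "priority": self.priority,
            "mean_reverse_adaptedness": self.mean_reverse_adaptedness,
        }).rename_axis("cell_id").to_csv(path, float_format="%.10g")
        return path


def pairwise_transfer(
    model,
    grid_now: ClimateGrid,
    grid_future: ClimateGrid,
    donor_cells: Sequence[int],
    recipient_cells: Sequence[int],
) -> TransferMatrix:
    """Engine offsets between donor current climates and recipient future climates.

    The matrix entry (d, r) is exactly the engine's pairwise offset between
    the current climate of donor cell d and the future climate of recipient
    cell r; the same quantity underlies both forward and reverse summaries.
    """
    donor_cells = np.asarray(list(donor_cells))
    recipient_cells = np.asarray(list(recipient_cells))
    if donor_cells.size == 0 or recipient_cells.size == 0:
        raise ValueError("donor and recipient sets must be non-empty")
    Ed = model.embed(grid_now.values().loc[donor_cells])
    Er = model.embed(grid_future.values().loc[recipient_cells])
    off = model.pair_offset(Ed, Er)
    return TransferMatrix(
        donors=donor_cells, recipients=recipient_cells,
        offset=np.maximum(off, 0.0), method=model.method,
        current=grid_now.scenario.label, future=grid_future.scenario.label,
    )


def reverse_adaptedness(tm: TransferMatrix) -> pd.Series:
    """Mean adaptedness of each donor over all recipient cells (row means)."""
    return pd.Series(
        tm.adaptedness.mean(axis=1), index=pd.Index(tm.donors, name="cell_id"),
        name="mean_reverse_adaptedness",
    )


def forward_adaptedness(tm: TransferMatrix) -> pd.Series:
    """Mean adaptedness of each recipient over all donor cells (column means)."""
    return pd.Series(
        tm.adaptedness.mean(axis=0), index=pd.Index(tm.recipients, name="cell_id"),
        name="mean_forward_adaptedness",
    )


def baseline_adaptedness(
    model,
    grid_now: ClimateGrid,
    grid_future: ClimateGrid,
    focal_cells: Sequence[int],
) -> pd.Series:
    """Adaptedness of each focal cell to its own future climate (no transfer)."""
    focal = list(focal_cells)
    surface: AdaptednessSurface = model.offset(
        grid_now.subset(focal), grid_future.subset(focal)
    )
    return surface.table["adaptedness"].rename("baseline_adaptedness")


def seed_source_priority(tm: TransferMatrix, baseline: pd.Series) -> SeedPriorityMap:
    """Fraction of recipients each donor strictly improves over baseline.

    B(d, r) = 1 iff transfer adaptedness(d, r) > baseline(r); ties count as
    no improvement.  Priority(d) = sum_r B(d, r) / n_recipients.
    """
    missing = set(tm.recipients) - set(baseline.index)
    if missing:
        raise ValueError(f"baseline missing recipients: {sorted(missing)[:5]}")
    base = baseline.loc[tm.recipients].to_numpy(float)
    improved = tm.adaptedness > base[None, :]
    prio = pd.Series(
        improved.mean(axis=1), index=pd.Index(tm.donors, name="cell_id"),
        name="priority",
    )
    return SeedPriorityMap(
        priority=prio,
        n_recipients=len(tm.recipients),
        mean_reverse_adaptedness=reverse_adaptedness(tm),
    )


def radius_donors(
    grid: ClimateGrid,
    focal_cells: Sequence[int],
    radius_km: float = 50.0,
    scope: str = "radius",
) -> np.ndarray:
    """Donor cell subset for a focal site.

    ``scope`` is one of ``site`` (the focal cells themselves), ``radius``
    (every cell whose minimum Haversine distance to a focal cell is at most
    ``radius_km``), or ``range`` (every cell of the grid/range mask).
    """
    focal = np.asarray(list(focal_cells))
    if scope == "site":
        return np.sort(focal)
    if scope == "range":
        return np.sort(grid.cell_ids)
    if scope != "radius":
        raise ValueError("scope must be 'site', 'radius' or 'range'")
    cells = grid.data
    all_pts = pd.DataFrame({"lon": cells["x"], "lat": cells["y"]})
    focal_pts = all_pts.loc[focal]
    # distance from every cell to the nearest focal cell
    both = pd.concat([all_pts, focal_pts])
    d = haversine_matrix(both)[: len(all_pts), len(all_pts):]
    keep = d.min(axis=1) <= radius_km + 1e-9
    return np.sort(cells.index.to_numpy()[keep])
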