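"""Blood-vessel detection from typed cell maps.

Vessels are defined as endothelial and mural cells tightly connected in
space: the vascular-type cells are linked by single-linkage at a distance
threshold ε (default 30 µm, cell-diameter scale) and each connected
component of at least ``min_size`` cells is one vessel. Downstream
statistics cover vessel counts, sizes, composition, the percentage of
cells in vessels, and per-cell distance-to-vessel maps capped at 150 µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import CellMap, ValidationError

__all__ = [
    "VesselComponent",
    "VesselSet",
    "DistanceMap",
    "detect_vessels",
    "vessel_stats",
    "distance_to_vessel",
    "compare_groups",
]


@dataclass(frozen=True)
class VesselComponent:
    cell_ids: tuple[str, ...]
    size: int
    composition: dict[str, int]
    centroid: tuple[float, float]


@dataclass(frozen=True)
class VesselSet:
    """Disjoint connected vascular components of one sample."""

    components: tuple[VesselComponent, ...]
    linkage_um: float
    min_size: int
    vascular_types: tuple[str, ...]
    n_vascular_cells: int  # all vascular-type cells, retained or not

    @property
    def n_vessels(self) -> int:
        return len(self.components)

    @property
    def member_ids(self) -> set[str]:
        return {cid for c in self.components for cid in c.cell_ids}

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.components], dtype=int)


def detect_vessels(
    cells: CellMap,
    vascular_types=("endothelial", "mural"),
    linkage_um: float = 30.0,
    min_size: int = 5,
) -> VesselSet:
    """Single-linkage connected components over vascular-type cells.

    Two vascular cells are linked when their distance is ≤ ``linkage_um``;
    components smaller than ``min_size`` are discarded. A sample with no
    vascular cells yields an empty VesselSet.
    """
    if linkage_um <= 0:
        raise ValidationError("linkage distance must be positive")
    vascular_types = tuple(vascular_types)
    if not vascular_types:
        raise ValidationError("vascular type set must be nonempty")
    mask = np.isin(cells.cell_types, vascular_types)
    xy = cells.coords[mask]
    ids = cells.cell_ids[mask]
    vtypes = cells.cell_types[mask]
    n = len(xy)
    if n == 0:
        return VesselSet((), float(linkage_um), int(min_size), vascular_types, 0)
    pairs = cKDTree(xy).query_pairs(r=linkage_um, output_type="ndarray")
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    comps = []
    for c in np.unique(comp):
        member = comp == c
        if member.sum() < min_size:
            continue
        ctypes, counts = np.unique(vtypes[member], return_counts=True)
        comps.append(
            VesselComponent(
                cell_ids=tuple(sorted(ids[member])),
                size=int(member.sum()),
                composition={str(t): int(k) for t, k in zip(ctypes, counts)},
                centroid=tuple(np.round(xy[member].mean(axis=0), 6)),
            )
        )
    comps.sort(key=lambda c: (-c.size, c.cell_ids))
    return VesselSet(
        tuple(comps), float(linkage_um), int(min_size), vascular_types, n
    )


def vessel_stats(
    vset: VesselSet, cells: CellMap, large_min: int = 50, percent_of: str = "all_cells"
) -> dict:
    """Vessel summary statistics for one sample.

    ``percent`` is 100 × (cells in vessel components) / (all cells) by
    default; ``percent_of="vascular_cells"`` uses the vascular-type cell
    count as the denominator instead.
    """
    sizes = vset.sizes()
    in_vessels = int(sizes.sum())
    denom = cells.n_cells if percent_of == "all_cells" else max(vset.n_vascular_cells, 1)
    return {
        "sample_id": cells.sample_id,
        "n_vessels": vset.n_vessels,
        "sizes": sizes.tolist(),
        "cells_in_vessels": in_vessels,
        "percent_vessel": 100.0 * in_vessels / denom if denom else 0.0,
        "n_large": int((sizes >= large_min).sum()),
        "large_min": int(large_min),
        "composition": [c.composition for c in vset.components],
    }


@dataclass(frozen=True)
class DistanceMap:
    """Per-cell distance to the nearest vessel, binned and capped.

    ``table`` columns: cell_id, distance_um (floor-binned, capped),
    over_cap (raw distance exceeded the cap). Vessel members are exactly 0.
    """

    table: pd.DataFrame
    cap_um: float
    bin_um: float


def distance_to_vessel(
    cells: CellMap, vset: VesselSet, cap_um: float = 150.0, bin_um: float = 10.0
) -> DistanceMap:
    """Min distance from each cell to any vessel member cell.

    Distances are rounded down to multiples of ``bin_um`` and reported at
    most ``cap_um``; cells whose raw distance exceeds the cap carry the
    cap value and an over-cap flag. With no vessels at all, every cell is
    flagged over-cap at the cap value.
    """
    if cap_um <= 0 or bin_um <= 0:
        raise ValidationError("cap and bin must be positive")
    member = vset.member_ids
    if not member:
        table = pd.DataFrame(
            {
                "cell_id": cells.cell_ids,
                "distance_um": np.full(cells.n_cells, float(cap_um)),
                "over_cap": np.ones(cells.n_cells, dtype=bool),
            }
        )
        return DistanceMap(table, float(cap_um), float(bin_um))
    is_member = np.isin(cells.cell_ids, list(member))
    tree = cKDTree(cells.coords[is_member])
    raw = tree.query(cells.coords)[0]
    raw[is_member] = 0.0
    binned = np.floor(raw / bin_um) * bin_um
    over = raw > cap_um
    binned = np.minimum(binned, cap_um)
    table = pd.DataFrame(
        {"cell_id": cells.cell_ids, "distance_um": binned, "over_cap": over}
    )
    return DistanceMap(table, float(cap_um), float(bin_um))


def compare_groups(
    per_sample_values: pd.Series, classes: dict[str, str]
) -> dict:
    """Welch two-sample t-test of a vessel metric between structure classes.

    ``per_sample_values`` is indexed by sample_id; ``classes`` maps sample
    → {"high", "low"}. Both classes need ≥ 2 samples.
    """
    high = per_sample_values[[s for s in per_sample_values.index if classes.get(s) == "high"]]
    low = per_sample_values[[s for s in per_sample_values.index if classes.get(s) == "low"]]
    if len(high) < 2 or len(low) < 2:
        raise ValidationError("each structure class needs at least 2 samples")
    t, p = stats.ttest_ind(high, low, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "mean_high": float(high.mean()),
        "mean_low": float(low.mean()),
        "sd_high": float(high.std(ddof=1)),
        "sd_low": float(low.std(ddof=1)),
        "n_high": int(len(high)),
        "n_low": int(len(low)),
    }
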