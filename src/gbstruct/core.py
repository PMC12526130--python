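"""Core domain types and pipeline configuration.

The pipeline's universal input is a *typed cell map*: one tissue section's
worth of cells, each with a micrometre-scale (x, y) position and a
categorical cell-type label. Everything downstream — neighbor graphs,
niche clustering, neighborhood enrichment, vessel detection — consumes this
one structure. Expression matrices and survival tables are optional side
inputs used by the signature and survival stages.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CellMap",
    "ExpressionMatrix",
    "SurvivalTable",
    "PipelineConfig",
    "DEFAULT_CELL_TYPES",
    "VASCULAR_TYPES",
    "derive_seed",
    "ValidationError",
    "SchemaError",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing a required column or has the wrong shape."""


#: Default level-3-style label universe: malignant states, myeloid, lymphoid,
#: glial/neuronal, and vascular compartments.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "AC-like",
    "MES-hypoxia",
    "MES-like",
    "NPC-like",
    "OPC-like",
    "cycling",
    "TAM-BDM",
    "TAM-MG",
    "T-cell",
    "NK",
    "B-cell",
    "DC",
    "oligodendrocyte",
    "astrocyte",
    "neuron",
    "endothelial",
    "mural",
)

#: Cell types treated as vessel constituents by the vessel detector.
VASCULAR_TYPES: tuple[str, ...] = ("endothelial", "mural")


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a stable per-stream seed from a master seed and string tokens.

    Hash-based so that per-sample random streams do not depend on the order
    in which samples are processed. The result is a nonnegative int below
    2**31, usable by every numpy generator.
    """
    payload = "/".join([str(int(seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class CellMap:
    """One sample's typed cells with µm coordinates.

    ``cells`` has columns ``cell_id, x, y, cell_type, sample_id``.
    Coordinates are continuous micrometres with arbitrary origin (y up);
    no grid or pixel assumption is made.
    """

    cells: pd.DataFrame
    label_set: tuple[str, ...] = DEFAULT_CELL_TYPES

    REQUIRED_COLUMNS = ("cell_id", "x", "y", "cell_type", "sample_id")

    def __post_init__(self) -> None:
        df = self.cells
        for col in self.REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"cell map is missing required column {col!r}")
        if len(df) < 2:
            raise ValidationError("a cell map needs at least 2 cells")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
            raise ValidationError(f"non-finite coordinate at row {bad}")
        ids = df["cell_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicated cell_id {dup!r}")
        if df["sample_id"].nunique() != 1:
            raise ValidationError("a CellMap holds exactly one sample_id")
        if self.label_set is not None:
            unknown = set(df["cell_type"].unique()) - set(self.label_set)
            if unknown:
                raise ValidationError(
                    f"cell types not in the declared label set: {sorted(unknown)}"
                )
        # normalize dtypes once; frozen dataclass, so bypass __setattr__
        clean = df.copy()
        clean["cell_id"] = ids.to_numpy()
        clean["sample_id"] = df["sample_id"].astype(str).to_numpy()
        clean["cell_type"] = df["cell_type"].astype(str).to_numpy()
        clean["x"] = xy[:, 0]
        clean["y"] = xy[:, 1]
        clean = clean.reset_index(drop=True)
        object.__setattr__(self, "cells", clean)

    @property
    def sample_id(self) -> str:
        return str(self.cells["sample_id"].iloc[0])

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of positions in µm."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    @property
    def cell_types(self) -> np.ndarray:
        return self.cells["cell_type"].to_numpy()

    def type_fractions(self) -> pd.Series:
        """Per-type fraction of cells, indexed by the full label set."""
        counts = self.cells["cell_type"].value_counts()
        frac = counts.reindex(list(self.label_set), fill_value=0) / self.n_cells
        frac.name = self.sample_id
        return frac


@dataclass(frozen=True)
class ExpressionMatrix:
    """Cells × genes nonnegative expression, row-aligned to a CellMap."""

    values: np.ndarray
    cell_ids: np.ndarray
    genes: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        cell_ids = np.asarray(self.cell_ids, dtype=object)
        genes = np.asarray(self.genes, dtype=object)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2D matrix")
        if values.shape != (len(cell_ids), len(genes)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(cell_ids)} cells x {len(genes)} genes"
            )
        if values.size and values.min() < 0:
            raise ValidationError("expression values must be nonnegative")
        if len(set(genes.tolist())) != len(genes):
            raise ValidationError("gene names must be unique")
        if len(set(cell_ids.tolist())) != len(cell_ids):
            raise ValidationError("cell ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "genes", genes)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.genes)


@dataclass(frozen=True)
class SurvivalTable:
    """Per-patient time-to-event data with standard prognostic covariates.

    ``table`` columns: patient_id, time (days, > 0), event (0/1), group
    (optional categorical), age (years), sex, mgmt.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("patient_id", "time", "event")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"survival table is missing column {col!r}")
        if df["patient_id"].astype(str).duplicated().any():
            raise ValidationError("duplicated patient_id in survival table")
        time = df["time"].to_numpy(dtype=float)
        if not np.all(time > 0):
            raise ValidationError("survival times must be strictly positive")
        ev = df["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        clean = df.copy().reset_index(drop=True)
        clean["patient_id"] = clean["patient_id"].astype(str)
        clean["time"] = time
        clean["event"] = ev.astype(int)
        object.__setattr__(self, "table", clean)

    @property
    def n_patients(self) -> int:
        return len(self.table)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, in the units they act on.

    Defaults follow the analysis this package implements: 40 µm radius
    neighborhoods for enrichment, 15-NN neighborhoods for niche composition,
    7 niches, a permutation null of 1000 shuffles, a 150 µm cap on
    distance-to-vessel maps, and a Pearson r > 0.6 cutoff for the structure
    signature.
    """

    radius_um: float = 40.0
    knn_k: int = 15
    n_permutations: int = 1000
    rng_seed: int = 0
    niche_k: int = 7
    vessel_link_um: float = 30.0
    vessel_min_cells: int = 5
    large_vessel_min_cells: int = 50
    distance_cap_um: float = 150.0
    distance_bin_um: float = 10.0
    signature_r_threshold: float = 0.6
    edge_display_z: float = 15.0
    refine_max_iter: int = 10
    include_diagonal: bool = True
    vascular_types: tuple[str, ...] = VASCULAR_TYPES

    def __post_init__(self) -> None:
        positive = {
            "radius_um": self.radius_um,
            "n_permutations": self.n_permutations,
            "vessel_link_um": self.vessel_link_um,
            "vessel_min_cells": self.vessel_min_cells,
            "large_vessel_min_cells": self.large_vessel_min_cells,
            "distance_cap_um": self.distance_cap_um,
            "distance_bin_um": self.distance_bin_um,
            "edge_display_z": self.edge_display_z,
            "refine_max_iter": self.refine_max_iter,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.niche_k < 2:
            raise ValidationError("niche_k must be >= 2")
        self.vascular_types = tuple(self.vascular_types)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vascular_types"] = list(self.vascular_types)
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat key: value config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError("config file must be a flat mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
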