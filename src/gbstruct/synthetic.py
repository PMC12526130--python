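"""Synthetic tissue cohorts with planted spatial architecture.

The generator emulates the kind of data the pipeline is built for: a
cohort of ~13 tumor sections, each a 2D µm-scale canvas carrying tens of
thousands of typed cells organized into seven recurrent niche territories
(proliferative, non-hypoxia-reliant, hypoxia-responsive, immune-interwoven,
vascular, peripheral, perivascular), with curvilinear vessels laid as
strands of endothelial and mural cells.

A single *disorder* parameter λ ∈ [0, 1] controls organization: each
cell's type label is independently redrawn from the global type frequency
with probability λ, so λ=0 keeps the planted architecture intact and λ=1
destroys it entirely while holding cell density constant. Gene expression
includes a set of *structure genes* whose sample-mean expression scales
with (1 − λ), and survival times follow an exponential model whose hazard
is tied to the planted structure score, so the signature and survival
stages have a ground truth to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    CellMap,
    DEFAULT_CELL_TYPES,
    ExpressionMatrix,
    SurvivalTable,
    ValidationError,
    derive_seed,
)

__all__ = [
    "NicheTemplate",
    "SynthConfig",
    "SyntheticSample",
    "SyntheticCohort",
    "default_template",
    "generate_sample",
    "generate_cohort",
    "simulate_survival",
]

NICHE_NAMES = (
    "proliferative",
    "non-hypoxia-reliant",
    "hypoxia-responsive",
    "immune-interwoven",
    "vascular",
    "peripheral",
    "perivascular",
)

#: Blob niches are laid out as Voronoi territories of seeded centers in the
#: tissue interior; the peripheral niche is a border band and the vascular /
#: perivascular niches follow the planted vessel strands.
_BLOB_NICHES = (
    "proliferative",
    "non-hypoxia-reliant",
    "hypoxia-responsive",
    "immune-interwoven",
)


@dataclass(frozen=True)
class NicheTemplate:
    """Niche names, per-niche cell-type composition, and layout parameters.

    ``compositions`` maps each niche name to a probability vector over
    ``cell_types``. Layout parameters control the spatial footprints:
    Voronoi blob centers for interior niches, a border band for the
    peripheral niche, and distance bands around vessels for the vascular
    and perivascular niches.
    """

    cell_types: tuple[str, ...]
    compositions: dict[str, np.ndarray]
    centers_per_niche: int = 2
    border_band_um: float = 140.0
    vascular_band_um: float = 30.0
    perivascular_band_um: float = 80.0

    def __post_init__(self) -> None:
        names = list(self.compositions)
        if len(set(names)) != len(names):
            raise ValidationError("niche names must be unique")
        for name, vec in self.compositions.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (len(self.cell_types),):
                raise ValidationError(
                    f"composition for {name!r} has wrong length"
                )
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-8:
                raise ValidationError(
                    f"composition for {name!r} is not a probability vector"
                )
            self.compositions[name] = v

    @property
    def niche_names(self) -> tuple[str, ...]:
        return tuple(self.compositions)


def default_template() -> NicheTemplate:
    """The standard seven-niche template over the default label set.

    Compositions are illustrative: each niche is dominated by the cell
    types that characterize it (cycling cells in the proliferative niche,
    hypoxic MES-like cells and blood-derived macrophages in the
    hypoxia-responsive niche, endothelium and mural cells in the
    vasculature, oligodendrocytes/neurons at the periphery, ...), with
    minority admixture so neighborhoods are not trivially one-hot.
    """
    t = list(DEFAULT_CELL_TYPES)

    def vec(**weights: float) -> np.ndarray:
        v = np.zeros(len(t))
        for name, w in weights.items():
            v[t.index(name.replace("_", "-"))] = w
        return v / v.sum()

    comps = {
        "proliferative": vec(cycling=0.45, NPC_like=0.25, OPC_like=0.20, AC_like=0.05, TAM_BDM=0.05),
        "non-hypoxia-reliant": vec(MES_like=0.35, AC_like=0.30, OPC_like=0.20, astrocyte=0.10, T_cell=0.05),
        "hypoxia-responsive": vec(MES_hypoxia=0.55, TAM_BDM=0.25, MES_like=0.10, DC=0.05, neuron=0.05),
        "immune-interwoven": vec(TAM_BDM=0.28, T_cell=0.25, NK=0.15, B_cell=0.12, DC=0.10, TAM_MG=0.10),
        "vascular": vec(endothelial=0.30, mural=0.20, T_cell=0.15, TAM_BDM=0.10, AC_like=0.15, NK=0.10),
        "peripheral": vec(oligodendrocyte=0.35, neuron=0.25, astrocyte=0.15, TAM_MG=0.15, NPC_like=0.10),
        "perivascular": vec(mural=0.20, DC=0.20, B_cell=0.20, TAM_MG=0.20, astrocyte=0.10, endothelial=0.05, NK=0.05),
    }
    return NicheTemplate(cell_types=tuple(t), compositions=comps)


@dataclass
class SynthConfig:
    """Generator parameters for one cohort.

    ``disorder`` is the λ parameter; ``structure_effect`` scales how
    strongly structure-gene expression tracks (1 − λ); ``survival_beta``
    is the log-hazard coefficient on the planted (standardized) structure
    score.
    """

    n_cells: int = 10_000
    canvas_um: float = 1_000.0
    disorder: float = 0.0
    n_vessels: int = 2
    vessel_spacing_um: float = 20.0
    vessel_step_um: float = 40.0
    mural_flank_prob: float = 0.4
    mural_flank_offset_um: float = 8.0
    n_genes: int = 209
    n_structure_genes: int = 10
    structure_effect: float = 1.5
    base_rate: float = 0.5
    survival_beta: float = 0.7
    baseline_hazard_per_day: float = np.log(2) / 365.0
    followup_days: float = 1825.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.disorder <= 1.0):
            raise ValidationError(f"disorder must be in [0, 1], got {self.disorder}")
        if self.n_cells < 100:
            raise ValidationError("n_cells must be >= 100 in cohort mode")
        if self.n_structure_genes > self.n_genes:
            raise ValidationError("n_structure_genes cannot exceed n_genes")

    def gene_names(self) -> np.ndarray:
        struct = [f"STRUCT{i + 1:02d}" for i in range(self.n_structure_genes)]
        null = [f"GENE{i + 1:03d}" for i in range(self.n_genes - self.n_structure_genes)]
        return np.array(struct + null, dtype=object)

    def structure_genes(self) -> list[str]:
        return [f"STRUCT{i + 1:02d}" for i in range(self.n_structure_genes)]


@dataclass(frozen=True)
class SyntheticSample:
    cell_map: CellMap
    expression: ExpressionMatrix
    niche_truth: pd.Series  # planted per-cell niche label, index = cell_id
    disorder: float


@dataclass(frozen=True)
class SyntheticCohort:
    samples: dict[str, SyntheticSample]
    survival: SurvivalTable
    structure_scores: pd.Series  # planted standardized structure score per sample
    structure_genes: list[str]
    template: NicheTemplate

    def cell_maps(self) -> dict[str, CellMap]:
        return {sid: s.cell_map for sid, s in self.samples.items()}


def _vessel_paths(rng: np.random.Generator, cfg: SynthConfig) -> list[np.ndarray]:
    """Curvilinear vessel center-lines as random-walk polylines."""
    paths = []
    L = cfg.canvas_um
    for _ in range(cfg.n_vessels):
        # start on a random border point heading inward
        side = rng.integers(4)
        pos = rng.uniform(0, L)
        start = {
            0: (pos, 0.0),
            1: (pos, L),
            2: (0.0, pos),
            3: (L, pos),
        }[int(side)]
        heading = {0: np.pi / 2, 1: -np.pi / 2, 2: 0.0, 3: np.pi}[int(side)]
        heading += rng.uniform(-0.5, 0.5)
        pts = [np.array(start)]
        for _ in range(200):
            heading += rng.normal(0.0, 0.25)
            nxt = pts[-1] + cfg.vessel_step_um * np.array(
                [np.cos(heading), np.sin(heading)]
            )
            pts.append(nxt)
            if not (0 <= nxt[0] <= L and 0 <= nxt[1] <= L):
                break
        paths.append(np.array(pts))
    return paths


def _densify(path: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing."""
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        return path[:1]
    s = np.arange(0.0, total, spacing)
    x = np.interp(s, arclen, path[:, 0])
    y = np.interp(s, arclen, path[:, 1])
    return np.column_stack([x, y])


def generate_sample(
    template: NicheTemplate,
    config: SynthConfig,
    seed: int,
    sample_id: str = "S01",
) -> SyntheticSample:
    """Generate one tissue section.

    Cells are placed uniformly at constant density; planted niche
    territories (Voronoi blobs, a border band, and vessel-centred bands)
    determine each cell's niche, and its type is drawn from that niche's
    composition. Vessel strands are laid along polylines with
    ``vessel_spacing_um`` spacing: an endothelial core with mural flanks.
    With probability λ (= ``config.disorder``) a cell's label is redrawn
    from the global type frequency, so λ=1 yields spatially independent
    labels at unchanged density.
    """
    rng = np.random.default_rng(seed)
    L = config.canvas_um
    types = np.array(template.cell_types, dtype=object)
    t_index = {t: i for i, t in enumerate(types)}

    # --- vessel strands ---------------------------------------------------
    paths = _vessel_paths(rng, config)
    strand_xy, strand_type = [], []
    for path in paths:
        line = _densify(path, config.vessel_spacing_um)
        if len(line) < 2:
            continue
        tangent = np.gradient(line, axis=0)
        norm = np.hypot(tangent[:, 0], tangent[:, 1])
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]]) / norm[:, None]
        jitter = rng.normal(0.0, 2.0, size=line.shape)
        strand_xy.append(line + jitter)
        strand_type.extend(["endothelial"] * len(line))
        flank = rng.random(len(line)) < config.mural_flank_prob
        sign = rng.choice([-1.0, 1.0], size=len(line))
        off = line[flank] + (sign[flank] * config.mural_flank_offset_um)[:, None] * normal[flank]
        off += rng.normal(0.0, 2.0, size=off.shape)
        strand_xy.append(off)
        strand_type.extend(["mural"] * len(off))
    strand_xy = np.concatenate(strand_xy) if strand_xy else np.empty((0, 2))
    strand_type = np.array(strand_type, dtype=object)
    inside = (
        (strand_xy[:, 0] >= 0)
        & (strand_xy[:, 0] <= L)
        & (strand_xy[:, 1] >= 0)
        & (strand_xy[:, 1] <= L)
    )
    strand_xy, strand_type = strand_xy[inside], strand_type[inside]
    if len(strand_xy) > config.n_cells // 2:  # pathological configs only
        keep = rng.choice(len(strand_xy), config.n_cells // 2, replace=False)
        strand_xy, strand_type = strand_xy[keep], strand_type[keep]
    n_free = config.n_cells - len(strand_xy)

    # --- free cells and their planted niches ------------------------------
    free_xy = rng.uniform(0.0, L, size=(n_free, 2))
    dense_paths = (
        np.concatenate([_densify(p, 5.0) for p in paths]) if paths else np.empty((0, 2))
    )
    if len(dense_paths):
        d_vessel = cKDTree(dense_paths).query(free_xy)[0]
    else:
        d_vessel = np.full(n_free, np.inf)
    border = np.minimum.reduce(
        [free_xy[:, 0], free_xy[:, 1], L - free_xy[:, 0], L - free_xy[:, 1]]
    )
    # keep blob centers off the border/vessel bands; clamp for tiny canvases
    margin = min(template.border_band_um + template.perivascular_band_um, 0.35 * L)
    centers, center_niche = [], []
    for niche in _BLOB_NICHES:
        pts = rng.uniform(margin, L - margin, size=(template.centers_per_niche, 2))
        centers.append(pts)
        center_niche.extend([niche] * len(pts))
    centers = np.concatenate(centers)
    center_niche = np.array(center_niche, dtype=object)
    nearest_center = cKDTree(centers).query(free_xy)[1]

    niche = np.array(center_niche[nearest_center], dtype=object)
    niche[border <= template.border_band_um] = "peripheral"
    niche[d_vessel <= template.perivascular_band_um] = "perivascular"
    niche[d_vessel <= template.vascular_band_um] = "vascular"

    # --- planted labels ---------------------------------------------------
    free_type = np.empty(n_free, dtype=object)
    for name in template.niche_names:
        mask = niche == name
        if mask.any():
            free_type[mask] = rng.choice(
                types, size=int(mask.sum()), p=template.compositions[name]
            )

    xy = np.concatenate([strand_xy, free_xy]) if len(strand_xy) else free_xy
    cell_type = np.concatenate([strand_type, free_type])
    planted_niche = np.concatenate(
        [np.full(len(strand_xy), "vascular", dtype=object), niche]
    )

    # --- disorder: label resampling from the global frequency -------------
    lam = config.disorder
    niche_counts = pd.Series(planted_niche).value_counts()
    global_freq = np.zeros(len(types))
    for name, cnt in niche_counts.items():
        global_freq += cnt * template.compositions[name]
    global_freq /= global_freq.sum()
    redraw = rng.random(config.n_cells) < lam
    cell_type[redraw] = rng.choice(types, size=int(redraw.sum()), p=global_freq)

    cell_ids = np.array(
        [f"{sample_id}_c{i:06d}" for i in range(config.n_cells)], dtype=object
    )
    cm = CellMap(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "x": xy[:, 0],
                "y": xy[:, 1],
                "cell_type": cell_type,
                "sample_id": sample_id,
            }
        ),
        label_set=tuple(template.cell_types),
    )

    expr = _generate_expression(rng, config, cell_ids, cell_type, t_index, lam)
    truth = pd.Series(planted_niche, index=cell_ids, name="niche")
    return SyntheticSample(cm, expr, truth, lam)


def _generate_expression(
    rng: np.random.Generator,
    cfg: SynthConfig,
    cell_ids: np.ndarray,
    cell_type: np.ndarray,
    t_index: dict,
    lam: float,
) -> ExpressionMatrix:
    """Poisson counts with per-type log-normal baselines.

    Null genes: rate depends only on cell type. Structure genes: a shared
    baseline multiplied by ``0.3 + structure_effect * (1 − λ)``, so their
    expected sample-mean expression decreases linearly in λ.
    """
    genes = cfg.gene_names()
    n_struct = cfg.n_structure_genes
    n_types = len(t_index)
    # per-(type, gene) baselines, drawn once per sample from a fixed substream
    base_rng = np.random.default_rng(derive_seed(cfg.seed, "gene-baselines"))
    base = cfg.base_rate * base_rng.lognormal(0.0, 0.7, size=(n_types, cfg.n_genes))
    base[:, :n_struct] = cfg.base_rate  # structure genes: type-independent
    tcodes = np.array([t_index[t] for t in cell_type])
    rate = base[tcodes]
    rate[:, :n_struct] *= 0.3 + cfg.structure_effect * (1.0 - lam)
    counts = rng.poisson(rate).astype(np.int32)
    return ExpressionMatrix(counts, cell_ids, genes)


def simulate_survival(
    scores: pd.Series,
    beta: float,
    seed: int,
    baseline_hazard_per_day: float = np.log(2) / 365.0,
    followup_days: float = 1825.0,
    age_beta: float = 0.02,
    mgmt_beta: float = -0.3,
) -> SurvivalTable:
    """Exponential survival with hazard ∝ exp(β · score + covariate terms).

    ``scores`` indexes patients; censoring is independent uniform over the
    follow-up window (≈20% censored at the default baseline hazard). Age
    (centred at 60), sex (no effect), and MGMT methylation (protective)
    are included as covariates so adjusted hazard models have something to
    adjust for.
    """
    rng = np.random.default_rng(seed)
    n = len(scores)
    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.choice(np.array(["female", "male"], dtype=object), size=n)
    mgmt = rng.choice(
        np.array(["methylated", "unmethylated"], dtype=object), size=n
    )
    loghaz = (
        beta * scores.to_numpy(dtype=float)
        + age_beta * (age - 60.0)
        + mgmt_beta * (mgmt == "methylated")
    )
    rate = baseline_hazard_per_day * np.exp(loghaz)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, followup_days, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 0.5)  # strictly positive, half-day floor
    return SurvivalTable(
        pd.DataFrame(
            {
                "patient_id": scores.index.astype(str),
                "time": time,
                "event": event,
                "group": "",
                "age": age,
                "sex": sex,
                "mgmt": mgmt,
            }
        )
    )


def generate_cohort(
    template: NicheTemplate,
    config: SynthConfig,
    n_samples: int = 13,
    lambdas=None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a cohort of samples spanning a disorder schedule.

    ``lambdas`` defaults to a linear 0 → 1 schedule over the samples. Each
    sample doubles as one patient whose planted structure score is the
    standardized (1 − λ); survival times follow ``simulate_survival`` with
    the config's β.
    """
    if n_samples < 2:
        raise ValidationError("a cohort needs at least 2 samples")
    if lambdas is None:
        lambdas = np.linspace(0.0, 1.0, n_samples)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) != n_samples:
        raise ValidationError("lambda schedule length must equal n_samples")
    if np.ptp(lambdas) == 0 and config.survival_beta != 0:
        warnings.warn(
            "constant disorder schedule with nonzero survival beta: "
            "no structure contrast to detect",
            stacklevel=2,
        )
    master = config.seed if seed is None else seed
    samples: dict[str, SyntheticSample] = {}
    for i, lam in enumerate(lambdas):
        sid = f"S{i + 1:02d}"
        cfg_i = SynthConfig(**{**config.__dict__, "disorder": float(lam)})
        samples[sid] = generate_sample(
            template, cfg_i, derive_seed(master, "sample", sid), sample_id=sid
        )
    struct = 1.0 - lambdas
    sd = struct.std()
    scores = (struct - struct.mean()) / (sd if sd > 0 else 1.0)
    scores = pd.Series(scores, index=list(samples), name="structure_score")
    survival = simulate_survival(
        scores,
        config.survival_beta,
        derive_seed(master, "survival"),
        baseline_hazard_per_day=config.baseline_hazard_per_day,
        followup_days=config.followup_days,
    )
    return SyntheticCohort(
        samples=samples,
        survival=survival,
        structure_scores=scores,
        structure_genes=config.structure_genes(),
        template=template,
    )
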