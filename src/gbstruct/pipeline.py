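"""End-to-end orchestration: cohort in, report bundle out.

The pipeline ties the stages together in their natural order — graphs →
enrichment → TSS → niches → vessels → signature → survival — writing one
CSV per artifact plus a JSON run summary. Every randomized stage draws
its seed by hashing the config seed with the stage name (and sample id
where applicable), so results are independent of sample processing order
and reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .core import CellMap, PipelineConfig, ValidationError, derive_seed
from .enrichment import nhood_enrichment, self_enrichment
from .graphs import build_knn_graph, build_radius_graph, neighborhood_composition
from .niches import cluster_niches, niche_profiles, pool_compositions, refine_niches
from .survival import (
    cox_adjusted,
    derive_signature,
    gene_tss_correlation,
    km_estimate,
    logrank_test,
    sample_mean_expression,
    score_and_stratify,
)
from .tss import classify_structure, compute_tss, correlate_with_tss
from .vessels import compare_groups, detect_vessels, distance_to_vessel, vessel_stats

log = logging.getLogger("gbstruct")

__all__ = ["load_cohort_dir", "write_cohort_dir", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample_id: str | None, cause: Exception):
        self.stage, self.sample_id = stage, sample_id
        where = f"stage {stage!r}" + (f", sample {sample_id!r}" if sample_id else "")
        super().__init__(f"{where}: {cause}")


def write_cohort_dir(cohort, outdir) -> Path:
    """Write a synthetic cohort in the on-disk layout the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {"disorder": {}, "structure_genes": cohort.structure_genes}
    for sid, sample in cohort.samples.items():
        gio.write_cell_map(sample.cell_map, outdir / f"cells_{sid}.csv")
        gio.write_expression_mtx(
            sample.expression,
            outdir / f"expr_{sid}.mtx",
            outdir / f"expr_{sid}.cells.txt",
            outdir / f"expr_{sid}.genes.txt",
        )
        sample.niche_truth.rename("niche").to_frame().to_csv(
            outdir / f"truth_niches_{sid}.csv", index_label="cell_id"
        )
        truth["disorder"][sid] = sample.disorder
    gio.write_survival(cohort.survival, outdir / "survival.csv")
    truth["structure_scores"] = cohort.structure_scores.to_dict()
    gio.write_json(truth, outdir / "truth.json")
    return outdir


def load_cohort_dir(indir, label_set=None):
    """Load cell maps (+ optional expression, survival) from a cohort dir."""
    indir = Path(indir)
    cell_files = sorted(indir.glob("cells_*.csv"))
    if not cell_files:
        raise ValidationError(f"no samples: no cells_*.csv files in {indir}")
    if label_set is None:
        # one shared label universe across the cohort, so composition
        # columns and enrichment matrices align between samples
        observed: set[str] = set()
        for f in cell_files:
            observed |= set(pd.read_csv(f, usecols=["cell_type"])["cell_type"].astype(str))
        label_set = tuple(sorted(observed))
    cell_maps: dict[str, CellMap] = {}
    exprs = {}
    for f in cell_files:
        cm = gio.read_cell_map(f, label_set=label_set)
        sid = cm.sample_id
        cell_maps[sid] = cm
        mtx = indir / f"expr_{sid}.mtx"
        if mtx.exists():
            exprs[sid] = gio.read_expression(
                mtx, indir / f"expr_{sid}.cells.txt", indir / f"expr_{sid}.genes.txt"
            )
    surv_path = indir / "survival.csv"
    survival = gio.read_survival(surv_path) if surv_path.exists() else None
    return cell_maps, exprs, survival


def run_pipeline(config: PipelineConfig, indir, outdir) -> dict:
    """Run every stage on a cohort directory and write the report bundle.

    Returns the run summary (also written as ``summary.json``). Any stage
    failure aborts with the stage name and sample id in the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed

    try:
        cell_maps, exprs, survival = load_cohort_dir(indir)
    except Exception as exc:
        raise StageError("load", None, exc) from exc
    sample_ids = sorted(cell_maps)
    log.info("loaded %d samples", len(sample_ids))
    label_set = cell_maps[sample_ids[0]].label_set

    radius_graphs, knn_graphs, compositions = {}, {}, {}
    for sid in sample_ids:
        try:
            cm = cell_maps[sid]
            radius_graphs[sid] = build_radius_graph(cm, config.radius_um)
            knn_graphs[sid] = build_knn_graph(cm, config.knn_k)
            compositions[sid] = neighborhood_composition(cm, knn_graphs[sid])
        except Exception as exc:
            raise StageError("graph", sid, exc) from exc

    # --- enrichment and TSS ----------------------------------------------
    tss_values, self_enr = {}, {}
    for sid in sample_ids:
        try:
            res = nhood_enrichment(
                radius_graphs[sid],
                cell_maps[sid].cell_types,
                label_set,
                n_permutations=config.n_permutations,
                seed=derive_seed(seed, "enrich", sid),
            )
            gio_path = outdir / f"enrichment_z_{sid}.csv"
            res.z_frame().to_csv(gio_path, float_format=gio.FLOAT_FORMAT)
            tss_values[sid] = compute_tss(res, include_diagonal=config.include_diagonal)
            self_enr[sid] = self_enrichment(res)
        except Exception as exc:
            raise StageError("enrichment", sid, exc) from exc

    try:
        classes = classify_structure(tss_values)
        tss_table = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "tss": [tss_values[s] for s in sample_ids],
                "structure_class": [classes[s] for s in sample_ids],
            }
        )
        tss_table.to_csv(outdir / "tss.csv", index=False, float_format=gio.FLOAT_FORMAT)
        abundance = pd.DataFrame(
            {sid: cell_maps[sid].type_fractions() for sid in sample_ids}
        ).T
        corr_ab = correlate_with_tss(abundance, tss_values)
        corr_se = correlate_with_tss(pd.DataFrame(self_enr).T, tss_values)
        pd.DataFrame(
            {
                "abundance_r": corr_ab.r,
                "abundance_undefined": corr_ab.undefined,
                "self_enrichment_r": corr_se.r,
                "self_enrichment_undefined": corr_se.undefined,
            }
        ).to_csv(
            outdir / "structure_correlations.csv",
            index_label="cell_type",
            float_format=gio.FLOAT_FORMAT,
        )
    except Exception as exc:
        raise StageError("tss", None, exc) from exc

    # --- niches -----------------------------------------------------------
    try:
        pooled, isolated = pool_compositions(compositions)
        coords = {
            sid: cell_maps[sid].cells.set_index("cell_id")[["x", "y"]]
            for sid in sample_ids
        }
        initial = cluster_niches(
            pooled,
            config.niche_k,
            seed=derive_seed(seed, "niche"),
            isolated=isolated,
            coords=coords,
        )
        refined = refine_niches(initial, knn_graphs, max_iter=config.refine_max_iter)
        assignment = niche_profiles(refined, cell_maps, k=config.niche_k)
        lab_df = assignment.labels.rename("niche").reset_index()
        lab_df.to_csv(outdir / "niche_labels.csv", index=False)
        assignment.profiles.to_csv(
            outdir / "niche_profiles.csv", float_format=gio.FLOAT_FORMAT
        )
        assignment.sample_frequencies.to_csv(
            outdir / "niche_sample_frequencies.csv", float_format=gio.FLOAT_FORMAT
        )
    except Exception as exc:
        raise StageError("niches", None, exc) from exc

    # --- vessels ----------------------------------------------------------
    vessel_rows = []
    try:
        for sid in sample_ids:
            vset = detect_vessels(
                cell_maps[sid],
                vascular_types=config.vascular_types,
                linkage_um=config.vessel_link_um,
                min_size=config.vessel_min_cells,
            )
            stats_ = vessel_stats(
                vset, cell_maps[sid], large_min=config.large_vessel_min_cells
            )
            dmap = distance_to_vessel(
                cell_maps[sid],
                vset,
                cap_um=config.distance_cap_um,
                bin_um=config.distance_bin_um,
            )
            dmap.table.to_csv(
                outdir / f"vessel_distance_{sid}.csv",
                index=False,
                float_format=gio.FLOAT_FORMAT,
            )
            vessel_rows.append(
                {
                    "sample_id": sid,
                    "n_vessels": stats_["n_vessels"],
                    "percent_vessel": stats_["percent_vessel"],
                    "n_large": stats_["n_large"],
                    "max_size": max(stats_["sizes"], default=0),
                }
            )
        vdf = pd.DataFrame(vessel_rows).set_index("sample_id")
        vdf.to_csv(outdir / "vessels.csv", float_format=gio.FLOAT_FORMAT)
        vessel_tests = {}
        if min(pd.Series(classes).value_counts().reindex(["high", "low"]).fillna(0)) >= 2:
            for metric in ("percent_vessel", "n_large"):
                vessel_tests[metric] = compare_groups(vdf[metric], classes)
    except Exception as exc:
        raise StageError("vessels", None, exc) from exc

    # --- signature and survival -------------------------------------------
    summary = {
        "n_samples": len(sample_ids),
        "n_cells": int(sum(cm.n_cells for cm in cell_maps.values())),
        "tss": {s: tss_values[s] for s in sample_ids},
        "structure_class": classes,
        "n_niches": assignment.k,
        "vessel_tests": vessel_tests,
        "config": config.to_dict(),
    }
    if exprs and len(exprs) == len(sample_ids) and len(sample_ids) >= 3:
        try:
            corr = gene_tss_correlation(exprs, tss_values)
            signature = derive_signature(corr, threshold=config.signature_r_threshold)
            corr.assign(selected=corr.index.isin(signature.genes)).to_csv(
                outdir / "signature.csv",
                index_label="gene",
                float_format=gio.FLOAT_FORMAT,
            )
            summary["signature_genes"] = list(signature.genes)
        except Exception as exc:
            raise StageError("signature", None, exc) from exc
        if survival is not None and not signature.is_empty() and len(sample_ids) < 4:
            summary["survival_skipped"] = "fewer than 4 patients"
        elif survival is not None and not signature.is_empty():
            try:
                pseudobulk = sample_mean_expression(exprs)
                strat = score_and_stratify(pseudobulk, signature)
                strat.to_csv(
                    outdir / "survival_groups.csv",
                    index_label="patient_id",
                    float_format=gio.FLOAT_FORMAT,
                )
                groups = pd.Series(
                    strat["group"].to_numpy(), index=strat.index.astype(str)
                )
                curves = km_estimate(survival, groups)
                for gname, curve in curves.items():
                    curve.to_csv(
                        outdir / f"km_{gname}.csv",
                        index=False,
                        float_format=gio.FLOAT_FORMAT,
                    )
                lr = logrank_test(survival, groups)
                summary["logrank"] = lr
                st = survival.table.copy()
                st["group"] = groups.reindex(st["patient_id"]).to_numpy()
                try:
                    summary["cox"] = cox_adjusted(
                        type(survival)(st), group_col="group"
                    )
                except ValidationError as exc:
                    summary["cox"] = {"error": str(exc)}
            except StageError:
                raise
            except Exception as exc:
                raise StageError("survival", None, exc) from exc

    gio.write_json(summary, outdir / "summary.json")
    return summary
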