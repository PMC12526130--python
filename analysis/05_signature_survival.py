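"""Derive the structure signature and stratify survival.

Correlates per-gene sample-mean expression (library-size normalized,
log1p) with the TSS across samples, selects genes with r > 0.6 as the
structure signature, scores each patient (pseudo-bulk sample means) by
mean z-scored signature expression, median-splits into high/low groups,
and compares overall survival with Kaplan–Meier curves, the log-rank
test, and a Cox model adjusted for age, sex and MGMT status.
Requires 03_structure_scoring.py to have written results/tables/tss.csv.
"""

from pathlib import Path

import pandas as pd

import gbstruct as gb

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    _, exprs, survival = gb.load_cohort_dir(ROOT / "data")
    out = ROOT / "tables"
    tss = pd.read_csv(out / "tss.csv", index_col="sample_id")["tss"].to_dict()

    corr = gb.gene_tss_correlation(exprs, tss)
    signature = gb.derive_signature(corr, threshold=0.6)
    corr.assign(selected=corr.index.isin(signature.genes)).to_csv(
        out / "signature.csv", index_label="gene"
    )
    print(f"signature: {len(signature.genes)} genes with r > 0.6:")
    print("  " + ", ".join(signature.genes))

    pseudobulk = gb.sample_mean_expression(exprs)
    strat = gb.score_and_stratify(pseudobulk, signature)
    strat.to_csv(out / "survival_groups.csv", index_label="patient_id")
    groups = pd.Series(strat["group"].to_numpy(), index=strat.index.astype(str))

    curves = gb.km_estimate(survival, groups)
    for g, curve in curves.items():
        curve.to_csv(out / f"km_{g}.csv", index=False)
        median_t = curve.loc[curve["survival"] <= 0.5, "time"]
        med = f"{median_t.iloc[0]:.0f} d" if len(median_t) else "not reached"
        print(f"  {g} group: n = {int(curve['at_risk'].iloc[0])}, median survival {med}")

    lr = gb.logrank_test(survival, groups)
    print(f"log-rank: statistic {lr['statistic']:.2f}, p = {lr['p']:.4f}")

    table = survival.table.copy()
    # numeric indicator so the reported hazard ratio is high vs low
    table["group_high"] = (
        groups.reindex(table["patient_id"]).to_numpy() == "high"
    ).astype(float)
    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        cox = gb.cox_adjusted(gb.SurvivalTable(table), group_col="group_high")
    separated = cox["se"] > 10 or any("separation" in str(c.message) for c in caught)
    if separated:
        print(
            "adjusted hazards model: complete separation at this cohort size "
            f"(coef {cox['coef']:.1f}); the group effect is too strong for a "
            "finite hazard-ratio estimate"
        )
    else:
        print(
            f"adjusted hazard ratio (high vs low): {cox['hazard_ratio']:.2f} "
            f"[{cox['ci_low']:.2f}, {cox['ci_high']:.2f}], p = {cox['p']:.4f}"
        )


if __name__ == "__main__":
    main()
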