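"""Detect blood vessels and contrast vasculature between structure classes.

Vessels are single-linkage components (ε=30 µm) of endothelial+mural
cells with at least 5 members. Per sample this writes vessel counts,
sizes, the percentage of cells in vessels, and a distance-to-vessel map
capped at 150 µm; percent-vessel and large-vessel counts are compared
between highly and lowly structured samples with Welch t-tests.
Requires 03_structure_scoring.py to have written results/tables/tss.csv.
"""

from pathlib import Path

import pandas as pd

import gbstruct as gb

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cell_maps, _, _ = gb.load_cohort_dir(ROOT / "data")
    out = ROOT / "tables"
    classes = pd.read_csv(out / "tss.csv", index_col="sample_id")[
        "structure_class"
    ].to_dict()

    rows = []
    for sid, cm in cell_maps.items():
        vset = gb.detect_vessels(cm, linkage_um=30.0, min_size=5)
        stats = gb.vessel_stats(vset, cm, large_min=50)
        dmap = gb.distance_to_vessel(cm, vset, cap_um=150.0, bin_um=10.0)
        dmap.table.to_csv(out / f"vessel_distance_{sid}.csv", index=False)
        rows.append(
            {
                "sample_id": sid,
                "n_vessels": stats["n_vessels"],
                "percent_vessel": stats["percent_vessel"],
                "n_large": stats["n_large"],
                "max_size": max(stats["sizes"], default=0),
                "structure_class": classes[sid],
            }
        )
    vdf = pd.DataFrame(rows).set_index("sample_id")
    vdf.to_csv(out / "vessels.csv")
    print(vdf.round(2))

    for metric in ("percent_vessel", "n_large"):
        res = gb.compare_groups(vdf[metric], classes)
        print(
            f"\n{metric}: high {res['mean_high']:.2f} ± {res['sd_high']:.2f} "
            f"vs low {res['mean_low']:.2f} ± {res['sd_low']:.2f} "
            f"(Welch t = {res['t']:.2f}, p = {res['p']:.3g})"
        )


if __name__ == "__main__":
    main()
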