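# gbstruct

Spatial architecture analysis of glioblastoma from typed single-cell maps.

Targeted in-situ sequencing yields, per tissue section, a table of cells
with µm coordinates and cell-type labels (malignant states such as
AC-/NPC-/OPC-/MES-like, myeloid and lymphoid populations, glia,
endothelium, mural cells). `gbstruct` turns a cohort of such maps into a
quantitative account of tumor organization:

* **Niches** — each cell's microenvironment is the cell-type composition
  of its 15 nearest neighbors; pooled k-means over these vectors plus
  spatial majority refinement yields recurrent niches shared across
  samples (proliferative, hypoxia-responsive, vascular, peripheral, ...).
* **Tumor Structure Score (TSS)** — neighborhood enrichment compares, for
  every cell-type pair, the number of 40 µm-radius neighbor edges against
  a label-permutation null, giving a z-score matrix per sample; the TSS
  is the mean of |z| over type pairs. High TSS = compartmentalized,
  organized tissue; samples are median-split into highly/lowly
  structured.
* **Vessels** — endothelial+mural cells tightly connected in space
  (single-linkage, ε = 30 µm, ≥ 5 cells) form vessel components; the
  package reports counts, sizes, composition, percent of cells in
  vessels, distance-to-vessel maps (capped at 150 µm), and
  high-vs-low-structure contrasts (Welch t-tests).
* **Structure signature and survival** — genes whose per-sample mean
  expression has Pearson r > 0.6 with the TSS form a signature; patients
  scored by mean z-scored signature expression are median-split and
  compared by Kaplan–Meier curves, the log-rank test, and a Cox model
  adjusted for age, sex and MGMT status.

A synthetic tissue generator plants all of this structure — seven niche
territories, curvilinear vessels, structure-tracking genes, survival tied
to organization — behind a single disorder knob λ ∈ [0, 1], so every
stage is testable end to end without access to any real dataset.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
import gbstruct as gb

# a synthetic cohort: 13 sections, disorder 0 -> 1, one patient each
cohort = gb.generate_cohort(gb.default_template(), gb.SynthConfig(seed=0),
                            n_samples=13, seed=0)

tss = {}
for sid, sample in cohort.samples.items():
    g = gb.build_radius_graph(sample.cell_map, 40.0)
    res = gb.nhood_enrichment(g, sample.cell_map.cell_types,
                              sample.cell_map.label_set, 1000,
                              seed=gb.derive_seed(0, "enrich", sid))
    tss[sid] = gb.compute_tss(res)
print({s: round(v, 1) for s, v in list(tss.items())[:4]})
# {'S01': 35.0, 'S02': 27.6, 'S03': 23.8, 'S04': 19.2}
```

The ordered section (S01, λ=0) scores a TSS of ~35 — dozens of type
pairs co-locate far more than chance — and the score falls monotonically
toward ~0.7 for the fully shuffled section (S13, λ=1), where no pair
deviates from the permutation null.

The numbered drivers under `analysis/` run the full study on this cohort
and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # 13 samples, 130000 cells
python analysis/02_niche_identification.py # 7 niches, present in 7/7 samples
python analysis/03_structure_scoring.py    # TSS 35.0 ... 0.7, high/low split
python analysis/04_vessel_architecture.py  # percent-vessel 7.2 vs 5.2 (high vs low)
python analysis/05_signature_survival.py   # 10-gene signature, log-rank p = 0.0007
```

On the default cohort the niche stage recovers exactly 7 niches in every
sample; the signature stage selects exactly the 10 planted structure
genes; and the high-signature group has markedly shorter survival
(log-rank statistic 11.6, p = 0.0007; the 13-patient adjusted hazards
model separates completely, which the driver reports as such).

There is also a CLI mirroring the stages:

```bash
gbstruct simulate --n-samples 13 --seed 0 --outdir results/data
gbstruct run-all --indir results/data --seed 0 --outdir results/run
```

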