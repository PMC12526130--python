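"""Tumor Structure Score: per-sample tissue-organization quantification.

The TSS of a sample is the mean of the absolute neighborhood-enrichment
z-scores over unordered cell-type pairs (upper triangle of the z matrix,
diagonal included by default so self-organization contributes). High TSS
means cell types are compartmentalized into well-defined territories; low
TSS means a disordered patchwork. Samples are classified highly/lowly
structured by a median split, and organization is correlated with
per-type abundance and self-enrichment across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .enrichment import EnrichmentResult

__all__ = [
    "compute_tss",
    "classify_structure",
    "correlate_with_tss",
    "StructureCorrelations",
]


def compute_tss(result: EnrichmentResult, include_diagonal: bool = True) -> float:
    """Mean |z| over unordered type pairs.

    ``include_diagonal=True`` (default) averages the upper triangle
    including the diagonal, so each unordered pair — including same-type
    pairs — contributes once. Degenerate pairs carry z = 0 by the
    permutation-std guard and simply dilute the mean; an all-zero z gives
    TSS = 0.
    """
    z = result.z
    if z.size == 0:
        raise ValidationError("empty z matrix")
    iu = np.triu_indices(z.shape[0], k=0 if include_diagonal else 1)
    if len(iu[0]) == 0:
        raise ValidationError("no type pairs to average")
    return float(np.abs(z[iu]).mean())


def classify_structure(tss_per_sample: dict[str, float]) -> dict[str, str]:
    """Median split of per-sample TSS into {high, low}.

    Strictly above the median → ``high``; at or below → ``low`` (ties go
    low). All-equal TSS yields all-low with a warning.
    """
    if len(tss_per_sample) < 2:
        raise ValidationError("classification needs at least 2 samples")
    values = np.array(list(tss_per_sample.values()), dtype=float)
    med = float(np.median(values))
    if np.ptp(values) == 0:
        warnings.warn("all TSS values equal: every sample classified low", stacklevel=2)
    return {
        sid: ("high" if v > med else "low") for sid, v in tss_per_sample.items()
    }


@dataclass(frozen=True)
class StructureCorrelations:
    """Per-cell-type Pearson r of a sample-level quantity against TSS."""

    r: pd.Series
    undefined: pd.Series  # True where an input vector was constant


def correlate_with_tss(
    per_sample_values: pd.DataFrame, tss_per_sample: dict[str, float]
) -> StructureCorrelations:
    """Pearson r of each column of ``per_sample_values`` against TSS.

    ``per_sample_values`` is samples × cell-types (e.g. abundance
    fractions or self-enrichment scores), indexed by sample_id. Constant
    columns (or constant TSS) are flagged undefined and carry NaN.
    """
    samples = list(per_sample_values.index)
    if set(samples) != set(tss_per_sample):
        raise ValidationError("samples in values and TSS do not match")
    if len(samples) < 3:
        raise ValidationError("correlation needs at least 3 samples")
    tss = np.array([tss_per_sample[s] for s in samples], dtype=float)
    rs, undef = {}, {}
    tss_const = np.ptp(tss) == 0
    for col in per_sample_values.columns:
        v = per_sample_values[col].to_numpy(dtype=float)
        if np.ptp(v) == 0 or tss_const:
            rs[col], undef[col] = np.nan, True
        else:
            rs[col] = float(stats.pearsonr(v, tss)[0])
            undef[col] = False
    return StructureCorrelations(
        r=pd.Series(rs, name="r"), undefined=pd.Series(undef, name="undefined")
    )
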