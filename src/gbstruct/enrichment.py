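"""Permutation-null neighborhood enrichment between cell-type pairs.

For a fixed spatial graph, the observed statistic for a type pair (a, b)
is the number of undirected edges whose endpoint types are {a, b}, each
edge counted exactly once. The null is a uniform permutation of the type
labels over cells — the graph and the type frequencies are preserved —
and the enrichment z-score is (observed − permutation mean) / permutation
std, with z set to 0 wherever the permutation std is 0 (degenerate pairs:
absent types, single-type samples, tiny graphs). The diagonal of z is the
*self-enrichment* of each type: its tendency to neighbor its own kind
more often than random placement would produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError, derive_seed
from .graphs import SpatialGraph

__all__ = [
    "EnrichmentResult",
    "count_pair_edges",
    "nhood_enrichment",
    "cohort_enrichment",
    "self_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed pair-edge counts, permutation moments, and z-scores.

    All matrices are types × types and symmetric; the diagonal holds
    same-type edge counts (each counted once), so the sum over unordered
    pairs — upper triangle including the diagonal — equals the edge count.
    """

    cell_types: tuple[str, ...]
    observed: np.ndarray
    perm_mean: np.ndarray
    perm_std: np.ndarray
    z: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        for m in (self.observed, self.perm_mean, self.perm_std, self.z):
            if m.shape != (len(self.cell_types), len(self.cell_types)):
                raise ValidationError("enrichment matrices must be types x types")
        if not np.allclose(self.z, self.z.T):
            raise ValidationError("z matrix must be symmetric")
        if np.any(self.z[self.perm_std == 0] != 0):
            raise ValidationError("z must be 0 wherever the permutation std is 0")

    def z_frame(self) -> pd.DataFrame:
        t = list(self.cell_types)
        return pd.DataFrame(self.z, index=t, columns=t)


def _label_codes(labels, categories) -> tuple[np.ndarray, tuple[str, ...]]:
    categories = tuple(categories)
    lookup = {c: i for i, c in enumerate(categories)}
    try:
        codes = np.array([lookup[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"unknown cell type label {exc.args[0]!r}") from None
    return codes, categories


def _pair_counts(codes_i: np.ndarray, codes_j: np.ndarray, n_types: int) -> np.ndarray:
    """Symmetric pair-edge count matrix from per-edge endpoint codes."""
    a = np.minimum(codes_i, codes_j)
    b = np.maximum(codes_i, codes_j)
    flat = np.bincount(a * n_types + b, minlength=n_types * n_types)
    upper = flat.reshape(n_types, n_types).astype(np.float64)
    full = upper + upper.T - np.diag(np.diag(upper))
    return full


def count_pair_edges(graph: SpatialGraph, labels, categories) -> np.ndarray:
    """Observed counts: entry (a, b) = number of edges with endpoint types
    {a, b}; symmetric, diagonal = same-type edges, upper-triangle total =
    |E|.
    """
    codes, categories = _label_codes(labels, categories)
    if len(codes) != graph.n_nodes:
        raise ValidationError("labels must cover all graph nodes")
    return _pair_counts(codes[graph.edges_i], codes[graph.edges_j], len(categories))


def _permuted_counts(
    graph: SpatialGraph,
    codes: np.ndarray,
    n_types: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_permutations, T, T) pair-count matrices under label shuffling."""
    out = np.empty((n_permutations, n_types, n_types), dtype=np.float64)
    ei, ej = graph.edges_i, graph.edges_j
    for p in range(n_permutations):
        perm = codes[rng.permutation(len(codes))]
        out[p] = _pair_counts(perm[ei], perm[ej], n_types)
    return out


def nhood_enrichment(
    graph: SpatialGraph,
    labels,
    categories,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation neighborhood-enrichment z-scores for one sample.

    Labels are shuffled uniformly over cells ``n_permutations`` times with
    the graph fixed; deterministic given ``seed``. A single distinct label
    yields an all-zero z with a warning rather than an error.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    codes, categories = _label_codes(labels, categories)
    if len(codes) != graph.n_nodes:
        raise ValidationError("labels must cover all graph nodes")
    if len(np.unique(codes)) < 2:
        warnings.warn(
            "single cell type present: all enrichment z-scores are 0",
            stacklevel=2,
        )
    n_types = len(categories)
    observed = _pair_counts(codes[graph.edges_i], codes[graph.edges_j], n_types)
    rng = np.random.default_rng(seed)
    perms = _permuted_counts(graph, codes, n_types, n_permutations, rng)
    mean = perms.mean(axis=0)
    std = perms.std(axis=0)  # population std over permutations
    z = np.divide(observed - mean, std, out=np.zeros_like(mean), where=std > 0)
    return EnrichmentResult(
        categories, observed, mean, std, z, n_permutations, int(seed)
    )


def cohort_enrichment(
    members: dict[str, tuple[SpatialGraph, np.ndarray]],
    categories,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pooled enrichment over a group of samples.

    Observed counts are summed over member samples; the permutation null
    shuffles labels *within* each sample (its own graph fixed) and sums
    the per-sample counts permutation-by-permutation, so the pooled z has
    the same within-sample null as the per-sample statistic. Per-sample
    random streams are derived by hashing (seed, sample_id); a group with
    a single member therefore reproduces that sample's own result when
    given the same derived seed.
    """
    if not members:
        raise ValidationError("cohort group has no samples")
    categories = tuple(categories)
    n_types = len(categories)
    observed = np.zeros((n_types, n_types))
    totals = np.zeros((n_permutations, n_types, n_types))
    for sample_id in sorted(members):
        graph, labels = members[sample_id]
        codes, _ = _label_codes(labels, categories)
        if len(codes) != graph.n_nodes:
            raise ValidationError(
                f"labels do not cover graph nodes in sample {sample_id}"
            )
        observed += _pair_counts(
            codes[graph.edges_i], codes[graph.edges_j], n_types
        )
        rng = np.random.default_rng(derive_seed(seed, sample_id))
        totals += _permuted_counts(graph, codes, n_types, n_permutations, rng)
    mean = totals.mean(axis=0)
    std = totals.std(axis=0)
    z = np.divide(observed - mean, std, out=np.zeros_like(mean), where=std > 0)
    return EnrichmentResult(
        categories, observed, mean, std, z, n_permutations, int(seed)
    )


def self_enrichment(result: EnrichmentResult) -> pd.Series:
    """The diagonal of z, labeled by cell type."""
    return pd.Series(
        np.diag(result.z), index=list(result.cell_types), name="self_enrichment"
    )
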