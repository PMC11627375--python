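"""Spatial clustering of GWAS variants across traits, with a permutation null.

The statistic is the number of variant clusters containing two or more
distinct trait labels, where clusters are single-linkage groups of variants
on one chromosome with consecutive gaps <= ``max_gap`` (default 100 kb; the
semantics of ``bedtools cluster -d``). The null shuffles every variant to an
independent uniform position on its own chromosome, preserving the
per-(chromosome, trait) count exactly, and recounts the statistic.

The empirical p-value is ``#{null >= observed} / n_perms`` (one-sided
enrichment). With an integer-valued statistic this p is super-uniform under
the null; :attr:`PermutationResult.p_randomized` carries the tie-broken
variant, exactly Uniform(0,1) under exchangeability, used for calibration
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_core import GenomeAssembly, Variant

__all__ = [
    "ClusterResult",
    "PermutationResult",
    "cluster_variants",
    "shuffle_variants",
    "clustering_permutation_test",
]


@dataclass
class ClusterResult:
    """Cluster assignment of variants and multi-trait cluster tally."""

    cluster_assignments: dict[int, int]  # variant list index -> cluster id
    n_clusters: int
    n_multi_trait_clusters: int

    def __post_init__(self) -> None:
        assert self.n_multi_trait_clusters <= self.n_clusters


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null.

    ``p_empirical`` follows the count-based formula
    ``#{null >= observed} / n_perms``; when that count is zero it is reported
    as the bound ``1 / n_perms`` with ``p_is_upper_bound`` set (read it as
    "p < 1/n_perms"). ``z`` is ``(observed - null mean) / null SD``, NaN with
    ``z_defined=False`` when the null is degenerate (SD = 0).
    """

    observed: float
    null_values: np.ndarray
    n_perms: int
    seed: int
    n_greater_equal: int = field(init=False)
    n_equal: int = field(init=False)
    p_empirical: float = field(init=False)
    p_is_upper_bound: bool = field(init=False)
    z: float = field(init=False)
    z_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        null = np.asarray(self.null_values, dtype=float)
        self.n_greater_equal = int(np.sum(null >= self.observed))
        self.n_equal = int(np.sum(null == self.observed))
        if self.n_greater_equal == 0:
            self.p_empirical = 1.0 / self.n_perms
            self.p_is_upper_bound = True
        else:
            self.p_empirical = self.n_greater_equal / self.n_perms
            self.p_is_upper_bound = False
        sd = float(null.std())
        if sd == 0.0:
            self.z = float("nan")
            self.z_defined = False
        else:
            self.z = float((self.observed - null.mean()) / sd)
            self.z_defined = True

    @property
    def p_string(self) -> str:
        if self.p_is_upper_bound:
            return f"< {1.0 / self.n_perms:g}"
        return f"{self.p_empirical:g}"

    def p_smoothed(self) -> float:
        """Add-one smoothed p: ``(k + 1) / (n + 1)``."""
        n_greater = self.n_greater_equal  # count with >= convention
        return (n_greater + 1) / (self.n_perms + 1)

    def p_randomized(self, rng: np.random.Generator) -> float:
        """Tie-broken p-value, exactly Uniform(0,1) under exchangeability.

        ``(#{null > obs} + U * (1 + #{null == obs})) / (n_perms + 1)`` with
        U ~ Uniform(0,1); used to assess calibration of discrete statistics.
        """
        n_strict = self.n_greater_equal - self.n_equal
        u = rng.random()
        return (n_strict + u * (1 + self.n_equal)) / (self.n_perms + 1)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "z": None if not self.z_defined else self.z,
            "z_defined": self.z_defined,
            "p_empirical": self.p_empirical,
            "p_is_upper_bound": self.p_is_upper_bound,
            "p_string": self.p_string,
            "n_perms": self.n_perms,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _encode(variants, assembly: GenomeAssembly):
    """Map variants onto one super-coordinate axis with inter-chromosome
    spacers wide enough that clusters can never span chromosomes."""
    chrom_index = {c: i for i, (c, _) in enumerate(assembly.chromosomes)}
    lengths = np.array([length for _, length in assembly.chromosomes], dtype=np.int64)
    c = np.array([chrom_index[v.chrom] for v in variants], dtype=np.int64)
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    traits = sorted({v.cancer for v in variants})
    trait_index = {t: i for i, t in enumerate(traits)}
    t = np.array([trait_index[v.cancer] for v in variants], dtype=np.int64)
    return c, pos, t, lengths, len(traits)


def _chrom_offsets(lengths: np.ndarray, max_gap: int) -> np.ndarray:
    spaced = lengths + max_gap + 2
    return np.concatenate([[0], np.cumsum(spaced)[:-1]])


def _count_clusters(x: np.ndarray, t: np.ndarray, n_traits: int, max_gap: int):
    """(n_clusters, n_multi_trait) for super-coordinates x with trait codes t."""
    if len(x) == 0:
        return 0, 0
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ts = t[order]
    new = np.empty(len(xs), dtype=bool)
    new[0] = True
    np.greater(xs[1:] - xs[:-1], max_gap, out=new[1:])
    cid = np.cumsum(new) - 1
    n_clusters = int(cid[-1]) + 1
    # distinct traits per cluster via unique (cluster, trait) pairs
    pair = cid * n_traits + ts
    uniq = np.unique(pair)
    per_cluster = np.bincount(uniq // n_traits, minlength=n_clusters)
    return n_clusters, int(np.sum(per_cluster >= 2))


def cluster_variants(
    variants: list[Variant],
    assembly: GenomeAssembly,
    max_gap: int = 100_000,
    mode: str = "linkage",
) -> ClusterResult:
    """Assign variants to clusters and count multi-trait clusters.

    ``mode='linkage'`` (default) uses single-linkage max-gap clustering:
    consecutive position-sorted variants on one chromosome join one cluster
    iff their gap is <= ``max_gap``. ``mode='tiling'`` instead bins variants
    into fixed non-overlapping windows of ``max_gap`` bp (sensitivity
    alternative).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if mode not in ("linkage", "tiling"):
        raise ValueError(f"unknown mode {mode!r}")
    if not variants:
        return ClusterResult({}, 0, 0)
    c, pos, t, lengths, n_traits = _encode(variants, assembly)
    if mode == "tiling":
        window = max(max_gap, 1)
        key = c * (int(lengths.max()) // window + 2) + pos // window
        uniq, cid = np.unique(key, return_inverse=True)
        n_clusters = len(uniq)
        pair = np.unique(cid * n_traits + t)
        per_cluster = np.bincount(pair // n_traits, minlength=n_clusters)
        n_multi = int(np.sum(per_cluster >= 2))
        assignments = {i: int(cid[i]) for i in range(len(variants))}
        return ClusterResult(assignments, n_clusters, n_multi)
    offsets = _chrom_offsets(lengths, max_gap)
    x = offsets[c] + pos
    order = np.argsort(x, kind="stable")
    xs = x[order]
    new = np.empty(len(xs), dtype=bool)
    new[0] = True
    new[1:] = (xs[1:] - xs[:-1]) > max_gap
    cid_sorted = np.cumsum(new) - 1
    cid = np.empty(len(xs), dtype=np.int64)
    cid[order] = cid_sorted
    n_clusters, n_multi = _count_clusters(x, t, n_traits, max_gap)
    assignments = {i: int(cid[i]) for i in range(len(variants))}
    return ClusterResult(assignments, n_clusters, n_multi)


def shuffle_variants(
    variants: list[Variant],
    assembly: GenomeAssembly,
    rng_seed: int | np.random.Generator,
) -> list[Variant]:
    """Shuffle variant positions uniformly within their own chromosomes.

    Chromosome, trait label and signal ID are untouched, so per-(chromosome,
    trait) counts are conserved exactly — the chromosome-preserving null.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lengths = assembly.lengths
    out = []
    for v in variants:
        new_pos = int(rng.integers(0, lengths[v.chrom]))
        out.append(
            Variant(
                id=v.id,
                chrom=v.chrom,
                pos=new_pos,
                cancer=v.cancer,
                signal_id=v.signal_id,
                is_index=v.is_index,
                r2=v.r2,
            )
        )
    return out


def clustering_permutation_test(
    variants: list[Variant],
    assembly: GenomeAssembly,
    max_gap: int = 100_000,
    n_perms: int = 1_000_000,
    rng_seed: int = 0,
) -> PermutationResult:
    """Permutation test for cross-trait spatial clustering enrichment.

    Observed statistic: number of multi-trait clusters at the real positions.
    Null: all variants re-placed uniformly per chromosome each iteration
    (jointly, all traits at once), statistic recounted. One-sided p for
    enrichment (null >= observed).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    c, pos, t, lengths, n_traits = _encode(variants, assembly)
    offsets = _chrom_offsets(lengths, max_gap)
    _, observed = _count_clusters(offsets[c] + pos, t, n_traits, max_gap)
    rng = np.random.default_rng(rng_seed)
    var_lengths = lengths[c].astype(float)
    null = np.empty(n_perms, dtype=np.int64)
    for i in range(n_perms):
        rand_pos = (rng.random(len(c)) * var_lengths).astype(np.int64)
        _, null[i] = _count_clusters(offsets[c] + rand_pos, t, n_traits, max_gap)
    return PermutationResult(
        observed=float(observed),
        null_values=null,
        n_perms=n_perms,
        seed=rng_seed if isinstance(rng_seed, int) else -1,
    )
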