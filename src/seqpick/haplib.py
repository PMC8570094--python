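"""Haplotype library construction and the animal x haplotype incidence matrix.

The genome is tiled into non-overlapping blocks of consecutive SNPs
(default 100 per block) within each chromosome.  Within a block, the 2n
observed haplotypes are deduplicated and then merged by greedy leader
clustering with a mismatch tolerance (default 10% of the block length),
so that haplotypes differing at only a few sites count as identical.
The resulting library induces a sparse binary incidence matrix A with
a_ij = 1 iff animal j carries haplotype cluster i on at least one
chromosome copy; carriage is binary, so homozygous carriers contribute a
single 1.  Cluster frequencies are counts over the 2n observed gametes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from seqpick.simulator import PhasedPopulation

__all__ = [
    "BlockDefinition",
    "HaplotypeCluster",
    "HaplotypeLibrary",
    "IncidenceMatrix",
    "define_blocks",
    "cluster_block_haplotypes",
    "build_library",
    "build_incidence",
    "filter_common",
]

DEFAULT_BLOCK_LENGTH = 100
DEFAULT_MISMATCH = 0.10
DEFAULT_MIN_FREQ = 0.01


@dataclass(frozen=True)
class BlockDefinition:
    """One haplotype block: a half-open window [start, end) of SNP columns.

    Indices are global 0-based column indices into the phased matrix;
    blocks never span chromosome boundaries.
    """

    block_id: int
    chromosome: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeCluster:
    haplotype_id: int
    block_id: int
    representative: np.ndarray
    count: int
    frequency: float


@dataclass
class HaplotypeLibrary:
    """Per-block clusters of distinct (mismatch-merged) haplotypes."""

    blocks: list[BlockDefinition]
    clusters: list[HaplotypeCluster]
    n_animals: int
    #: per block, per observed gamete-haplotype (2n of them), the global
    #: cluster id it was assigned to; used to build the incidence matrix
    assignments: list[np.ndarray]

    @property
    def p(self) -> int:
        """Total number of distinct haplotypes across all blocks."""
        return len(self.clusters)


@dataclass
class IncidenceMatrix:
    """Sparse binary p x n matrix: haplotypes (rows) by animals (columns).

    ``h`` holds the row (haplotype) frequencies over 2n gametes;
    ``common_mask`` flags rows at or above the common-frequency threshold.
    """

    A: sp.csr_matrix
    h: np.ndarray
    animal_ids: np.ndarray
    haplotype_ids: np.ndarray
    common_mask: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]


def define_blocks(snp_chrom: np.ndarray, block_length: int = DEFAULT_BLOCK_LENGTH) -> list[BlockDefinition]:
    """Tile each chromosome with consecutive windows of ``block_length`` SNPs.

    A trailing shorter block is emitted when a chromosome's SNP count is
    not a multiple of the block length.
    """
    snp_chrom = np.asarray(snp_chrom)
    if snp_chrom.size == 0:
        raise ValueError("empty SNP map")
    if block_length <= 0:
        raise ValueError("block_length must be positive")
    if np.any(np.diff(snp_chrom) < 0):
        raise ValueError("SNP map must be sorted by chromosome")
    blocks: list[BlockDefinition] = []
    block_id = 0
    for chrom in np.unique(snp_chrom):
        cols = np.flatnonzero(snp_chrom == chrom)
        lo, hi = cols[0], cols[-1] + 1
        for start in range(lo, hi, block_length):
            end = min(start + block_length, hi)
            blocks.append(BlockDefinition(block_id, int(chrom), int(start), int(end)))
            block_id += 1
    return blocks


def _hamming_to_reps(reps: np.ndarray, hap: np.ndarray) -> np.ndarray:
    return np.count_nonzero(reps != hap[None, :], axis=1)


def cluster_block_haplotypes(
    observed: np.ndarray, mismatch_tolerance: float = DEFAULT_MISMATCH
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy leader clustering of one block's observed haplotypes.

    Distinct raw haplotypes are processed in descending raw-count order
    (ties by lexicographic allele string).  Each joins the first existing
    cluster whose representative differs at <= floor(tolerance * L)
    sites ("up to" the tolerance is inclusive), else founds a new cluster
    with itself as representative.

    Returns ``(representatives, counts, assignment)`` where
    ``representatives`` is (k, L), ``counts`` the per-cluster summed raw
    counts, and ``assignment`` maps each row of ``observed`` to its
    cluster index.
    """
    observed = np.ascontiguousarray(observed, dtype=np.uint8)
    if observed.ndim != 2:
        raise ValueError("observed must be a 2-D array of allele vectors")
    if not 0.0 <= mismatch_tolerance < 0.5:
        raise ValueError("mismatch_tolerance must be in [0, 0.5)")
    L = observed.shape[1]
    max_diff = int(np.floor(mismatch_tolerance * L))

    distinct, inverse, counts = np.unique(
        observed, axis=0, return_inverse=True, return_counts=True
    )
    # descending count; ties by lexicographic allele string (np.unique
    # already yields lexicographic order, and argsort is stable)
    order = np.argsort(-counts, kind="stable")

    rep_rows: list[int] = []
    cluster_counts: list[int] = []
    distinct_to_cluster = np.empty(len(distinct), dtype=np.int64)
    reps_arr = np.empty((0, L), dtype=np.uint8)
    for d in order:
        hap = distinct[d]
        if len(rep_rows):
            dists = _hamming_to_reps(reps_arr, hap)
            hits = np.flatnonzero(dists <= max_diff)
        else:
            hits = np.empty(0, dtype=np.int64)
        if hits.size:
            k = int(hits[0])
            cluster_counts[k] += int(counts[d])
        else:
            k = len(rep_rows)
            rep_rows.append(int(d))
            cluster_counts.append(int(counts[d]))
            reps_arr = np.vstack([reps_arr, hap[None, :]])
        distinct_to_cluster[d] = k

    assignment = distinct_to_cluster[inverse]
    return reps_arr, np.asarray(cluster_counts, dtype=np.int64), assignment


def build_library(
    pop: PhasedPopulation,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    mismatch_tolerance: float = DEFAULT_MISMATCH,
) -> HaplotypeLibrary:
    """Build the full haplotype library for a phased population."""
    haps = pop.haplotypes
    if haps.max() > 1 or haps.min() < 0:
        raise ValueError("alleles must be biallelic 0/1")
    n = pop.n_animals
    blocks = define_blocks(pop.snp_chrom, block_length)
    clusters: list[HaplotypeCluster] = []
    assignments: list[np.ndarray] = []
    next_id = 0
    two_n = 2 * n
    for blk in blocks:
        observed = haps[:, :, blk.start : blk.end].reshape(two_n, blk.length)
        reps, counts, assign = cluster_block_haplotypes(observed, mismatch_tolerance)
        for k in range(len(counts)):
            clusters.append(
                HaplotypeCluster(
                    haplotype_id=next_id + k,
                    block_id=blk.block_id,
                    representative=reps[k],
                    count=int(counts[k]),
                    frequency=counts[k] / two_n,
                )
            )
        assignments.append(assign + next_id)
        next_id += len(counts)
    return HaplotypeLibrary(blocks=blocks, clusters=clusters, n_animals=n, assignments=assignments)


def build_incidence(pop: PhasedPopulation, library: HaplotypeLibrary) -> IncidenceMatrix:
    """Form the sparse binary incidence matrix A from a built library.

    a_ij = 1 iff at least one of animal j's two block haplotypes was
    assigned to cluster i; homozygous carriage still yields a single 1.
    """
    n = pop.n_animals
    if library.n_animals != n:
        raise ValueError("library was built from a different population size")
    p = library.p
    rows_parts = []
    cols_parts = []
    animal_index = np.repeat(np.arange(n), 2)  # gamete g belongs to animal g//2
    for assign in library.assignments:
        rows_parts.append(assign)
        cols_parts.append(animal_index)
    rows = np.concatenate(rows_parts)
    cols = np.concatenate(cols_parts)
    data = np.ones(len(rows), dtype=np.int8)
    A = sp.coo_matrix((data, (rows, cols)), shape=(p, n)).tocsr()
    A.data = np.ones_like(A.data)  # carriage, not dosage
    h = np.array([c.frequency for c in library.clusters])
    return IncidenceMatrix(
        A=A,
        h=h,
        animal_ids=pop.animal_ids.copy(),
        haplotype_ids=np.arange(p),
        common_mask=None,
    )


def filter_common(M: IncidenceMatrix, min_freq: float = DEFAULT_MIN_FREQ) -> IncidenceMatrix:
    """Keep only rows with frequency >= ``min_freq`` (the common haplotypes).

    The frequency exactly at the threshold is retained; only strictly
    lower frequencies are excluded.  Animal columns are preserved, so
    some columns may become all-zero.
    """
    if not 0.0 <= min_freq < 1.0:
        raise ValueError("min_freq must be in [0, 1)")
    keep = M.h >= min_freq
    if not keep.any():
        raise ValueError("frequency filter removed every haplotype (empty problem)")
    sub = M.A[keep].tocsr()
    return IncidenceMatrix(
        A=sub,
        h=M.h[keep],
        animal_ids=M.animal_ids,
        haplotype_ids=M.haplotype_ids[keep],
        common_mask=np.ones(int(keep.sum()), dtype=bool),
    )
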