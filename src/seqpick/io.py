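"""Readers and writers for the formats seqpick touches.

Phased VCF (GT with ``|``; ``/`` is rejected), a plain haplotype-matrix
TSV (one row per gamete: animal_id, hap_index, allele string), pedigree
CSV, the library as JSON, and the incidence matrix as Matrix Market with
row/column label sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from seqpick.haplib import HaplotypeLibrary, IncidenceMatrix
from seqpick.simulator import PhasedPopulation

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_haplotype_tsv",
    "read_haplotype_tsv",
    "write_pedigree_csv",
    "write_library_json",
    "write_incidence_mtx",
    "read_incidence_mtx",
]


def write_vcf(pop: PhasedPopulation, path) -> None:
    """Write the population as a minimal phased VCF (chr1..chrK contigs).

    Positions are 1-based SNP indices within each chromosome; REF/ALT
    are placeholder A/B alleles since only the 0/1 phase matters.
    """
    path = Path(path)
    chroms = np.unique(pop.snp_chrom)
    sample_names = [f"ANIMAL_{int(a)}" for a in pop.animal_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seqpick\n")
        for c in chroms:
            n_c = int((pop.snp_chrom == c).sum())
            fh.write(f"##contig=<ID=chr{int(c) + 1},length={n_c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        h0 = pop.haplotypes[:, 0, :]
        h1 = pop.haplotypes[:, 1, :]
        pos_within = np.zeros(pop.n_snps, dtype=np.int64)
        for c in chroms:
            cols = np.flatnonzero(pop.snp_chrom == c)
            pos_within[cols] = np.arange(1, len(cols) + 1)
        for s in range(pop.n_snps):
            gts = "\t".join(f"{h0[j, s]}|{h1[j, s]}" for j in range(pop.n_animals))
            fh.write(
                f"chr{int(pop.snp_chrom[s]) + 1}\t{pos_within[s]}\tsnp{s}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> PhasedPopulation:
    """Read a phased biallelic VCF into a population.

    Every genotype must be phased (``|``); unphased or missing calls
    raise ``ValueError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    h0_rows, h1_rows, chroms = [], [], []
    chrom_ids: dict[str, int] = {}
    for var in vcf:
        g = var.genotype.array()
        if np.any(g[:, 2] == 0):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        if np.any(g[:, :2] < 0):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        if np.any(g[:, :2] > 1):
            raise ValueError(f"non-biallelic genotype at {var.CHROM}:{var.POS}")
        h0_rows.append(g[:, 0].astype(np.uint8))
        h1_rows.append(g[:, 1].astype(np.uint8))
        if var.CHROM not in chrom_ids:
            chrom_ids[var.CHROM] = len(chrom_ids)
        chroms.append(chrom_ids[var.CHROM])
    if not h0_rows:
        raise ValueError("VCF contains no variants")
    h0 = np.stack(h0_rows, axis=1)
    h1 = np.stack(h1_rows, axis=1)
    haps = np.stack([h0, h1], axis=1)
    ids = []
    for s in samples:
        ids.append(int(s.rsplit("_", 1)[1]) if s.startswith("ANIMAL_") else len(ids))
    return PhasedPopulation(
        animal_ids=np.asarray(ids, dtype=np.int64),
        haplotypes=haps,
        snp_chrom=np.asarray(chroms, dtype=np.int64),
        sex=np.full(n, -1, dtype=np.int8),
        generation=np.zeros(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
    )


def write_haplotype_tsv(pop: PhasedPopulation, path) -> None:
    """One row per gamete: animal_id, hap_index (1/2), allele string.

    A leading comment line records the per-chromosome SNP counts so the
    map can be reconstructed on read.
    """
    path = Path(path)
    chroms, counts = np.unique(pop.snp_chrom, return_counts=True)
    with open(path, "w") as fh:
        fh.write("#chrom_snp_counts=" + ",".join(str(int(c)) for c in counts) + "\n")
        fh.write("animal_id\thap_index\talleles\n")
        for j in range(pop.n_animals):
            for g in (0, 1):
                alleles = "".join(map(str, pop.haplotypes[j, g]))
                fh.write(f"{int(pop.animal_ids[j])}\t{g + 1}\t{alleles}\n")


def read_haplotype_tsv(path) -> PhasedPopulation:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#chrom_snp_counts="):
            raise ValueError("missing chromosome map header line")
        counts = [int(x) for x in header.split("=", 1)[1].split(",")]
        df = pd.read_csv(fh, sep="\t", dtype={"animal_id": np.int64, "alleles": str})
    snp_chrom = np.repeat(np.arange(len(counts)), counts)
    ids = df["animal_id"].unique()
    n = len(ids)
    m = len(snp_chrom)
    haps = np.empty((n, 2, m), dtype=np.uint8)
    pos = {int(a): j for j, a in enumerate(ids)}
    for _, row in df.iterrows():
        vec = np.frombuffer(row["alleles"].encode(), dtype=np.uint8) - ord("0")
        if len(vec) != m:
            raise ValueError("allele string length does not match the SNP map")
        haps[pos[int(row["animal_id"])], int(row["hap_index"]) - 1] = vec
    return PhasedPopulation(
        animal_ids=ids.astype(np.int64),
        haplotypes=haps,
        snp_chrom=snp_chrom,
        sex=np.full(n, -1, dtype=np.int8),
        generation=np.zeros(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
    )


def write_pedigree_csv(pop: PhasedPopulation, path) -> None:
    df = pd.DataFrame(
        {
            "animal": pop.animal_ids,
            "sire": pop.sire,
            "dam": pop.dam,
            "sex": np.where(pop.sex == 0, "M", "F"),
            "generation": pop.generation,
        }
    )
    df.to_csv(path, index=False)


def write_library_json(library: HaplotypeLibrary, path) -> None:
    payload = {
        "n_animals": library.n_animals,
        "p": library.p,
        "blocks": [
            {
                "block_id": b.block_id,
                "chromosome": b.chromosome,
                "start": b.start,
                "end": b.end,
            }
            for b in library.blocks
        ],
        "clusters": [
            {
                "haplotype_id": c.haplotype_id,
                "block_id": c.block_id,
                "representative": "".join(map(str, c.representative)),
                "count": c.count,
                "frequency": c.frequency,
            }
            for c in library.clusters
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_incidence_mtx(M: IncidenceMatrix, prefix) -> None:
    """Write A as Matrix Market plus ``.rows``/``.cols`` label sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), M.A.tocoo())
    np.savetxt(prefix.with_suffix(".rows"), np.c_[M.haplotype_ids, M.h], fmt="%d %.10g")
    np.savetxt(prefix.with_suffix(".cols"), M.animal_ids, fmt="%d")


def read_incidence_mtx(prefix) -> IncidenceMatrix:
    prefix = Path(prefix)
    A = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    A.data = np.ones_like(A.data)
    rows = np.loadtxt(prefix.with_suffix(".rows"), ndmin=2)
    cols = np.loadtxt(prefix.with_suffix(".cols"), dtype=np.int64, ndmin=1)
    return IncidenceMatrix(
        A=A,
        h=rows[:, 1],
        animal_ids=cols,
        haplotype_ids=rows[:, 0].astype(np.int64),
    )
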