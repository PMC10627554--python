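"""Diploid SNP genotype matrices with a population map, plus VCF I/O.

The in-memory container is a loci x individuals matrix of alternate-allele
counts (0/1/2) together with an individual -> population assignment.  On
disk it is a minimal VCFv4.2 (single contig ``chrSim``, GT-only, unphased)
and a two-column whitespace-separated population map, the common conventions
for unlinked GBS SNP panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class GenotypeSnpMatrix:
    """Unlinked biallelic SNP genotypes for a set of diploid individuals.

    Parameters
    ----------
    genotypes
        ``(n_loci, n_individuals)`` array of alternate-allele counts in
        {0, 1, 2}; -1 marks a missing call.
    samples
        Individual identifiers, one per column.
    populations
        Population label of each individual (same order as ``samples``).
    locus_ids
        Optional locus identifiers; defaults to ``L1..Ln``.
    """

    genotypes: np.ndarray
    samples: list[str]
    populations: list[str]
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (loci x individuals)")
        n_loci, n_ind = self.genotypes.shape
        if len(self.samples) != n_ind or len(self.populations) != n_ind:
            raise ValueError("samples/populations length mismatch")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if not self.locus_ids:
            self.locus_ids = [f"L{i + 1}" for i in range(n_loci)]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def population_names(self) -> list[str]:
        return list(dict.fromkeys(self.populations))

    def columns_for(self, pop: str) -> np.ndarray:
        cols = np.array(
            [i for i, p in enumerate(self.populations) if p == pop],
            dtype=np.int64,
        )
        if cols.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return cols

    def subset_populations(self, pops: list[str]) -> "GenotypeSnpMatrix":
        cols = np.concatenate([self.columns_for(p) for p in pops])
        return GenotypeSnpMatrix(
            self.genotypes[:, cols],
            [self.samples[i] for i in cols],
            [self.populations[i] for i in cols],
            list(self.locus_ids),
        )

    # -- I/O ---------------------------------------------------------------

    def write_vcf(self, path) -> None:
        """Write a minimal VCFv4.2: contig chrSim, positions 1..n_loci,
        alleles A/T, GT-only unphased."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID=chrSim,length={max(self.n_loci, 1)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
            for i in range(self.n_loci):
                row = "\t".join(code[int(g)] for g in self.genotypes[i])
                fh.write(f"chrSim\t{i + 1}\t{self.locus_ids[i]}\tA\tT\t.\t"
                         f"PASS\t.\tGT\t{row}\n")

    def write_popmap(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in zip(self.samples, self.populations):
                fh.write(f"{s}\t{p}\n")

    @classmethod
    def from_vcf(cls, vcf_path, popmap_path) -> "GenotypeSnpMatrix":
        """Read genotypes from a VCF (plain or bgzipped) and a popmap.

        Only samples present in the popmap are kept, in VCF column order.
        Multi-allelic sites raise; GT alone is interpreted.
        """
        from cyvcf2 import VCF

        popmap = read_popmap(popmap_path)
        vcf = VCF(str(vcf_path))
        keep = [i for i, s in enumerate(vcf.samples) if s in popmap]
        if not keep:
            raise ValueError("no VCF sample appears in the population map")
        samples = [vcf.samples[i] for i in keep]
        rows = []
        ids = []
        for var in vcf:
            if len(var.ALT) > 1:
                raise ValueError(
                    f"multi-allelic site at {var.CHROM}:{var.POS}"
                )
            gt = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            row = np.empty(len(keep), dtype=np.int8)
            for j, i in enumerate(keep):
                g = gt[i]
                row[j] = {0: 0, 1: 1, 3: 2}.get(int(g), -1)
            rows.append(row)
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        vcf.close()
        geno = (np.vstack(rows) if rows
                else np.empty((0, len(keep)), dtype=np.int8))
        return cls(geno, samples, [popmap[s] for s in samples], ids)


def read_popmap(path) -> dict[str, str]:
    """Two whitespace-separated columns: sample then population."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            out[parts[0]] = parts[1]
    return out
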