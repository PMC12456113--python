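"""Readers and writers: VCF, plain genotype TSV, popmap, coordinates.

VCF is the canonical interchange format (1-based positions, standard).
Simulated VCFs set REF to the ancestral and ALT to the derived allele, so
genotype codes count derived alleles; for real, unpolarised VCFs the codes
count ALT alleles and polarisation-sensitive single-site statistics should
be interpreted accordingly.  The TSV matrix (individuals x loci, -1 for
missing) exists for human-readable fixtures.  Internal locus indices are
0-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coalsim import MISSING, GenotypeMatrix

__all__ = [
    "read_popmap",
    "write_popmap",
    "read_genotypes",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_vcf",
    "write_vcf",
    "read_coordinates",
]


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV: individual, population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["individual"], df["population"]))


def write_popmap(g: GenotypeMatrix, path) -> None:
    pd.DataFrame({"individual": g.individuals, "population": g.populations}) \
        .to_csv(path, sep="\t", header=False, index=False)


def write_matrix_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.genotypes, index=g.individuals, columns=g.loci)
    df.to_csv(path, sep="\t", index_label="individual")


def read_matrix_tsv(path, popmap: dict[str, str]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual")
    return _apply_popmap(df.to_numpy(dtype=np.int8), list(df.index),
                         list(df.columns), popmap)


def _apply_popmap(gt, individuals, loci, popmap) -> GenotypeMatrix:
    unknown = [i for i in individuals if i not in popmap]
    if unknown:
        raise ValueError(f"individuals absent from popmap: {unknown}")
    # order individuals as in the popmap
    order = [i for i in popmap if i in set(individuals)]
    idx = [individuals.index(i) for i in order]
    gt = np.asarray(gt)[idx]
    return GenotypeMatrix(gt, order, [popmap[i] for i in order], list(loci))


def write_vcf(g: GenotypeMatrix, path, chrom_prefix: str = "locus") -> None:
    """Biallelic VCF, one record per locus; REF=A (ancestral), ALT=T (derived)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in g.loci:
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individuals) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, locus in enumerate(g.loci):
            calls = "\t".join(code[int(x)] for x in g.genotypes[:, j])
            fh.write(f"{locus}\t1\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path, popmap: dict[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into 0/1/2/missing ALT-dosage codes.

    Multiallelic records are rejected with a count reported in the error;
    non-diploid genotypes raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    loci = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is phasing
            raise ValueError(f"non-diploid genotype at {var.CHROM}:{var.POS}")
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        dose = (alleles > 0).sum(axis=1).astype(np.int8)
        dose[missing] = MISSING
        rows.append(dose)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if n_multi:
        import logging
        logging.getLogger(__name__).info("dropped %d multiallelic records", n_multi)
    if not rows:
        raise ValueError("no biallelic records in VCF")
    gt = np.stack(rows, axis=1)
    return _apply_popmap(gt, individuals, loci, popmap)


def read_genotypes(path, popmap_path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, otherwise TSV matrix."""
    popmap = read_popmap(popmap_path)
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path, popmap)
    return read_matrix_tsv(path, popmap)


def read_coordinates(path) -> tuple[np.ndarray, list[str]]:
    """TSV with columns individual, lat, lon -> (coords array, labels)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    lat = df[cols.get("lat", "lat")].to_numpy(float)
    lon = df[cols.get("lon", "lon")].to_numpy(float)
    labels = df[cols.get("individual", df.columns[0])].astype(str).tolist()
    return np.column_stack([lat, lon]), labels
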