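"""Reading and writing the pipeline's on-disk formats.

VCF (v4.2, biallelic diploid GT only) for genotype matrices, FASTA for
marker alignments, and small plain-text tables for population maps, truth
records and joint SFS matrices.
"""

from __future__ import annotations

import os

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from cyvcf2 import VCF

from .containers import GenotypeMatrix

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2: CHROM = scaffold id, 1-based POS, diploid GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for sc in dict.fromkeys(G.scaffolds):  # unique, order-preserving
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.samples) + "\n")
        for j in range(G.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in G.genotypes[:, j])
            fh.write(f"{G.scaffolds[j]}\t{G.positions[j]}\t.\t{G.ref[j]}\t"
                     f"{G.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown/missing, 3=hom-alt
_GT_TYPE_TO_DOSAGE = np.array([0, 1, -1, 2], dtype=np.int8)


def read_vcf(path, popmap=None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix.

    Population labels come from ``popmap`` (a mapping sample -> label, or the
    path of a two-column TSV) when given, otherwise from the sample-name
    prefix before the first underscore.  Multiallelic or malformed records
    are rejected with the offending 1-based record index.
    """
    if isinstance(popmap, (str, os.PathLike)):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    scaffolds, positions, ref, alt, rows = [], [], [], [], []
    i = 0
    try:
        for i, v in enumerate(vcf, start=1):
            if len(v.ALT) != 1:
                raise ValueError(
                    f"record {i} ({v.CHROM}:{v.POS}) is not biallelic "
                    f"(ALT={v.ALT}); only biallelic SNPs are supported"
                )
            scaffolds.append(v.CHROM)
            positions.append(v.POS)
            ref.append(v.REF)
            alt.append(v.ALT[0])
            rows.append(_GT_TYPE_TO_DOSAGE[v.gt_types])
    except ValueError:
        raise
    except Exception as exc:  # htslib parse failures
        raise ValueError(f"malformed VCF record at index {i + 1} in {path}: {exc}")
    if popmap is not None:
        populations = [popmap[s] for s in samples]
    else:
        populations = [s.split("_", 1)[0] for s in samples]
    genotypes = np.column_stack(rows) if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(genotypes, samples, populations, scaffolds, positions,
                          ref, alt)


def write_popmap(G: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(G.samples, G.populations):
            fh.write(f"{s}\t{p}\n")


def read_popmap(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                s, p = line.split()[:2]
                out[s] = p
    return out


def write_fasta(aln: MultipleSeqAlignment, path) -> None:
    SeqIO.write(list(aln), str(path), "fasta")


def read_fasta(path) -> MultipleSeqAlignment:
    return AlignIO.read(str(path), "fasta")


def write_truth(truth, path) -> None:
    """Truth record as a plain-text key-value table."""
    m = truth.model
    with open(path, "w") as fh:
        fh.write(f"family\t{m.family}\n")
        for key in ("nu_D", "nu_T", "T0", "T1", "M_DT", "M_TD", "F_D", "F_T"):
            fh.write(f"{key}\t{getattr(m, key)}\n")
        fh.write("freq_D\t" + ",".join(f"{x:.6g}" for x in truth.freq_D) + "\n")
        fh.write("freq_T\t" + ",".join(f"{x:.6g}" for x in truth.freq_T) + "\n")
        fh.write("categories\t" + ",".join(truth.categories) + "\n")


def write_sfs(sfs, path) -> None:
    """Joint SFS as a plain-text matrix with a one-line header."""
    with open(path, "w") as fh:
        fh.write(f"#n_D={sfs.n_D}\tn_T={sfs.n_T}\tfolded={int(sfs.folded)}\n")
        for row in sfs.data:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def read_sfs(path):
    from .sfs import JointSFS

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing SFS header line")
        fields = dict(kv.split("=") for kv in header[1:].split())
        data = np.loadtxt(fh)
    return JointSFS(data, int(fields["n_D"]), int(fields["n_T"]),
                    folded=bool(int(fields["folded"])))
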