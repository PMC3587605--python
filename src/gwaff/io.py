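"""Standard-format output: consensus FASTA, panel TSV/VCF, matrix TSVs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .assemble import LocusSet
from .fingerprint import AFMatrix
from .panel import SNPPanel


def write_loci_fasta(loci: LocusSet, path) -> None:
    records = [SeqRecord(Seq(loci.locus(i).consensus), id=f"locus_{i}",
                         description=f"depth={loci.depths[i]}")
               for i in range(len(loci))]
    seqio_write(records, str(path), "fasta")


def write_locus_depths(loci: LocusSet, path) -> None:
    pd.DataFrame({"locus_id": range(len(loci)),
                  "depth": loci.depths}).to_csv(path, sep="\t", index=False)


def write_panel_tsv(panel: SNPPanel, path) -> None:
    panel.sites.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_panel_tsv(path, maf_threshold: float, min_allele_reads: int) -> SNPPanel:
    return SNPPanel(pd.read_csv(path, sep="\t"), maf_threshold, min_allele_reads)


def write_panel_vcf(panel: SNPPanel, loci: LocusSet, path) -> None:
    """Minimal VCFv4.2 export: consensus loci as contigs, 1-based positions,
    pooled alternate-allele frequency in INFO/AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Pooled alternate allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Pooled ref+alt depth">\n')
        for i in range(len(loci)):
            fh.write(f"##contig=<ID=locus_{i},length={loci.width}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in panel.sites.itertuples():
            fh.write(f"locus_{row.locus_id}\t{row.offset + 1}\t.\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t"
                     f"AF={row.pool_maf:.6g};DP={int(row.pool_depth)}\n")


def write_af_matrix(matrix: AFMatrix, prefix) -> None:
    """Wide TSVs (<prefix>.af.tsv, <prefix>.cov.tsv, <prefix>.samples.tsv):
    rows = samples, columns = panel sites."""
    prefix = Path(prefix)
    matrix.af.to_csv(prefix.with_suffix(".af.tsv"), sep="\t",
                     float_format="%.6g")
    matrix.cov.to_csv(prefix.with_suffix(".cov.tsv"), sep="\t")
    matrix.samples.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t",
                          index=False)


def write_af_matrix_long(matrix: AFMatrix, path) -> None:
    long = (matrix.af.rename_axis(index="sample")
            .reset_index().melt(id_vars="sample", value_name="af"))
    cov = (matrix.cov.rename_axis(index="sample")
           .reset_index().melt(id_vars="sample", value_name="cov"))
    long["cov"] = cov["cov"]
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")
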