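"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: VCF 4.2 with one ALT per record and INFO
keys ``GENE``, ``CSQCLASS``, ``DELSCORE``, ``AF_EXT``; tab-separated tables
for phenotypes, transcript models, pedigrees and results.  Coordinates are
1-based inclusive everywhere, including the transcript table (which is
BED-like in shape but keeps VCF coordinate conventions; this is stated in
the file header).  Table writers prepend ``#``-prefixed provenance lines
(package version, seed, config hash) that the package's own readers skip.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .famscore import FamilyMember, Pedigree
from .qualify import Consequence, TranscriptModel, Variant

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_transcripts",
    "write_transcripts",
    "read_pedigrees",
    "write_pedigrees",
    "write_table",
    "read_table",
    "format_p",
]

_RELATION_TO_FILE = {"index": "index", "first_degree": "first", "second_degree": "second"}
_RELATION_FROM_FILE = {v: k for k, v in _RELATION_TO_FILE.items()}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=geneburden
##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene">
##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=DELSCORE,Number=1,Type=Float,Description="Deleteriousness score">
##INFO=<ID=AF_EXT,Number=1,Type=Float,Description="External allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _contig_lines(variants) -> str:
    chroms = sorted({v.chrom for v in variants})
    return "".join(f"##contig=<ID={c}>\n" for c in chroms)


def write_vcf(
    path: str | Path,
    variants: Sequence[Variant],
    genotypes: np.ndarray,
    sample_ids: Sequence[str],
) -> None:
    """Write one-ALT-per-record VCF 4.2; allele counts 0/1/2 map to
    0/0, 0/1, 1/1 and negative counts to ``./.``.  The header carries no
    timestamp, so identical inputs give byte-identical files."""
    order = np.lexsort(
        (np.array([v.alt for v in variants], dtype=object),
         np.array([v.pos for v in variants]),
         np.array([v.chrom for v in variants], dtype=object))
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(variants))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j in order:
            v = variants[j]
            info = [f"GENE={v.gene_id}", f"CSQCLASS={v.consequence.value}"]
            if v.delscore is not None:
                info.append(f"DELSCORE={v.delscore:.6g}")
            if v.af_ext is not None:
                info.append(f"AF_EXT={v.af_ext:.6g}")
            gts = "\t".join(gt_str.get(int(g), "./.") for g in genotypes[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{';'.join(info)}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path):
    """Read an annotated VCF into ``(variants, genotypes, sample_ids)``.

    ``genotypes`` is a sample × variant alternate-allele-count matrix with
    -1 for missing genotypes; sample order follows the VCF header.  Raises
    on multi-allelic records (pre-split them) and on records missing the
    ``GENE`` or ``CSQCLASS`` INFO keys.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.REF}->{','.join(rec.ALT)}); split multi-allelic sites "
                "(e.g. `bcftools norm -m-`) before analysis"
            )
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQCLASS")
        for key, val in (("GENE", gene), ("CSQCLASS", csq)):
            if val is None:
                raise ValueError(
                    f"record at {rec.CHROM}:{rec.POS} lacks required INFO key {key}"
                )
        delscore = rec.INFO.get("DELSCORE")
        af_ext = rec.INFO.get("AF_EXT")
        ac = np.empty(len(sample_ids), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                ac[i] = -1
            else:
                ac[i] = sum(1 for a in alleles if a > 0)
        variants.append(
            Variant(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                gene_id=gene, consequence=Consequence(csq),
                delscore=None if delscore is None else float(delscore),
                af_ext=None if af_ext is None else float(af_ext),
            )
        )
        cols.append(ac)
    genotypes = (
        np.stack(cols, axis=1) if cols else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    # cohort MAF from called alleles
    for j, v in enumerate(variants):
        called = genotypes[:, j] >= 0
        n_alleles = 2 * int(called.sum())
        if n_alleles:
            p = float(genotypes[called, j].sum()) / n_alleles
            v.maf = min(p, 1.0 - p)
    return variants, genotypes, sample_ids


def write_phenotypes(path: str | Path, samples: pd.DataFrame, header: Sequence[str] = ()) -> None:
    write_table(path, samples[["sample_id", "status", "er_status", "study"]], header)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"sample_id", "status", "er_status", "study"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    return df


def write_transcripts(
    path: str | Path, transcripts: Sequence[TranscriptModel], header: Sequence[str] = ()
) -> None:
    rows = [
        {
            "transcript_id": tx.transcript_id,
            "gene_id": tx.gene_id,
            "strand": tx.strand,
            "cds_intervals": ",".join(f"{s}-{e}" for s, e in tx.cds_intervals),
        }
        for tx in transcripts
    ]
    head = list(header) + ["coordinates are 1-based inclusive"]
    write_table(path, pd.DataFrame(rows), head)


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    df = read_table(path)
    out = []
    for _, row in df.iterrows():
        ivals = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(row["cds_intervals"]).split(",")
        )
        out.append(
            TranscriptModel(
                transcript_id=row["transcript_id"], gene_id=row["gene_id"],
                strand=row["strand"], cds_intervals=ivals,
            )
        )
    return out


def write_pedigrees(path: str | Path, pedigrees: Sequence[Pedigree], header: Sequence[str] = ()) -> None:
    rows = []
    for ped in pedigrees:
        for m in ped.members:
            rows.append(
                {
                    "family_id": ped.family_id,
                    "member_id": m.member_id,
                    "relation": _RELATION_TO_FILE[m.relation],
                    "ages_at_dx": ";".join(f"{a:g}" for a in m.ages_at_dx),
                }
            )
    write_table(path, pd.DataFrame(rows), header)


def read_pedigrees(path: str | Path) -> list[Pedigree]:
    df = read_table(path)
    pedigrees = []
    for fam, grp in df.groupby("family_id", sort=True):
        members = tuple(
            FamilyMember(
                member_id=str(row["member_id"]),
                relation=_RELATION_FROM_FILE[str(row["relation"])],
                ages_at_dx=tuple(
                    float(a) for a in str(row["ages_at_dx"]).split(";") if a not in ("", "nan")
                ),
            )
            for _, row in grp.iterrows()
        )
        pedigrees.append(Pedigree(family_id=str(fam), members=members))
    return pedigrees


def write_table(path: str | Path, df: pd.DataFrame, header: Sequence[str] = ()) -> None:
    """TSV writer with ``#`` provenance lines before the column header."""
    buf = _io.StringIO()
    for line in header:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def format_p(p: float) -> str:
    """Report-style p-value: 3 significant figures, scientific below 1e-3."""
    if not np.isfinite(p):
        return "NA"
    if p < 1e-3:
        return f"{p:.2e}"
    return f"{p:.3g}"


def format_or(x: float) -> str:
    """Report-style odds ratio / CI bound: two decimals, Inf-coded."""
    if np.isnan(x):
        return "NA"
    if np.isinf(x):
        return "Inf"
    return f"{x:.2f}"
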