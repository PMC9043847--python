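"""Readers and writers for the pipeline's input formats.

Formats: multi-sample VCF 4.2 (GT only; male chrX calls are written
haploid, as a single-allele genotype), 6-column PED (2 = affected,
1 = unaffected), the variant annotation TSV, the gene-level normalized
testis expression (NE) TSV and the interaction edge-list TSV.  VCF access
goes through pysam; the tabular formats through pandas.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import Effect, VariantRecord

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_ped",
    "read_ped",
    "write_annotations",
    "read_annotations",
    "write_ne_table",
    "read_ne_table",
    "write_edges",
    "read_edges",
]

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def write_vcf(
    path: Path,
    variants: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    dosage: np.ndarray,
    sample_sex: Optional[Sequence[int]] = None,
) -> None:
    """Write a multi-sample VCF 4.2 with GT calls from a dosage matrix.

    ``sample_sex`` uses PED coding (1 = male, 2 = female); males are written
    as haploid single-allele genotypes on chrX/chrY.  Dosage 2 maps to the
    alt allele (hom-alt diploid, or hemizygous alt for haploid calls).
    """
    dosage = np.asarray(dosage)
    if dosage.shape != (len(sample_ids), len(variants)):
        raise ValueError("dosage shape must be (n_samples, n_variants)")
    sex = list(sample_sex) if sample_sex is not None else [1] * len(sample_ids)

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig in _CONTIGS:
        header.add_line(f"##contig=<ID={contig}>")
    for s in sample_ids:
        header.add_sample(s)

    order = sorted(range(len(variants)), key=lambda j: (_CONTIGS.index(variants[j].chrom), variants[j].pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in order:
            v = variants[j]
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                id=f"var{j:06d}",
            )
            haploid_site = v.chrom in ("chrX", "chrY", "X", "Y")
            for i, s in enumerate(sample_ids):
                d = int(dosage[i, j])
                if haploid_site and sex[i] == 1:
                    rec.samples[s]["GT"] = (1,) if d > 0 else (0,)
                else:
                    rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[d]
            vcf.write(rec)


def read_vcf(path: Path) -> tuple[list[str], list[tuple], np.ndarray, dict]:
    """Read GT dosages from a VCF.

    Returns (sample_ids, variant_keys, dosage, id_by_key).  Haploid
    (single-allele) calls are coded 0/2.  Variant keys are
    (chrom, pos, ref, alt) in file order.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        keys: list[tuple] = []
        ids: dict[tuple, str] = {}
        rows = []
        for rec in vcf:
            key = (rec.contig, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".")
            keys.append(key)
            ids[key] = rec.id
            row = np.zeros(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or all(a is None for a in gt):
                    continue
                n_alt = sum(1 for a in gt if a == 1)
                row[i] = 2 * n_alt if len(gt) == 1 else n_alt
            rows.append(row)
    dosage = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return samples, keys, dosage, ids


_PED_COLUMNS = ["family_id", "individual_id", "paternal_id", "maternal_id", "sex", "phenotype"]


def write_ped(path: Path, rows: Sequence[tuple]) -> None:
    """Write 6-column PED rows (fam, ind, pat, mat, sex, phenotype)."""
    df = pd.DataFrame(list(rows), columns=_PED_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_ped(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_PED_COLUMNS, dtype=str)
    df["sex"] = df["sex"].astype(int)
    df["phenotype"] = df["phenotype"].astype(int)
    return df


_ANNOT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript_accession",
    "hgvs_c", "hgvs_p", "effect", "ref_af",
]


def write_annotations(path: Path, variants: Sequence[VariantRecord]) -> None:
    """Annotation TSV; an empty ref_af field means uncatalogued."""
    df = pd.DataFrame(
        [
            (
                v.chrom, v.pos, v.ref, v.alt, v.gene, v.transcript,
                v.hgvs_c, v.hgvs_p, v.effect.value,
                "" if v.ref_af is None else repr(float(v.ref_af)),
            )
            for v in variants
        ],
        columns=_ANNOT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                transcript=row.transcript_accession,
                hgvs_c=row.hgvs_c,
                hgvs_p=row.hgvs_p,
                effect=Effect(row.effect),
                ref_af=None if row.ref_af == "" else float(row.ref_af),
            )
        )
    return records


def write_ne_table(path: Path, ne_table: dict) -> None:
    """Gene -> normalized testis expression; missing values written empty."""
    df = pd.DataFrame(
        [(g, "" if ne is None or (isinstance(ne, float) and math.isnan(ne)) else repr(float(ne)))
         for g, ne in ne_table.items()],
        columns=["gene", "ne"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_ne_table(path: Path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        row.gene: (math.nan if row.ne == "" else float(row.ne))
        for row in df.itertuples(index=False)
    }


def write_edges(path: Path, edges: Sequence[tuple]) -> None:
    df = pd.DataFrame(list(edges), columns=["geneA", "geneB", "score"])
    df["score"] = df["score"].map(lambda s: repr(float(s)))
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: Path) -> list[tuple]:
    df = pd.read_csv(
        path, sep="\t", dtype={"geneA": str, "geneB": str, "score": float},
        float_precision="round_trip",
    )
    return [(row.geneA, row.geneB, float(row.score)) for row in df.itertuples(index=False)]
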