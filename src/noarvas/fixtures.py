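"""Worked-example inputs shipped with the package.

These small TSVs transcribe the published study's printed result tables for
a cohort of 133 idiopathic non-obstructive azoospermia patients, 343 fertile
male controls and 11 parent-proband trios.  They serve as end-to-end inputs
for the prioritization logic: the trio-candidate table carries, per proband
LOF, the inheritance call, Sanger validation outcome, testis expression (NE),
the gene's case-control association p-value and odds ratio, and whether the
protein is linked to the meiosis interaction network.

Genomic coordinates are not printed in those tables, so the loaders
synthesize placeholder positions; every field the downstream logic consumes
(gene, HGVS, effect, inheritance, validation, NE, p, OR, link) is literal.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .burden import OddsRatio
from .prioritize import InheritanceModel, SampleLof
from .trio import AnnotatedTrioCall, Inheritance, TrioVariantCall, Validation, Zygosity
from .variants import Effect, VariantRecord

__all__ = [
    "trio_candidate_table",
    "trio_candidate_calls",
    "known_gene_findings_table",
    "known_gene_findings",
    "known_gene_models",
    "seed_genes",
    "ENROLLED",
    "EXCLUSION_STAGES",
    "N_PATIENTS",
    "N_CONTROLS",
    "N_TRIOS",
    "RVAS_RECOVERED_KNOWN_GENES",
]

#: Enrollment waterfall of the worked example: 1739 enrolled men, minus the
#: printed stage exclusions, leaves the 133 patients who went to exome
#: sequencing alongside 343 controls and 11 trios.
ENROLLED = 1739
EXCLUSION_STAGES = (
    ("abnormal karyotype", 299),
    ("AZF microdeletion", 281),
    ("declined further sequencing", 1023),
    ("known-gene panel positive", 3),
)
N_PATIENTS = 133
N_CONTROLS = 343
N_TRIOS = 11

#: Known NOA genes that the case-control association scan itself recovered
#: in the worked example ("yellow" tier).  Patients carrying rare LOFs in
#: these genes count toward the combined heritability fraction.
RVAS_RECOVERED_KNOWN_GENES = ("BRCA2", "SYCP3", "TDRD7")


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("noarvas").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


@lru_cache(maxsize=None)
def trio_candidate_table() -> pd.DataFrame:
    """The trio-candidate worked-example table as a raw DataFrame."""
    return _read_tsv("trio_candidates.tsv")


def _validation(raw: str) -> Validation:
    return {
        "True": Validation.TRUE,
        "False": Validation.FALSE,
        "NA": Validation.NOT_ASSESSED,
    }[raw]


def trio_candidate_calls() -> list[AnnotatedTrioCall]:
    """The trio-candidate table as annotated trio calls ready for tiering."""
    rows = trio_candidate_table()
    calls = []
    for i, row in enumerate(rows.itertuples(index=False)):
        hemi = row.zygosity == "hemizygous"
        inheritance = Inheritance(row.inheritance)
        if inheritance == Inheritance.MATERNAL:
            mother, father = 1, 0
        else:  # de novo
            mother, father = 0, 0
        proband_gt = 2 if hemi else 1
        variant = VariantRecord(
            chrom=row.chromosome,
            pos=1000 + i,  # placeholder: coordinates are not printed
            ref="A",
            alt="C",
            gene=row.gene,
            transcript=row.accession,
            hgvs_c=row.hgvs_c,
            hgvs_p="" if row.hgvs_p == "NA" else row.hgvs_p,
            effect=Effect(row.effect),
            ref_af=None,
        )
        call = TrioVariantCall(
            family_id=row.proband,
            variant=variant,
            proband=proband_gt,
            mother=mother,
            father=father,
            hemizygous=hemi,
            validation=_validation(row.validation),
            inheritance=inheritance,
        )
        if row.or_rvas == "not_estimable":
            orr = OddsRatio(None, None, None, estimable=False)
        elif row.or_rvas == "NA":
            orr = None
        else:
            orr = OddsRatio(float(row.or_rvas), None, None, estimable=True)
        ne = None if row.ne == "NA" else float(row.ne)
        linked = {"Linked": True, "Not Linked": False, "NA": False}[row.network]
        calls.append(
            AnnotatedTrioCall(
                call=call,
                p_value=float(row.p_rvas),
                odds_ratio=orr,
                ne=ne,
                linked=linked,
            )
        )
    return calls


@lru_cache(maxsize=None)
def known_gene_findings_table() -> pd.DataFrame:
    """Known-gene LOF findings among the 133 patients (raw DataFrame)."""
    return _read_tsv("known_gene_findings.tsv")


def known_gene_findings() -> list[SampleLof]:
    """The known-gene findings as screening inputs."""
    rows = known_gene_findings_table()
    return [
        SampleLof(
            sample=row.patient,
            gene=row.gene,
            zygosity=Zygosity(row.zygosity),
            hgvs_c=row.hgvs_c,
            hgvs_p="" if row.hgvs_p == "NA" else row.hgvs_p,
        )
        for row in rows.itertuples(index=False)
    ]


@lru_cache(maxsize=None)
def known_gene_models() -> dict[str, InheritanceModel]:
    """Previously reported NOA genes and their inheritance models."""
    df = _read_tsv("known_genes.tsv")
    return {
        row.gene: InheritanceModel(row.inheritance_model)
        for row in df.itertuples(index=False)
    }


@lru_cache(maxsize=None)
def seed_genes() -> tuple[str, ...]:
    """Previously reported NOA genes used to seed the interaction network."""
    text = resources.files("noarvas").joinpath("data", "seed_genes.txt").read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())
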