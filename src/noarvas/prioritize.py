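"""Candidate-gene prioritization and cohort-level accounting.

Combines the case-control burden results, the trio linkage output and the
interaction-network flags into:

* significance tiers for the association scan — "red" (p < 1e-4 with an
  estimable OR > 1), "blue" (1e-4 <= p < 0.05, testis NE > 16, OR > 6 or not
  estimable), "yellow" (p < 0.05 and a previously reported NOA gene; a known
  gene is reported yellow even when its numbers would satisfy red/blue);
* a known-gene screen over per-sample LOF findings honouring each gene's
  inheritance model (AD: one het allele suffices; XL: a hemizygous allele in
  a male suffices; AR: a single het allele leaves causality uncertain until
  a second pathogenic allele is found);
* top trio candidates (p < 0.05, OR not estimable because no control carries
  the gene's rare LOFs, network-linked, Sanger-validated) and expansive
  candidates (p < 0.05; OR > 1 or not estimable; NE >= 1; validated; not
  already top);
* heritability-fraction and enrollment-exclusion arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

from .burden import GeneBurdenResult
from .trio import AnnotatedTrioCall, Validation, Zygosity

__all__ = [
    "InheritanceModel",
    "KnownGeneEntry",
    "SampleLof",
    "ScreenStatus",
    "ScreenFinding",
    "TierAssignment",
    "StageCount",
    "CandidateReport",
    "assign_tiers",
    "screen_known_genes",
    "top_candidates",
    "expansive_candidates",
    "heritability_fraction",
    "exclusion_accounting",
    "solved_probands",
]


class InheritanceModel(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"


@dataclass(frozen=True)
class KnownGeneEntry:
    gene: str
    inheritance_model: InheritanceModel


@dataclass(frozen=True)
class SampleLof:
    """One rare LOF observed in one sample (known-gene screening input)."""

    sample: str
    gene: str
    zygosity: Zygosity
    hgvs_c: str = ""
    hgvs_p: str = ""


class ScreenStatus(str, Enum):
    REPORTABLE = "reportable"
    UNCERTAIN = "uncertain (second allele undetermined)"


@dataclass(frozen=True)
class ScreenFinding:
    sample: str
    gene: str
    model: InheritanceModel
    status: ScreenStatus
    n_alleles: int


@dataclass
class TierAssignment:
    red: list
    blue: list
    yellow: list
    untiered: list


def assign_tiers(
    results: Sequence[GeneBurdenResult],
    known_genes: Sequence[str],
    p_strong: float = 1e-4,
    p_sig: float = 0.05,
    ne_blue: float = 16.0,
    or_blue: float = 6.0,
) -> TierAssignment:
    """Assign association-scan significance tiers.

    Yellow takes precedence: a known gene meeting p < p_sig is reported
    yellow regardless of its OR/NE numerics, so the three tiers stay
    mutually exclusive.
    """
    known = set(known_genes)
    red, blue, yellow, untiered = [], [], [], []
    for r in results:
        orr = r.odds_ratio
        if r.p_value < p_sig and r.gene in known:
            yellow.append(r.gene)
        elif r.p_value < p_strong and orr.estimable and orr.estimate > 1:
            red.append(r.gene)
        elif (
            p_strong <= r.p_value < p_sig
            and r.ne is not None
            and r.ne > ne_blue
            and (not orr.estimable or orr.estimate > or_blue)
        ):
            blue.append(r.gene)
        else:
            untiered.append(r.gene)
    return TierAssignment(red=red, blue=blue, yellow=yellow, untiered=untiered)


def screen_known_genes(
    sample_lofs: Sequence[SampleLof],
    known_models: Mapping[str, InheritanceModel],
) -> list[ScreenFinding]:
    """Screen per-sample LOFs against the known-gene inheritance models.

    Input LOFs are assumed already classified and rare-filtered.  Findings
    in genes not on the known list are ignored.  Alleles are counted per
    (sample, gene): a homozygous call counts two.
    """
    grouped: dict[tuple, list[SampleLof]] = {}
    for lof in sample_lofs:
        if lof.gene in known_models:
            grouped.setdefault((lof.sample, lof.gene), []).append(lof)

    findings = []
    for (sample, gene), lofs in sorted(grouped.items()):
        model = InheritanceModel(known_models[gene])
        n_alleles = sum(2 if l.zygosity == Zygosity.HOMOZYGOUS else 1 for l in lofs)
        if model == InheritanceModel.AD:
            status = ScreenStatus.REPORTABLE
        elif model == InheritanceModel.XL:
            status = (
                ScreenStatus.REPORTABLE
                if any(l.zygosity == Zygosity.HEMIZYGOUS for l in lofs)
                else ScreenStatus.UNCERTAIN
            )
        else:  # AR: need both alleles hit
            status = (
                ScreenStatus.REPORTABLE if n_alleles >= 2 else ScreenStatus.UNCERTAIN
            )
        findings.append(
            ScreenFinding(sample=sample, gene=gene, model=model, status=status, n_alleles=n_alleles)
        )
    return findings


def _passes_validation(call) -> bool:
    return call.validation == Validation.TRUE


def top_candidates(
    annotated: Sequence[AnnotatedTrioCall],
    p_sig: float = 0.05,
) -> dict[str, list[str]]:
    """Per-proband top candidate genes from annotated trio calls.

    Criteria (all required): association p < p_sig; OR not estimable (the
    gene's rare LOFs are absent from every control); linked to the seed
    protein network; Sanger validation passed.
    """
    out: dict[str, list[str]] = {}
    for a in annotated:
        if a.p_value is None or not a.p_value < p_sig:
            continue
        if a.odds_ratio is None or a.odds_ratio.estimable:
            continue
        if not a.linked:
            continue
        if not _passes_validation(a.call):
            continue
        genes = out.setdefault(a.proband, [])
        if a.gene not in genes:
            genes.append(a.gene)
    return {k: sorted(v) for k, v in sorted(out.items())}


def expansive_candidates(
    annotated: Sequence[AnnotatedTrioCall],
    top: Mapping[str, Sequence[str]],
    p_sig: float = 0.05,
    ne_min: float = 1.0,
) -> dict[str, list[str]]:
    """Per-proband expansive candidates, excluding genes already in the top set.

    Criteria: p < p_sig; OR > 1 or not estimable; NE >= ne_min (a gene with
    no expression record never qualifies); validated; not a top candidate.
    """
    top_genes = {g for genes in top.values() for g in genes}
    out: dict[str, list[str]] = {}
    for a in annotated:
        if a.gene in top_genes:
            continue
        if a.p_value is None or not a.p_value < p_sig:
            continue
        orr = a.odds_ratio
        if orr is None or (orr.estimable and not orr.estimate > 1):
            continue
        if a.ne is None or not a.ne >= ne_min:
            continue
        if not _passes_validation(a.call):
            continue
        genes = out.setdefault(a.proband, [])
        if a.gene not in genes:
            genes.append(a.gene)
    return {k: sorted(v) for k, v in sorted(out.items())}


def heritability_fraction(solved: int, cohort_size: int) -> float:
    """Percentage of the cohort explained, rounded half-up to two decimals."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if not 0 <= solved <= cohort_size:
        raise ValueError("solved count must lie in [0, cohort_size]")
    pct = Decimal(100 * solved) / Decimal(cohort_size)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StageCount:
    label: str
    excluded: int
    remaining: int


def exclusion_accounting(
    stages: Sequence[tuple[str, int]],
    enrolled: int,
) -> list[StageCount]:
    """Sequential enrollment waterfall: subtract each stage's exclusions.

    Raises if any stage count is negative or the running remainder would
    drop below zero.
    """
    if enrolled < 0:
        raise ValueError("enrolled must be non-negative")
    remaining = enrolled
    out = []
    for label, excluded in stages:
        if excluded < 0:
            raise ValueError(f"negative exclusion count at stage {label!r}")
        remaining -= excluded
        if remaining < 0:
            raise ValueError(f"exclusions exceed enrollment at stage {label!r}")
        out.append(StageCount(label=label, excluded=excluded, remaining=remaining))
    return out


def solved_probands(
    top: Mapping[str, Sequence[str]],
    known_findings: Sequence[ScreenFinding] = (),
    rvas_recovered_known: Sequence[str] = (),
) -> tuple[set, set]:
    """(trio-solved, known-gene-solved) sample sets.

    A trio proband is solved by carrying >= 1 top candidate gene.  A screened
    patient is solved by a LOF in a known gene that the case-control scan
    itself recovered (the "yellow" genes) — for those genes the association
    evidence stands in for the second-allele requirement of AR models.
    """
    trio_solved = {p for p, genes in top.items() if genes}
    recovered = set(rvas_recovered_known)
    known_solved = {f.sample for f in known_findings if f.gene in recovered}
    return trio_solved, known_solved


@dataclass
class CandidateReport:
    """Aggregate prioritization output for one full pipeline run."""

    tiers: TierAssignment
    top_candidates: dict
    expansive_candidates: dict
    known_findings: list
    solved_trio: set
    solved_known: set
    cohort_size: int
    waterfall: list = field(default_factory=list)

    @property
    def heritability_top(self) -> float:
        return heritability_fraction(len(self.solved_trio), self.cohort_size)

    @property
    def heritability_combined(self) -> float:
        return heritability_fraction(
            len(self.solved_trio | self.solved_known), self.cohort_size
        )
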