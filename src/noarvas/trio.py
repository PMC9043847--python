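"""Trio (proband + parents) inheritance classification and linkage filtering.

Because non-obstructive azoospermia is gender-limited — an affected man's
father was by definition fertile — a causative allele is expected to be
maternally inherited or to have arisen de novo.  The linkage filter therefore
excludes paternally inherited LOFs and keeps a proband LOF only when it is
absent from all sequenced male controls.  Sanger validation outcomes are
consumed as input flags; de novo calls fail validation often enough
(sequencing artifacts) that unvalidated calls are disqualified downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

from .burden import GeneBurdenResult, OddsRatio
from .variants import VariantRecord, classify_lof

__all__ = [
    "Inheritance",
    "Zygosity",
    "Validation",
    "TrioVariantCall",
    "AnnotatedTrioCall",
    "MendelianInconsistencyWarning",
    "classify_inheritance",
    "classify_call",
    "trio_filter",
    "annotate_with_rvas",
]


class Inheritance(str, Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    DE_NOVO = "de_novo"
    BIPARENTAL = "biparental"
    UNRESOLVED = "unresolved"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HEMIZYGOUS = "hemizygous"
    HOMOZYGOUS = "homozygous"


class Validation(str, Enum):
    TRUE = "true"
    FALSE = "false"
    NOT_ASSESSED = "not_assessed"


class MendelianInconsistencyWarning(UserWarning):
    """A genotype configuration impossible under Mendelian transmission."""


@dataclass(frozen=True)
class TrioVariantCall:
    """One proband variant with parental genotypes at the same site.

    Genotypes are alt-allele dosages: diploid 0/1/2, hemizygous male X coded
    0/2 with ``hemizygous=True``.  ``None`` marks a missing parental call.
    """

    family_id: str
    variant: VariantRecord
    proband: int
    mother: Optional[int]
    father: Optional[int]
    hemizygous: bool = False
    validation: Validation = Validation.NOT_ASSESSED
    inheritance: Optional[Inheritance] = None

    @property
    def zygosity(self) -> Zygosity:
        if self.hemizygous:
            return Zygosity.HEMIZYGOUS
        return Zygosity.HOMOZYGOUS if self.proband == 2 else Zygosity.HETEROZYGOUS


def classify_inheritance(
    proband: int,
    mother: Optional[int],
    father: Optional[int],
    hemizygous: bool = False,
) -> Inheritance:
    """Classify the origin of the proband's alt allele from allele presence.

    mother-only -> maternal; father-only -> paternal; both -> biparental;
    neither -> de novo; a missing parental genotype -> unresolved.  A
    Mendelian-impossible configuration (e.g. a homozygous-alt proband with a
    hom-ref parent) is flagged unresolved with a warning, never silently
    classified.  A hemizygous (male X) allele cannot come from the father:
    with the mother negative it is de novo regardless of the father.
    """
    if proband <= 0:
        raise ValueError("classify_inheritance expects a proband carrying the alt allele")
    if mother is None or father is None:
        return Inheritance.UNRESOLVED

    in_mother = mother > 0
    in_father = father > 0

    if hemizygous:
        return Inheritance.MATERNAL if in_mother else Inheritance.DE_NOVO

    if proband == 2 and not (in_mother and in_father):
        warnings.warn(
            "homozygous-alt proband with a parent lacking the allele; "
            "flagged unresolved",
            MendelianInconsistencyWarning,
            stacklevel=2,
        )
        return Inheritance.UNRESOLVED
    if in_mother and in_father:
        return Inheritance.BIPARENTAL
    if in_mother:
        return Inheritance.MATERNAL
    if in_father:
        return Inheritance.PATERNAL
    return Inheritance.DE_NOVO


def classify_call(call: TrioVariantCall) -> TrioVariantCall:
    """Return the call with its ``inheritance`` field filled in."""
    inh = classify_inheritance(call.proband, call.mother, call.father, call.hemizygous)
    return replace(call, inheritance=inh)


def trio_filter(
    calls: Sequence[TrioVariantCall],
    control_carriers: Mapping[tuple, int],
) -> list[TrioVariantCall]:
    """Apply the linkage filter to classified proband calls.

    A call is retained iff the variant is LOF, the inheritance is maternal
    or de novo (paternal alleles cannot explain a gender-limited phenotype
    in the son of a fertile father), and the exact variant is absent from
    the sequenced controls (carrier count 0; a variant missing from the map
    counts as absent).
    """
    kept = []
    for call in calls:
        if call.inheritance is None:
            call = classify_call(call)
        if call.inheritance not in (Inheritance.MATERNAL, Inheritance.DE_NOVO):
            continue
        if not classify_lof(call.variant):
            continue
        if control_carriers.get(call.variant.key, 0) > 0:
            continue
        kept.append(call)
    return kept


@dataclass(frozen=True)
class AnnotatedTrioCall:
    """A retained trio call joined with its gene's association statistics.

    Missing statistics (gene not in the association output, or no expression
    record) are ``None`` — absent, never coerced to zero.
    """

    call: TrioVariantCall
    p_value: Optional[float]
    odds_ratio: Optional[OddsRatio]
    ne: Optional[float]
    linked: Optional[bool]

    @property
    def gene(self) -> str:
        return self.call.variant.gene

    @property
    def proband(self) -> str:
        return self.call.family_id


def annotate_with_rvas(
    calls: Sequence[TrioVariantCall],
    rvas_results: Mapping[str, GeneBurdenResult] | Sequence[GeneBurdenResult],
    ne_table: Mapping[str, float],
    linked_genes: Optional[set] = None,
) -> list[AnnotatedTrioCall]:
    """Join retained calls to per-gene burden statistics and expression.

    The join is keyed on the gene symbol and is order-independent.
    ``linked_genes`` (optional) marks genes connected to the seed protein
    network; when omitted the flag is left ``None``.
    """
    if not isinstance(rvas_results, Mapping):
        rvas_results = {r.gene: r for r in rvas_results}
    annotated = []
    for call in calls:
        gene = call.variant.gene
        res = rvas_results.get(gene)
        ne = ne_table.get(gene)
        if ne is not None and isinstance(ne, float) and math.isnan(ne):
            ne = None
        annotated.append(
            AnnotatedTrioCall(
                call=call,
                p_value=res.p_value if res is not None else None,
                odds_ratio=res.odds_ratio if res is not None else None,
                ne=float(ne) if ne is not None else None,
                linked=(gene in linked_genes) if linked_genes is not None else None,
            )
        )
    return annotated
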