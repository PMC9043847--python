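"""Variant-level classification and pre-filtering.

Three screens are applied to annotated exome variants before any gene-level
association is attempted:

1. loss-of-function (LOF) classification — frameshift, nonsense
   (premature stop), start-codon loss, stop loss, or disruption of a
   canonical splice site (intronic offset within +/- 2 bp of the exon
   boundary, parsed from the coding HGVS string);
2. the rare-frequency filter — keep a variant only if its reference-catalog
   allele frequency is below a threshold (default 1%) or it is uncatalogued;
3. an exact Hardy-Weinberg equilibrium (HWE) screen — sites whose genotype
   counts deviate from HWE (exact conditional test, p < alpha) are treated as
   likely genotyping artifacts and removed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Effect",
    "VariantRecord",
    "GenotypeCounts",
    "HweFilterResult",
    "HgvsParseError",
    "classify_lof",
    "splice_offset",
    "rare_filter",
    "hwe_exact_test",
    "apply_hwe_filter",
    "genotype_counts_from_dosage",
]


class HgvsParseError(ValueError):
    """Raised when a splice variant's coding HGVS cannot be parsed."""


class Effect(str, Enum):
    """Consequence classes used by the annotation input."""

    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    START_CODON_LOSS = "start_codon_loss"
    STOP_LOSS = "stop_loss"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    INDEL_INFRAME = "indel_inframe"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_RETAINED = "stop_retained"
    OTHER = "other"


#: Effect classes that are loss-of-function irrespective of position.
_LOF_ALWAYS = frozenset(
    {Effect.FRAMESHIFT, Effect.NONSENSE, Effect.START_CODON_LOSS, Effect.STOP_LOSS}
)
_SPLICE = frozenset({Effect.SPLICE_ACCEPTOR, Effect.SPLICE_DONOR})

# Coding HGVS with an intronic offset: c.123+1G>A, c.349-2A>C, c.-13-2A>C,
# c.1299+2delT, c.*55-1G>T.  Group 2 is the signed intronic offset.
_SPLICE_RE = re.compile(r"^c\.([-*]?\d+)([+-]\d+)")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic site.

    ``ref_af`` is the allele frequency in the reference catalogs
    (gnomAD / 1000 Genomes); ``None`` means the variant is uncatalogued,
    which is a *pass* condition for the rare filter, distinct from 0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    effect: Effect = Effect.OTHER
    ref_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not isinstance(self.effect, Effect):
            object.__setattr__(self, "effect", Effect(self.effect))

    @property
    def key(self) -> tuple:
        """Exact-variant identity used for control-absence lookups."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_lof(self) -> bool:
        return classify_lof(self)


def splice_offset(hgvs_c: str) -> int:
    """Signed intronic offset of a splice-region HGVS coding description.

    Accepts forms like ``c.349-2A>C`` (offset -2), ``c.3474+1G>C`` (+1) and
    UTR-anchored positions such as ``c.-13-2A>C`` (-2).  Whitespace is
    ignored.  Raises :class:`HgvsParseError` for anything else — a splice
    variant whose position cannot be read is an error, never silently
    non-LOF.
    """
    cleaned = re.sub(r"\s+", "", hgvs_c or "")
    m = _SPLICE_RE.match(cleaned)
    if m is None:
        raise HgvsParseError(f"cannot parse intronic offset from {hgvs_c!r}")
    return int(m.group(2))


def classify_lof(record: VariantRecord) -> bool:
    """True iff the variant is a putative loss-of-function allele.

    Frameshift, nonsense, start-codon loss and stop loss always qualify;
    splice acceptor/donor variants qualify only when they hit the canonical
    dinucleotide, i.e. the intronic offset magnitude is <= 2.
    """
    effect = record.effect
    if effect in _LOF_ALWAYS:
        return True
    if effect in _SPLICE:
        return abs(splice_offset(record.hgvs_c)) <= 2
    return False


def rare_filter(record: VariantRecord, threshold: float = 0.01) -> bool:
    """Keep (True) iff the variant is uncatalogued or rarer than ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if record.ref_af is None or (isinstance(record.ref_af, float) and math.isnan(record.ref_af)):
        return True
    return record.ref_af < threshold


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts at one biallelic site."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Full enumeration of the conditional distribution of the heterozygote
    count given the allele counts; the p-value sums the probabilities of all
    heterozygote configurations (same parity as the minor-allele count) whose
    probability does not exceed that of the observed configuration.  No
    mid-p adjustment.  Symmetric in ref/alt relabeling.
    """
    n = counts.total
    if n < 1:
        raise ValueError("hwe_exact_test requires at least one genotype")
    n_minor = 2 * counts.n_hom_alt + counts.n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    if n_minor == 0:
        return 1.0  # monomorphic: a single possible configuration

    het_values = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) up to the shared normalizing constant:
    #   P(h) proportional to 2^h / ( ((n_minor-h)/2)! h! ((n_major-h)/2)! ... )
    n_major = 2 * n - n_minor
    hom_minor = (n_minor - het_values) // 2
    hom_major = n - het_values - hom_minor
    valid = hom_major >= 0
    het_values, hom_minor, hom_major = het_values[valid], hom_minor[valid], hom_major[valid]
    logp = (
        het_values * math.log(2.0)
        - _lgamma_arr(hom_minor + 1)
        - _lgamma_arr(het_values + 1)
        - _lgamma_arr(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = counts.n_het
    p_obs = prob[het_values == obs]
    if p_obs.size == 0:  # observed het count inconsistent with allele parity
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = float(prob[prob <= p_obs[0] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def genotype_counts_from_dosage(dosage: np.ndarray) -> GenotypeCounts:
    """Collapse a diploid 0/1/2 dosage column into genotype counts."""
    dosage = np.asarray(dosage)
    return GenotypeCounts(
        n_hom_ref=int((dosage == 0).sum()),
        n_het=int((dosage == 1).sum()),
        n_hom_alt=int((dosage == 2).sum()),
    )


@dataclass
class HweFilterResult:
    retained: list  # VariantRecord
    retained_indices: np.ndarray
    removed: int
    p_values: dict = field(default_factory=dict)

    def report_line(self) -> str:
        return f"removed_hwe={self.removed}"


def apply_hwe_filter(
    records: Sequence[VariantRecord],
    dosage: np.ndarray,
    alpha: float = 0.05,
    skip_chroms: Sequence[str] = ("chrX", "X", "chrY", "Y"),
) -> HweFilterResult:
    """Remove sites whose genotypes fail the exact HWE test at ``alpha``.

    ``dosage`` is the sample x variant matrix aligned with ``records``.
    Sex-chromosome sites are skipped (retained untested): in an all-male
    cohort these calls are hemizygous and the heterozygote class the test is
    built on does not exist.
    """
    dosage = np.asarray(dosage)
    if dosage.shape[1] != len(records):
        raise ValueError("dosage columns must align with variant records")
    retained: list[VariantRecord] = []
    kept_idx: list[int] = []
    p_values: dict[tuple, float] = {}
    removed = 0
    for j, rec in enumerate(records):
        if rec.chrom in skip_chroms:
            retained.append(rec)
            kept_idx.append(j)
            continue
        p = hwe_exact_test(genotype_counts_from_dosage(dosage[:, j]))
        p_values[rec.key] = p
        if p < alpha:
            removed += 1
        else:
            retained.append(rec)
            kept_idx.append(j)
    return HweFilterResult(
        retained=retained,
        retained_indices=np.asarray(kept_idx, dtype=int),
        removed=removed,
        p_values=p_values,
    )
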