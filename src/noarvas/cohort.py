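"""Synthetic case-control cohorts and trio families.

The generator emulates the statistical structure the downstream analysis
assumes: an all-male cohort (default 133 cases, 343 controls) typed at rare
(reference AF < 1% or uncatalogued) loss-of-function variants spread over a
configurable gene set; a handful of planted risk genes whose carrier rate is
enriched in cases; one X-chromosome gene with hemizygous 0/2 dosage coding;
a normalized-testis-expression table with occasional missing genes; an
interaction edge list in which planted genes tend to attach to the seed-gene
core; and trio families whose probands carry a mixture of paternally
inherited, maternally inherited and de novo LOFs, the latter failing Sanger
validation at a configurable rate (de novo calls from short-read data are
frequently sequencing artifacts).

Every stochastic draw flows from a single integer seed, so a configuration
reproduces its dataset — and the files written from it — byte for byte.
A truth channel (planted genes, per-site inheritance labels) is retained for
parameter-recovery testing; it is written to a JSON sidecar, never into the
standard input files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as _io
from .burden import CohortGenotypes
from .trio import Inheritance, TrioVariantCall, Validation
from .variants import Effect, GenotypeCounts, VariantRecord

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "TrioSite",
    "TrioFamily",
    "CohortDataset",
    "Manifest",
    "generate_cohort",
    "generate_trios",
    "write_inputs",
    "read_inputs",
    "control_carrier_counts",
    "trio_calls",
    "simulate_hwe_genotype_counts",
]


class ConfigurationError(ValueError):
    """An invalid simulation parameter; the message names the field."""


_PROB_FIELDS = (
    "planted_carrier_rate_cases",
    "planted_carrier_rate_controls",
    "background_lof_rate",
    "fraction_uncatalogued",
    "de_novo_false_positive_rate",
    "fraction_nonlof_variants",
    "ne_missing_fraction",
    "trio_control_overlap",
    "trio_planted_fraction",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated study: 133 cases vs 343 fertile male
    controls, 11 trios, rare LOFs (catalogued AF below 1% or uncatalogued),
    a small set of planted risk genes with case-enriched carriers, and a
    high de novo validation-failure rate.
    """

    n_cases: int = 133
    n_controls: int = 343
    n_trios: int = 11
    n_genes: int = 200
    n_planted_risk_genes: int = 5
    planted_carrier_rate_cases: float = 0.05
    planted_carrier_rate_controls: float = 0.002
    background_lof_rate: float = 0.015
    reference_af_range: tuple = (1e-5, 0.01)
    fraction_uncatalogued: float = 0.3
    de_novo_false_positive_rate: float = 0.7
    rng_seed: int = 0
    # generator shape parameters
    mean_lof_variants_per_gene: float = 3.0
    fraction_nonlof_variants: float = 0.2
    ne_missing_fraction: float = 0.05
    include_x_gene: bool = True
    mean_maternal_lofs: float = 2.0
    mean_paternal_lofs: float = 2.0
    mean_denovo_lofs: float = 1.5
    trio_control_overlap: float = 0.3
    trio_planted_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_trios", "n_genes", "n_planted_risk_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_planted_risk_genes > self.n_genes:
            raise ConfigurationError("n_planted_risk_genes must not exceed n_genes")
        lo, hi = self.reference_af_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("reference_af_range must be an interval within [0, 1]")
        if self.mean_lof_variants_per_gene < 1.0:
            raise ConfigurationError("mean_lof_variants_per_gene must be >= 1")


@dataclass(frozen=True)
class TrioSite:
    """One proband variant site in a trio, with ground-truth labels."""

    variant: VariantRecord
    proband: int
    mother: int
    father: int
    hemizygous: bool
    truth_inheritance: Inheritance
    validation: Validation
    in_controls: bool


@dataclass
class TrioFamily:
    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    sites: list


@dataclass
class CohortDataset:
    """A complete synthetic input bundle plus the truth channel."""

    genotypes: CohortGenotypes
    variants: list
    pedigree: list
    ne_table: dict
    ppi_edges: list
    seed_genes: tuple
    truth: tuple  # planted risk genes
    trios: list = field(default_factory=list)
    gene_chrom: dict = field(default_factory=dict)


_BASES = np.array(list("ACGT"))
_LOF_EFFECTS = [
    Effect.FRAMESHIFT, Effect.NONSENSE, Effect.SPLICE_DONOR,
    Effect.SPLICE_ACCEPTOR, Effect.START_CODON_LOSS, Effect.STOP_LOSS,
]
_LOF_PROBS = [0.40, 0.25, 0.15, 0.10, 0.05, 0.05]
_NONLOF_EFFECTS = [Effect.MISSENSE, Effect.SYNONYMOUS, Effect.INDEL_INFRAME, Effect.STOP_RETAINED]
_NONLOF_PROBS = [0.65, 0.20, 0.10, 0.05]


def _draw_bases(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def _make_variant(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    gene: str,
    effect: Effect,
    cfg: SimulationConfig,
    force_lof_splice: bool = True,
) -> VariantRecord:
    ref, alt = _draw_bases(rng)
    k = int(rng.integers(2, 4000))
    if effect == Effect.FRAMESHIFT:
        ref = ref + alt
        hgvs_c = f"c.{k}del{alt}"
        hgvs_p = f"p.Xaa{k // 3 + 1}fs"
        ref, alt = ref, ref[0]
    elif effect == Effect.START_CODON_LOSS:
        ref, alt = "A", "G"
        hgvs_c = "c.1A>G"
        hgvs_p = "p.0?"
    elif effect in (Effect.SPLICE_DONOR, Effect.SPLICE_ACCEPTOR):
        if force_lof_splice or rng.random() < 0.9:
            off = int(rng.integers(1, 3))
        else:
            off = int(rng.integers(3, 9))  # near-splice but non-canonical
        sign = "+" if effect == Effect.SPLICE_DONOR else "-"
        hgvs_c = f"c.{k}{sign}{off}{ref}>{alt}"
        hgvs_p = ""
    else:
        hgvs_c = f"c.{k}{ref}>{alt}"
        hgvs_p = f"p.Xaa{k // 3 + 1}*" if effect == Effect.NONSENSE else f"p.Xaa{k // 3 + 1}Yaa"
    ref_af = None
    if rng.random() >= cfg.fraction_uncatalogued:
        lo, hi = cfg.reference_af_range
        ref_af = float(rng.uniform(lo, hi))
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        transcript=f"NM_{int(rng.integers(1000, 999999)):06d}.1",
        hgvs_c=hgvs_c, hgvs_p=hgvs_p, effect=effect, ref_af=ref_af,
    )


def generate_cohort(config: SimulationConfig, with_trios: bool = True) -> CohortDataset:
    """Generate a full synthetic dataset under ``config``.

    Planted risk genes receive case carriers at
    ``planted_carrier_rate_cases`` and control carriers at
    ``planted_carrier_rate_controls``; all other genes draw carriers at the
    background rate identically in both groups.  Planted genes always have
    an expression record (NE > 16) and attach to the seed network with high
    probability, so they are discoverable by the full prioritization chain.
    """
    from .fixtures import seed_genes as _fixture_seeds

    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    x_gene = genes[-1] if (cfg.include_x_gene and cfg.n_genes > 0) else None
    plantable = [g for g in genes if g != x_gene]
    if cfg.n_planted_risk_genes > len(plantable):
        raise ConfigurationError("n_planted_risk_genes exceeds available autosomal genes")
    planted = sorted(
        rng.choice(plantable, size=cfg.n_planted_risk_genes, replace=False).tolist()
    ) if cfg.n_planted_risk_genes else []
    planted_set = set(planted)

    gene_chrom = {
        g: ("chrX" if g == x_gene else f"chr{(i % 22) + 1}") for i, g in enumerate(genes)
    }
    pos_counter: dict[str, int] = {}

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 1_000_000) + int(rng.integers(500, 5000))
        return pos_counter[chrom]

    variants: list[VariantRecord] = []
    gene_lof_cols: dict[str, list[int]] = {}
    for g in genes:
        chrom = gene_chrom[g]
        m = 1 + int(rng.poisson(cfg.mean_lof_variants_per_gene - 1.0))
        cols = []
        for _ in range(m):
            effect = _LOF_EFFECTS[rng.choice(len(_LOF_EFFECTS), p=_LOF_PROBS)]
            variants.append(_make_variant(rng, chrom, next_pos(chrom), g, effect, cfg))
            cols.append(len(variants) - 1)
        gene_lof_cols[g] = cols
        n_extra = int(rng.poisson(cfg.fraction_nonlof_variants * m))
        for _ in range(n_extra):
            if rng.random() < 0.15:  # splice-class variant beyond the canonical +/-2
                effect = Effect.SPLICE_DONOR if rng.random() < 0.5 else Effect.SPLICE_ACCEPTOR
                v = _make_variant(rng, chrom, next_pos(chrom), g, effect, cfg,
                                  force_lof_splice=False)
                # re-draw until actually non-canonical, to keep this column non-LOF
                while v.is_lof:
                    v = _make_variant(rng, chrom, next_pos(chrom), g, effect, cfg,
                                      force_lof_splice=False)
            else:
                effect = _NONLOF_EFFECTS[rng.choice(len(_NONLOF_EFFECTS), p=_NONLOF_PROBS)]
                v = _make_variant(rng, chrom, next_pos(chrom), g, effect, cfg)
            variants.append(v)

    n = cfg.n_cases + cfg.n_controls
    dosage = np.zeros((n, len(variants)), dtype=np.int8)
    phenotype = np.concatenate(
        [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
    )
    for g in genes:
        cols = gene_lof_cols[g]
        p_case = cfg.planted_carrier_rate_cases if g in planted_set else cfg.background_lof_rate
        p_ctrl = cfg.planted_carrier_rate_controls if g in planted_set else cfg.background_lof_rate
        carrier = np.concatenate(
            [rng.random(cfg.n_cases) < p_case, rng.random(cfg.n_controls) < p_ctrl]
        )
        idx = np.flatnonzero(carrier)
        if idx.size:
            w = rng.dirichlet(np.ones(len(cols)))
            assigned = rng.choice(len(cols), size=idx.size, p=w)
            val = 2 if g == x_gene else 1
            for i, a in zip(idx, assigned):
                dosage[i, cols[a]] = val
    # background carriers at non-LOF columns, identical in both groups
    nonlof_cols = [j for j, v in enumerate(variants) if not v.is_lof]
    for j in nonlof_cols:
        carrier = rng.random(n) < cfg.background_lof_rate / 2.0
        val = 2 if variants[j].chrom == "chrX" else 1
        dosage[carrier, j] = val

    # order variants by genome coordinate so written VCFs preserve the order
    contig_rank = {c: i for i, c in enumerate([f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"])}
    order = sorted(range(len(variants)), key=lambda j: (contig_rank[variants[j].chrom], variants[j].pos))
    variants = [variants[j] for j in order]
    dosage = dosage[:, order]

    sample_ids = [f"case_{i + 1:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(cfg.n_controls)
    ]
    genotypes = CohortGenotypes(
        sample_ids=sample_ids, phenotype=phenotype, dosage=dosage, variants=variants
    )

    ne_table: dict[str, float] = {}
    for g in genes:
        if g in planted_set:
            ne_table[g] = float(16.1 + rng.gamma(2.0, 10.0))
        elif rng.random() < cfg.ne_missing_fraction:
            ne_table[g] = float("nan")
        else:
            ne_table[g] = float(rng.lognormal(mean=1.5, sigma=1.2))

    seeds = _fixture_seeds()
    edges: list[tuple] = []
    for a, b in zip(seeds[:-1], seeds[1:]):
        edges.append((a, b, float(rng.uniform(0.6, 0.95))))
    for _ in range(15):
        a, b = rng.choice(len(seeds), size=2, replace=False)
        edges.append((seeds[a], seeds[b], float(rng.uniform(0.6, 0.95))))
    for g in genes:
        if g in planted_set:
            if rng.random() < 0.9:
                edges.append((g, seeds[rng.integers(len(seeds))], float(rng.uniform(0.5, 0.95))))
        else:
            r = rng.random()
            if r < 0.12:
                edges.append((g, seeds[rng.integers(len(seeds))], float(rng.uniform(0.45, 0.9))))
            elif r < 0.22:
                other = genes[rng.integers(len(genes))]
                if other != g:
                    edges.append((g, other, float(rng.uniform(0.45, 0.9))))
            if rng.random() < 0.05:  # low-confidence edge, dropped at load time
                edges.append((g, seeds[rng.integers(len(seeds))], float(rng.uniform(0.15, 0.39))))

    pedigree = [(s, s, "0", "0", 1, 2) for s in sample_ids[: cfg.n_cases]]
    pedigree += [(s, s, "0", "0", 1, 1) for s in sample_ids[cfg.n_cases:]]

    dataset = CohortDataset(
        genotypes=genotypes,
        variants=variants,
        pedigree=pedigree,
        ne_table=ne_table,
        ppi_edges=edges,
        seed_genes=seeds,
        truth=tuple(planted),
        trios=[],
        gene_chrom=gene_chrom,
    )
    if with_trios and cfg.n_trios:
        dataset.trios = generate_trios(cfg, dataset, rng=rng)
        for fam in dataset.trios:
            dataset.pedigree.append((fam.family_id, fam.father_id, "0", "0", 1, 1))
            dataset.pedigree.append((fam.family_id, fam.mother_id, "0", "0", 2, 1))
            dataset.pedigree.append(
                (fam.family_id, fam.proband_id, fam.father_id, fam.mother_id, 1, 2)
            )
    return dataset


def generate_trios(
    config: SimulationConfig,
    cohort: CohortDataset,
    rng: Optional[np.random.Generator] = None,
) -> list[TrioFamily]:
    """Generate trio families whose probands carry mixed-origin LOFs.

    Each proband receives maternally inherited, paternally inherited and de
    novo heterozygous LOFs (counts Poisson around the configured means; at
    least one maternal and one de novo).  A fraction of inherited LOFs reuse
    a cohort variant carried by at least one control (``in_controls=True``),
    to exercise the control-absence rule; de novo sites are always novel.
    De novo calls fail validation with probability
    ``de_novo_false_positive_rate``.  Ground-truth inheritance labels are
    kept on every site.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    genes = list(cohort.gene_chrom) or ["G0001"]
    gene_chrom = dict(cohort.gene_chrom) or {"G0001": "chr1"}

    pos_counter: dict[str, int] = {}
    for v in cohort.variants:
        pos_counter[v.chrom] = max(pos_counter.get(v.chrom, 1_000_000), v.pos)

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 1_000_000) + int(rng.integers(500, 5000))
        return pos_counter[chrom]

    ctrl_counts = control_carrier_counts(cohort)
    shared_pool = [
        v for v in cohort.variants
        if v.is_lof and ctrl_counts.get(v.key, 0) > 0 and v.chrom != "chrX"
    ]

    planted_pool = [g for g in cohort.truth if gene_chrom.get(g, "") != "chrX"]

    def new_variant(allow_x: bool, allow_planted: bool = False) -> VariantRecord:
        # trio candidates can hit the same risk genes the case-control scan
        # flags, so the joint analysis has something to corroborate
        if allow_planted and planted_pool and rng.random() < cfg.trio_planted_fraction:
            g = planted_pool[int(rng.integers(len(planted_pool)))]
        else:
            g = genes[int(rng.integers(len(genes)))]
            if not allow_x:
                while gene_chrom[g] == "chrX":
                    g = genes[int(rng.integers(len(genes)))]
        chrom = gene_chrom[g]
        effect = _LOF_EFFECTS[rng.choice(len(_LOF_EFFECTS), p=_LOF_PROBS)]
        return _make_variant(rng, chrom, next_pos(chrom), g, effect, cfg)

    families = []
    for t in range(cfg.n_trios):
        fam = f"F{t + 1:02d}"
        sites: list[TrioSite] = []

        def add_site(variant: VariantRecord, inheritance: Inheritance, in_controls: bool) -> None:
            hemi = variant.chrom == "chrX"
            pg = 2 if hemi else 1
            mg = (1, 0)[inheritance != Inheritance.MATERNAL]
            fg = 1 if (inheritance == Inheritance.PATERNAL and not hemi) else 0
            if inheritance == Inheritance.DE_NOVO:
                mg = fg = 0
            validation = Validation.TRUE
            if inheritance == Inheritance.DE_NOVO:
                validation = (
                    Validation.FALSE
                    if rng.random() < cfg.de_novo_false_positive_rate
                    else Validation.TRUE
                )
            sites.append(
                TrioSite(
                    variant=variant, proband=pg, mother=mg, father=fg, hemizygous=hemi,
                    truth_inheritance=inheritance, validation=validation,
                    in_controls=in_controls,
                )
            )

        n_mat = 1 + int(rng.poisson(max(cfg.mean_maternal_lofs - 1.0, 0.0)))
        n_pat = int(rng.poisson(cfg.mean_paternal_lofs))
        n_dnv = 1 + int(rng.poisson(max(cfg.mean_denovo_lofs - 1.0, 0.0)))
        for _ in range(n_mat):
            if shared_pool and rng.random() < cfg.trio_control_overlap:
                v = shared_pool[int(rng.integers(len(shared_pool)))]
                add_site(v, Inheritance.MATERNAL, in_controls=True)
            else:
                add_site(new_variant(allow_x=True, allow_planted=True),
                         Inheritance.MATERNAL, in_controls=False)
        for _ in range(n_pat):
            add_site(new_variant(allow_x=False), Inheritance.PATERNAL, in_controls=False)
        for _ in range(n_dnv):
            add_site(new_variant(allow_x=True, allow_planted=True),
                     Inheritance.DE_NOVO, in_controls=False)

        contig_rank = {c: i for i, c in enumerate([f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"])}
        sites.sort(key=lambda s: (contig_rank[s.variant.chrom], s.variant.pos))
        families.append(
            TrioFamily(
                family_id=fam,
                proband_id=f"{fam}_proband",
                father_id=f"{fam}_father",
                mother_id=f"{fam}_mother",
                sites=sites,
            )
        )
    return families


def control_carrier_counts(dataset: CohortDataset) -> dict[tuple, int]:
    """Per-variant carrier counts among the control samples."""
    controls = dataset.genotypes.phenotype == 0
    carriers = (dataset.genotypes.dosage[controls] > 0).sum(axis=0)
    return {v.key: int(c) for v, c in zip(dataset.variants, carriers)}


def trio_calls(family: TrioFamily) -> list[TrioVariantCall]:
    """Convert a family's sites into unclassified trio calls."""
    return [
        TrioVariantCall(
            family_id=family.family_id,
            variant=s.variant,
            proband=s.proband,
            mother=s.mother,
            father=s.father,
            hemizygous=s.hemizygous,
            validation=s.validation,
        )
        for s in family.sites
    ]


@dataclass
class Manifest:
    """Files written by :func:`write_inputs`.

    ``inputs`` holds the five standard pipeline inputs (VCF, PED,
    annotation TSV, NE TSV, edge-list TSV); ``sidecars`` holds the
    seed-gene list, per-family trio VCFs and the truth JSON.
    """

    directory: Path
    inputs: dict
    sidecars: dict


def write_inputs(dataset: CohortDataset, directory: Path) -> Manifest:
    """Write every input format; write-then-read reproduces the dataset."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {directory}: {exc}") from exc

    g = dataset.genotypes
    inputs = {
        "vcf": directory / "cohort.vcf",
        "ped": directory / "samples.ped",
        "annotations": directory / "annotations.tsv",
        "ne": directory / "ne.tsv",
        "edges": directory / "ppi_edges.tsv",
    }
    _io.write_vcf(inputs["vcf"], dataset.variants, g.sample_ids, g.dosage,
                  sample_sex=[1] * len(g.sample_ids))
    _io.write_ped(inputs["ped"], dataset.pedigree)

    all_variants = list(dataset.variants)
    seen = {v.key for v in all_variants}
    for fam in dataset.trios:
        for s in fam.sites:
            if s.variant.key not in seen:
                all_variants.append(s.variant)
                seen.add(s.variant.key)
    _io.write_annotations(inputs["annotations"], all_variants)
    _io.write_ne_table(inputs["ne"], dataset.ne_table)
    _io.write_edges(inputs["edges"], dataset.ppi_edges)

    sidecars: dict = {}
    seeds_path = directory / "seed_genes.txt"
    seeds_path.write_text("\n".join(dataset.seed_genes) + "\n")
    sidecars["seed_genes"] = seeds_path

    trio_paths = {}
    for fam in dataset.trios:
        path = directory / f"trio_{fam.family_id}.vcf"
        samples = [fam.proband_id, fam.father_id, fam.mother_id]
        sex = [1, 1, 2]
        fam_variants = [s.variant for s in fam.sites]
        fam_dosage = np.array(
            [[s.proband for s in fam.sites], [s.father for s in fam.sites],
             [s.mother for s in fam.sites]],
            dtype=np.int8,
        )
        _io.write_vcf(path, fam_variants, samples, fam_dosage, sample_sex=sex)
        trio_paths[fam.family_id] = path
    sidecars["trio_vcfs"] = trio_paths

    truth = {
        "planted_genes": list(dataset.truth),
        "gene_chrom": dataset.gene_chrom,
        "trios": {
            fam.family_id: [
                {
                    "key": list(s.variant.key),
                    "inheritance": s.truth_inheritance.value,
                    "validation": s.validation.value,
                    "in_controls": s.in_controls,
                }
                for s in fam.sites
            ]
            for fam in dataset.trios
        },
    }
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    sidecars["truth"] = truth_path
    return Manifest(directory=directory, inputs=inputs, sidecars=sidecars)


def read_inputs(directory: Path) -> CohortDataset:
    """Reconstruct a :class:`CohortDataset` written by :func:`write_inputs`."""
    directory = Path(directory)
    records = _io.read_annotations(directory / "annotations.tsv")
    by_key = {r.key: r for r in records}

    samples, keys, dosage, _ = _io.read_vcf(directory / "cohort.vcf")
    variants = [by_key[k] for k in keys]
    ped = _io.read_ped(directory / "samples.ped")
    ped_rows = [tuple(row) for row in ped.itertuples(index=False)]
    pheno_by_id = dict(zip(ped["individual_id"], ped["phenotype"]))
    phenotype = np.array([1 if pheno_by_id[s] == 2 else 0 for s in samples], dtype=np.int8)
    genotypes = CohortGenotypes(
        sample_ids=samples, phenotype=phenotype, dosage=dosage, variants=variants
    )

    ne_table = _io.read_ne_table(directory / "ne.tsv")
    edges = _io.read_edges(directory / "ppi_edges.tsv")
    seeds = tuple(
        line.strip()
        for line in (directory / "seed_genes.txt").read_text().splitlines()
        if line.strip()
    )
    truth = json.loads((directory / "truth.json").read_text())

    trios = []
    fam_members = ped[ped["family_id"].isin(truth["trios"].keys())]
    for fam_id, meta in truth["trios"].items():
        rows = fam_members[fam_members["family_id"] == fam_id]
        proband = rows[rows["phenotype"] == 2]["individual_id"].iloc[0]
        father = rows[(rows["phenotype"] == 1) & (rows["sex"] == 1)]["individual_id"].iloc[0]
        mother = rows[rows["sex"] == 2]["individual_id"].iloc[0]
        t_samples, t_keys, t_dosage, _ = _io.read_vcf(directory / f"trio_{fam_id}.vcf")
        meta_by_key = {tuple(m["key"]): m for m in meta}
        sites = []
        for j, key in enumerate(t_keys):
            m = meta_by_key[key]
            col = {s: t_dosage[i, j] for i, s in enumerate(t_samples)}
            sites.append(
                TrioSite(
                    variant=by_key[key],
                    proband=int(col[proband]),
                    mother=int(col[mother]),
                    father=int(col[father]),
                    hemizygous=key[0] in ("chrX", "X"),
                    truth_inheritance=Inheritance(m["inheritance"]),
                    validation=Validation(m["validation"]),
                    in_controls=bool(m["in_controls"]),
                )
            )
        trios.append(
            TrioFamily(family_id=fam_id, proband_id=proband, father_id=father,
                       mother_id=mother, sites=sites)
        )
    trios.sort(key=lambda f: f.family_id)

    return CohortDataset(
        genotypes=genotypes,
        variants=variants,
        pedigree=ped_rows,
        ne_table=ne_table,
        ppi_edges=edges,
        seed_genes=seeds,
        truth=tuple(truth["planted_genes"]),
        trios=trios,
        gene_chrom=dict(truth.get("gene_chrom", {})),
    )


def simulate_hwe_genotype_counts(
    n_samples: int,
    maf: float,
    n_variants: int,
    rng: np.random.Generator,
) -> list[GenotypeCounts]:
    """Genotype counts sampled under exact Hardy-Weinberg proportions.

    Used for calibrating the exact HWE test: at a common minor-allele
    frequency the conditional null distribution is rich enough for the
    rejection rate at level alpha to approach alpha.
    """
    p = maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    draws = rng.multinomial(n_samples, probs, size=n_variants)
    return [GenotypeCounts(int(a), int(b), int(c)) for a, b, c in draws]
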