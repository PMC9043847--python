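"""Synthetic cohort generator: study conditions, truth channel, file round-trip."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

import noarvas as na
from noarvas import SimulationConfig
from noarvas.trio import Inheritance, Validation


class TestConfigValidation:
    def test_defaults_mirror_the_study(self):
        cfg = SimulationConfig()
        assert (cfg.n_cases, cfg.n_controls, cfg.n_trios) == (133, 343, 11)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"planted_carrier_rate_cases": 1.5}, "planted_carrier_rate_cases"),
            ({"background_lof_rate": -0.1}, "background_lof_rate"),
            ({"de_novo_false_positive_rate": 2.0}, "de_novo_false_positive_rate"),
            ({"n_genes": 3, "n_planted_risk_genes": 5}, "n_planted_risk_genes"),
            ({"reference_af_range": (0.5, 0.1)}, "reference_af_range"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(na.ConfigurationError, match=field):
            SimulationConfig(**kwargs)


class TestGenerateCohort:
    def test_cohort_sizes(self, small_cohort):
        g = small_cohort.genotypes
        assert g.n_cases == 133 and g.n_controls == 343
        assert len(g.sample_ids) == 476

    def test_all_variants_rare_or_uncatalogued(self, small_cohort):
        for v in small_cohort.variants:
            assert v.ref_af is None or v.ref_af < 0.01

    def test_every_gene_has_expression_record(self, small_cohort):
        genes = {v.gene for v in small_cohort.variants}
        assert genes <= set(small_cohort.ne_table)  # NaN marks missing explicitly

    def test_truth_genes_exist(self, small_cohort):
        assert set(small_cohort.truth) <= {v.gene for v in small_cohort.variants}

    def test_no_planting_means_equal_rates(self):
        cfg = SimulationConfig(rng_seed=2, n_planted_risk_genes=0, n_genes=400, n_trios=0)
        ds = na.generate_cohort(cfg, with_trios=False)
        cases = ds.genotypes.phenotype == 1
        lof = np.array([v.is_lof for v in ds.variants])
        carrier_case = (ds.genotypes.dosage[cases][:, lof] > 0).mean()
        carrier_ctrl = (ds.genotypes.dosage[~cases][:, lof] > 0).mean()
        # both groups draw from the same background rate
        assert carrier_case == pytest.approx(carrier_ctrl, abs=3 * 0.002)

    def test_planted_case_carrier_rate(self):
        # 1000 replicate genes at rate 0.05 in cases, 0 in controls
        cfg = SimulationConfig(
            rng_seed=3, n_genes=1000, n_planted_risk_genes=999,
            planted_carrier_rate_cases=0.05, planted_carrier_rate_controls=0.0,
            n_trios=0, include_x_gene=True,
        )
        ds = na.generate_cohort(cfg, with_trios=False)
        cases = ds.genotypes.phenotype == 1
        planted = set(ds.truth)
        rates = []
        for gene in planted:
            cols = [j for j, v in enumerate(ds.variants) if v.gene == gene and v.is_lof]
            rates.append((ds.genotypes.dosage[cases][:, cols] > 0).any(axis=1).mean())
        mean_rate = float(np.mean(rates))
        sd = math.sqrt(0.05 * 0.95 / (133 * len(planted)))
        assert abs(mean_rate - 0.05) < 3 * sd
        ctrl_cols = [
            j for j, v in enumerate(ds.variants) if v.gene in planted and v.is_lof
        ]
        assert (ds.genotypes.dosage[~cases][:, ctrl_cols] == 0).all()

    def test_x_gene_uses_hemizygous_coding(self, small_cohort):
        x_cols = [j for j, v in enumerate(small_cohort.variants) if v.chrom == "chrX"]
        assert x_cols
        assert set(np.unique(small_cohort.genotypes.dosage[:, x_cols])) <= {0, 2}


class TestGenerateTrios:
    def test_requested_number_of_families(self, small_cohort):
        assert len(small_cohort.trios) == 5
        for fam in small_cohort.trios:
            assert fam.proband_id and fam.mother_id and fam.father_id

    def test_eleven_trios_by_default(self):
        ds = na.generate_cohort(SimulationConfig(rng_seed=1, n_genes=30))
        assert len(ds.trios) == 11

    @pytest.mark.parametrize("rate,expected", [(0.0, Validation.TRUE), (1.0, Validation.FALSE)])
    def test_de_novo_validation_rate_extremes(self, rate, expected):
        cfg = SimulationConfig(rng_seed=4, n_genes=30, n_trios=8,
                               de_novo_false_positive_rate=rate)
        ds = na.generate_cohort(cfg)
        dnv = [
            s for fam in ds.trios for s in fam.sites
            if s.truth_inheritance == Inheritance.DE_NOVO
        ]
        assert dnv and all(s.validation == expected for s in dnv)

    def test_mendelian_consistency_of_inherited_sites(self, small_cohort):
        for fam in small_cohort.trios:
            for s in fam.sites:
                if s.truth_inheritance == Inheritance.MATERNAL:
                    assert s.mother > 0 and s.father == 0
                elif s.truth_inheritance == Inheritance.PATERNAL:
                    assert s.father > 0 and s.mother == 0
                elif s.truth_inheritance == Inheritance.DE_NOVO:
                    assert s.mother == 0 and s.father == 0

    def test_classifier_recovers_planted_labels(self, small_cohort):
        for fam in small_cohort.trios:
            for call, site in zip(na.trio_calls(fam), fam.sites):
                assert na.classify_call(call).inheritance == site.truth_inheritance

    def test_control_overlap_sites_are_carried_by_controls(self, small_cohort):
        counts = na.control_carrier_counts(small_cohort)
        flagged = [
            s for fam in small_cohort.trios for s in fam.sites if s.in_controls
        ]
        assert flagged  # the scenario exercises the control-absence rule
        for s in flagged:
            assert counts.get(s.variant.key, 0) > 0


def _tree_digest(directory: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(directory).iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestWriteReadInputs:
    def test_manifest_lists_five_input_files(self, small_cohort, tmp_path):
        manifest = na.write_inputs(small_cohort, tmp_path / "out")
        assert len(manifest.inputs) == 5
        for path in manifest.inputs.values():
            assert path.exists()

    def test_round_trip_reproduces_dataset(self, small_cohort, tmp_path):
        na.write_inputs(small_cohort, tmp_path / "rt")
        ds2 = na.read_inputs(tmp_path / "rt")
        assert np.array_equal(small_cohort.genotypes.dosage, ds2.genotypes.dosage)
        assert small_cohort.genotypes.sample_ids == ds2.genotypes.sample_ids
        assert small_cohort.variants == ds2.variants
        assert small_cohort.truth == ds2.truth
        assert small_cohort.seed_genes == ds2.seed_genes
        assert small_cohort.ppi_edges == ds2.ppi_edges
        for g, ne in small_cohort.ne_table.items():
            other = ds2.ne_table[g]
            assert (math.isnan(ne) and math.isnan(other)) or ne == other
        assert [f.family_id for f in small_cohort.trios] == [f.family_id for f in ds2.trios]
        for f1, f2 in zip(small_cohort.trios, ds2.trios):
            assert f1.sites == f2.sites

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(rng_seed=5, n_genes=25, n_trios=3)
        na.write_inputs(na.generate_cohort(cfg), tmp_path / "a")
        na.write_inputs(na.generate_cohort(cfg), tmp_path / "b")
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")

    def test_empty_dataset_gives_header_only_vcf(self, tmp_path):
        cfg = SimulationConfig(rng_seed=6, n_genes=0, n_trios=0,
                               n_planted_risk_genes=0, include_x_gene=False)
        ds = na.generate_cohort(cfg, with_trios=False)
        manifest = na.write_inputs(ds, tmp_path / "empty")
        body = [
            line for line in manifest.inputs["vcf"].read_text().splitlines()
            if line and not line.startswith("#")
        ]
        assert body == []
        ds2 = na.read_inputs(tmp_path / "empty")
        assert ds2.genotypes.dosage.shape == (476, 0)

    def test_unwritable_directory_raises(self, small_cohort):
        with pytest.raises(OSError):
            na.write_inputs(small_cohort, Path("/proc/nope/sub"))


def test_thresholds_yaml_round_trip(tmp_path):
    path = tmp_path / "run.yaml"
    path.write_text("maf: 0.005\nhwe_alpha: 0.01\n")
    th = na.load_thresholds(path)
    assert th.maf == 0.005 and th.hwe_alpha == 0.01 and th.p_sig == 0.05
    path.write_text("nonsense_key: 1\n")
    with pytest.raises(ValueError):
        na.load_thresholds(path)
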