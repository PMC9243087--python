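"""Generator contracts: determinism, conservation, expected VAFs, processes."""

import numpy as np
import pytest

from clonopanel import SimulationConfig, simulate_cohort
from clonopanel.simulate import (
    ConfigurationError,
    expected_contaminated_normal_vaf,
    expected_tumor_vaf,
    inject_artifacts,
    sample_counts,
)
from clonopanel.cohort_io import bundles_equal
from clonopanel.signature import count_motif_opportunities


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"purity_range": (0.0, 0.9)}, "purity_range"),
            ({"purity_range": (0.9, 0.4)}, "purity_range"),
            ({"contamination_fraction_range": (0.0, 0.7)}, "contamination_fraction_range"),
            ({"ccf_grid": (0.2, 0.5)}, "ccf_grid"),
            ({"ccf_grid": (0.0, 1.0)}, "ccf_grid"),
            ({"apobec_weight": 1.5}, "apobec_weight"),
            ({"artifact_rate": -1.0}, "artifact_rate"),
            ({"n_clones_range": (3, 2)}, "n_clones_range"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**kwargs)


class TestDeterminismAndConservation:
    def test_same_config_same_seed_identical_bundles(self):
        cfg = SimulationConfig(n_patients=3, panel_size=150_000, seed=5)
        assert bundles_equal(simulate_cohort(cfg), simulate_cohort(cfg))

    def test_truth_classes_partition_call_sets(self, small_bundle):
        tv = small_bundle.truth.variants
        for pid, p in small_bundle.patients.items():
            sub = tv[tv.patient == pid]
            assert len(p.tumor) == int(sub.in_tumor.sum())
            assert len(p.normal) == int(sub.in_normal.sum())
            tumor_classes = set(sub[sub.in_tumor]["class"])
            assert tumor_classes <= {"somatic", "germline_common", "artifact"}
            assert set(sub[sub["class"] == "contaminant_only"].in_tumor.unique()) <= {False}

    def test_somatic_truth_ccf_equals_clone_ccf(self, small_bundle):
        tv = small_bundle.truth.variants
        clones = small_bundle.truth.clones.set_index(["patient", "clone_id"])["ccf"]
        som = tv[tv["class"] == "somatic"]
        for row in som.itertuples(index=False):
            assert row.ccf == clones.loc[(row.patient, row.clone_id)]

    def test_exactly_one_trunk_clone_per_patient(self, small_bundle):
        for pid, grp in small_bundle.truth.clones.groupby("patient"):
            assert (grp.ccf == 1.0).sum() == 1


class TestReadCountSampling:
    def test_mean_simulated_vaf_matches_expectation(self):
        rng = np.random.default_rng(11)
        evaf = expected_tumor_vaf(ccf=0.6, m=1.0, purity=0.7, cn=3.0)
        vafs = []
        for _ in range(1000):
            f, r, d, *_ = sample_counts(evaf, 600.0, rng)
            vafs.append((f + r) / d)
        se = np.std(vafs, ddof=1) / np.sqrt(len(vafs))
        assert abs(np.mean(vafs) - evaf) < 3 * se + 1e-12

    def test_noise_free_counts_carry_exact_expected_vaf(self):
        rng = np.random.default_rng(0)
        f, r, d, o12, o21, ve = sample_counts(0.3125, 600.0, rng, noise_free=True)
        assert ve == 0.3125
        assert f + r == round(0.3125 * 600)

    def test_contaminated_normal_vaf_monotone_in_fraction(self):
        vals = [expected_contaminated_normal_vaf(1.0, 1.0, f, 2.0) for f in (0.0, 0.1, 0.3)]
        assert vals[0] == 0.0 and vals[0] < vals[1] < vals[2]


class TestMutationalProcess:
    @staticmethod
    def _motif_fraction(bundle):
        res = bundle.resources
        tv = bundle.truth.variants
        snvs = tv[(tv["class"] == "somatic") & (tv.ref.str.len() == 1) & (tv.alt.str.len() == 1)]
        deam = snvs[((snvs.ref == "C") & snvs.alt.isin(["T", "G"]))
                    | ((snvs.ref == "G") & snvs.alt.isin(["A", "C"]))]
        n_in = 0
        for row in deam.itertuples(index=False):
            tri = res.trinucleotide(row.contig, row.pos)
            if tri is None:
                continue
            if row.ref == "C" and tri[0] == "T" and tri[2] in "AT":
                n_in += 1
            elif row.ref == "G" and tri[2] == "A" and tri[0] in "AT":
                n_in += 1
        return n_in, len(deam)

    def test_zero_weight_matches_panel_background(self):
        cfg = SimulationConfig(n_patients=20, panel_size=400_000, seed=23,
                               apobec_weight=0.0, somatic_rate_per_mb=60.0,
                               indel_fraction=0.0, artifact_rate=0.0,
                               germline_snp_rate=0.0)
        bundle = simulate_cohort(cfg)
        n_in, n = self._motif_fraction(bundle)
        ctx_in, ctx_out = count_motif_opportunities(bundle.resources)
        background = ctx_in / (ctx_in + ctx_out)
        se = np.sqrt(background * (1 - background) / n)
        assert abs(n_in / n - background) < 3 * se

    def test_high_weight_concentrates_at_motif(self):
        cfg = SimulationConfig(n_patients=20, panel_size=400_000, seed=23,
                               apobec_weight=0.8, somatic_rate_per_mb=60.0,
                               indel_fraction=0.0, artifact_rate=0.0,
                               germline_snp_rate=0.0)
        n_in, n = self._motif_fraction(simulate_cohort(cfg))
        assert n_in / n > 0.5


class TestArtifactInjection:
    def _normals(self, n=10):
        return {f"N{i}": [] for i in range(n)}

    POOL = [("chr1", 100, "A", "T"), ("chr1", 500, "C", "A")]

    def test_rate_zero_leaves_calls_unchanged(self):
        out, truth = inject_artifacts(self._normals(), self.POOL, rate=0.0, seed=1)
        assert all(not calls for calls in out.values())
        assert truth.empty

    def test_each_site_hits_at_least_three_samples(self):
        out, truth = inject_artifacts(self._normals(), self.POOL, rate=1.0, seed=1)
        per_site = truth.groupby(["contig", "pos"])["sample"].nunique()
        assert (per_site >= 3).all()

    def test_whitelist_eligible_marking(self, tiny_resources):
        pool = [("chrT", 13, tiny_resources.base_at("chrT", 13), "T")]
        _, truth = inject_artifacts(self._normals(), pool, rate=1.0, seed=2,
                                    resources=tiny_resources)
        assert truth.whitelist_eligible.all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_artifacts(self._normals(), self.POOL, rate=-1.0, seed=0)
        with pytest.raises(ValueError):
            inject_artifacts(self._normals(), [], rate=1.0, seed=0)


class TestContaminationStructure:
    def test_blood_only_variants_absent_from_tumor(self, small_bundle):
        tv = small_bundle.truth.variants
        blood = tv[tv["class"] == "contaminant_only"]
        for pid, p in small_bundle.patients.items():
            tumor_keys = {c.key for c in p.tumor}
            for row in blood[blood.patient == pid].itertuples(index=False):
                assert (row.contig, row.pos, row.ref, row.alt) not in tumor_keys
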