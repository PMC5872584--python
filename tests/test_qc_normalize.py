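"""Each QC rule is checked at its boundary, against planted failures, and
for the bookkeeping invariants (reason partitioning, retention arithmetic,
idempotence)."""

import numpy as np
import pandas as pd
import pytest

from natalmeth import (
    InputError,
    MethylSet,
    GenotypeSet,
    bisulfite_filter,
    detection_p_filter,
    duplicate_check,
    genotype_concordance,
    intensity_filter,
    quantile_normalize,
    run_qc,
    sex_check,
    plant_qc_failures,
)
from natalmeth.qc_normalize import (
    BISULFITE_FAIL,
    DETECTION_P_FAIL,
    DUPLICATE,
    GENOTYPE_DISCORDANT,
    LOW_INTENSITY,
    SEX_MISMATCH,
)
from conftest import correlated_pair


def tiny_mset(n=4, p=6, **kw):
    rng = np.random.default_rng(0)
    manifest = pd.DataFrame(
        {
            "id": [f"cg{j}" for j in range(p)],
            "chrom": "1",
            "pos": 100 + 10 * np.arange(p),
            "probe_type": ["I", "II"] * (p // 2),
            "gene": "",
        }
    )
    return MethylSet(beta=rng.uniform(0.2, 0.8, (n, p)), manifest=manifest, **kw)


class TestIntensityFilter:
    @pytest.mark.parametrize(
        "med_m,med_u,expect_fail",
        [(3000, 2600, False), (3000, 2400, True), (2500, 2500, False), (2499, 5000, True)],
    )
    def test_median_rule_strict(self, med_m, med_u, expect_fail):
        m = tiny_mset()
        m.meth = np.full((4, 6), float(med_m))
        m.unmeth = np.full((4, 6), float(med_u))
        frag = intensity_filter(m, 2500.0)
        assert (0 in frag) == expect_fail
        if expect_fail:
            assert frag[0] == LOW_INTENSITY

    def test_requires_intensities(self):
        with pytest.raises(InputError):
            intensity_filter(tiny_mset())


class TestBisulfiteFilter:
    @pytest.mark.parametrize("median,expect_fail", [(95, False), (79, True), (80, False)])
    def test_median_score_rule(self, median, expect_fail):
        m = tiny_mset(control_scores=np.full((4, 10), float(median)))
        assert (0 in bisulfite_filter(m)) == expect_fail

    def test_wrong_control_count_rejected(self):
        m = tiny_mset(control_scores=np.full((4, 9), 90.0))
        with pytest.raises(InputError):
            bisulfite_filter(m)


class TestDuplicateCheck:
    def test_identical_fingerprints_flagged(self):
        rng = np.random.default_rng(1)
        snp = rng.uniform(0, 1, (5, 65))
        snp[3] = snp[1]
        frag = duplicate_check(tiny_mset(n=5, snp_probe_beta=snp))
        assert set(frag) == {1, 3}

    def test_independent_samples_not_flagged(self):
        rng = np.random.default_rng(2)
        snp = rng.uniform(0, 1, (100, 65))
        assert duplicate_check(tiny_mset(n=100, snp_probe_beta=snp)) == {}

    @pytest.mark.parametrize("r,expect", [(0.96, True), (0.94, False)])
    def test_threshold_is_strict_at_0_95(self, r, expect):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(65)
        y = correlated_pair(x, r, rng)
        snp = rng.uniform(0.3, 0.7, (4, 65))
        snp[0] = 0.5 + 0.1 * (x - x.mean()) / x.std()
        snp[1] = 0.5 + 0.1 * (y - y.mean()) / y.std()
        flagged = set(duplicate_check(tiny_mset(snp_probe_beta=np.clip(snp, 0, 1))))
        assert ({0, 1} <= flagged) == expect


class TestSexCheck:
    def test_planted_mislabel_flagged(self, small_bundle):
        sheet = small_bundle.sheet.copy()
        sheet.loc[sheet.index[7], "sex"] = "F" if sheet.iloc[7]["sex"] == "M" else "M"
        assert sex_check(small_bundle.mset, sheet) == {7: SEX_MISMATCH}

    def test_correct_labels_unflagged(self, small_bundle):
        assert sex_check(small_bundle.mset, small_bundle.sheet) == {}

    def test_coordinate_sign_invariance(self, small_bundle):
        """Reflecting the methylation space flips the MDS coordinate sign;
        the flags must not change."""
        m = small_bundle.mset
        flipped = MethylSet(
            beta=1.0 - m.beta, manifest=m.manifest, sample_ids=list(m.sample_ids)
        )
        sheet = small_bundle.sheet.copy()
        sheet.loc[sheet.index[3], "sex"] = "F" if sheet.iloc[3]["sex"] == "M" else "M"
        assert sex_check(flipped, sheet) == sex_check(m, sheet)


class TestGenotypeConcordance:
    def make(self, dosage, probe_beta):
        n, v = dosage.shape
        variants = pd.DataFrame(
            {
                "id": [f"rs{j}" for j in range(v)],
                "chrom": "1",
                "pos": 1000 + 10 * np.arange(v),
                "effect_allele": "A",
                "other_allele": "G",
                "freq": 0.5,
            }
        )
        geno = GenotypeSet(dosage=dosage, variants=variants)
        m = tiny_mset(n=n, snp_probe_beta=probe_beta)
        return m, geno, [(j, f"rs{j}") for j in range(v)]

    def test_exact_encoding_passes(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (6, 10)).astype(float)
        m, g, pmap = self.make(d, d / 2.0)
        assert genotype_concordance(m, g, pmap) == {}

    def test_sample_swap_fails(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (6, 40)).astype(float)
        probes = d / 2.0
        probes[0] = rng.integers(0, 3, 40) / 2.0  # unrelated individual
        m, g, pmap = self.make(d, probes)
        frag = genotype_concordance(m, g, pmap)
        assert frag == {0: GENOTYPE_DISCORDANT}

    def test_eight_of_ten_calls_fail_at_0_9(self):
        d = np.tile(np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], float), (2, 1))
        probes = d / 2.0
        probes[0, :2] = [1.0, 0.0]  # two discordant calls: 8/10 = 0.8 < 0.9
        m, g, pmap = self.make(d, probes)
        assert 0 in genotype_concordance(m, g, pmap, min_concord=0.9)


class TestDetectionP:
    def test_sample_rule_hand_count(self):
        detp = np.full((4, 200), 0.01)
        detp[1, :3] = 0.1  # 1.5% of probes > 0.05
        mset = MethylSet(
            beta=np.full((4, 200), 0.5),
            manifest=pd.DataFrame(
                {"id": [f"cg{j}" for j in range(200)], "chrom": "1",
                 "pos": np.arange(200) + 1, "probe_type": "II", "gene": ""}
            ),
            detection_p=detp,
        )
        frag, probe_keep = detection_p_filter(mset)
        assert frag == {1: DETECTION_P_FAIL}
        # every probe that failed in that sample also exceeds 1% of samples
        assert (~probe_keep).sum() == 3

    def test_probe_rule_hand_count(self):
        detp = np.full((4, 200), 0.01)
        detp[0, 4] = 0.2  # probe 4: 1 of 4 samples (25%) above cut
        mset = MethylSet(
            beta=np.full((4, 200), 0.5),
            manifest=pd.DataFrame(
                {"id": [f"cg{j}" for j in range(200)], "chrom": "1",
                 "pos": np.arange(200) + 1, "probe_type": "II", "gene": ""}
            ),
            detection_p=detp,
        )
        frag, probe_keep = detection_p_filter(mset)
        assert not probe_keep[4] and probe_keep.sum() == 199
        # sample 0 itself stays: 1/200 probes = 0.5% does not exceed 1%
        assert frag == {}

    def test_all_good_nothing_fails(self):
        mset = MethylSet(
            beta=np.full((3, 8), 0.5),
            manifest=pd.DataFrame(
                {"id": [f"cg{j}" for j in range(8)], "chrom": "1",
                 "pos": np.arange(8) + 1, "probe_type": "I", "gene": ""}
            ),
            detection_p=np.full((3, 8), 0.01),
        )
        frag, probe_keep = detection_p_filter(mset)
        assert frag == {} and probe_keep.all()


class TestQuantileNormalize:
    def test_distributions_identical_after(self, small_bundle):
        norm = quantile_normalize(small_bundle.mset)
        ptype = norm.manifest["probe_type"].to_numpy()
        for t in ("I", "II"):
            cols = ptype == t
            sorted_m = np.sort(norm.meth[:, cols], axis=1)
            assert np.allclose(sorted_m, sorted_m[0][None, :], atol=1e-9)
        assert norm.beta.min() >= 0 and norm.beta.max() <= 1

    def test_rank_order_preserved(self, small_bundle):
        m = small_bundle.mset
        norm = quantile_normalize(m)
        ptype = m.manifest["probe_type"].to_numpy()
        for t in ("I", "II"):
            cols = np.where(ptype == t)[0]
            before = np.argsort(m.meth[0, cols], kind="stable")
            after = np.argsort(norm.meth[0, cols], kind="stable")
            np.testing.assert_array_equal(before, after)

    def test_permuted_samples_equal_multisets(self):
        rng = np.random.default_rng(6)
        row = rng.uniform(100, 10_000, 40)
        perm = rng.permutation(row)
        manifest = pd.DataFrame(
            {"id": [f"cg{j}" for j in range(40)], "chrom": "1",
             "pos": np.arange(40) + 1, "probe_type": "II", "gene": ""}
        )
        m = MethylSet(
            beta=np.full((2, 40), 0.5),
            manifest=manifest,
            meth=np.vstack([row, perm]),
            unmeth=np.vstack([row, perm]) * 0.9,
        )
        norm = quantile_normalize(m)
        np.testing.assert_allclose(np.sort(norm.meth[0]), np.sort(norm.meth[1]))

    def test_single_sample_identity(self):
        m = tiny_mset(n=1)
        m.meth = np.array([[5.0, 3.0, 8.0, 1.0, 2.0, 9.0]])
        m.unmeth = m.meth * 2
        norm = quantile_normalize(m)
        np.testing.assert_array_equal(norm.meth, m.meth)


class TestRunQC:
    def test_clean_cohort_fully_retained(self, small_bundle, probe_map):
        _, report = run_qc(
            small_bundle.mset, small_bundle.geno, small_bundle.sheet,
            probe_variant_map=probe_map,
        )
        assert report.retention_pct == 100.0

    def test_planted_failures_partition_reasons(self, small_bundle, probe_map):
        planted = plant_qc_failures(
            small_bundle,
            low_intensity=[0, 1],
            bisulfite=[2],
            duplicate_pairs=[(3, 4)],
            sex_mismatch=[5],
            genotype_discordant=[6],
            detection_p=[7],
        )
        retained, report = run_qc(
            planted.mset, planted.geno, planted.sheet, probe_variant_map=probe_map
        )
        failed = report.samples[~report.samples["passed"]]
        assert set(failed.index) == set(range(8))
        reason_of = dict(zip(failed.index, failed["reasons"]))
        assert reason_of[0] == LOW_INTENSITY and reason_of[1] == LOW_INTENSITY
        assert reason_of[2] == BISULFITE_FAIL
        assert DUPLICATE in reason_of[3] and DUPLICATE in reason_of[4]
        assert reason_of[5] == SEX_MISMATCH
        assert reason_of[6] == GENOTYPE_DISCORDANT
        assert reason_of[7] == DETECTION_P_FAIL
        assert report.retention_pct == round(100 * (200 - 8) / 200, 1)

    def test_idempotent_on_retained_output(self, small_bundle, probe_map):
        planted = plant_qc_failures(small_bundle, low_intensity=[0], detection_p=[3])
        retained, report = run_qc(
            planted.mset, planted.geno, planted.sheet,
            probe_variant_map=probe_map, normalize=False,
        )
        keep = report.samples["passed"].to_numpy()
        sheet2 = planted.sheet.loc[keep].reset_index(drop=True)
        geno2 = GenotypeSet(
            dosage=planted.geno.dosage[keep],
            variants=planted.geno.variants,
            sample_ids=[s for s, k in zip(planted.geno.sample_ids, keep) if k],
        )
        _, report2 = run_qc(retained, geno2, sheet2, probe_variant_map=probe_map, normalize=False)
        assert report2.retention_pct == 100.0
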