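"""The scan engine must agree with an independent least-squares oracle to
numerical precision, stay calibrated under the null, and recover planted
exposures, interactions and conditioning structure."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from natalmeth import (
    ClumpParams,
    GenotypeSet,
    MethylSet,
    ModelSpec,
    SimConfig,
    compute_prs,
    conditional_prs_ewas,
    ewas,
    generate_cohort,
    generate_genotypes,
    genetic_pcs,
    global_mean_test,
    interaction_ewas,
    ld_clump,
    power_two_sample,
    prs_ewas,
    stratified_prs_ewas,
)
from natalmeth.prs_builder import PRSProfile


def mset_from_beta(beta):
    beta = np.asarray(beta, float)
    p = beta.shape[1]
    manifest = pd.DataFrame(
        {"id": [f"cg{j}" for j in range(p)], "chrom": "1",
         "pos": np.arange(p) + 1, "probe_type": "II", "gene": ""}
    )
    return MethylSet(beta=beta, manifest=manifest)


class TestEwasCore:
    def test_exact_linear_relationship(self):
        x = np.linspace(0.05, 0.5, 10)
        y = (2.0 * x + 0.0).reshape(-1, 1) / 2  # keep in [0,1]
        res = ewas(mset_from_beta(y), pd.DataFrame({"x": x}), ModelSpec(exposure="x"))
        assert res["estimate"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert res["se"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        data = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "urbanicity": rng.integers(1, 6, n),
                "sex": rng.choice(["M", "F"], n),
            }
        )
        Y = rng.uniform(0.2, 0.8, (n, 5))
        res = ewas(
            mset_from_beta(Y), data,
            ModelSpec(exposure="x", covariates=["c1", "urbanicity", "sex"]),
        )
        X = pd.get_dummies(
            data.assign(urbanicity=data["urbanicity"].astype("category")),
            columns=["urbanicity"], drop_first=True,
        )
        X["sex"] = (X["sex"] == "M").astype(float)
        X = sm.add_constant(X[["x", "c1", "urbanicity_2", "urbanicity_3",
                               "urbanicity_4", "urbanicity_5", "sex"]].astype(float))
        for j in range(5):
            fit = sm.OLS(Y[:, j], X).fit()
            assert res["estimate"].iloc[j] == pytest.approx(fit.params["x"], abs=1e-8)
            assert res["se"].iloc[j] == pytest.approx(fit.bse["x"], abs=1e-8)
            assert res["p"].iloc[j] == pytest.approx(fit.pvalues["x"], abs=1e-8)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        n, m = 500, 2000
        Y = rng.uniform(0.3, 0.7, (n, m))
        data = pd.DataFrame({"x": rng.normal(size=n), "c": rng.normal(size=n)})
        res = ewas(mset_from_beta(Y), data, ModelSpec(exposure="x", covariates=["c"]))
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / m)

    def test_orthogonal_covariate_leaves_estimate(self):
        rng = np.random.default_rng(78)
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        # orthogonalize z against x, the outcome and the intercept
        y = np.clip(0.5 + 0.01 * x + rng.normal(0, 0.01, n), 0, 1)
        M = np.column_stack([np.ones(n), x, y])
        z = z - M @ np.linalg.lstsq(M, z, rcond=None)[0]
        base = ewas(mset_from_beta(y[:, None]), pd.DataFrame({"x": x}), ModelSpec(exposure="x"))
        with_z = ewas(
            mset_from_beta(y[:, None]), pd.DataFrame({"x": x, "z": z}),
            ModelSpec(exposure="x", covariates=["z"]),
        )
        assert abs(base["estimate"].iloc[0] - with_z["estimate"].iloc[0]) < 1e-6

    def test_zero_variance_cpg_skipped(self):
        rng = np.random.default_rng(79)
        Y = rng.uniform(0.2, 0.8, (30, 3))
        Y[:, 1] = 0.5
        res = ewas(mset_from_beta(Y), pd.DataFrame({"x": rng.normal(size=30)}),
                   ModelSpec(exposure="x"))
        assert len(res) == 2 and res.attrs["skipped"] == ["cg1"]

    def test_collinear_covariate_dropped_fit_returned(self):
        rng = np.random.default_rng(80)
        n = 50
        x = rng.normal(size=n)
        data = pd.DataFrame({"x": x, "twin": 2.0 * x})
        Y = rng.uniform(0.3, 0.7, (n, 2))
        res = ewas(mset_from_beta(Y), data, ModelSpec(exposure="x", covariates=["twin"]))
        assert res.attrs["dropped_columns"] == ["twin"]
        assert len(res) == 2 and np.isfinite(res["p"]).all()


class TestInteraction:
    def make(self, delta_m, delta_f, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        sex = rng.choice(["M", "F"], n)
        status = rng.choice(["case", "control"], n)
        eff = np.where(status == "case", np.where(sex == "M", delta_m, delta_f), 0.0)
        y = np.clip(0.5 + eff + rng.normal(0, 0.02, n), 0, 1)
        return mset_from_beta(y[:, None]), pd.DataFrame({"sex": sex, "case_status": status})

    def test_male_only_effect_recovered(self):
        mset, data = self.make(0.03, 0.0)
        spec = ModelSpec(exposure="case_status", interaction="sex")
        res = interaction_ewas(mset, data, spec)
        assert res["estimate"].iloc[0] == pytest.approx(0.03, abs=3 * res["se"].iloc[0])

    def test_homogeneous_effect_no_interaction(self):
        mset, data = self.make(0.03, 0.03)
        res = interaction_ewas(mset, data, ModelSpec(exposure="case_status", interaction="sex"))
        assert abs(res["estimate"].iloc[0]) < 3 * res["se"].iloc[0] + 1e-3

    def test_relabeling_flips_sign(self):
        mset, data = self.make(0.03, 0.0, seed=4)
        spec = ModelSpec(exposure="case_status", interaction="sex")
        a = interaction_ewas(mset, data, spec)
        swapped = data.assign(sex=np.where(data["sex"] == "M", "F", "M"))
        b = interaction_ewas(mset, swapped, spec)
        assert a["estimate"].iloc[0] == pytest.approx(-b["estimate"].iloc[0], abs=1e-10)

    def test_empty_cell_rejected(self):
        mset, data = self.make(0.0, 0.0, n=100)
        data.loc[data["sex"] == "M", "case_status"] = "case"
        with pytest.raises(Exception):
            interaction_ewas(mset, data, ModelSpec(exposure="case_status", interaction="sex"))


class TestGeneticPcs:
    def test_population_structure_on_pc1(self):
        rng = np.random.default_rng(90)
        n, v = 300, 120
        pop = np.repeat([0, 1], n // 2)
        f = np.where(pop[:, None] == 0, 0.2, 0.6)
        dosage = rng.binomial(2, np.broadcast_to(f, (n, v))).astype(float)
        variants = pd.DataFrame(
            {"id": [f"rs{j}" for j in range(v)], "chrom": "1",
             "pos": np.arange(v) + 1, "effect_allele": "A", "other_allele": "G",
             "freq": np.full(v, 0.4)}
        )
        pcs, ev = genetic_pcs(GenotypeSet(dosage=dosage, variants=variants), 5)
        r = np.corrcoef(pcs[:, 0], pop)[0, 1]
        assert abs(r) > 0.9
        assert np.all(np.diff(ev) <= 1e-12)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))


@pytest.fixture(scope="module")
def effect_cohort():
    """A cohort with one injected score-linked CpG, analyzed with the full
    covariate model (PCs, sex, batch, cell composition, smoking,
    gestational age, birth weight)."""
    from natalmeth import CellReference, estimate_cell_composition
    from natalmeth.synthetic_cohort import cell_reference

    cfg = SimConfig(
        n_samples=1264, n_variants=150, n_cpgs=400, seed=101,
        prs_effect_sites=[(7, -0.0014)], noise_sd=0.01,
    )
    bundle = generate_cohort(cfg)
    retained = ld_clump(bundle.sumstats, bundle.geno, ClumpParams())
    profile = compute_prs(bundle.sumstats, bundle.geno, retained, [1.0])
    pcs, _ = genetic_pcs(bundle.geno, 5)
    data = bundle.sheet.copy().reset_index(drop=True)
    for k in range(5):
        data[f"pc{k + 1}"] = pcs[:, k]
    B = cell_reference(cfg)
    ref = CellReference(pd.DataFrame(
        B, index=[f"cell{k}" for k in range(B.shape[0])], columns=bundle.mset.cpg_ids,
    ))
    cells = estimate_cell_composition(bundle.mset, ref).reset_index(drop=True)
    for k in range(B.shape[0]):
        data[f"cell{k}"] = cells[f"cell{k}"].to_numpy()
    covs = (
        [f"pc{k + 1}" for k in range(5)]
        + ["sex", "batch", "maternal_smoking", "gestational_age", "birth_weight"]
        + [f"cell{k}" for k in range(B.shape[0])]
    )
    return bundle, profile, data, covs


class TestPrsScans:

    def test_injected_effect_within_ci(self, effect_cohort):
        bundle, profile, data, covs = effect_cohort
        res = prs_ewas(bundle.mset, profile, 1.0, data, covs)
        row = res[res["cpg"] == "cg0000007"].iloc[0]
        assert abs(row["estimate"] - (-0.0014)) < 1.96 * row["se"]

    def test_permuted_prs_null_uniform(self, effect_cohort):
        bundle, profile, data, covs = effect_cohort
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(data))
        shuffled = PRSProfile(
            scores=profile.scores.iloc[perm].reset_index(drop=True),
            n_nonmissing=profile.n_nonmissing.iloc[perm].reset_index(drop=True),
            thresholds=profile.thresholds,
            n_selected=profile.n_selected,
        )
        res = prs_ewas(bundle.mset, shuffled, 1.0, data, covs)
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / len(res)) + 0.01

    def test_stratified_scan_homogeneous(self, effect_cohort):
        bundle, profile, data, covs = effect_cohort
        out = stratified_prs_ewas(bundle.mset, profile, 1.0, data, covs)
        case = out["case"].set_index("cpg").loc["cg0000007"]
        ctrl = out["control"].set_index("cpg").loc["cg0000007"]
        joint_se = np.hypot(case["se"], ctrl["se"])
        assert abs(case["estimate"] - ctrl["estimate"]) < 2.5 * joint_se
        comb = out["combined"].set_index("cpg")
        assert (comb["se"] < out["case"].set_index("cpg")["se"] + 1e-15).all()
        assert out["pooled_vs_combined_logp_r"] > 0.9


class TestConditioning:
    def build(self, n_causal_snps, seed=7):
        """A CpG driven entirely by a few variants that also make up the
        score: conditioning on them must absorb the score association."""
        rng = np.random.default_rng(seed)
        n, v = 1500, n_causal_snps + 6
        dosage = rng.binomial(2, 0.4, (n, v)).astype(float)
        variants = pd.DataFrame(
            {"id": [f"rs{j}" for j in range(v)], "chrom": "1",
             "pos": 1000 * (np.arange(v) + 1), "effect_allele": "A",
             "other_allele": "G", "freq": np.full(v, 0.4)}
        )
        geno = GenotypeSet(dosage=dosage, variants=variants)
        w = np.full(n_causal_snps, 0.05)
        score = dosage[:, :n_causal_snps] @ w + 0.02 * dosage[:, n_causal_snps:].sum(axis=1)
        y = np.clip(0.5 + 0.10 * (dosage[:, :n_causal_snps] @ w) + rng.normal(0, 0.01, n), 0, 1)
        profile = PRSProfile(
            scores=pd.DataFrame({1.0: score}),
            n_nonmissing=pd.DataFrame({1.0: np.full(n, v)}),
            thresholds=[1.0], n_selected={1.0: v},
        )
        data = pd.DataFrame({"dummy": np.zeros(n)})
        return mset_from_beta(y[:, None]), profile, data, geno

    def test_single_mediator_kills_association(self):
        mset, profile, data, geno = self.build(1)
        trace = conditional_prs_ewas(mset, profile, 1.0, data, geno, ["rs0"], "cg0")
        assert trace["prs_p"].iloc[0] < 0.05
        assert trace["prs_p"].iloc[-1] > 0.05 and trace["k_added"].iloc[-1] == 1

    def test_four_mediators_needed(self):
        mset, profile, data, geno = self.build(4)
        snps = ["rs0", "rs1", "rs2", "rs3"]
        trace = conditional_prs_ewas(mset, profile, 1.0, data, geno, snps, "cg0")
        crossed = trace[trace["prs_p"] > 0.05]
        assert not crossed.empty and crossed["k_added"].iloc[0] >= 4

    def test_irrelevant_snps_leave_p(self):
        mset, profile, data, geno = self.build(1, seed=8)
        # condition on variants unrelated to the CpG (the tail block)
        trace = conditional_prs_ewas(
            mset, profile, 1.0, data, geno, ["rs4", "rs5"], "cg0", stop_p=1.1
        )
        logp = -np.log10(trace["prs_p"].to_numpy())
        assert abs(logp[0] - logp[-1]) < 0.25 * max(logp[0], 1.0)


class TestPowerAndGlobalMean:
    def test_null_power_equals_alpha(self):
        for alpha in (0.05, 1e-3):
            assert power_two_sample(0.0, 1.0, 100, 100, alpha) == pytest.approx(alpha, rel=1e-9)

    def test_hand_evaluated_shift(self):
        # delta/SE = 6 at alpha 1e-7: power = Phi(6 - 5.3267) ~ 0.7496
        se_unit = np.sqrt(1 / 50 + 1 / 50)
        power = power_two_sample(6.0 * se_unit, 1.0, 50, 50, 1e-7)
        assert power == pytest.approx(0.7496, abs=0.001)

    def test_monotone_in_n(self):
        powers = [power_two_sample(0.3, 1.2, n, n, 1e-7) for n in (200, 400, 800, 1600)]
        assert all(np.diff(powers) > 0)

    def test_global_mean_null_and_planted_shift(self):
        rng = np.random.default_rng(99)
        n = 1200
        status = np.array(["case", "control"] * (n // 2))
        base = rng.uniform(0.4, 0.6, (n, 300))
        sheet = pd.DataFrame({"case_status": status})
        null = global_mean_test(mset_from_beta(base), sheet)
        assert null["p"] > 1e-4
        shifted = base + np.where(status == "case", 0.01, 0.0)[:, None]
        res = global_mean_test(mset_from_beta(np.clip(shifted, 0, 1)), sheet)
        assert res["p"] < 1e-6 and res["difference"] == pytest.approx(1.0, abs=0.2)

    def test_constant_betas_give_fifty_percent_means(self):
        sheet = pd.DataFrame({"case_status": ["case", "case", "control", "control"]})
        res = global_mean_test(mset_from_beta(np.full((4, 10), 0.5)), sheet)
        assert res["case_mean"] == pytest.approx(50.0)
        assert res["difference"] == pytest.approx(0.0)
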