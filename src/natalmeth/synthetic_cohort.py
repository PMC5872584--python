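"""Synthetic neonatal case-control cohort generator.

Produces genotype, methylome, GWAS summary-statistic and sample-sheet
bundles with the statistical structure the downstream analysis stages
assume: LD-blocked diallelic genotypes (latent Gaussian AR(1) haplotypes),
beta-valued methylomes built as convex mixtures of cell-type reference
profiles with additive mQTL, polygenic-score, smoking, batch and
gestational-age effects, detection p-values and control-metric columns for
the QC stages, and 1:1 case-control matching on sex and birth month/year.

Everything is a pure function of :class:`SimConfig` (including its seed),
so identical configurations yield bitwise-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ConfigurationError,
    GenotypeSet,
    MethylSet,
    SUMSTATS_COLUMNS,
)

# offsets added to the config seed so each generation stage draws from an
# independent, reproducible stream
_SEED_GENO = 1
_SEED_SHEET = 2
_SEED_SUMSTATS = 3
_SEED_METH = 4
_SEED_LIABILITY = 5
_SEED_PLANT = 6


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the structure of a neonatal blood-spot 450K study:
    ~1.3k samples in matched case-control pairs, maternal-smoking rates of
    29.0% (cases) vs 21.2% (controls), gestational age ~N(39.6, 1.77) weeks
    and birth weight ~N(3525, 560) g.
    """

    n_samples: int = 1264
    n_variants: int = 300
    n_cpgs: int = 2000
    ld_rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cell_types: int = 6
    mqtl_effects: list[tuple[int, int, float]] = field(default_factory=list)
    prs_effect_sites: list[tuple[int, float]] = field(default_factory=list)
    smoking_effect_sites: list[tuple[int, float]] = field(default_factory=list)
    noise_sd: float = 0.02
    seed: int = 0

    # genomic layout
    chrom: str = "1"
    start_pos: int = 1_000_000
    variant_spacing: int = 2_000

    # genotype nuisance structure
    missing_rate: float = 0.01

    # GWAS architecture behind the liability / polygenic score
    n_causal: int = 20
    causal_sd: float = 0.05
    n_gwas: int = 45_162
    liability_noise: float = 1.0
    prs_injection_p_t: float = 1.0

    # sample-sheet structure
    case_smoking_rate: float = 0.290
    control_smoking_rate: float = 0.212
    ga_match_tol: float = 1.0   # weeks; within-pair gestational-age matching window
    batch_size: int = 96

    # methylome nuisance structure
    batch_sd: float = 0.003
    ga_effect_sd: float = 0.0005
    det_fail_frac: float = 0.0005
    with_intensities: bool = True
    intensity_scale: float = 12_000.0
    beta_offset: float = 100.0

    # sex-chromosome probes appended after the autosomal CpGs
    n_x_cpgs: int = 40
    n_y_cpgs: int = 20

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for v, c, _ in self.mqtl_effects:
            if not (0 <= v < self.n_variants and 0 <= c < self.n_cpgs):
                raise ConfigurationError(f"mqtl effect index ({v}, {c}) out of range")
        for c, _ in list(self.prs_effect_sites) + list(self.smoking_effect_sites):
            if not (0 <= c < self.n_cpgs):
                raise ConfigurationError(f"effect CpG index {c} out of range")


class CohortBundle(NamedTuple):
    """Full synthetic bundle; the first four fields are the public dataset."""

    geno: GenotypeSet
    mset: MethylSet
    sheet: pd.DataFrame
    sumstats: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(config: SimConfig) -> GenotypeSet:
    """Simulate LD-blocked diallelic dosages.

    Each haplotype carries a latent standard-Gaussian AR(1) process with
    lag-one correlation ``ld_rho`` along the variant lattice; the allele is
    the indicator that the latent value falls below the allele-frequency
    quantile, and the dosage is the sum of the two haplotypes. Missing
    calls are injected completely at random at ``missing_rate``.
    """
    config.validate()
    if config.n_samples < 2 or config.n_variants < 1:
        raise ConfigurationError("need n_samples >= 2 and n_variants >= 1")
    rng = np.random.default_rng(config.seed + _SEED_GENO)
    n, v = config.n_samples, config.n_variants
    freq = rng.uniform(*config.maf_range, size=v)
    tau = stats.norm.ppf(freq)

    # two latent haplotypes per sample, AR(1) along variants
    rho = config.ld_rho
    eps = rng.standard_normal((2 * n, v))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, v):
        z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
    alleles = (z < tau).astype(float)
    dosage = alleles[:n] + alleles[n:]

    if config.missing_rate > 0:
        miss = rng.random((n, v)) < config.missing_rate
        dosage[miss] = np.nan

    pos = config.start_pos + config.variant_spacing * np.arange(v)
    variants = pd.DataFrame(
        {
            "id": [f"rs{j:06d}" for j in range(v)],
            "chrom": config.chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "freq": freq,
        }
    )
    return GenotypeSet(dosage=dosage, variants=variants)


# ---------------------------------------------------------------------------
# sample sheet with 1:1 matching
# ---------------------------------------------------------------------------

_BIRTH_YEARS = np.arange(1998, 2003)
_BIRTH_YEAR_P = np.array([0.318, 0.283, 0.070, 0.137, 0.192])
_URBANICITY_P = np.array([0.18, 0.14, 0.085, 0.28, 0.315])


def generate_sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Draw matched case-control pairs sharing sex, birth month and year.

    Case status within each pair is provisional (first member = case) until
    :func:`generate_cohort` reassigns it from the genetic liability; the
    pair structure itself never changes.
    """
    config.validate()
    if config.n_samples % 2 != 0:
        raise ConfigurationError("n_samples must be even (1:1 matched pairs)")
    rng = np.random.default_rng(config.seed + _SEED_SHEET)
    n_pairs = config.n_samples // 2

    sex = rng.choice(["M", "F"], size=n_pairs)
    month = rng.integers(1, 13, size=n_pairs)
    year = rng.choice(_BIRTH_YEARS, size=n_pairs, p=_BIRTH_YEAR_P / _BIRTH_YEAR_P.sum())
    urban = rng.choice(np.arange(1, 6), size=n_pairs, p=_URBANICITY_P / _URBANICITY_P.sum())
    ga_case = rng.normal(39.6, 1.77, size=n_pairs)
    ga_ctrl = ga_case + rng.uniform(-config.ga_match_tol, config.ga_match_tol, size=n_pairs)

    rows = []
    for p in range(n_pairs):
        for status, ga in (("case", ga_case[p]), ("control", ga_ctrl[p])):
            rows.append(
                {
                    "sample_id": f"S{len(rows):05d}",
                    "case_status": status,
                    "pair_id": p,
                    "sex": sex[p],
                    "birth_month": int(month[p]),
                    "birth_year": int(year[p]),
                    "gestational_age": float(np.clip(ga, 30.0, 44.0)),
                    "urbanicity": int(urban[p]),
                    "maternal_smoking": "no",
                    "birth_weight": float(rng.normal(3525.0, 560.0)),
                    "days_to_sampling": float(np.clip(rng.normal(6.08, 3.24), 1.0, 30.0)),
                    "batch": f"plate{len(rows) // config.batch_size:02d}",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def generate_sumstats(
    config: SimConfig,
    true_beta: np.ndarray,
    n_gwas: int,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Noisy per-variant GWAS estimates around the true effects.

    SE is analytic for a standardized quantitative trait,
    ``1 / sqrt(2 f (1-f) n_gwas)``, so doubling the GWAS sample divides it
    by sqrt(2); p-values come from the two-sided z statistic.
    """
    config.validate()
    if n_gwas <= 0:
        raise ConfigurationError("n_gwas must be positive")
    true_beta = np.asarray(true_beta, float)
    rng = np.random.default_rng(config.seed + _SEED_SUMSTATS)
    if variants is None:
        # regenerate the frequency lattice the genotype generator would draw
        fr = np.random.default_rng(config.seed + _SEED_GENO).uniform(
            *config.maf_range, size=len(true_beta)
        )
        variants = pd.DataFrame(
            {
                "id": [f"rs{j:06d}" for j in range(len(true_beta))],
                "chrom": config.chrom,
                "pos": config.start_pos + config.variant_spacing * np.arange(len(true_beta)),
                "effect_allele": "A",
                "other_allele": "G",
                "freq": fr,
            }
        )
    freq = variants["freq"].to_numpy(float)
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * n_gwas)
    beta_hat = true_beta + se * rng.standard_normal(len(true_beta))
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "SNP": variants["id"].to_numpy(),
            "CHR": variants["chrom"].to_numpy(),
            "BP": variants["pos"].to_numpy(),
            "A1": variants["effect_allele"].to_numpy(),
            "A2": variants["other_allele"].to_numpy(),
            "BETA": beta_hat,
            "SE": se,
            "P": np.clip(p, 1e-300, 1.0),
            "FRQ": freq,
            "N": n_gwas,
        }
    )[SUMSTATS_COLUMNS]


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def cell_reference(config: SimConfig) -> np.ndarray:
    """Cell-type reference profile matrix B (cell type x CpG), Beta(2,2)-drawn
    once per seed and held fixed across all methylome draws for that seed."""
    rng = np.random.default_rng(config.seed + _SEED_METH)
    n_total = config.n_cpgs + config.n_x_cpgs + config.n_y_cpgs
    return rng.beta(2.0, 2.0, size=(config.n_cell_types, n_total))


def _cell_alpha(k: int) -> np.ndarray:
    """Dirichlet concentration for cell fractions; blood-like when k = 6."""
    if k == 6:
        return 60.0 * np.array([0.55, 0.20, 0.09, 0.07, 0.05, 0.04])
    return np.full(k, 5.0)


def _cpg_manifest(config: SimConfig) -> pd.DataFrame:
    span = max(config.n_variants * config.variant_spacing, config.n_cpgs)
    raw = config.start_pos + np.floor(
        (np.arange(config.n_cpgs) + 0.5) * span / config.n_cpgs
    ).astype(int)
    # force strict monotonicity if rounding collides
    auto_pos = raw.copy()
    for j in range(1, len(auto_pos)):
        if auto_pos[j] <= auto_pos[j - 1]:
            auto_pos[j] = auto_pos[j - 1] + 1
    rows = {
        "id": [f"cg{j:07d}" for j in range(config.n_cpgs)],
        "chrom": [config.chrom] * config.n_cpgs,
        "pos": list(auto_pos),
    }
    for chrom, count in (("X", config.n_x_cpgs), ("Y", config.n_y_cpgs)):
        rows["id"] += [f"cg{chrom}{j:05d}" for j in range(count)]
        rows["chrom"] += [chrom] * count
        rows["pos"] += list(1_000 + 1_000 * np.arange(count))
    n_total = len(rows["id"])
    man = pd.DataFrame(rows)
    # alternate probe designs deterministically: even columns type II, odd I
    man["probe_type"] = np.where(np.arange(n_total) % 2 == 0, "II", "I")
    man["gene"] = [f"GENE{j // 8}" for j in range(n_total)]
    return man


def generate_methylome(
    config: SimConfig,
    geno: GenotypeSet,
    sheet: pd.DataFrame,
    prs: np.ndarray,
) -> MethylSet:
    """Build betas as cell-mixture baselines plus injected effects.

    beta = clip(omega @ B + mQTL + PRS + smoking + batch + GA trend + noise, 0, 1)
    with per-sample cell fractions omega drawn from a Dirichlet and the
    reference profiles B fixed per seed. When intensities are requested the
    authoritative beta is recomputed as M / (M + U + offset).
    """
    config.validate()
    n = config.n_samples
    if geno.n_samples != n or len(sheet) != n or len(prs) != n:
        raise ConfigurationError("genotypes, sheet and prs must all have n_samples rows")
    rng = np.random.default_rng(config.seed + _SEED_METH)
    B = rng.beta(2.0, 2.0, size=(config.n_cell_types, config.n_cpgs + config.n_x_cpgs + config.n_y_cpgs))
    n_total = B.shape[1]
    omega = rng.dirichlet(_cell_alpha(config.n_cell_types), size=n)
    beta = omega @ B

    dos = geno.imputed_dosage()
    for v, c, eff in config.mqtl_effects:
        beta[:, c] += eff * dos[:, v]
    prs = np.asarray(prs, float)
    prs_c = prs - prs.mean()
    for c, eff in config.prs_effect_sites:
        beta[:, c] += eff * prs_c
    smoking = (sheet["maternal_smoking"].to_numpy() == "yes").astype(float)
    for c, eff in config.smoking_effect_sites:
        beta[:, c] += eff * smoking

    # batch and gestational-age nuisance structure on every CpG
    batches, batch_idx = np.unique(sheet["batch"].to_numpy(), return_inverse=True)
    batch_fx = rng.normal(0.0, config.batch_sd, size=(len(batches), n_total))
    beta += batch_fx[batch_idx]
    ga = sheet["gestational_age"].to_numpy(float)
    ga_slope = rng.normal(0.0, config.ga_effect_sd, size=n_total)
    beta += np.outer(ga - ga.mean(), ga_slope)

    # sex-chromosome probes: bimodal by true sex (X: females high, Y: males high)
    male = (sheet["sex"].to_numpy() == "M").astype(float)
    x_cols = slice(config.n_cpgs, config.n_cpgs + config.n_x_cpgs)
    y_cols = slice(config.n_cpgs + config.n_x_cpgs, n_total)
    beta[:, x_cols] = 0.65 - 0.40 * male[:, None] + rng.normal(0, 0.03, (n, config.n_x_cpgs))
    beta[:, y_cols] = 0.08 + 0.47 * male[:, None] + rng.normal(0, 0.03, (n, config.n_y_cpgs))

    if config.noise_sd > 0:
        beta += rng.normal(0.0, config.noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)

    meth = unmeth = None
    if config.with_intensities:
        total = config.intensity_scale * rng.lognormal(0.0, 0.15, size=(n, 1)) * rng.uniform(
            0.8, 1.2, size=beta.shape
        )
        meth = beta * (total + config.beta_offset)
        unmeth = np.clip(total - meth, 0.0, None)
        beta = meth / (meth + unmeth + config.beta_offset)

    detection_p = rng.uniform(1e-4, 0.04, size=beta.shape)
    if config.det_fail_frac > 0:
        fail = rng.random(beta.shape) < config.det_fail_frac
        detection_p[fail] = rng.uniform(0.051, 1.0, size=int(fail.sum()))

    control_scores = np.clip(rng.normal(95.0, 2.5, size=(n, 10)), 0.0, 100.0)

    # the 65 genotyping probes mirror the first (up to) 65 genotyped variants
    n_snp = min(65, geno.n_variants)
    snp_probe = np.clip(dos[:, :n_snp] / 2.0 + rng.normal(0, 0.02, (n, n_snp)), 0.0, 1.0)
    if n_snp < 65:
        pad_f = rng.uniform(0.1, 0.9, size=65 - n_snp)
        pad_g = rng.binomial(2, pad_f, size=(n, 65 - n_snp)).astype(float)
        snp_probe = np.hstack(
            [snp_probe, np.clip(pad_g / 2.0 + rng.normal(0, 0.02, pad_g.shape), 0.0, 1.0)]
        )

    return MethylSet(
        beta=beta,
        manifest=_cpg_manifest(config),
        sample_ids=sheet["sample_id"].tolist(),
        meth=meth,
        unmeth=unmeth,
        detection_p=detection_p,
        control_scores=control_scores,
        snp_probe_beta=snp_probe,
    )


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def snp_probe_map(geno: GenotypeSet) -> list[tuple[int, str]]:
    """(probe index, variant id) pairs linking the genotyping probes to the
    variants they mirror."""
    return [(j, geno.variants["id"].iloc[j]) for j in range(min(65, geno.n_variants))]


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate an internally consistent genotype/methylome/sheet/sumstats
    bundle with 50% cases.

    Case status is assigned within each matched pair to the member with the
    higher genetic liability (causal-variant burden plus logistic noise), so
    cases carry elevated polygenic scores; maternal smoking is then drawn at
    the case and control rates. The per-sample score driving the injected
    PRS-linked methylation effects is computed through the package's own
    clump-and-score pipeline so downstream scans measure exactly the
    injected effect.
    """
    config.validate()
    if config.n_samples % 2 != 0:
        raise ConfigurationError("n_samples must be even (1:1 matched pairs)")
    geno = generate_genotypes(config)
    sheet = generate_sample_sheet(config)

    rng = np.random.default_rng(config.seed + _SEED_LIABILITY)
    causal_idx = rng.choice(config.n_variants, size=min(config.n_causal, config.n_variants), replace=False)
    w = rng.normal(0.0, config.causal_sd, size=len(causal_idx))
    true_beta = np.zeros(config.n_variants)
    true_beta[causal_idx] = w

    dos = geno.imputed_dosage()
    liab = dos[:, causal_idx] @ w
    liab = (liab - liab.mean()) / max(liab.std(), 1e-12)
    liab = liab + config.liability_noise * rng.logistic(size=config.n_samples)

    # within each pair the higher-liability member becomes the case
    status = np.array(["control"] * config.n_samples, dtype=object)
    pair_ids = sheet["pair_id"].to_numpy()
    for p in np.unique(pair_ids):
        members = np.where(pair_ids == p)[0]
        status[members[np.argmax(liab[members])]] = "case"
    sheet = sheet.copy()
    sheet["case_status"] = status
    is_case = status == "case"
    rate = np.where(is_case, config.case_smoking_rate, config.control_smoking_rate)
    sheet["maternal_smoking"] = np.where(
        rng.random(config.n_samples) < rate, "yes", "no"
    )

    sumstats = generate_sumstats(config, true_beta, config.n_gwas, geno.variants)

    # score used for effect injection: the package's own PRS at p_T
    from .prs_builder import ClumpParams, compute_prs, ld_clump

    retained = ld_clump(sumstats, geno, ClumpParams())
    profile = compute_prs(sumstats, geno, retained, [config.prs_injection_p_t])
    prs = profile.scores.iloc[:, 0].to_numpy(float)

    mset = generate_methylome(config, geno, sheet, prs)
    truth = {
        "true_variant_beta": true_beta.tolist(),
        "causal_variants": sorted(int(i) for i in causal_idx),
        "prs": prs.tolist(),
        "mqtl_effects": [list(e) for e in config.mqtl_effects],
        "prs_effect_sites": [list(e) for e in config.prs_effect_sites],
        "smoking_effect_sites": [list(e) for e in config.smoking_effect_sites],
        "snp_probe_map": [[i, v] for i, v in snp_probe_map(geno)],
        "seed": config.seed,
    }
    return CohortBundle(geno, mset, sheet, sumstats, truth)


# ---------------------------------------------------------------------------
# planted QC failures (fixture support for the QC pipeline)
# ---------------------------------------------------------------------------

def plant_qc_failures(
    bundle: CohortBundle,
    *,
    low_intensity: list[int] = (),
    bisulfite: list[int] = (),
    duplicate_pairs: list[tuple[int, int]] = (),
    sex_mismatch: list[int] = (),
    genotype_discordant: list[int] = (),
    detection_p: list[int] = (),
    seed: int = 0,
) -> CohortBundle:
    """Return a copy of the bundle with specific QC failure modes planted.

    Each argument lists sample indices to corrupt: intensities scaled below
    the median-2500 rule, bisulfite control scores dropped below 80, the
    genotyping-probe fingerprint copied between duplicate pairs, reported
    sex flipped, the fingerprint shuffled against the genotypes, or >1% of
    detection p-values pushed above 0.05.
    """
    rng = np.random.default_rng(seed + _SEED_PLANT)
    mset, sheet = bundle.mset, bundle.sheet.copy()
    beta = mset.beta.copy()
    meth = None if mset.meth is None else mset.meth.copy()
    unmeth = None if mset.unmeth is None else mset.unmeth.copy()
    detp = None if mset.detection_p is None else mset.detection_p.copy()
    scores = None if mset.control_scores is None else mset.control_scores.copy()
    snp = None if mset.snp_probe_beta is None else mset.snp_probe_beta.copy()

    if len(low_intensity) and meth is None:
        raise ConfigurationError("cannot plant low-intensity failures without intensities")
    for i in low_intensity:
        shrink = 2000.0 / max(np.median(meth[i]), np.median(unmeth[i]))
        meth[i] *= shrink
        unmeth[i] *= shrink
    for i in bisulfite:
        scores[i] = rng.uniform(60.0, 75.0, size=scores.shape[1])
    for a, b in duplicate_pairs:
        snp[b] = snp[a]
    for i in sex_mismatch:
        sheet.loc[sheet.index[i], "sex"] = "F" if sheet.iloc[i]["sex"] == "M" else "M"
    for i in genotype_discordant:
        snp[i] = rng.permutation(snp[i])
    for i in detection_p:
        n_fail = max(int(np.ceil(0.02 * detp.shape[1])), 2)
        cols = rng.choice(detp.shape[1], size=n_fail, replace=False)
        detp[i, cols] = rng.uniform(0.06, 0.9, size=n_fail)

    new_mset = MethylSet(
        beta=beta,
        manifest=mset.manifest.copy(),
        sample_ids=list(mset.sample_ids),
        meth=meth,
        unmeth=unmeth,
        detection_p=detp,
        control_scores=scores,
        snp_probe_beta=snp,
    )
    return CohortBundle(bundle.geno, new_mset, sheet, bundle.sumstats, dict(bundle.truth))
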