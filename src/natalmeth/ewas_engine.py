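"""Per-CpG linear-model association scans.

One vectorized ordinary-least-squares engine drives the case-control
scan, the sex-interaction scan, the polygenic-score scan, stratified and
SNP-conditioned variants, genetic principal components, a global-mean
test and an analytic power calculator. Betas are analyzed untransformed
(effects are reported in methylation-proportion units), categorical
covariates are expanded to indicator contrasts, and collinear design
columns are dropped (never the exposure) and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeSet, InputError, MethylSet, NatalmethError, assoc_frame

logger = logging.getLogger(__name__)

#: reporting thresholds: experiment-wide and "discovery"
EXPERIMENT_WIDE_P = 1e-7
DISCOVERY_P = 5e-5

#: sample-sheet columns treated as categorical by default
DEFAULT_CATEGORICAL = {
    "sex",
    "batch",
    "urbanicity",
    "birth_month",
    "birth_year",
    "case_status",
    "maternal_smoking",
}


@dataclass
class ModelSpec:
    """Design specification for a per-CpG linear model.

    ``exposure`` and ``covariates`` name columns of the sample-level data
    frame handed to :func:`ewas`; ``interaction`` adds an
    exposure x covariate product term and makes it the reported
    coefficient.
    """

    exposure: str
    covariates: list[str] = field(default_factory=list)
    interaction: str | None = None
    categorical: set[str] = field(default_factory=lambda: set(DEFAULT_CATEGORICAL))


def _encode(data: pd.DataFrame, name: str, categorical: set[str]) -> pd.DataFrame:
    """Encode one covariate as numeric column(s) (indicator contrasts for
    categorical variables, dropping the first level)."""
    col = data[name]
    # fixed codings so estimate signs read case-vs-control, male-vs-female,
    # exposed-vs-unexposed
    binary_codes = {"case_status": "case", "sex": "M", "maternal_smoking": "yes"}
    if name in binary_codes and set(col.unique()) <= {"case", "control", "M", "F", "yes", "no"}:
        return (col == binary_codes[name]).astype(float).to_frame(name)
    if name in categorical or col.dtype == object or str(col.dtype) == "category":
        dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
        return dummies.astype(float)
    return col.astype(float).to_frame(name)


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], int, list[str]]:
    """Assemble the design matrix.

    Returns (X, column names, index of the reported coefficient, dropped
    collinear columns). Column order: intercept, exposure, interaction
    product (if any), covariates. Collinear columns are dropped greedily
    in that order, so the exposure always survives.
    """
    blocks = [pd.DataFrame({"intercept": np.ones(len(data))})]
    exposure = _encode(data, spec.exposure, spec.categorical)
    if exposure.shape[1] != 1:
        raise InputError(
            f"exposure {spec.exposure!r} must encode to a single column; "
            f"got {list(exposure.columns)}"
        )
    blocks.append(exposure)
    report_name = exposure.columns[0]
    if spec.interaction is not None:
        inter = _encode(data, spec.interaction, spec.categorical)
        if inter.shape[1] != 1:
            raise InputError("interaction covariate must encode to a single column")
        prod = exposure.iloc[:, 0] * inter.iloc[:, 0]
        report_name = f"{exposure.columns[0]}:{inter.columns[0]}"
        blocks.append(prod.to_frame(report_name))
        blocks.append(inter)
    for name in spec.covariates:
        if spec.interaction is not None and name == spec.interaction:
            continue
        blocks.append(_encode(data, name, spec.categorical))
    full = pd.concat(blocks, axis=1)

    # greedy collinearity pruning, left to right
    X = full.to_numpy(float)
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(full.columns[j])
    if dropped:
        logger.warning("dropped collinear design columns: %s", dropped)
    names = [full.columns[j] for j in keep]
    if report_name not in names:
        raise InputError(f"reported coefficient {report_name!r} was dropped as collinear")
    return X[:, keep], names, names.index(report_name), dropped


def _ols_scan(X: np.ndarray, Y: np.ndarray, coef_idx: int):
    """Vectorized OLS of every column of Y on X; returns the coefficient of
    interest with its SE, t and two-sided p per column."""
    n, p = X.shape
    if n < p + 2:
        raise InputError(f"need at least {p + 2} complete cases, have {n}")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coefs = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coefs
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    est = coefs[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, np.inf * np.sign(est))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return est, se, t, np.clip(pvals, np.finfo(float).tiny, 1.0), dof


def ewas(mset: MethylSet, data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-CpG OLS scan of methylation on the exposure plus covariates.

    ``data`` has one row per sample, aligned with ``mset``. Rows with any
    missing design value are dropped (complete-case analysis) and the
    per-CpG n reported. Zero-variance CpGs are skipped and listed in
    ``result.attrs['skipped']``; dropped collinear columns in
    ``result.attrs['dropped_columns']``.
    """
    if len(data) != mset.n_samples:
        raise InputError("data must have one row per methylation sample")
    X, names, coef_idx, dropped = build_design(data.reset_index(drop=True), spec)
    rows = np.isfinite(X).all(axis=1)
    X = X[rows]
    Y = mset.beta[rows]
    usable = np.isfinite(Y).all(axis=0) & (Y.std(axis=0) > 0)
    skipped = [c for c, u in zip(mset.cpg_ids, usable) if not u]
    if skipped:
        logger.warning("skipping %d zero-variance or incomplete CpGs", len(skipped))
    est, se, t, p, dof = _ols_scan(X, Y[:, usable], coef_idx)
    man = mset.manifest.loc[usable]
    out = assoc_frame(
        cpg=man["id"].to_numpy(),
        estimate=est,
        se=se,
        t=t,
        p=p,
        n=np.full(usable.sum(), X.shape[0]),
        chrom=man["chrom"].to_numpy(),
        pos=man["pos"].to_numpy(),
    )
    out.attrs["skipped"] = skipped
    out.attrs["dropped_columns"] = dropped
    out.attrs["dof"] = dof
    return out


def interaction_ewas(mset: MethylSet, data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Scan reporting the exposure x interaction product coefficient.

    Requires every exposure x interaction cell to be populated.
    """
    if spec.interaction is None:
        raise InputError("spec.interaction must be set")
    cells = data.groupby([spec.exposure, spec.interaction], observed=False).size()
    exp_levels = data[spec.exposure].nunique()
    int_levels = data[spec.interaction].nunique()
    if (cells == 0).any() or len(cells) < exp_levels * int_levels:
        raise NatalmethError("every exposure x interaction cell must be nonempty")
    return ewas(mset, data, spec)


def genetic_pcs(geno: GenotypeSet, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the column-standardized dosage matrix.

    Missing dosages are replaced with the column mean; monomorphic
    variants are dropped with a warning. Returns (n x k scores, fraction
    of variance explained per component, non-increasing).
    """
    if k >= min(geno.n_samples, geno.n_variants):
        raise InputError("k must be below min(n_samples, n_variants)")
    d = geno.dosage.copy()
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    sd = d.std(axis=0)
    mono = sd == 0
    if mono.any():
        logger.warning("dropping %d monomorphic variants from PCA", int(mono.sum()))
        d = d[:, ~mono]
        mean, sd = mean[~mono], sd[~mono]
    z = (d - d.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    explained = (s**2) / (s**2).sum()
    return scores, explained[:k]


def prs_ewas(
    mset: MethylSet,
    profile,
    p_t: float,
    data: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Polygenic-score EWAS at threshold ``p_t``.

    The exposure is the score at ``p_t`` from a
    :class:`~natalmeth.prs_builder.PRSProfile`; the count of non-missing
    genotypes at that threshold is always included as a covariate, plus
    whatever columns of ``data`` are named in ``covariates``.
    """
    if p_t not in profile.scores.columns:
        raise InputError(f"profile holds no score at p_T={p_t}")
    data = data.reset_index(drop=True).copy()
    data["prs"] = profile.scores[p_t].to_numpy(float)
    data["prs_n_nonmissing"] = profile.n_nonmissing[p_t].to_numpy(float)
    covs = ["prs_n_nonmissing"] + list(covariates or [])
    return ewas(mset, data, ModelSpec(exposure="prs", covariates=covs))


def stratified_prs_ewas(
    mset: MethylSet,
    profile,
    p_t: float,
    data: pd.DataFrame,
    covariates: list[str] | None = None,
) -> dict:
    """Polygenic-score EWAS run separately in cases and controls.

    Returns per-stratum scans, their inverse-variance fixed-effect
    combination, and the correlation of -log10 p between the pooled scan
    and the combined stratified scan.
    """
    data = data.reset_index(drop=True)
    is_case = data["case_status"].to_numpy() == "case"
    results = {}
    for label, mask in (("case", is_case), ("control", ~is_case)):
        sub = mset.subset(sample_mask=mask)
        subprof = type(profile)(
            scores=profile.scores.loc[mask],
            n_nonmissing=profile.n_nonmissing.loc[mask],
            thresholds=profile.thresholds,
            n_selected=profile.n_selected,
        )
        results[label] = prs_ewas(sub, subprof, p_t, data.loc[mask], covariates)
    merged = results["case"].merge(
        results["control"], on="cpg", suffixes=("_case", "_control")
    )
    w1 = 1.0 / merged["se_case"] ** 2
    w2 = 1.0 / merged["se_control"] ** 2
    est = (w1 * merged["estimate_case"] + w2 * merged["estimate_control"]) / (w1 + w2)
    se = np.sqrt(1.0 / (w1 + w2))
    z = est / se
    combined = assoc_frame(
        cpg=merged["cpg"].to_numpy(),
        estimate=est.to_numpy(),
        se=se.to_numpy(),
        t=z.to_numpy(),
        p=np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
        n=(merged["n_case"] + merged["n_control"]).to_numpy(),
        chrom=merged["chr_case"].to_numpy(),
        pos=merged["pos_case"].to_numpy(),
    )
    pooled = prs_ewas(mset, profile, p_t, data, covariates)
    both = pooled.merge(combined, on="cpg", suffixes=("_pooled", "_combined"))
    r = float(
        np.corrcoef(-np.log10(both["p_pooled"]), -np.log10(both["p_combined"]))[0, 1]
    )
    return {
        "case": results["case"],
        "control": results["control"],
        "combined": combined,
        "pooled_vs_combined_logp_r": r,
    }


def conditional_prs_ewas(
    mset: MethylSet,
    profile,
    p_t: float,
    data: pd.DataFrame,
    geno: GenotypeSet,
    snps: list[str],
    cpg: str,
    covariates: list[str] | None = None,
    stop_p: float = 0.05,
) -> pd.DataFrame:
    """Iterative SNP conditioning of a score-associated CpG.

    SNP dosages from ``snps`` (already ordered, e.g. by ascending GWAS p)
    are added one at a time as covariates to the score model for ``cpg``;
    after each addition the score term's p-value is recorded, together
    with whether the newly added SNP is itself associated with the CpG
    (its own coefficient p < 0.05). Stops once the score term's p exceeds
    ``stop_p`` or the list is exhausted. Degenerate additions (SNP
    collinear with the existing design) are skipped with a warning.
    """
    cpg_ids = mset.cpg_ids
    if cpg not in cpg_ids:
        raise InputError(f"CpG {cpg!r} not present")
    cmask = np.array([c == cpg for c in cpg_ids])
    sub = mset.subset(cpg_mask=cmask)
    vid_to_col = {v: j for j, v in enumerate(geno.variants["id"])}
    data = data.reset_index(drop=True).copy()
    data["prs"] = profile.scores[p_t].to_numpy(float)
    data["prs_n_nonmissing"] = profile.n_nonmissing[p_t].to_numpy(float)
    base_covs = ["prs_n_nonmissing"] + list(covariates or [])
    dos = geno.imputed_dosage()

    rows = []
    added: list[str] = []
    k = 0
    res = ewas(sub, data, ModelSpec(exposure="prs", covariates=base_covs))
    rows.append({"k_added": 0, "snp": "", "prs_p": float(res["p"].iloc[0]),
                 "prs_estimate": float(res["estimate"].iloc[0]), "snp_p": np.nan,
                 "snp_associated": False})
    for snp in snps:
        if rows[-1]["prs_p"] > stop_p:
            break
        if snp not in vid_to_col:
            logger.warning("conditioning SNP %s not genotyped; skipped", snp)
            continue
        col = f"snp_{snp}"
        data[col] = dos[:, vid_to_col[snp]]
        trial_covs = base_covs + [f"snp_{s}" for s in added] + [col]
        res = ewas(sub, data, ModelSpec(exposure="prs", covariates=trial_covs))
        if col in res.attrs["dropped_columns"]:
            logger.warning("conditioning SNP %s collinear with design; skipped", snp)
            data = data.drop(columns=col)
            continue
        added.append(snp)
        k += 1
        snp_res = ewas(sub, data, ModelSpec(exposure=col, covariates=[c for c in trial_covs if c != col] + ["prs"]))
        snp_p = float(snp_res["p"].iloc[0])
        rows.append(
            {
                "k_added": k,
                "snp": snp,
                "prs_p": float(res["p"].iloc[0]),
                "prs_estimate": float(res["estimate"].iloc[0]),
                "snp_p": snp_p,
                "snp_associated": snp_p < 0.05,
            }
        )
    return pd.DataFrame(rows)


def power_two_sample(delta: float, sd: float, n1: int, n2: int, alpha: float) -> float:
    """Normal-approximation power of a two-sided two-sample mean test.

    power = Phi(-z_{alpha/2} + delta/SE) + Phi(-z_{alpha/2} - delta/SE)
    with SE = sd * sqrt(1/n1 + 1/n2).
    """
    if sd <= 0 or n1 <= 0 or n2 <= 0 or not (0 < alpha < 1):
        raise InputError("sd, n1, n2 must be positive and alpha in (0, 1)")
    se = sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    z = stats.norm.isf(alpha / 2.0)
    shift = delta / se
    return float(stats.norm.cdf(-z + shift) + stats.norm.cdf(-z - shift))


def global_mean_test(mset: MethylSet, sheet: pd.DataFrame) -> dict:
    """Welch t-test of the per-sample mean methylation (in %) by case status."""
    means = 100.0 * mset.beta.mean(axis=1)
    is_case = sheet["case_status"].to_numpy() == "case"
    a, b = means[is_case], means[~is_case]
    if len(a) < 2 or len(b) < 2:
        raise NatalmethError("both classes need at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "case_mean": float(a.mean()),
        "case_sd": float(a.std(ddof=1)),
        "control_mean": float(b.mean()),
        "control_sd": float(b.std(ddof=1)),
        "difference": float(a.mean() - b.mean()),
        "t": float(t),
        "p": float(p),
    }
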