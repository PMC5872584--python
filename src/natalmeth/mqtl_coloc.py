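"""cis-mQTL mapping and Bayesian colocalization under the five-hypothesis
framework.

The mQTL scan fits, for every (variant, CpG) pair inside a cis window, an
additive linear model of methylation on allele dosage with covariates
(sex and the first five genetic principal components by convention). It
is implemented as a matrix scan — both sides residualized against the
covariates, then correlations converted to t statistics — which is
algebraically identical to per-pair OLS.

Colocalization compares two association scans over one region via
per-variant Wakefield approximate Bayes factors, accumulating evidence
for five hypotheses: no causal variant (H0), a causal variant for one
trait only (H1/H2), two distinct causal variants (H3), or a single shared
causal variant (H4). All hypothesis sums are evaluated in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .containers import GenotypeSet, InputError, MethylSet

logger = logging.getLogger(__name__)

#: reporting threshold for individual mQTL pairs
MQTL_SIGNIFICANCE_P = 1e-13

#: default prior probabilities that a variant is causal for trait 1 only,
#: trait 2 only, or both
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

#: default prior effect standard deviations (sqrt W) by trait type
PRIOR_SD_QUANTITATIVE = 0.2
PRIOR_SD_CASE_CONTROL = 0.15


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def cis_pairs(
    variants: pd.DataFrame,
    manifest: pd.DataFrame,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """All (variant, CpG) pairs on the same chromosome with
    |pos_variant - pos_cpg| <= window_bp (inclusive boundary, 1-based
    positions). Chromosome labels are normalized by stripping any 'chr'
    prefix."""
    v = variants[["id", "chrom", "pos"]].copy()
    v["chrom"] = v["chrom"].map(_norm_chrom)
    c = manifest[["id", "chrom", "pos"]].copy()
    c["chrom"] = c["chrom"].map(_norm_chrom)
    merged = v.merge(c, on="chrom", suffixes=("_variant", "_cpg"))
    merged = merged[(merged["pos_variant"] - merged["pos_cpg"]).abs() <= window_bp]
    return merged.rename(columns={"id_variant": "variant", "id_cpg": "cpg"})[
        ["variant", "cpg", "chrom", "pos_variant", "pos_cpg"]
    ].reset_index(drop=True)


def mqtl_scan(
    mset: MethylSet,
    geno: GenotypeSet,
    pairs: pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive cis-mQTL scan: methylation ~ dosage + covariates.

    Both methylation and dosages are residualized against the covariate
    matrix (an intercept is always included), then per-pair slopes, SEs,
    t and p are recovered from the residual correlations — numerically
    equal to fitting each pair by OLS. Missing dosages are imputed as
    2 x allele frequency; monomorphic variants are skipped and recorded.
    """
    n = mset.n_samples
    if geno.n_samples != n:
        raise InputError("methylation and genotype sample counts differ")
    Z = np.ones((n, 1))
    if covariates is not None:
        C = covariates.to_numpy(float) if hasattr(covariates, "to_numpy") else np.asarray(covariates, float)
        Z = np.hstack([Z, C])
    q = Z.shape[1]
    dof = n - q - 1
    if dof < 2:
        raise InputError("insufficient complete cases for the covariate set")

    # residualize via QR projection
    Q, _ = np.linalg.qr(Z)

    def resid(M):
        return M - Q @ (Q.T @ M)

    vid_to_col = {v: j for j, v in enumerate(geno.variants["id"])}
    cid_to_col = {c: j for j, c in enumerate(mset.manifest["id"])}
    vcols = pairs["variant"].map(vid_to_col)
    ccols = pairs["cpg"].map(cid_to_col)
    if vcols.isna().any() or ccols.isna().any():
        raise InputError("pairs reference unknown variant or CpG ids")

    uniq_v = np.unique(vcols.to_numpy(int))
    uniq_c = np.unique(ccols.to_numpy(int))
    dos = geno.imputed_dosage()[:, uniq_v]
    mono = dos.std(axis=0) == 0
    X = resid(dos)
    Y = resid(mset.beta[:, uniq_c])
    ssx = (X**2).sum(axis=0)
    ssy = (Y**2).sum(axis=0)
    v_index = {v: i for i, v in enumerate(uniq_v)}
    c_index = {c: i for i, c in enumerate(uniq_c)}

    vi = vcols.map(v_index).to_numpy(int)
    ci = ccols.map(c_index).to_numpy(int)
    sxy = np.einsum("ij,ij->j", X[:, vi], Y[:, ci])
    keep = ~mono[vi]
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("skipping %d pairs with monomorphic variants", n_skipped)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / ssx[vi]
        r2 = sxy**2 / (ssx[vi] * ssy[ci])
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        t = np.sign(sxy) * np.sqrt(r2 * dof / (1.0 - r2))
        se = slope / t
        # recover SE directly where t == 0
        se = np.where(t == 0, np.sqrt(ssy[ci] / dof / ssx[vi]), se)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), dof), 1e-300, 1.0)
    out = pairs.copy()
    out["estimate"] = slope
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["n"] = n
    out["significant"] = out["p"] < MQTL_SIGNIFICANCE_P
    out = out[keep].reset_index(drop=True)
    out.attrs["n_skipped_monomorphic"] = n_skipped
    return out


def wakefield_abf(beta: float, varbeta: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for a single-variant association.

    ABF = sqrt(1 - r) * exp(z^2 r / 2), with r = W / (V + W),
    z = beta / sqrt(V), V the variance of the estimate and W the prior
    effect variance (prior_sd squared). Returns the natural log.
    """
    beta = np.asarray(beta, float)
    varbeta = np.asarray(varbeta, float)
    if np.any(varbeta <= 0):
        raise InputError("varbeta must be positive")
    W = prior_sd**2
    r = W / (varbeta + W)
    z2 = beta**2 / varbeta
    out = 0.5 * np.log1p(-r) + z2 * r / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class ColocResult:
    """Posterior probabilities over H0..H4 with per-variant log-ABFs."""

    pp: np.ndarray                 # length-5 vector, sums to 1
    labf1: np.ndarray
    labf2: np.ndarray
    n_variants: int
    priors: tuple[float, float, float] = DEFAULT_PRIORS

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])


def coloc_posteriors(
    beta1,
    varbeta1,
    beta2,
    varbeta2,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_QUANTITATIVE,
) -> ColocResult:
    """Five-hypothesis posteriors from two sets of per-variant estimates.

    Unnormalized weights: H0 = 1; H1 = p1 sum_j BF1_j; H2 = p2 sum_j
    BF2_j; H3 = p1 p2 sum_{j != k} BF1_j BF2_k; H4 = p12 sum_j BF1_j
    BF2_j; all sums evaluated in log space so large Bayes factors cannot
    overflow.
    """
    p1, p2, p12 = priors
    if not (0 < p1 < 1 and 0 < p2 < 1 and 0 < p12 < 1):
        raise InputError("priors must lie in (0, 1)")
    if p12 > min(p1, p2):
        raise InputError("p12 must not exceed min(p1, p2)")
    l1 = np.atleast_1d(wakefield_abf(np.asarray(beta1, float), np.asarray(varbeta1, float), prior_sd1))
    l2 = np.atleast_1d(wakefield_abf(np.asarray(beta2, float), np.asarray(varbeta2, float), prior_sd2))
    return coloc_posteriors_from_labf(l1, l2, priors)


def coloc_posteriors_from_labf(
    labf1,
    labf2,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> ColocResult:
    """Five-hypothesis posteriors from precomputed per-variant log-ABFs."""
    p1, p2, p12 = priors
    if not (0 < p1 < 1 and 0 < p2 < 1 and 0 < p12 < 1):
        raise InputError("priors must lie in (0, 1)")
    if p12 > min(p1, p2):
        raise InputError("p12 must not exceed min(p1, p2)")
    l1 = np.atleast_1d(np.asarray(labf1, float))
    l2 = np.atleast_1d(np.asarray(labf2, float))
    if l1.shape != l2.shape or l1.size == 0:
        raise InputError("the two traits must share a nonempty variant set")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # log( sum_{j != k} BF1_j BF2_k ) = log( exp(s1 + s2) - exp(s12) )
    if s1 + s2 > s12:
        cross = s1 + s2 + np.log1p(-np.exp(s12 - s1 - s2))
    else:
        cross = -np.inf  # single variant: H3 impossible
    logw = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + cross,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))
    pp = pp / pp.sum()
    return ColocResult(pp=pp, labf1=l1, labf2=l2, n_variants=l1.size, priors=priors)


def region_coloc(
    sumstats: pd.DataFrame,
    mqtl: pd.DataFrame,
    geno_variants: pd.DataFrame,
    index_variants: list[str],
    manifest: pd.DataFrame,
    region_bp: int = 250_000,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd_gwas: float = PRIOR_SD_CASE_CONTROL,
    prior_sd_mqtl: float = PRIOR_SD_QUANTITATIVE,
) -> pd.DataFrame:
    """Colocalize GWAS and mQTL signals around index variants.

    For every CpG within ``region_bp`` (inclusive) of an index variant,
    the shared variant set (GWAS x that CpG's mQTL results) is fed to
    :func:`coloc_posteriors`; GWAS effects are harmonized to the
    genotype effect allele (flipping the sign when the alleles are
    swapped; unresolvable variants dropped and counted). Reports the
    posterior vector plus the support criteria PP3 + PP4 > 0.99 and
    PP4 / PP3 > 1.
    """
    ss = sumstats.set_index("SNP")
    missing_index = [v for v in index_variants if v not in ss.index]
    if missing_index:
        raise InputError(f"index variants absent from summary statistics: {missing_index}")
    gvar = geno_variants.set_index("id")
    man = manifest.copy()
    man["chrom_n"] = man["chrom"].map(_norm_chrom)

    rows = []
    for iv in index_variants:
        iv_chrom = _norm_chrom(ss.loc[iv, "CHR"])
        iv_pos = int(ss.loc[iv, "BP"])
        near = man[
            (man["chrom_n"] == iv_chrom) & ((man["pos"] - iv_pos).abs() <= region_bp)
        ]
        for cpg in near["id"]:
            sub = mqtl[mqtl["cpg"] == cpg]
            shared = [v for v in sub["variant"] if v in ss.index]
            if not shared:
                logger.warning("CpG %s: empty shared variant set; skipped", cpg)
                continue
            sub = sub.set_index("variant").loc[shared]
            g_beta, g_var, keep = [], [], []
            n_dropped = 0
            for v in shared:
                a1, a2 = ss.loc[v, "A1"], ss.loc[v, "A2"]
                ea = gvar.loc[v, "effect_allele"] if v in gvar.index else a1
                oa = gvar.loc[v, "other_allele"] if v in gvar.index else a2
                b = float(ss.loc[v, "BETA"])
                if (a1, a2) == (ea, oa):
                    pass
                elif (a1, a2) == (oa, ea):
                    b = -b
                else:
                    n_dropped += 1
                    continue
                g_beta.append(b)
                g_var.append(float(ss.loc[v, "SE"]) ** 2)
                keep.append(v)
            if n_dropped:
                logger.warning("CpG %s: dropped %d unharmonizable variants", cpg, n_dropped)
            if not keep:
                continue
            res = coloc_posteriors(
                np.array(g_beta),
                np.array(g_var),
                sub.loc[keep, "estimate"].to_numpy(float),
                sub.loc[keep, "se"].to_numpy(float) ** 2,
                priors=priors,
                prior_sd1=prior_sd_gwas,
                prior_sd2=prior_sd_mqtl,
            )
            pp = res.pp
            pp3plus4 = float(pp[3] + pp[4])
            ratio = float(pp[4] / pp[3]) if pp[3] > 0 else np.inf
            rows.append(
                {
                    "cpg": cpg,
                    "index_variant": iv,
                    "n_variants": res.n_variants,
                    "pp0": pp[0],
                    "pp1": pp[1],
                    "pp2": pp[2],
                    "pp3": pp[3],
                    "pp4": pp[4],
                    "pp3plus4": pp3plus4,
                    "pp4_over_pp3": ratio,
                    "supported": pp3plus4 > 0.99,
                    "shared_preferred": ratio > 1.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cpg", "index_variant", "n_variants", "pp0", "pp1", "pp2", "pp3",
            "pp4", "pp3plus4", "pp4_over_pp3", "supported", "shared_preferred",
        ],
    )
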