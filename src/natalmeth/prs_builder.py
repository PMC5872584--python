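"""Polygenic risk score construction from GWAS summary statistics.

Variants are greedily LD-clumped (index variants visited in ascending
GWAS p-value; neighbors within the distance window whose in-sample dosage
r-squared exceeds the threshold are removed), then scores are computed at
a ladder of p-value thresholds as weighted sums of effect-allele dosages,
with mean-dosage imputation (2 x allele frequency) for missing calls and
the count of non-missing genotypes carried as a downstream covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeSet, InputError, NatalmethError

logger = logging.getLogger(__name__)

#: the ten score-selection thresholds, from genome-wide significance to 1
DEFAULT_P_THRESHOLDS = [5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0]


@dataclass
class ClumpParams:
    """Greedy LD-clumping settings (index p, secondary p, r2, window)."""

    clump_p1: float = 1.0
    clump_p2: float = 1.0
    clump_r2: float = 0.1
    clump_kb: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.clump_p1 <= 1 and 0 < self.clump_p2 <= 1):
            raise InputError("clump p-value thresholds must lie in (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise InputError("clump_r2 must lie in [0, 1]")
        if self.clump_kb <= 0:
            raise InputError("clump_kb must be positive")


@dataclass
class PRSProfile:
    """Per-sample scores and non-missing genotype counts per threshold."""

    scores: pd.DataFrame        # samples x thresholds
    n_nonmissing: pd.DataFrame  # samples x thresholds
    thresholds: list[float] = field(default_factory=list)
    n_selected: dict[float, int] = field(default_factory=dict)


def _shared_variants(sumstats: pd.DataFrame, geno: GenotypeSet) -> pd.DataFrame:
    """Inner-join summary statistics onto genotyped variants, keeping the
    genotype column index."""
    gvar = geno.variants.reset_index().rename(columns={"index": "_col"})
    merged = sumstats.merge(gvar, left_on="SNP", right_on="id", how="inner")
    if merged.empty:
        raise NatalmethError("no variants shared between summary statistics and genotypes")
    return merged


def ld_clump(
    sumstats: pd.DataFrame,
    geno: GenotypeSet,
    params: ClumpParams | None = None,
) -> list[str]:
    """Greedy LD clumping; returns retained variant ids.

    Variants with p <= clump_p1 are visited in ascending p (ties broken by
    chromosome then position). Each index variant removes all not-yet-
    retained variants with p <= clump_p2 lying within clump_kb kilobases
    on the same chromosome whose in-sample dosage r2 exceeds clump_r2.
    Removed variants never become index variants. The result does not
    depend on the input row order.
    """
    params = params or ClumpParams()
    merged = _shared_variants(sumstats, geno)
    merged = merged.sort_values(
        ["P", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    dos = geno.imputed_dosage()
    cols = merged["_col"].to_numpy()
    x = dos[:, cols]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: r2 = 0 with everything
    xs = x / sd

    p = merged["P"].to_numpy(float)
    chrom = merged["chrom"].astype(str).to_numpy()
    pos = merged["pos"].to_numpy(float)
    window = params.clump_kb * 1000.0

    m = len(merged)
    removed = np.zeros(m, dtype=bool)
    retained_idx: list[int] = []
    n = x.shape[0]
    for i in range(m):
        if removed[i] or p[i] > params.clump_p1:
            continue
        retained_idx.append(i)
        near = (
            (~removed)
            & (p <= params.clump_p2)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        near[retained_idx] = False
        if near.any():
            r = xs[:, near].T @ xs[:, i] / n
            kill = np.where(near)[0][r**2 > params.clump_r2]
            removed[kill] = True
    kept = merged.iloc[retained_idx].sort_values(["chrom", "pos"])
    return kept["SNP"].tolist()


def compute_prs(
    sumstats: pd.DataFrame,
    geno: GenotypeSet,
    retained: list[str],
    thresholds: list[float] | None = None,
) -> PRSProfile:
    """Weighted allele sums over retained variants at each threshold.

    A variant contributes when its GWAS p is strictly below the threshold.
    Alleles are harmonized to the genotype effect allele: when the summary
    statistics report the opposite orientation the dosage is flipped
    (2 - d); unresolvable allele pairs are dropped with a warning. Missing
    dosages are imputed as 2 x allele frequency inside the sum while
    ``n_nonmissing`` counts observed genotypes among selected variants.
    """
    thresholds = list(thresholds) if thresholds is not None else list(DEFAULT_P_THRESHOLDS)
    merged = _shared_variants(sumstats, geno)
    merged = merged[merged["SNP"].isin(retained)].reset_index(drop=True)

    same = (merged["A1"] == merged["effect_allele"]) & (merged["A2"] == merged["other_allele"])
    flipped = (merged["A1"] == merged["other_allele"]) & (merged["A2"] == merged["effect_allele"])
    bad = ~(same | flipped)
    if bad.any():
        logger.warning(
            "dropping %d variants with unresolvable alleles (e.g. %s)",
            int(bad.sum()),
            merged.loc[bad, "SNP"].head(3).tolist(),
        )
        merged = merged[~bad].reset_index(drop=True)
        same, flipped = same[~bad].reset_index(drop=True), flipped[~bad].reset_index(drop=True)

    cols = merged["_col"].to_numpy()
    raw = geno.dosage[:, cols]
    d = raw.copy()
    observed = ~np.isnan(raw)
    fill = 2.0 * merged["freq"].to_numpy(float)
    idx = np.where(np.isnan(d))
    d[idx] = fill[idx[1]]

    # harmonize to the genotype effect allele by flipping the weight sign
    beta = np.where(flipped.to_numpy(), -1.0, 1.0) * merged["BETA"].to_numpy(float)
    p = merged["P"].to_numpy(float)
    scores = {}
    nonmiss = {}
    n_selected = {}
    for t in thresholds:
        sel = p < t
        scores[t] = d[:, sel] @ beta[sel]
        nonmiss[t] = observed[:, sel].sum(axis=1)
        n_selected[t] = int(sel.sum())
    sample_ids = geno.sample_ids
    return PRSProfile(
        scores=pd.DataFrame(scores, index=sample_ids),
        n_nonmissing=pd.DataFrame(nonmiss, index=sample_ids),
        thresholds=thresholds,
        n_selected=n_selected,
    )


def prs_case_control_test(profile: PRSProfile, sheet: pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample test of score by case status at every threshold.

    Returns one row per threshold (difference = case mean - control mean)
    plus a ``best`` flag on the most significant threshold.
    """
    is_case = (sheet["case_status"].to_numpy() == "case")
    if is_case.all() or not is_case.any():
        raise NatalmethError("both cases and controls are required")
    rows = []
    for t in profile.thresholds:
        s = profile.scores[t].to_numpy(float)
        a, b = s[is_case], s[~is_case]
        tt, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "p_T": t,
                "n_variants": profile.n_selected.get(t, np.nan),
                "difference": a.mean() - b.mean(),
                "t": float(tt),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["best"] = out["p"] == out["p"].min()
    return out
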