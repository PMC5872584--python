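"""Cross-cohort combination and sliding-window regional analysis.

Per-CpG p-values from independent cohorts are combined with Fisher's
method (restricted to CpGs present in at least two cohorts), flagged for
direction consistency, and pooled by inverse-variance weighting. Sign
tests compare the directions of a primary cohort's top loci against a
replication cohort. Regional (DMR) analysis slides fixed-width windows
over CpG positions and scores each window with Brown's correlated-Fisher
statistic, using the empirical correlation of the member CpGs' betas and
the Kost-McDermott polynomial covariance approximation; window-level
multiple testing is Bonferroni over tested windows.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InputError, NatalmethError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def fisher_combine(pvals) -> float:
    """Fisher's method: X2 = -2 sum(ln p) ~ chi-square with 2k df.

    Zero p-values are clamped to 1e-300 with a warning. A single p-value
    is returned unchanged (the chi-square-2 identity).
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise InputError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("clamping %d zero p-values to %g", int((p == 0).sum()), P_FLOOR)
        p = np.clip(p, P_FLOOR, 1.0)
    x2 = -2.0 * np.sum(np.log(p))
    return float(np.clip(stats.chi2.sf(x2, 2 * p.size), P_FLOOR, 1.0))


def meta_analyze(
    cohorts: list[pd.DataFrame],
    consistent_only: bool = False,
) -> pd.DataFrame:
    """Fisher-combine per-CpG results across cohorts.

    Each cohort frame carries columns ``cpg, estimate, se, p, direction``
    (the per-feature association schema). Only CpGs present in at least
    two cohorts are reported, with the number of contributing cohorts, a
    direction-consistency flag (all contributing signs equal), the
    inverse-variance pooled mean difference, and significance flags at
    the experiment-wide (1e-7) and discovery (5e-5) thresholds. With
    ``consistent_only`` the output is restricted to direction-consistent
    CpGs.
    """
    if len(cohorts) < 2:
        raise InputError("need at least two cohorts")
    frames = []
    for i, c in enumerate(cohorts):
        if c["cpg"].duplicated().any():
            raise InputError(f"cohort {i} has duplicated CpG ids")
        frames.append(c[["cpg", "estimate", "se", "p", "direction"]].assign(_cohort=i))
    allr = pd.concat(frames, ignore_index=True)
    rows = []
    for cpg, grp in allr.groupby("cpg", sort=True):
        if len(grp) < 2:
            continue
        p_comb = fisher_combine(grp["p"].to_numpy())
        w = 1.0 / grp["se"].to_numpy() ** 2
        pooled = float(np.sum(w * grp["estimate"].to_numpy()) / np.sum(w))
        signs = np.sign(grp["estimate"].to_numpy())
        rows.append(
            {
                "cpg": cpg,
                "k": len(grp),
                "p_combined": p_comb,
                "direction_consistent": bool(np.all(signs == signs[0])),
                "pooled_difference": pooled,
            }
        )
    if not rows:
        logger.warning("no CpG present in at least two cohorts")
        return pd.DataFrame(
            columns=["cpg", "k", "p_combined", "direction_consistent", "pooled_difference",
                     "experiment_wide", "discovery"]
        )
    out = pd.DataFrame(rows)
    out["experiment_wide"] = out["p_combined"] < 1e-7
    out["discovery"] = out["p_combined"] < 5e-5
    if consistent_only:
        out = out[out["direction_consistent"]].reset_index(drop=True)
    return out


def sign_test_directions(
    primary: pd.DataFrame,
    other: pd.DataFrame,
    top_k: int | None = None,
    p_select: float = 5e-5,
) -> dict:
    """Exact binomial test of direction concordance for top loci.

    Loci are selected in the primary cohort at ``p_select`` (or as the
    ``top_k`` smallest p-values if given); among those also present in
    the replication cohort, the count of matching effect directions is
    tested two-sided against 0.5. Selected CpGs absent from the other
    cohort are excluded and counted.
    """
    prim = primary.sort_values("p", kind="stable")
    sel = prim.head(top_k) if top_k is not None else prim[prim["p"] <= p_select]
    if sel.empty:
        raise NatalmethError("no loci selected in the primary cohort")
    other_dir = other.set_index("cpg")["direction"]
    present = sel[sel["cpg"].isin(other_dir.index)]
    n_absent = len(sel) - len(present)
    if present.empty:
        raise NatalmethError("no selected loci present in the replication cohort")
    match = (
        present["direction"].to_numpy() == other_dir.loc[present["cpg"]].to_numpy()
    )
    n_consistent = int(match.sum())
    res = stats.binomtest(n_consistent, len(present), 0.5, alternative="two-sided")
    return {
        "n_selected": len(sel),
        "n_compared": len(present),
        "n_absent": n_absent,
        "n_consistent": n_consistent,
        "p": float(res.pvalue),
    }


def _brown_combine(pvals: np.ndarray, betas: np.ndarray) -> float:
    """Brown's method: Fisher statistic with scale/df corrected for the
    empirical correlation of the member CpGs' betas (Kost-McDermott
    covariance polynomial)."""
    k = len(pvals)
    p = np.clip(pvals, P_FLOOR, 1.0)
    x2 = -2.0 * np.sum(np.log(p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(betas.T)
    cov_sum = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            rho = r[i, j]
            if not np.isfinite(rho):
                rho = 0.0
            rho = abs(rho)
            cov_sum += rho * (3.263 + rho * (0.710 + 0.027 * rho))
    mean = 2.0 * k
    var = 4.0 * k + 2.0 * cov_sum
    c = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    return float(np.clip(stats.chi2.sf(x2 / c, df), P_FLOOR, 1.0))


def dmr_scan(
    assoc: pd.DataFrame,
    mset,
    window_bp: int = 1000,
    min_cpgs: int = 2,
) -> pd.DataFrame:
    """Sliding-window regional scan over per-CpG association results.

    Windows of width ``window_bp`` are anchored at each CpG position per
    chromosome (duplicate member sets are collapsed); windows holding at
    least ``min_cpgs`` association results are scored with Brown's
    method using the empirical inter-CpG correlation of their betas from
    ``mset``. Output columns include the Bonferroni-adjusted window p.
    Output is invariant to CpG column order.
    """
    man = mset.manifest
    col_of = {c: j for j, c in enumerate(man["id"])}
    ainfo = assoc.set_index("cpg")
    rows = []
    seen: set[tuple] = set()
    for chrom, grp in man.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        ids = grp["id"].to_numpy()
        pos = grp["pos"].to_numpy()
        tested = np.isin(ids, ainfo.index)
        for anchor in range(len(grp)):
            inwin = (pos >= pos[anchor]) & (pos < pos[anchor] + window_bp) & tested
            members = tuple(ids[inwin])
            if len(members) < min_cpgs or members in seen:
                continue
            seen.add(members)
            pv = ainfo.loc[list(members), "p"].to_numpy(float)
            betas = mset.beta[:, [col_of[c] for c in members]]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[inwin].min()),
                    "end": int(pos[inwin].max()),
                    "n_cpgs": len(members),
                    "cpgs": ";".join(members),
                    "p": _brown_combine(pv, betas),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "cpgs", "p", "p_bonferroni"])
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.clip(out["p"] * len(out), 0.0, 1.0)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)
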