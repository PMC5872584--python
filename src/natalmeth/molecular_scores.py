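"""Methylation-derived linear predictors and cell-composition estimation.

Implements the linear-clock machinery (gestational-age and chronological-
age clocks, prenatal-smoking score) as weighted sums of CpG betas plus an
optional age-calibration transform, and reference-based cell-type
deconvolution by nonnegative constrained projection of each sample's
methylation profile onto cell-type reference profiles.

Coefficient tables are pluggable: the engines accept any published clock
or smoking-score table supplied in the TSV format documented in
:func:`read_coefficient_table`; synthetic tables are used for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import InputError, MethylSet, NatalmethError

logger = logging.getLogger(__name__)


@dataclass
class CoefficientTable:
    """CpG weights for a linear methylation predictor.

    ``transform``: "identity" or "age_calibration". The age calibration
    maps the linear predictor x to (1 + A) * exp(x) - 1 for x <= 0 and
    (1 + A) * x + A otherwise, with adult age A (default 20) — the
    standard anti-log transform used by chronological-age clocks.
    """

    weights: pd.Series  # indexed by CpG id, score units per beta unit
    intercept: float = 0.0
    transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights.to_numpy(float))):
            raise InputError("coefficient weights must be finite")
        if self.transform not in ("identity", "age_calibration"):
            raise InputError(f"unknown transform {self.transform!r}")


@dataclass
class CellReference:
    """Cell type x CpG mean-beta reference profiles."""

    profiles: pd.DataFrame  # rows = cell types, columns = CpG ids

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy(float)
        if vals.min() < 0 or vals.max() > 1:
            raise InputError("reference profiles must lie in [0, 1]")


def age_calibration(x: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Piecewise anti-log age calibration: (1+A)e^x - 1 below 0, linear above."""
    x = np.asarray(x, float)
    return np.where(x <= 0, (1 + adult_age) * np.exp(x) - 1, (1 + adult_age) * x + adult_age)


def linear_score(mset: MethylSet, coefs: CoefficientTable) -> np.ndarray:
    """Per-sample predictor: transform(intercept + sum_j w_j beta_ij).

    Coefficient CpGs absent from the data are dropped with a warning;
    NaN betas at a present coefficient CpG are imputed with that CpG's
    cohort mean. Raises if no coefficient CpG overlaps the data.
    """
    col_index = {c: j for j, c in enumerate(mset.manifest["id"])}
    present = [c for c in coefs.weights.index if c in col_index]
    missing = [c for c in coefs.weights.index if c not in col_index]
    if not present:
        raise InputError(
            f"no coefficient CpGs found in the methylation data; missing: {missing[:10]}..."
            if len(missing) > 10
            else f"no coefficient CpGs found in the methylation data; missing: {missing}"
        )
    if missing:
        logger.warning(
            "%d coefficient CpGs absent from the data were dropped (e.g. %s)",
            len(missing),
            missing[:5],
        )
    cols = np.array([col_index[c] for c in present])
    b = mset.beta[:, cols].copy()
    if np.isnan(b).any():
        logger.warning("imputing cohort mean beta at %d missing entries", int(np.isnan(b).sum()))
        col_mean = np.nanmean(b, axis=0)
        idx = np.where(np.isnan(b))
        b[idx] = col_mean[idx[1]]
    w = coefs.weights.loc[present].to_numpy(float)
    x = coefs.intercept + b @ w
    if coefs.transform == "age_calibration":
        return age_calibration(x, coefs.adult_age)
    return x


def estimate_cell_composition(mset: MethylSet, ref: CellReference) -> pd.DataFrame:
    """Reference-based deconvolution by nonnegative least squares.

    For each sample solves min_w ||m - B^T w||^2 subject to w >= 0 over
    the CpGs shared between the data and the reference; no sum-to-one
    equality is imposed, and the row sum is reported as a QC column.
    """
    shared = [c for c in ref.profiles.columns if c in set(mset.manifest["id"])]
    k = len(ref.profiles)
    if len(shared) < k:
        raise InputError(
            f"need at least {k} shared discriminating CpGs, found {len(shared)}"
        )
    B = ref.profiles[shared].to_numpy(float)  # k x p
    if np.linalg.matrix_rank(B) < k:
        raise InputError("reference profile matrix is rank deficient")
    col_index = {c: j for j, c in enumerate(mset.manifest["id"])}
    m = mset.beta[:, [col_index[c] for c in shared]]
    out = np.empty((mset.n_samples, k))
    for i in range(mset.n_samples):
        out[i], _ = optimize.nnls(B.T, m[i])
    frame = pd.DataFrame(out, columns=list(ref.profiles.index), index=mset.sample_ids)
    frame["cell_sum"] = frame.sum(axis=1)
    return frame


def compare_score_to_truth(score: np.ndarray, truth: np.ndarray) -> dict:
    """Pearson correlation of a predictor with its ground truth, plus the
    predictor's mean and sd."""
    score = np.asarray(score, float)
    truth = np.asarray(truth, float)
    if len(score) < 3:
        raise InputError("need at least 3 samples")
    if score.std() == 0 or truth.std() == 0:
        raise InputError("zero variance in score or truth")
    r, _ = stats.pearsonr(score, truth)
    return {"r": float(r), "mean": float(score.mean()), "sd": float(score.std(ddof=1))}


def score_group_test(score: np.ndarray, group: np.ndarray) -> dict:
    """Welch two-sample t-test of a score between two exposure groups.

    ``group`` is boolean-like; the difference reported is mean(exposed) -
    mean(unexposed).
    """
    score = np.asarray(score, float)
    group = np.asarray(group).astype(bool)
    a, b = score[group], score[~group]
    if len(a) < 2 or len(b) < 2:
        raise NatalmethError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "difference": float(a.mean() - b.mean()),
        "t": float(t),
        "p": float(p),
        "n": int(len(score)),
    }


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def read_coefficient_table(path) -> CoefficientTable:
    """Read a `cpg\\tweight` TSV with optional `#intercept=`, `#transform=`
    and `#adult_age=` header lines."""
    meta = {"intercept": 0.0, "transform": "identity", "adult_age": 20.0}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key in ("intercept", "adult_age"):
                    meta[key] = float(val)
                elif key == "transform":
                    meta[key] = val.strip()
                continue
            if line.startswith("cpg\t"):
                continue
            cpg, weight = line.split("\t")[:2]
            rows.append((cpg, float(weight)))
    weights = pd.Series(dict(rows), name="weight")
    return CoefficientTable(
        weights=weights,
        intercept=meta["intercept"],
        transform=meta["transform"],
        adult_age=meta["adult_age"],
    )


def write_coefficient_table(coefs: CoefficientTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#intercept={coefs.intercept}\n")
        fh.write(f"#transform={coefs.transform}\n")
        fh.write(f"#adult_age={coefs.adult_age}\n")
        fh.write("cpg\tweight\n")
        for cpg, w in coefs.weights.items():
            fh.write(f"{cpg}\t{w}\n")
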