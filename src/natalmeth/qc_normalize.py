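"""Sample/probe quality control and intensity-based quantile normalization
for 450K-style methylation arrays.

The pipeline applies, in order: (1) median methylated/unmethylated
intensity filtering, (2) bisulfite-conversion control scoring, (3) plate
control presence check, (4) duplicate detection via the 65 genotyping
probes, (5) sex verification by multidimensional scaling of X and Y
probes, (6) genotype concordance against array genotypes, and
(7) detection-p-value filtering of samples and probes; retained samples
are then quantile-normalized within probe type on the methylated and
unmethylated channels separately and betas recomputed as
M / (M + U + offset).

All "<" thresholds are strict: a median of exactly 2500 (intensity) or 80
(bisulfite) passes. The detection-p sample and probe criteria are
evaluated simultaneously on the full input matrix, making the result
order-independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import GenotypeSet, InputError, MethylSet

logger = logging.getLogger(__name__)

LOW_INTENSITY = "low_intensity"
BISULFITE_FAIL = "bisulfite_fail"
DUPLICATE = "duplicate"
SEX_MISMATCH = "sex_mismatch"
GENOTYPE_DISCORDANT = "genotype_discordant"
DETECTION_P_FAIL = "detection_p_fail"

#: the order in which failure reasons are recorded (= pipeline step order)
REASON_ORDER = [
    LOW_INTENSITY,
    BISULFITE_FAIL,
    DUPLICATE,
    SEX_MISMATCH,
    GENOTYPE_DISCORDANT,
    DETECTION_P_FAIL,
]


@dataclass
class QCReport:
    """Per-sample and per-probe pass/fail bookkeeping.

    ``samples`` columns: sample_id, passed, reasons (';'-joined, in step
    order). ``probes`` columns: cpg, passed, reason.
    """

    samples: pd.DataFrame
    probes: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.samples)

    @property
    def n_retained(self) -> int:
        return int(self.samples["passed"].sum())

    @property
    def retention_pct(self) -> float:
        """Retention as a percentage, rounded to one decimal."""
        return round(100.0 * self.n_retained / self.n_input, 1)


# ---------------------------------------------------------------------------
# individual filters; each returns {sample index -> reason} (or probe info)
# ---------------------------------------------------------------------------

def intensity_filter(mset: MethylSet, threshold: float = 2500.0) -> dict[int, str]:
    """Fail samples whose median methylated OR unmethylated intensity is
    strictly below ``threshold``."""
    if mset.meth is None or mset.unmeth is None:
        raise InputError("intensity filter requires methylated/unmethylated intensities")
    med_m = np.median(mset.meth, axis=1)
    med_u = np.median(mset.unmeth, axis=1)
    fail = (med_m < threshold) | (med_u < threshold)
    return {int(i): LOW_INTENSITY for i in np.where(fail)[0]}


def bisulfite_filter(mset: MethylSet, threshold: float = 80.0) -> dict[int, str]:
    """Fail samples whose median bisulfite-conversion control score is
    strictly below ``threshold``."""
    if mset.control_scores is None:
        raise InputError("bisulfite filter requires control scores")
    if mset.control_scores.shape[1] != 10:
        raise InputError(
            f"expected 10 control scores per sample, got {mset.control_scores.shape[1]}"
        )
    med = np.median(mset.control_scores, axis=1)
    return {int(i): BISULFITE_FAIL for i in np.where(med < threshold)[0]}


def duplicate_check(mset: MethylSet, r_threshold: float = 0.95) -> dict[int, str]:
    """Flag all members of sample pairs whose genotyping-probe betas
    correlate above ``r_threshold`` (both members reported)."""
    if mset.snp_probe_beta is None:
        raise InputError("duplicate check requires genotyping-probe betas")
    x = mset.snp_probe_beta
    if x.shape[0] < 2:
        return {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows give nan correlations
        r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    flagged = np.where(np.nanmax(r, axis=1) > r_threshold)[0]
    return {int(i): DUPLICATE for i in flagged}


def _classical_mds_first_coord(x: np.ndarray) -> np.ndarray:
    """First principal coordinate of classical (Torgerson) MDS on Euclidean
    distances; equivalent to the first PC score of the centered data."""
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, 0] * s[0]


def sex_check(mset: MethylSet, sheet: pd.DataFrame, random_state: int = 0) -> dict[int, str]:
    """Verify reported sex by MDS of X-probe and Y-probe betas separately.

    The first MDS coordinate is split into two clusters (2-means); each
    cluster's sex is the majority reported label (ties resolved toward the
    reported labels, i.e. not flagged). A sample is flagged when its
    predicted sex disagrees with its reported sex on either chromosome. The
    result is invariant to the arbitrary sign of the MDS coordinate.
    """
    chroms = mset.manifest["chrom"].astype(str).str.upper()
    reported = sheet["sex"].to_numpy()
    for s in ("M", "F"):
        if (reported == s).sum() < 2:
            logger.warning("sex check skipped: fewer than 2 reported %s samples", s)
            return {}
    flagged: set[int] = set()
    for chrom in ("X", "Y"):
        cols = (chroms == chrom).to_numpy()
        if cols.sum() == 0:
            raise InputError(f"sex check requires probes on chromosome {chrom}")
        coord = _classical_mds_first_coord(mset.beta[:, cols])
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
        labels = km.fit_predict(coord.reshape(-1, 1))
        # majority reported sex per cluster; ties break toward reported label
        pred = np.empty(len(labels), dtype=object)
        for cl in (0, 1):
            members = labels == cl
            n_m = (reported[members] == "M").sum()
            n_f = members.sum() - n_m
            if n_m == n_f:
                pred[members] = reported[members]
            else:
                pred[members] = "M" if n_m > n_f else "F"
        flagged |= {int(i) for i in np.where(pred != reported)[0]}
    return {i: SEX_MISMATCH for i in sorted(flagged)}


def genotype_concordance(
    mset: MethylSet,
    geno: GenotypeSet,
    probe_variant_map: list[tuple[int, str]],
    min_concord: float = 0.9,
) -> dict[int, str]:
    """Fail samples whose discretized genotyping-probe calls agree with
    their array genotypes on fewer than ``min_concord`` of comparable loci.

    Probe betas are discretized as <0.2 -> 0, 0.2-0.8 -> 1, >0.8 -> 2.
    """
    if not probe_variant_map:
        raise InputError("genotype concordance requires a probe-variant map")
    if mset.snp_probe_beta is None:
        raise InputError("genotype concordance requires genotyping-probe betas")
    vid_to_col = {v: j for j, v in enumerate(geno.variants["id"])}
    pairs = [(p, vid_to_col[v]) for p, v in probe_variant_map if v in vid_to_col]
    if not pairs:
        raise InputError("no probe-variant pairs resolve against the genotype set")
    probe_cols = np.array([p for p, _ in pairs])
    var_cols = np.array([v for _, v in pairs])
    b = mset.snp_probe_beta[:, probe_cols]
    calls = np.where(b < 0.2, 0, np.where(b > 0.8, 2, 1)).astype(float)
    dos = geno.dosage[:, var_cols]
    out: dict[int, str] = {}
    for i in range(mset.n_samples):
        ok = ~np.isnan(dos[i])
        if ok.sum() == 0:
            logger.warning("sample %s has no overlapping genotype calls; skipped", i)
            continue
        concord = float(np.mean(calls[i, ok] == dos[i, ok]))
        if concord < min_concord:
            out[int(i)] = GENOTYPE_DISCORDANT
    return out


def detection_p_filter(
    mset: MethylSet,
    sample_frac: float = 0.01,
    probe_frac: float = 0.01,
    p_cut: float = 0.05,
) -> tuple[dict[int, str], np.ndarray]:
    """Simultaneous sample and probe detection-p filtering.

    A sample fails when more than ``sample_frac`` of its probes have
    detection p > ``p_cut``; a probe fails when more than ``probe_frac`` of
    samples have detection p > ``p_cut``. Both criteria are evaluated on
    the full input matrix before anything is dropped. Returns the failing
    samples and a boolean keep-mask over probes.
    """
    if mset.detection_p is None:
        raise InputError("detection-p filter requires detection p-values")
    bad = mset.detection_p > p_cut
    sample_fail = bad.mean(axis=1) > sample_frac
    probe_fail = bad.mean(axis=0) > probe_frac
    return (
        {int(i): DETECTION_P_FAIL for i in np.where(sample_fail)[0]},
        ~probe_fail,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _quantile_normalize_rows(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize each row (sample) to the mean sorted profile."""
    if x.shape[0] < 2:
        return x.copy()
    order = np.argsort(x, axis=1, kind="stable")
    ref = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    rows = np.arange(x.shape[0])[:, None]
    out[rows, order] = ref[None, :]
    return out


def quantile_normalize(mset: MethylSet, offset: float = 100.0) -> MethylSet:
    """Probe-type-wise quantile normalization of the methylated and
    unmethylated channels, with betas recomputed as M / (M + U + offset).

    Within each probe design type (I, II) every sample's intensity
    distribution is mapped to the mean empirical distribution across
    samples; rank order within sample and probe type is preserved. A
    single-sample input is returned unchanged (identity transform).
    """
    if mset.meth is None or mset.unmeth is None:
        raise InputError("quantile normalization requires intensities")
    meth = mset.meth.copy()
    unmeth = mset.unmeth.copy()
    ptype = mset.manifest["probe_type"].to_numpy()
    for t in ("I", "II"):
        cols = ptype == t
        if cols.sum() == 0:
            continue
        meth[:, cols] = _quantile_normalize_rows(meth[:, cols])
        unmeth[:, cols] = _quantile_normalize_rows(unmeth[:, cols])
    beta = meth / (meth + unmeth + offset)
    return MethylSet(
        beta=beta,
        manifest=mset.manifest.copy(),
        sample_ids=list(mset.sample_ids),
        meth=meth,
        unmeth=unmeth,
        detection_p=None if mset.detection_p is None else mset.detection_p.copy(),
        control_scores=None if mset.control_scores is None else mset.control_scores.copy(),
        snp_probe_beta=None if mset.snp_probe_beta is None else mset.snp_probe_beta.copy(),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_qc(
    mset: MethylSet,
    geno: GenotypeSet | None = None,
    sheet: pd.DataFrame | None = None,
    probe_variant_map: list[tuple[int, str]] | None = None,
    *,
    intensity_threshold: float = 2500.0,
    bisulfite_threshold: float = 80.0,
    duplicate_r: float = 0.95,
    min_concord: float = 0.9,
    sample_frac: float = 0.01,
    probe_frac: float = 0.01,
    detp_cut: float = 0.05,
    normalize: bool = True,
    offset: float = 100.0,
) -> tuple[MethylSet, QCReport]:
    """Apply the full QC pipeline then quantile normalization.

    Every step is evaluated on the full input so a failing sample carries
    the reasons of all steps it fails; failing samples and probes are then
    dropped together and the retained data normalized. Steps needing
    absent side-data (intensities, control scores, genotypes, ...) are
    skipped with a log message.
    """
    reasons: dict[int, list[str]] = {i: [] for i in range(mset.n_samples)}

    def record(frag: dict[int, str]) -> None:
        for i, reason in frag.items():
            reasons[i].append(reason)

    if mset.meth is not None and mset.unmeth is not None:
        frag = intensity_filter(mset, intensity_threshold)
        record(frag)
        logger.info("step 1 intensity: %d failures", len(frag))
    else:
        logger.info("step 1 intensity: skipped (no intensities)")
    if mset.control_scores is not None:
        frag = bisulfite_filter(mset, bisulfite_threshold)
        record(frag)
        logger.info("step 2 bisulfite: %d failures", len(frag))
    logger.info("step 3 plate controls: presence check only (no plate map supplied)")
    if mset.snp_probe_beta is not None:
        frag = duplicate_check(mset, duplicate_r)
        record(frag)
        logger.info("step 4 duplicates: %d flagged", len(frag))
    if sheet is not None:
        chroms = set(mset.manifest["chrom"].astype(str).str.upper())
        if {"X", "Y"} <= chroms:
            frag = sex_check(mset, sheet)
            record(frag)
            logger.info("step 5 sex check: %d mismatches", len(frag))
        else:
            logger.info("step 5 sex check: skipped (no X/Y probes)")
    if geno is not None and probe_variant_map and mset.snp_probe_beta is not None:
        frag = genotype_concordance(mset, geno, probe_variant_map, min_concord)
        record(frag)
        logger.info("step 6 concordance: %d failures", len(frag))
    probe_keep = np.ones(mset.n_cpgs, dtype=bool)
    if mset.detection_p is not None:
        frag, probe_keep = detection_p_filter(mset, sample_frac, probe_frac, detp_cut)
        record(frag)
        logger.info(
            "step 7 detection p: %d sample failures, %d probe failures",
            len(frag),
            int((~probe_keep).sum()),
        )

    sample_keep = np.array([len(reasons[i]) == 0 for i in range(mset.n_samples)])
    samples = pd.DataFrame(
        {
            "sample_id": mset.sample_ids,
            "passed": sample_keep,
            "reasons": [";".join(reasons[i]) for i in range(mset.n_samples)],
        }
    )
    probes = pd.DataFrame(
        {
            "cpg": mset.manifest["id"].to_numpy(),
            "passed": probe_keep,
            "reason": np.where(probe_keep, "", DETECTION_P_FAIL),
        }
    )
    report = QCReport(
        samples=samples,
        probes=probes,
        thresholds={
            "intensity": intensity_threshold,
            "bisulfite": bisulfite_threshold,
            "duplicate_r": duplicate_r,
            "min_concord": min_concord,
            "sample_frac": sample_frac,
            "probe_frac": probe_frac,
            "detp_cut": detp_cut,
        },
    )
    retained = mset.subset(sample_keep, probe_keep)
    if normalize and retained.meth is not None:
        retained = quantile_normalize(retained, offset)
    logger.info(
        "QC complete: %d/%d samples retained (%.1f%%)",
        report.n_retained,
        report.n_input,
        report.retention_pct,
    )
    return retained, report
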