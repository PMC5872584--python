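"""Core in-memory containers shared across the pipeline.

Genotypes are held as a dense sample x variant dosage matrix (float, with
``nan`` encoding a missing call) plus a variant metadata frame. Methylation
data are held as a sample x CpG beta matrix in [0, 1], optionally backed by
methylated/unmethylated intensity pairs and per-entry detection p-values,
together with a CpG manifest. Sample metadata, GWAS summary statistics and
per-feature association results travel as plain :class:`pandas.DataFrame`
objects with documented column schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column schema for GWAS summary statistics frames
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "FRQ", "N"]

#: column schema for sample sheets
SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "case_status",       # "case" / "control"
    "pair_id",           # 1:1 matched pair identifier
    "sex",               # "M" / "F"
    "birth_month",       # 1-12
    "birth_year",
    "gestational_age",   # weeks
    "urbanicity",        # 1-5
    "maternal_smoking",  # "yes" / "no"
    "birth_weight",      # grams
    "days_to_sampling",
    "batch",             # array/plate batch id
]

#: column schema for per-feature association results
ASSOC_COLUMNS = ["cpg", "chr", "pos", "estimate", "se", "t", "p", "n", "direction"]


class NatalmethError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(NatalmethError):
    """Invalid configuration or effect indices out of range."""


class InputError(NatalmethError):
    """Malformed or unsupported input data."""


@dataclass
class GenotypeSet:
    """Sample x variant dosages in {0, 1, 2, nan} with variant metadata.

    ``variants`` columns: ``id, chrom, pos, effect_allele, other_allele, freq``
    with 1-based positions strictly increasing within each chromosome and
    allele frequencies in (0, 1).
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise InputError("dosage must be a 2-D sample x variant matrix")
        if self.dosage.shape[1] != len(self.variants):
            raise InputError(
                f"dosage has {self.dosage.shape[1]} variant columns but the "
                f"metadata frame has {len(self.variants)} rows"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(self.dosage.shape[0])]
        self.variants = self.variants.reset_index(drop=True)
        freq = self.variants["freq"].to_numpy(float)
        if np.any((freq <= 0) | (freq >= 1)):
            raise InputError("allele frequencies must lie in (0, 1)")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise InputError("positions must be strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def imputed_dosage(self) -> np.ndarray:
        """Dosages with missing calls replaced by 2 x allele frequency."""
        d = self.dosage.copy()
        fill = 2.0 * self.variants["freq"].to_numpy(float)
        idx = np.where(np.isnan(d))
        d[idx] = fill[idx[1]]
        return d


@dataclass
class MethylSet:
    """Sample x CpG beta matrix with manifest and optional QC side-channels.

    ``manifest`` columns: ``id, chrom, pos, probe_type, gene`` (1-based
    positions, probe_type in {"I", "II"}); one row per beta column, in order.
    ``control_scores`` holds 10 bisulfite-conversion control scores per
    sample; ``snp_probe_beta`` the betas of the 65 genotyping probes.
    """

    beta: np.ndarray
    manifest: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)
    meth: np.ndarray | None = None
    unmeth: np.ndarray | None = None
    detection_p: np.ndarray | None = None
    control_scores: np.ndarray | None = None
    snp_probe_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise InputError("beta must be a 2-D sample x CpG matrix")
        if self.beta.shape[1] != len(self.manifest):
            raise InputError(
                f"beta has {self.beta.shape[1]} CpG columns but the manifest "
                f"has {len(self.manifest)} rows"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(self.beta.shape[0])]
        self.manifest = self.manifest.reset_index(drop=True)
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise InputError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[1]

    @property
    def cpg_ids(self) -> list[str]:
        return self.manifest["id"].tolist()

    def subset(self, sample_mask=None, cpg_mask=None) -> "MethylSet":
        """Row/column subset preserving all side matrices."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        cmask = np.ones(self.n_cpgs, bool) if cpg_mask is None else np.asarray(cpg_mask)

        def cut(a, cols=True):
            if a is None:
                return None
            a = a[smask]
            return a[:, cmask] if cols else a

        return MethylSet(
            beta=self.beta[smask][:, cmask],
            manifest=self.manifest.loc[cmask].reset_index(drop=True),
            sample_ids=[s for s, keep in zip(self.sample_ids, smask) if keep],
            meth=cut(self.meth),
            unmeth=cut(self.unmeth),
            detection_p=cut(self.detection_p),
            control_scores=cut(self.control_scores, cols=False),
            snp_probe_beta=cut(self.snp_probe_beta, cols=False),
        )


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-sheet schema and return the frame unchanged."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise InputError(f"sample sheet is missing columns: {missing}")
    return sheet


def assoc_frame(
    cpg, estimate, se, t, p, n, chrom=None, pos=None
) -> pd.DataFrame:
    """Assemble a per-feature association result frame with direction signs."""
    est = np.asarray(estimate, float)
    out = pd.DataFrame(
        {
            "cpg": cpg,
            "chr": chrom if chrom is not None else "",
            "pos": pos if pos is not None else -1,
            "estimate": est,
            "se": np.asarray(se, float),
            "t": np.asarray(t, float),
            "p": np.asarray(p, float),
            "n": np.asarray(n, int),
            "direction": np.sign(est).astype(int),
        }
    )
    return out
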