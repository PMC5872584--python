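"""TSV/VCF/BED interchange for the pipeline's containers.

TSV is the primary interchange format: dosage matrices travel as a
sample x variant table with a sibling variant-metadata table, betas and
detection p-values as sample x CpG tables, the CpG manifest as BED
(0-based half-open two-base intervals), and summary statistics with the
standard ``SNP CHR BP A1 A2 BETA SE P FRQ N`` columns. Genotypes can
also be read from VCF (GT-derived dosages via cyvcf2) and written as VCF
(via pysam).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeSet, InputError, MethylSet, SUMSTATS_COLUMNS


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(geno: GenotypeSet, dosage_path, variants_path) -> None:
    frame = pd.DataFrame(geno.dosage, index=geno.sample_ids, columns=geno.variants["id"])
    frame.index.name = "sample_id"
    frame.to_csv(dosage_path, sep="\t", na_rep="NA")
    geno.variants.to_csv(variants_path, sep="\t", index=False)


def read_genotypes_tsv(dosage_path, variants_path) -> GenotypeSet:
    frame = pd.read_csv(dosage_path, sep="\t", index_col="sample_id")
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    return GenotypeSet(
        dosage=frame.to_numpy(float),
        variants=variants,
        sample_ids=[str(s) for s in frame.index],
    )


def write_genotypes_vcf(geno: GenotypeSet, path) -> None:
    """Write hard-called dosages as a VCF with GT fields (missing -> ./.)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = pd.unique(geno.variants["chrom"].astype(str))
    for c in chroms:
        header.contigs.add(c)
    for s in geno.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, row in geno.variants.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                id=row["id"],
                alleles=(row["other_allele"], row["effect_allele"]),
            )
            for i, s in enumerate(geno.sample_ids):
                d = geno.dosage[i, j]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    k = int(round(d))
                    rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[k]
            vf.write(rec)


def read_genotypes_vcf(path) -> GenotypeSet:
    """Read GT-based dosages of the ALT (= effect) allele from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        rows.append(d)
        called = d[~np.isnan(d)]
        freq = float(called.mean() / 2.0) if called.size else 0.5
        meta.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "effect_allele": rec.ALT[0] if rec.ALT else "N",
                "other_allele": rec.REF,
                "freq": min(max(freq, 1e-6), 1 - 1e-6),
            }
        )
    if not rows:
        raise InputError(f"no variants in {path}")
    return GenotypeSet(
        dosage=np.vstack(rows).T, variants=pd.DataFrame(meta), sample_ids=samples
    )


def read_genotypes(path, variants_path=None) -> GenotypeSet:
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        return read_genotypes_vcf(path)
    if variants_path is None:
        variants_path = path.with_name(path.stem + ".variants.tsv")
    return read_genotypes_tsv(path, variants_path)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, sample_ids, col_ids, path) -> None:
    frame = pd.DataFrame(matrix, index=sample_ids, columns=col_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_manifest_bed(manifest: pd.DataFrame, path) -> None:
    """CpG manifest as BED: 0-based half-open width-2 intervals, with probe
    type and gene in extra columns."""
    bed = pd.DataFrame(
        {
            "chrom": manifest["chrom"],
            "start": manifest["pos"] - 1,
            "end": manifest["pos"] + 1,
            "name": manifest["id"],
            "score": 0,
            "strand": "+",
            "probe_type": manifest["probe_type"],
            "gene": manifest.get("gene", ""),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_manifest_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "probe_type", "gene"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "id": bed["name"],
            "chrom": bed["chrom"],
            "pos": bed["start"] + 1,  # back to 1-based CpG coordinate
            "probe_type": bed["probe_type"],
            "gene": bed["gene"],
        }
    )


def read_methylset(beta_path, manifest_path, meth_path=None, unmeth_path=None, detp_path=None) -> MethylSet:
    beta = read_matrix_tsv(beta_path)
    manifest = read_manifest_bed(manifest_path)
    kw = {}
    for key, p in (("meth", meth_path), ("unmeth", unmeth_path), ("detection_p", detp_path)):
        if p is not None:
            kw[key] = read_matrix_tsv(p).to_numpy(float)
    return MethylSet(
        beta=beta.to_numpy(float),
        manifest=manifest,
        sample_ids=[str(s) for s in beta.index],
        **kw,
    )


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in ss.columns]
    if missing:
        raise InputError(f"summary statistics missing columns: {missing}")
    return ss


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
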