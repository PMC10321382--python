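"""Readers and writers for the cohort's on-disk formats.

Phenotypes travel as TSV (one row per pregnancy), genotypes as either a
dense variant x sample TSV matrix or a VCF with per-sample dosage in the
``DS`` FORMAT field, PGS weights as a PGS-Catalog-like TSV.  VCF text is
written directly; reading goes through pysam when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_vcf",
    "read_vcf",
    "write_weights",
    "read_weights",
]


def write_cohort(cohort: Cohort, prefix: str | Path, vcf: bool = False) -> dict:
    """Write ``<prefix>.pheno.tsv`` plus dosages (TSV matrix or VCF).

    Returns the mapping of part name to written path.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"pheno": prefix.with_suffix(".pheno.tsv")}
    cohort.pheno.to_csv(paths["pheno"], sep="\t", index=False)
    if cohort.n_variants:
        if vcf:
            paths["genotypes"] = prefix.with_suffix(".vcf")
            write_vcf(cohort, paths["genotypes"])
        else:
            paths["genotypes"] = prefix.with_suffix(".dosage.tsv")
            mat = pd.DataFrame(
                cohort.dosages.T,
                index=cohort.variants["id"],
                columns=[f"s{i}" for i in range(cohort.n)],
            )
            meta = cohort.variants.set_index("id")
            pd.concat([meta, mat], axis=1).to_csv(paths["genotypes"], sep="\t")
    return paths


def read_cohort(prefix: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (TSV-matrix layout)."""
    prefix = Path(prefix)
    pheno = pd.read_csv(prefix.with_suffix(".pheno.tsv"), sep="\t")
    pheno["spontaneous"] = pheno["spontaneous"].astype(bool)
    geno_path = prefix.with_suffix(".dosage.tsv")
    vcf_path = prefix.with_suffix(".vcf")
    if geno_path.exists():
        tab = pd.read_csv(geno_path, sep="\t", index_col=0)
        meta_cols = ["chrom", "pos", "effect_allele", "other_allele"]
        variants = tab[meta_cols].reset_index().rename(columns={"index": "id"})
        variants["chrom"] = variants["chrom"].astype(str)
        dosages = tab.drop(columns=meta_cols).to_numpy(dtype=float).T
        return Cohort(pheno=pheno, dosages=dosages, variants=variants)
    if vcf_path.exists():
        dosages, variants = read_vcf(vcf_path)
        return Cohort(pheno=pheno, dosages=dosages, variants=variants)
    return Cohort(pheno=pheno)


def write_vcf(cohort: Cohort, path: str | Path) -> None:
    """Write dosages as a VCFv4.2 with the DS FORMAT field.

    The effect allele is written as ALT so that DS counts it directly.
    """
    v = cohort.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated '
            'alternate allele dosage">\n'
        )
        for c in sorted(v["chrom"].astype(str).unique(), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(f"s{i}" for i in range(cohort.n))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n"
        )
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].astype(str).to_numpy()))
        for j in order:
            ds = "\t".join(f"{d:.8g}" for d in cohort.dosages[:, j])
            fh.write(
                f"{v['chrom'].iloc[j]}\t{int(v['pos'].iloc[j])}\t{v['id'].iloc[j]}"
                f"\t{v['other_allele'].iloc[j]}\t{v['effect_allele'].iloc[j]}"
                f"\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read dosages (DS field) and variant metadata from a VCF.

    Returns (dosages with shape (n_samples, n_variants), variant table);
    the ALT allele is taken as the effect allele.
    """
    import pysam  # deferred: only needed for VCF input

    rows, meta = [], []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index else vf:
            ds = [rec.samples[s].get("DS") for s in rec.samples]
            rows.append([np.nan if d is None else float(d) for d in ds])
            meta.append(
                {
                    "id": rec.id,
                    "chrom": str(rec.chrom),
                    "pos": int(rec.pos),
                    "effect_allele": rec.alts[0],
                    "other_allele": rec.ref,
                }
            )
    return np.asarray(rows, dtype=float).T, pd.DataFrame(meta)


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights[["id", "effect_allele", "other_allele", "weight"]].to_csv(
        path, sep="\t", index=False
    )


def read_weights(path: str | Path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t")
    required = {"id", "effect_allele", "other_allele", "weight"}
    missing = required - set(w.columns)
    if missing:
        raise ValueError(f"weight file lacks columns: {sorted(missing)}")
    return w
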