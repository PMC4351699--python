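"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are enforced here and only here: SNP positions are
1-based internally (VCF convention); BED files are 0-based half-open and are
kept that way inside :class:`PeakSet` (SNP-vs-peak comparisons do the single
+/-1 conversion in :meth:`PeakSet.contains`).  Gene annotation files carry
1-based TSS/TES columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionTable,
    GeneAnnotation,
    GenotypeTable,
    PeakSet,
    TraitSnpList,
)

logger = logging.getLogger(__name__)

_GENO_META = ["chrom", "pos", "ref", "alt", "info_score"]


# ---------------------------------------------------------------- genotypes

def write_genotypes_tsv(genotypes: GenotypeTable, path) -> None:
    """Wide TSV: snp_id, metadata columns, then one dosage column per sample."""
    meta = genotypes.snps.copy()
    for col in _GENO_META:
        if col not in meta.columns:
            meta[col] = np.nan
    table = pd.concat([meta[_GENO_META], genotypes.dosages.T], axis=1)
    table.index.name = "snp_id"
    table.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeTable:
    table = pd.read_csv(path, sep="\t", index_col="snp_id", na_values=["NA"])
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate snp_id in {path}: {dups[:5]}")
    meta = table[_GENO_META].copy()
    meta["chrom"] = meta["chrom"].astype(str)
    meta["pos"] = meta["pos"].astype(np.int64)
    if meta["info_score"].isna().all():
        meta = meta.drop(columns=["info_score"])
    dosages = table.drop(columns=_GENO_META).T.astype(float)
    dosages.columns.name = None
    dosages.index.name = None
    meta.index.name = None
    return GenotypeTable(dosages, meta)


def write_genotypes_vcf(genotypes: GenotypeTable, path) -> None:
    """Minimal VCFv4.2 with GT (rounded hard call) and DS (exact dosage)."""
    snps = genotypes.snps
    samples = genotypes.sample_ids
    calls = genotypes.hard_calls()
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for snp_id, row in snps.iterrows():
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(snp_id),
                str(row.get("ref", "A")),
                str(row.get("alt", "G")),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            for s in samples:
                d = genotypes.dosages.at[s, snp_id]
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[calls.at[s, snp_id]]}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def read_genotypes_vcf(path) -> GenotypeTable:
    """VCF reader via cyvcf2; DS format field wins over hard GT calls."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts = [], [], [], [], []
    dosage_rows = []
    seen = set()
    for i, variant in enumerate(vcf, start=1):
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if vid in seen:
            raise ValueError(f"duplicate snp_id {vid!r} at record {i} of {path}")
        seen.add(vid)
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, float).reshape(-1)
        else:
            # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
            gt = np.asarray(variant.gt_types)
            row = np.where(gt == 3, 2.0, gt.astype(float))
            row[gt == 2] = np.nan
        if len(row) != len(samples):
            raise ValueError(f"malformed genotype row at record {i} of {path}")
        snp_ids.append(vid)
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0] if variant.ALT else ".")
        dosage_rows.append(row)
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, np.int64), "ref": refs, "alt": alts},
        index=snp_ids,
    )
    dosages = pd.DataFrame(np.asarray(dosage_rows).T, index=samples, columns=snp_ids)
    return GenotypeTable(dosages, meta)


def read_genotypes(path, format: str | None = None) -> GenotypeTable:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the suffix if None)."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------- matrices

def write_matrix_tsv(values: pd.DataFrame, path, index_name: str = "feature_id") -> None:
    out = values.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_expression(expr: ExpressionTable, values_path, detection_path=None) -> None:
    write_matrix_tsv(expr.values, values_path, "probe_id")
    if detection_path is not None and expr.detection_p is not None:
        write_matrix_tsv(expr.detection_p, detection_path, "probe_id")


def read_expression(values_path, detection_path=None) -> ExpressionTable:
    values = read_matrix_tsv(values_path)
    detection = read_matrix_tsv(detection_path) if detection_path else None
    return ExpressionTable(values, detection)


# --------------------------------------------------------------- annotation

def write_annotation(annotation: GeneAnnotation, path) -> None:
    out = annotation.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="probe_id")
    table["chrom"] = table["chrom"].astype(str)
    for col in ("multi_mapped", "contains_common_snp"):
        if col not in table.columns:
            table[col] = False
        table[col] = table[col].astype(bool)
    return GeneAnnotation(table)


# --------------------------------------------------------------------- BED

def read_bed(path, mark: str | None = None) -> PeakSet:
    """BED3+ reader; intervals stay 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append({"chrom": chrom, "start": start, "end": end})
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(mark or Path(str(path)).stem, intervals)


def write_bed(peaks: PeakSet, path) -> None:
    peaks.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ------------------------------------------------------------- trait lists

def read_trait_lists(path, universe=None) -> dict[str, TraitSnpList]:
    """TSV with ``trait`` and ``snp_id`` columns (optional ``source``).

    Duplicate (trait, snp) rows are deduplicated.  When ``universe`` is
    given, SNPs outside it are dropped with a logged count per trait.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"trait", "snp_id"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(table.columns)}"
        )
    lists: dict[str, TraitSnpList] = {}
    for trait, sub in table.groupby("trait", sort=False):
        source = sub["source"].iloc[0] if "source" in sub.columns else ""
        tl = TraitSnpList(trait, list(sub["snp_id"]), source if pd.notna(source) else "")
        if universe is not None:
            tl, n_dropped = tl.restrict_to_universe(universe)
            if n_dropped:
                logger.warning(
                    "trait %s: dropped %d SNPs outside the analysis universe", trait, n_dropped
                )
        lists[trait] = tl
    return lists


def write_trait_lists(lists: dict[str, TraitSnpList], path) -> None:
    rows = [
        {"trait": tl.trait, "snp_id": s, "source": tl.source}
        for tl in lists.values()
        for s in tl.snp_ids
    ]
    pd.DataFrame(rows, columns=["trait", "snp_id", "source"]).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------- results

def write_results(results: pd.DataFrame, path) -> None:
    """Association table with the stable column order."""
    from .eqtl import RESULT_COLUMNS

    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
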