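"""Core in-memory containers shared by every pipeline stage.

Conventions enforced here and relied on everywhere else:

* SNP positions are 1-based (VCF convention). BED intervals are converted to
  this convention exactly once, in :mod:`coloneqtl.io`.
* Genotypes are allelic dosages in ``[0, 2]`` (expected count of the
  alternate allele); missing values are ``NaN``, never 0.
* Expression matrices are probes x samples; genotype matrices are
  individuals x SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

SNP_META_COLUMNS = ["chrom", "pos", "ref", "alt", "info_score"]


def is_autosome(chrom: str) -> bool:
    return str(chrom) in AUTOSOMES


@dataclass
class GenotypeTable:
    """Dosage matrix (individuals x SNPs) plus per-SNP metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample_id with one column per snp_id; values in
        ``[0, 2]`` or ``NaN`` for missing.
    snps
        DataFrame indexed by snp_id with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` and optional ``info_score`` in ``[0, 1]``.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.snps.index.is_unique:
            dups = self.snps.index[self.snps.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate snp_ids: {dups[:5]}")
        if list(self.dosages.columns) != list(self.snps.index):
            self.dosages = self.dosages.loc[:, self.snps.index]
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")
        # canonical order: position-sorted within chromosome
        order = self.snps.sort_values(["chrom", "pos"], kind="stable").index
        if not order.equals(self.snps.index):
            self.snps = self.snps.loc[order]
            self.dosages = self.dosages.loc[:, order]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, snp_ids) -> "GenotypeTable":
        snp_ids = list(snp_ids)
        return GenotypeTable(self.dosages.loc[:, snp_ids].copy(), self.snps.loc[snp_ids].copy())

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        return self.dosages[snp_id].to_numpy(dtype=float)

    def hard_calls(self) -> pd.DataFrame:
        """Round dosages to {0,1,2} genotype calls, half away from zero."""
        vals = self.dosages.to_numpy(dtype=float)
        calls = np.floor(vals + 0.5)
        return pd.DataFrame(calls, index=self.dosages.index, columns=self.dosages.columns)


@dataclass
class GeneAnnotation:
    """Probe/gene annotation: positions, strand and QC flags.

    ``table`` is indexed by probe_id with columns ``gene_id``, ``chrom``,
    ``strand`` ('+'/'-'), ``tss``, ``tes`` (both 1-based bp), and boolean
    flags ``multi_mapped`` and ``contains_common_snp``.  For '+' genes
    tss <= tes; for '-' genes tss >= tes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("probe_ids must be unique")
        plus = self.table["strand"] == "+"
        bad = (plus & (self.table["tss"] > self.table["tes"])) | (
            ~plus & (self.table["tss"] < self.table["tes"])
        )
        if bad.any():
            raise ValueError(f"tss/tes inconsistent with strand for {list(self.table.index[bad])[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def gene_start_end(self) -> pd.DataFrame:
        """Strand-agnostic gene body bounds: start = min(tss, tes), end = max."""
        t = self.table
        return pd.DataFrame(
            {
                "chrom": t["chrom"],
                "start": np.minimum(t["tss"], t["tes"]),
                "end": np.maximum(t["tss"], t["tes"]),
            },
            index=t.index,
        )


@dataclass
class ExpressionTable:
    """Expression values and detection p-values, probes x samples."""

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("values and detection_p shapes differ")
            self.detection_p = self.detection_p.loc[self.values.index, self.values.columns]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_probes(self, probe_ids) -> "ExpressionTable":
        probe_ids = list(probe_ids)
        det = None if self.detection_p is None else self.detection_p.loc[probe_ids].copy()
        return ExpressionTable(self.values.loc[probe_ids].copy(), det)

    def subset_samples(self, sample_ids) -> "ExpressionTable":
        sample_ids = list(sample_ids)
        det = None if self.detection_p is None else self.detection_p[sample_ids].copy()
        return ExpressionTable(self.values[sample_ids].copy(), det)


@dataclass
class PeakSet:
    """Named set of genomic intervals (0-based half-open, BED convention)."""

    mark: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions in the (merged) peak intervals."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        for c, sub in self.intervals.groupby("chrom"):
            sel = chrom == c
            if not sel.any():
                continue
            starts, ends = _merge_intervals(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            )
            # 1-based pos p lies in a half-open interval iff start <= p-1 < end
            zero_based = pos[sel] - 1
            idx = np.searchsorted(starts, zero_based, side="right") - 1
            hit = np.zeros(int(sel.sum()), dtype=bool)
            valid = idx >= 0
            hit[valid] = zero_based[valid] < ends[idx[valid]]
            out[sel] = hit
        return out


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_start, m_end = [], []
    for s, e in zip(starts, ends):
        if m_end and s <= m_end[-1]:
            m_end[-1] = max(m_end[-1], e)
        else:
            m_start.append(s)
            m_end.append(e)
    return np.asarray(m_start, dtype=np.int64), np.asarray(m_end, dtype=np.int64)


@dataclass
class TraitSnpList:
    """SNPs reported as associated with one trait (GWAS-catalog style)."""

    trait: str
    snp_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.snp_ids:
            seen.setdefault(s, None)
        self.snp_ids = list(seen)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def restrict_to_universe(self, universe) -> tuple["TraitSnpList", int]:
        """Drop SNPs outside the analysis universe; return (new list, n dropped)."""
        uni = set(universe)
        kept = [s for s in self.snp_ids if s in uni]
        return TraitSnpList(self.trait, kept, self.source), len(self.snp_ids) - len(kept)


@dataclass
class CovariateSet:
    """Per-sample covariates (genotype PC1 ancestry proxy, expression PCs)."""

    table: pd.DataFrame  # samples x covariates

    def __post_init__(self) -> None:
        if len(self.table):
            mat = self.table.to_numpy(dtype=float)
            if mat.shape[1] and np.linalg.matrix_rank(mat) < mat.shape[1]:
                raise ValueError("covariate columns are linearly dependent")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def matrix(self, sample_ids=None) -> np.ndarray:
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return t.to_numpy(dtype=float)

    @staticmethod
    def empty(sample_ids) -> "CovariateSet":
        return CovariateSet(pd.DataFrame(index=list(sample_ids)))
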