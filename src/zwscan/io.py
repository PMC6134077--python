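"""Genotype, marker-map and phenotype file handling.

The on-disk layout mirrors the three supplementary files deposited with
ZW-fish sex-reversal studies: a phenotype TSV (id, sire, dam, genetic_sex,
phenotypic_sex, reversal), a genotype TSV (rows = individuals, columns =
markers, additive 0/1/2 coding with ``NA`` for missing) and a marker-map TSV
(marker_id, chromosome, position_bp, alleles).  A small VCF 4.2 subset is
supported for biallelic SNP input/output.

Internally genotypes are held as a float matrix with ``numpy.nan`` as the
missing sentinel; observed calls are always integers in {0, 1, 2}, counting
copies of the alternate allele.  Hemizygous Z-linked calls in ZW individuals
are carried on the diploid scale (0 or 2, never 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical chromosome ordering: autosomes 1..20, then the sex chromosomes.
CHROM_ORDER: list[str] = [str(c) for c in range(1, 21)] + ["W", "Z"]

MAP_COLUMNS = ["marker_id", "chromosome", "position_bp", "alleles"]
PHENO_COLUMNS = ["id", "sire", "dam", "genetic_sex", "phenotypic_sex", "reversal"]


def chrom_sort_key(label: str) -> tuple[int, int | str]:
    """Sort key placing numeric chromosomes first, then W, then Z."""
    s = str(label)
    if s in CHROM_ORDER:
        return (0, CHROM_ORDER.index(s))
    return (1, s)


@dataclass
class GenotypeData:
    """Individuals x markers additive genotype matrix tied to a marker map.

    Parameters
    ----------
    values
        Float array of shape ``(n_individuals, n_markers)``; entries in
        {0, 1, 2} or ``nan`` (missing).
    individual_ids
        One id per row, unique.
    marker_map
        DataFrame with columns ``marker_id, chromosome, position_bp,
        alleles`` (alleles as ``"REF/ALT"``), one row per matrix column,
        sorted by chromosome then position.
    """

    values: np.ndarray
    individual_ids: list[str]
    marker_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        n_ind, n_mark = self.values.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError(
                f"{len(self.individual_ids)} ids for {n_ind} genotype rows"
            )
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("individual ids are not unique")
        if len(self.marker_map) != n_mark:
            raise ValueError(
                f"marker map has {len(self.marker_map)} rows for "
                f"{n_mark} genotype columns"
            )
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = np.unique(obs[~np.isin(obs, (0.0, 1.0, 2.0))])
            raise ValueError(f"genotype codes outside {{0,1,2,NA}}: {bad[:5]}")
        self.marker_map = self.marker_map.reset_index(drop=True)

    # -- convenience ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.marker_map["marker_id"].tolist()

    def marker_index(self, marker_id: str) -> int:
        idx = self.marker_map.index[self.marker_map["marker_id"] == marker_id]
        if len(idx) != 1:
            raise KeyError(f"marker {marker_id!r} not found (or duplicated)")
        return int(idx[0])

    def select_markers(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            keep = np.zeros(self.n_markers, dtype=bool)
            keep[mask] = True
            mask = keep
        return GenotypeData(
            self.values[:, mask],
            list(self.individual_ids),
            self.marker_map.loc[mask].reset_index(drop=True),
        )

    def select_individuals(self, ids: Sequence[str]) -> "GenotypeData":
        pos = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [pos[str(i)] for i in ids]
        return GenotypeData(
            self.values[rows], [str(i) for i in ids], self.marker_map.copy()
        )


def _validate_marker_map(mm: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MAP_COLUMNS if c not in mm.columns]
    if missing:
        raise ValueError(f"marker map missing columns {missing}")
    mm = mm.copy()
    mm["chromosome"] = mm["chromosome"].astype(str)
    mm["position_bp"] = mm["position_bp"].astype(int)
    if (mm["position_bp"] <= 0).any():
        raise ValueError("marker positions must be positive (1-based bp)")
    if mm.duplicated(subset=["chromosome", "position_bp"]).any():
        raise ValueError("duplicate (chromosome, position) in marker map")
    return mm.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_marker_map(path: str | Path) -> pd.DataFrame:
    return _validate_marker_map(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_marker_map(mm: pd.DataFrame, path: str | Path) -> None:
    _validate_marker_map(mm)[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    ph = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    missing = [c for c in PHENO_COLUMNS if c not in ph.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    if ph["id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    if not ph["reversal"].isin([0, 1]).all():
        raise ValueError("reversal indicator must be 0/1")
    return ph


def write_phenotypes(ph: pd.DataFrame, path: str | Path) -> None:
    ph[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(geno_path: str | Path, map_path: str | Path) -> GenotypeData:
    """Read the genotype TSV (first column ``id``, then one column per marker)."""
    mm = read_marker_map(map_path)
    df = pd.read_csv(geno_path, sep="\t", index_col=0, na_values=["NA"])
    if list(df.columns) != mm["marker_id"].tolist():
        raise ValueError("genotype columns do not match the marker map order")
    return GenotypeData(df.to_numpy(dtype=float), [str(i) for i in df.index], mm)


def write_genotypes_tsv(
    data: GenotypeData, geno_path: str | Path, map_path: str | Path | None = None
) -> None:
    df = pd.DataFrame(
        data.values, index=pd.Index(data.individual_ids, name="id"),
        columns=data.marker_ids,
    )
    # integers with literal NA for missing
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(geno_path, sep="\t")
    if map_path is not None:
        write_marker_map(data.marker_map, map_path)


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path: str | Path) -> GenotypeData:
    """Read biallelic SNP records from a VCF into additive coding.

    GT fields are mapped to alternate-allele counts (``0/1`` -> 1, ``./.``
    -> missing).  Non-biallelic records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping non-biallelic record %s:%s", var.CHROM, var.POS
            )
            continue
        g = var.gt_types.astype(float)  # 0=hom ref,1=het,2=hom alt,3=unknown
        g[g == 3] = np.nan
        cols.append(g)
        rows.append(
            {
                "marker_id": var.ID or f"{var.CHROM}_{var.POS}",
                "chromosome": str(var.CHROM),
                "position_bp": int(var.POS),
                "alleles": f"{var.REF}/{var.ALT[0]}",
            }
        )
    vcf.close()
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    mm = _validate_marker_map(pd.DataFrame(rows))
    return GenotypeData(np.column_stack(cols), samples, mm)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(
    data: GenotypeData,
    path: str | Path,
    hemizygous_chroms: Iterable[str] = ("Z", "W"),
) -> None:
    """Write a minimal VCF 4.2 file.

    Hemizygous sex-chromosome genotypes are stored as homozygous diploid
    calls; records on those chromosomes carry the ``HEMI`` INFO flag so the
    convention is explicit in the file.
    """
    hemi = {str(c) for c in hemizygous_chroms}
    mm = data.marker_map
    chroms = list(dict.fromkeys(mm["chromosome"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zwscan\n")
        fh.write(
            '##INFO=<ID=HEMI,Number=0,Type=Flag,'
            'Description="Hemizygous locus coded as homozygous diploid">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.individual_ids)
            + "\n"
        )
        for j, row in mm.iterrows():
            ref, alt = str(row["alleles"]).split("/")
            info = "HEMI" if row["chromosome"] in hemi else "."
            gts = "\t".join(
                "./." if np.isnan(v) else _GT[v] for v in data.values[:, j]
            )
            fh.write(
                f"{row['chromosome']}\t{row['position_bp']}\t{row['marker_id']}"
                f"\t{ref}\t{alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_genotypes(
    path: str | Path, format: str = "tsv", map_path: str | Path | None = None
) -> GenotypeData:
    """Dispatching reader; ``format`` is ``"tsv"`` (requires map_path) or ``"vcf"``."""
    if format == "tsv":
        if map_path is None:
            raise ValueError("TSV genotypes require a marker-map path")
        return read_genotypes_tsv(path, map_path)
    if format == "vcf":
        return read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(
    data: GenotypeData,
    path: str | Path,
    format: str = "tsv",
    map_path: str | Path | None = None,
) -> None:
    if format == "tsv":
        write_genotypes_tsv(data, path, map_path)
    elif format == "vcf":
        write_genotypes_vcf(data, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
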