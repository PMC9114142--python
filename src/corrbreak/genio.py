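"""Genotype I/O and marker quality control.

The package's native interchange format is a dosage TSV (rows = individuals,
columns = markers, alt-allele counts 0/1/2, ``NA`` for missing) together with
a marker-map TSV (marker, scaffold, pos_bp).  VCF is supported as read-only
ingest of the GT field.  QC follows the usual exome-capture SNP pipeline:
markers are filtered on minor allele frequency and remaining missing cells
are mean-imputed (fractional values are kept; heterozygosity and IBS
statistics later ignore imputed cells, because an observed-heterozygosity
call on a fractional dosage is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix with a scaffold/position map.

    Parameters
    ----------
    individual_ids : array of str
        Row labels, unique.
    marker_ids : array of str
        Column labels, unique.
    dosages : ndarray, shape (n, m)
        Alt-allele dosages; ``np.nan`` marks missing calls.  After
        imputation values may be fractional in [0, 2].
    marker_map : DataFrame
        Indexed by marker id with columns ``scaffold`` and ``pos_bp``.
    population : array of str, optional
        Per-individual population tag.
    imputed : boolean ndarray, same shape as ``dosages``, optional
        Marks cells that were filled by imputation (not hard calls).
    """

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    marker_map: pd.DataFrame
    population: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id vectors")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        missing_in_map = set(self.marker_ids) - set(self.marker_map.index)
        if missing_in_map:
            raise ValueError(f"markers absent from map: {sorted(missing_in_map)[:5]}")
        # align map to marker order
        self.marker_map = self.marker_map.loc[list(self.marker_ids)]
        if (self.marker_map["pos_bp"] < 0).any():
            raise ValueError("negative bp positions in marker map")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def hard_call_mask(self) -> np.ndarray:
        """Boolean mask of cells that are genuine (non-missing, non-imputed) calls."""
        mask = ~np.isnan(self.dosages)
        if self.imputed is not None:
            mask &= ~self.imputed
        return mask

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per marker from observed calls only."""
        mask = self.hard_call_mask()
        with np.errstate(invalid="ignore"):
            counts = np.where(mask, self.dosages, 0.0).sum(axis=0)
            nobs = mask.sum(axis=0)
        freqs = np.full(self.n_markers, np.nan)
        ok = nobs > 0
        freqs[ok] = counts[ok] / (2.0 * nobs[ok])
        return freqs

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = {i: k for k, i in enumerate(self.individual_ids)}
        rows = np.array([idx[i] for i in ids], dtype=int)
        return GenotypeMatrix(
            individual_ids=self.individual_ids[rows],
            marker_ids=self.marker_ids.copy(),
            dosages=self.dosages[rows].copy(),
            marker_map=self.marker_map.copy(),
            population=None if self.population is None else np.asarray(self.population)[rows],
            imputed=None if self.imputed is None else self.imputed[rows].copy(),
        )

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = {m: k for k, m in enumerate(self.marker_ids)}
        cols = np.array([idx[m] for m in marker_ids], dtype=int)
        return GenotypeMatrix(
            individual_ids=self.individual_ids.copy(),
            marker_ids=self.marker_ids[cols],
            dosages=self.dosages[:, cols].copy(),
            marker_map=self.marker_map.iloc[cols].copy(),
            population=None if self.population is None else np.asarray(self.population).copy(),
            imputed=None if self.imputed is None else self.imputed[:, cols].copy(),
        )

    def by_population(self, tag: str) -> "GenotypeMatrix":
        if self.population is None:
            raise ValueError("no population tags present")
        ids = self.individual_ids[np.asarray(self.population) == tag]
        if len(ids) == 0:
            raise ValueError(f"no individuals tagged {tag!r}")
        return self.subset_individuals(ids)


@dataclass
class MarkerQCReport:
    n_input: int
    n_removed_maf: int
    n_removed_all_missing: int
    n_imputed_cells: int
    allele_freqs: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_maf - self.n_removed_all_missing

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_all_missing": self.n_removed_all_missing,
            "n_retained": self.n_retained,
            "n_imputed_cells": self.n_imputed_cells,
        }


def read_dosages(path, map_path, missing_token: str = MISSING_TOKEN) -> GenotypeMatrix:
    """Read a dosage TSV plus marker map into a :class:`GenotypeMatrix`.

    The TSV must have a header of marker ids with a leading id column and one
    row per individual.  Any token outside {0, 1, 2, missing} is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    values = np.full(df.shape, np.nan)
    valid = {"0": 0.0, "1": 1.0, "2": 2.0}
    arr = df.to_numpy()
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            tok = arr[r, c].strip()
            if tok == missing_token:
                continue
            if tok not in valid:
                raise ValueError(
                    f"invalid dosage token {tok!r} at individual {df.index[r]!r}, "
                    f"marker {df.columns[c]!r}"
                )
            values[r, c] = valid[tok]
    marker_map = read_marker_map(map_path)
    return GenotypeMatrix(
        individual_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        dosages=values,
        marker_map=marker_map,
    )


def write_dosages(g: GenotypeMatrix, path, missing_token: str = MISSING_TOKEN) -> None:
    """Write hard-called dosages as TSV (imputed/fractional cells written as-is)."""
    def fmt(v):
        if np.isnan(v):
            return missing_token
        if float(v).is_integer():
            return str(int(v))
        return repr(float(v))

    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, g.marker_ids)) + "\n")
        for i, ind in enumerate(g.individual_ids):
            fh.write(str(ind) + "\t" + "\t".join(fmt(v) for v in g.dosages[i]) + "\n")


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, sep="\t", dtype={"marker": str, "scaffold": str, "pos_bp": int})
    return mm.set_index("marker")


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.reset_index().rename(columns={"index": "marker"}).to_csv(
        path, sep="\t", index=False
    )


def read_vcf(path) -> GenotypeMatrix:
    """Ingest biallelic SNPs from a VCF into alt-allele dosages.

    Multi-allelic records and non-SNP ALTs are skipped (and counted on the
    returned object's ``marker_map.attrs['n_skipped']``); ``./.`` genotypes
    become missing.  CHROM maps to scaffold, POS (1-based) to position.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    marker_ids, scaffolds, positions, rows = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        scaffolds.append(rec.CHROM)
        positions.append(rec.POS)
        rows.append(dos)
    marker_map = pd.DataFrame(
        {"scaffold": scaffolds, "pos_bp": positions},
        index=pd.Index(marker_ids, name="marker"),
    )
    marker_map.attrs["n_skipped"] = n_skipped
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(
        individual_ids=samples,
        marker_ids=np.array(marker_ids, dtype=object),
        dosages=dosages,
        marker_map=marker_map,
    )


def maf_filter(g: GenotypeMatrix, threshold: float = 0.01) -> tuple[GenotypeMatrix, MarkerQCReport]:
    """Remove markers with minor allele frequency <= ``threshold``.

    The strict ``MAF > threshold`` retention rule is used; frequencies come
    from observed calls only.  All-missing markers are removed and counted
    separately.
    """
    freqs = g.allele_freqs()
    all_missing = np.isnan(freqs)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1.0 - freqs)
    keep = ~all_missing & (maf > threshold)
    n_removed_maf = int((~keep & ~all_missing).sum())
    out = g.subset_markers(g.marker_ids[keep])
    report = MarkerQCReport(
        n_input=g.n_markers,
        n_removed_maf=n_removed_maf,
        n_removed_all_missing=int(all_missing.sum()),
        n_imputed_cells=0,
        allele_freqs={m: float(f) for m, f in zip(g.marker_ids[keep], freqs[keep])},
    )
    return out, report


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing cells with the marker's mean observed dosage.

    Imputed values stay fractional; the returned matrix records which cells
    were imputed so downstream hard-call statistics can ignore them.
    """
    missing = np.isnan(g.dosages)
    if not missing.any():
        return replace(
            g,
            dosages=g.dosages.copy(),
            imputed=np.zeros_like(g.dosages, dtype=bool) if g.imputed is None else g.imputed.copy(),
        )
    nobs = (~missing).sum(axis=0)
    if (nobs == 0).any():
        bad = g.marker_ids[nobs == 0]
        raise ValueError(f"all-missing markers (filter first): {list(bad[:5])}")
    col_means = np.where(missing, 0.0, g.dosages).sum(axis=0) / nobs
    dosages = np.where(missing, col_means[None, :], g.dosages)
    imputed = missing if g.imputed is None else (missing | g.imputed)
    return replace(g, dosages=dosages, imputed=imputed)


# ---------------------------------------------------------------------------
# pedigree / phenotype / label tables

def read_pedigree(path) -> pd.DataFrame:
    """Pedigree TSV: id, sire, dam; founders have blank parents."""
    ped = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ped = ped.replace({"": None})
    return ped[["id", "sire", "dam"]]


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.fillna("").to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    """Label TSV: first column genotype id, column ``breaker`` holding 0/1."""
    df = pd.read_csv(path, sep="\t", dtype={"breaker": int})
    return df.set_index(df.columns[0])["breaker"]
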