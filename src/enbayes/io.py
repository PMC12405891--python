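"""Genotype, phenotype and prediction I/O plus marker quality control.

Containers
----------
:class:`GenotypeMatrix`
    Lines x markers matrix of alternate-allele dosages in [0, 2] (0/1/2 SNP
    codes, or fractional dosages after mean imputation).  This is the design
    matrix ``Z`` of the whole-genome regression ``y = mu*1 + Z u + e``.
:class:`PhenotypeVector`
    One trait value per line.
:class:`Dataset`
    A genotype matrix and phenotype vector over the same lines in the same
    order; what the Bayesian regressions consume.
:class:`PredictionMatrix`
    Lines x models matrix of predicted phenotypes; what ensemble weights act
    on.

File formats are plain delimited text (tab or comma, auto-detected): genotype
files have a header row of marker IDs and a first column of line IDs;
phenotype files are two columns (line ID, value) with a header; prediction
files have a header row of model names.  VCF genotype import converts each
call to its alternate-allele count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError, ValidationError

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "Dataset",
    "PredictionMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_predictions",
    "write_predictions",
    "maf_filter",
    "align",
]


def _as_id_array(ids, what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    if len(set(arr)) != arr.size:
        dupes = sorted({x for x in arr if list(arr).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return arr


@dataclass
class GenotypeMatrix:
    """Aligned lines x markers dosage matrix with identifiers.

    Invariants: no missing values, all dosages in [0, 2], unique line and
    marker identifiers.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = _as_id_array(self.line_ids, "line_ids")
        self.marker_ids = _as_id_array(self.marker_ids, "marker_ids")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (self.line_ids.size, self.marker_ids.size):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{self.line_ids.size} lines x {self.marker_ids.size} markers"
            )
        if not np.isfinite(self.dosages).all():
            raise ValidationError(
                "genotype matrix contains missing/non-finite values; "
                "load with impute=True or clean the file"
            )
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            bad = np.argwhere((self.dosages < 0) | (self.dosages > 2))[0]
            raise ValidationError(
                f"dosage outside [0, 2] at line {self.line_ids[bad[0]]!r}, "
                f"marker {self.marker_ids[bad[1]]!r}"
            )

    @property
    def n_lines(self) -> int:
        return self.line_ids.size

    @property
    def n_markers(self) -> int:
        return self.marker_ids.size

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker alternate-allele frequency f = mean(dosage) / 2."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency min(f, 1 - f), orientation-invariant."""
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)


@dataclass
class PhenotypeVector:
    """One finite trait value per (uniquely identified) line."""

    line_ids: np.ndarray
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.line_ids = _as_id_array(self.line_ids, "line_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.line_ids.size,):
            raise ValidationError("phenotype values must be one value per line")
        if not np.isfinite(self.values).all():
            raise ValidationError("phenotype contains non-finite values")

    @property
    def n_lines(self) -> int:
        return self.line_ids.size


@dataclass
class Dataset:
    """Genotypes and a phenotype over identical lines in identical order."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector

    def __post_init__(self) -> None:
        if not np.array_equal(self.genotypes.line_ids, self.phenotype.line_ids):
            raise ValidationError(
                "genotype and phenotype line_ids differ; use align() first"
            )

    @property
    def n_lines(self) -> int:
        return self.genotypes.n_lines

    @property
    def n_markers(self) -> int:
        return self.genotypes.n_markers

    def subset(self, rows: np.ndarray) -> "Dataset":
        """Row-subset (e.g. a cross-validation fold) preserving order."""
        g = GenotypeMatrix(
            self.genotypes.line_ids[rows],
            self.genotypes.marker_ids,
            self.genotypes.dosages[rows],
        )
        y = PhenotypeVector(
            self.phenotype.line_ids[rows],
            self.phenotype.values[rows],
            self.phenotype.trait_name,
        )
        return Dataset(g, y)


@dataclass
class PredictionMatrix:
    """Lines x models matrix of predicted phenotypes (one column per model)."""

    line_ids: np.ndarray
    model_names: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = _as_id_array(self.line_ids, "line_ids")
        self.model_names = _as_id_array(self.model_names, "model_names")
        if self.model_names.size < 1:
            raise ValidationError("prediction matrix needs at least one model")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.line_ids.size, self.model_names.size):
            raise ValidationError(
                f"prediction shape {self.values.shape} does not match ids"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("prediction matrix contains non-finite values")

    @property
    def n_models(self) -> int:
        return self.model_names.size

    def select_models(self, names) -> "PredictionMatrix":
        names = list(names)
        idx = []
        lookup = {m: i for i, m in enumerate(self.model_names)}
        for name in names:
            if name not in lookup:
                raise ValidationError(f"unknown model column {name!r}")
            idx.append(lookup[name])
        return PredictionMatrix(self.line_ids, np.array(names, dtype=object),
                                self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.model_names)


# ---------------------------------------------------------------------------
# delimited I/O


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_matrix_frame(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0,
                         na_values=["NA", "NaN", ""],
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:  # message carries the line number
        raise ParseError(f"{path}: {exc}") from exc
    # locate non-numeric cells so the error can name the line
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric value on data line {row + 2} "
            f"(line ID {df.index[row]!r})"
        )
    numeric.index = df.index.astype(str)
    numeric.columns = df.columns.astype(str)
    return numeric


def read_genotypes(
    path: str,
    format: str = "delimited",
    impute: bool = False,
    rescale_01_to_02: bool = False,
    max_markers: int | None = None,
) -> GenotypeMatrix:
    """Load a genotype dosage matrix from delimited text or VCF.

    Parameters
    ----------
    path:
        Delimited file (header = marker IDs, first column = line IDs) or a
        VCF.  VCF calls are converted to alternate-allele counts.
    impute:
        Replace missing cells with the per-marker mean of observed dosages.
        With ``impute=False`` missing data raises :class:`ValidationError`.
    rescale_01_to_02:
        Double all dosages (for files coded 0/0.5/1 instead of 0/1/2).
    max_markers:
        Keep only the first ``max_markers`` columns (never applied by
        default; opt-in for very wide marker sets).
    """
    if format == "delimited":
        df = _read_matrix_frame(path)
        line_ids, marker_ids = df.index.to_numpy(object), df.columns.to_numpy(object)
        dosages = df.to_numpy(float)
    elif format == "vcf":
        line_ids, marker_ids, dosages = _read_vcf_dosages(path)
    else:
        raise ValidationError(f"unknown genotype format {format!r}")

    if rescale_01_to_02:
        dosages = dosages * 2.0
    if max_markers is not None:
        marker_ids = marker_ids[:max_markers]
        dosages = dosages[:, :max_markers]
    if np.isnan(dosages).any():
        if not impute:
            raise ValidationError(
                f"{path}: missing genotype calls present; pass impute=True "
                "for per-marker mean imputation"
            )
        col_mean = np.nanmean(dosages, axis=0)
        nan_rows, nan_cols = np.nonzero(np.isnan(dosages))
        dosages[nan_rows, nan_cols] = col_mean[nan_cols]
    return GenotypeMatrix(line_ids, marker_ids, dosages)


def _read_vcf_dosages(path: str):
    from cyvcf2 import VCF  # heavy import kept local

    vcf = VCF(path)
    line_ids = np.array(vcf.samples, dtype=object)
    marker_ids, columns = [], []
    for variant in vcf:
        vid = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}"
        )
        col = np.empty(line_ids.size)
        for i, call in enumerate(variant.genotypes):
            alleles = [a for a in call[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = sum(1 for a in alleles if a > 0)
        marker_ids.append(vid)
        columns.append(col)
    vcf.close()
    if not marker_ids:
        raise ParseError(f"{path}: VCF contains no variant records")
    return line_ids, np.array(marker_ids, dtype=object), np.column_stack(columns)


def write_genotypes(g: GenotypeMatrix, path: str, sep: str = "\t") -> None:
    g.to_frame().to_csv(path, sep=sep, index_label="line_id",
                        float_format="%.17g")


def read_phenotype(path: str) -> PhenotypeVector:
    """Two-column delimited file (line ID, value) with a header row."""
    df = _read_matrix_frame(path)
    if df.shape[1] != 1:
        raise ParseError(
            f"{path}: expected 2 columns (line ID, value); got {df.shape[1] + 1}"
        )
    return PhenotypeVector(df.index.to_numpy(object), df.iloc[:, 0].to_numpy(float),
                           trait_name=str(df.columns[0]))


def write_phenotype(y: PhenotypeVector, path: str, sep: str = "\t") -> None:
    pd.DataFrame({y.trait_name: y.values}, index=y.line_ids).to_csv(
        path, sep=sep, index_label="line_id", float_format="%.17g"
    )


def read_predictions(path: str) -> PredictionMatrix:
    df = _read_matrix_frame(path)
    return PredictionMatrix(df.index.to_numpy(object), df.columns.to_numpy(object),
                            df.to_numpy(float))


def write_predictions(p: PredictionMatrix, path: str, sep: str = "\t") -> None:
    """Write line IDs plus one column per model; round-trips exactly."""
    p.to_frame().to_csv(path, sep=sep, index_label="line_id",
                        float_format="%.17g")


# ---------------------------------------------------------------------------
# quality control and alignment


def maf_filter(
    g: GenotypeMatrix, threshold: float = 0.05
) -> tuple[GenotypeMatrix, list]:
    """Drop markers with minor-allele frequency below ``threshold``.

    MAF is computed symmetrically as min(f, 1 - f) with f = mean(dosage)/2,
    so the filter is invariant to reference/alternate orientation.  Column
    order of retained markers is preserved.  Returns the filtered matrix and
    the list of removed marker IDs.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValidationError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    keep = g.maf() >= threshold
    removed = list(g.marker_ids[~keep])
    filtered = GenotypeMatrix(g.line_ids, g.marker_ids[keep], g.dosages[:, keep])
    return filtered, removed


@dataclass
class AlignmentReport:
    """Line IDs dropped from either side when intersecting genotype/phenotype."""

    dropped_genotype_ids: list = field(default_factory=list)
    dropped_phenotype_ids: list = field(default_factory=list)


def align(
    g: GenotypeMatrix, y: PhenotypeVector
) -> tuple[Dataset, AlignmentReport]:
    """Restrict genotypes and phenotype to their common lines, in one order.

    The canonical order is the genotype row order restricted to the
    intersection.  Raises :class:`AlignmentError` when no line is shared.
    """
    common = set(g.line_ids) & set(y.line_ids)
    if not common:
        raise AlignmentError("genotype and phenotype share no line IDs")
    keep = np.array([lid in common for lid in g.line_ids])
    order = g.line_ids[keep]
    y_lookup = {lid: i for i, lid in enumerate(y.line_ids)}
    y_idx = np.array([y_lookup[lid] for lid in order])
    ds = Dataset(
        GenotypeMatrix(order, g.marker_ids, g.dosages[keep]),
        PhenotypeVector(order, y.values[y_idx], y.trait_name),
    )
    report = AlignmentReport(
        dropped_genotype_ids=[lid for lid in g.line_ids if lid not in common],
        dropped_phenotype_ids=[lid for lid in y.line_ids if lid not in common],
    )
    return ds, report
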