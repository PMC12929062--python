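"""Readers, writers and in-memory containers for every external format the pipeline touches.

Coordinate convention: all internal coordinates are 1-based inclusive genomic
base pairs. BED input (0-based half-open) is converted at the boundary and
never leaks inside.

Genotype codes count copies of the *minor* allele (0/1/2). Recoding happens
once, at load time; every downstream module assumes minor-allele counts.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed external file (wrong dialect, multi-allelic VCF record, ...)."""


class SchemaError(ValueError):
    """Header or column contents do not match the requested schema."""


@dataclass
class GenotypeMatrix:
    """sample x marker matrix of minor-allele counts with a 1-based marker map.

    ``codes`` is a float array so that mean imputation of sporadic missing
    calls does not force integer truncation; markers without missingness stay
    exactly {0, 1, 2}.
    """

    sample_ids: list
    marker_ids: list
    codes: np.ndarray  # (n_samples, n_markers)
    map: pd.DataFrame  # columns: marker, chrom, pos (1-based bp)
    imputed_fraction: float = 0.0

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise FormatError("duplicate marker ids")
        if self.codes.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise FormatError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(self.map) != len(self.marker_ids):
            raise FormatError("marker map length mismatch")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise FormatError("genotype codes outside [0, 2]")
        for _, sub in self.map.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise FormatError("marker positions not strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (minor) allele per marker."""
        return np.nanmean(self.codes, axis=0) / 2.0

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            marker_ids=[self.marker_ids[i] for i in keep],
            codes=self.codes[:, keep],
            map=self.map.iloc[keep].reset_index(drop=True),
            imputed_fraction=self.imputed_fraction,
        )

    def subset_samples(self, sample_ids: list) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            marker_ids=self.marker_ids,
            codes=self.codes[rows, :],
            map=self.map,
            imputed_fraction=self.imputed_fraction,
        )


@dataclass
class PlotPhenotype:
    """Replicated field observations: one record per plot."""

    records: pd.DataFrame  # columns: genotype, environment, replicate, block, value

    REQUIRED = ("genotype", "environment", "replicate", "block", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise SchemaError(f"plot phenotype table missing columns {missing}")
        vals = pd.to_numeric(self.records["value"], errors="coerce")
        if vals.isna().any():
            raise SchemaError("non-numeric or missing plot values")
        self.records = self.records.assign(value=vals.astype(float))

    def environment(self, env: str) -> pd.DataFrame:
        sub = self.records[self.records["environment"] == env]
        if sub.empty:
            raise KeyError(f"no records for environment {env!r}")
        return sub.reset_index(drop=True)

    @property
    def environments(self) -> list:
        return sorted(self.records["environment"].unique())


@dataclass
class FeatureMatrix:
    """genotype x feature real matrix (ASV abundance, expression or ionome).

    ``coordinates`` (chrom, start, end; 1-based inclusive) is present iff
    ``feature_kind == "expression"``.
    """

    ids: list
    feature_ids: list
    values: np.ndarray
    feature_kind: str
    coordinates: pd.DataFrame | None = None

    KINDS = ("asv_abundance", "expression", "ionome")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_kind not in self.KINDS:
            raise SchemaError(f"unknown feature kind {self.feature_kind!r}")
        if self.values.shape != (len(self.ids), len(self.feature_ids)):
            raise SchemaError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("feature matrix contains non-finite values")
        if (self.feature_kind == "expression") != (self.coordinates is not None):
            raise SchemaError("coordinates must be present iff feature_kind is expression")
        if self.coordinates is not None:
            need = {"feature", "chrom", "start", "end"}
            if not need.issubset(self.coordinates.columns):
                raise SchemaError("gene coordinates need columns feature, chrom, start, end")
            if len(self.coordinates) != len(self.feature_ids):
                raise SchemaError("one coordinate row per feature required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.feature_ids)

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


# ---------------------------------------------------------------------------
# genotype input


def _finalize_genotypes(sample_ids, marker_ids, codes, gmap) -> GenotypeMatrix:
    """Sort map, recode to minor-allele counts, mean-impute missing calls."""
    gmap = pd.DataFrame(gmap, columns=["marker", "chrom", "pos"])
    order = np.lexsort((gmap["pos"].to_numpy(), gmap["chrom"].astype(str).to_numpy()))
    gmap = gmap.iloc[order].reset_index(drop=True)
    codes = np.asarray(codes, dtype=float)[:, order]
    marker_ids = [marker_ids[i] for i in order]

    dup = gmap.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise FormatError("duplicate marker position within chromosome")

    n_missing = int(np.isnan(codes).sum())
    # counted-allele frequency before recoding; ties (0.5) keep the raw coding
    freq = np.nanmean(codes, axis=0) / 2.0
    flip = freq > 0.5
    codes[:, flip] = 2.0 - codes[:, flip]
    if n_missing:
        col_mean = np.nanmean(codes, axis=0)
        rows, cols = np.nonzero(np.isnan(codes))
        codes[rows, cols] = col_mean[cols]
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        marker_ids=marker_ids,
        codes=codes,
        map=gmap,
        imputed_fraction=n_missing / codes.size,
    )


def _read_genotype_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    marker_ids, codes_cols, gmap = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS}; biallelic SNPs only"
            )
        mid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        if mid in set(marker_ids):
            raise FormatError(f"duplicate marker id {mid!r}")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = variant.gt_types.astype(float)
        col = np.where(gt == 3, 2.0, gt)
        col[gt == 2] = np.nan
        marker_ids.append(mid)
        codes_cols.append(col)
        gmap.append((mid, variant.CHROM, int(variant.POS)))
    if not marker_ids:
        raise FormatError("empty VCF")
    return _finalize_genotypes(sample_ids, marker_ids, np.column_stack(codes_cols), gmap)


def _parse_marker_position(marker_id: str):
    for sep in (":", "_"):
        if sep in marker_id:
            chrom, _, pos = marker_id.rpartition(sep)
            if pos.isdigit():
                return chrom, int(pos)
    return None


def _read_genotype_tsv(path: str) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise FormatError("empty genotype table")
    if len(set(header)) != len(header):
        raise FormatError("duplicate marker id in genotype table header")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise FormatError("empty genotype table")
    codes = df.to_numpy(dtype=float)
    marker_ids = [str(c) for c in df.columns]
    parsed = [_parse_marker_position(m) for m in marker_ids]
    if all(p is not None for p in parsed):
        gmap = [(m, c, p) for m, (c, p) in zip(marker_ids, parsed)]
    else:
        # no positional encoding in the ids: place markers on one pseudo-chromosome
        gmap = [(m, "un", i + 1) for i, m in enumerate(marker_ids)]
    return _finalize_genotypes([str(s) for s in df.index], marker_ids, codes, gmap)


def read_genotype_matrix(path: str, dialect: str = "tsv") -> GenotypeMatrix:
    """Load genotypes from a biallelic VCF or a sample x marker TSV.

    Codes are recoded so the counted allele has frequency <= 0.5 (ties keep
    ALT / the raw coding); missing calls are mean-imputed per marker and the
    imputed fraction recorded on the result.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_genotype_vcf(path)
    if dialect == "tsv":
        return _read_genotype_tsv(path)
    raise FormatError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# tabular input

_TABLE_SCHEMAS = ("plot_phenotype", "asv_counts", "feature_matrix", "bed_coordinates")


def read_table(path: str, schema: str, feature_kind: str = "ionome"):
    """Read one of the pipeline's tabular inputs into its typed container.

    BED input is 0-based half-open on disk and converted to the internal
    1-based inclusive convention here.
    """
    if schema not in _TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {_TABLE_SCHEMAS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise SchemaError(f"empty file: {path}")

    if schema == "bed_coordinates":
        bed = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "feature"],
            dtype={"chrom": str, "feature": str},
        )
        if bed.empty:
            raise SchemaError("empty BED file")
        if not (bed["start"] >= 0).all() or not (bed["end"] > bed["start"]).all():
            raise SchemaError("invalid BED intervals")
        out = bed.assign(start=bed["start"] + 1)  # 0-based half-open -> 1-based inclusive
        return out[["feature", "chrom", "start", "end"]]

    if schema == "plot_phenotype":
        df = pd.read_csv(path, sep="\t", comment="#")
        return PlotPhenotype(records=df)

    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise SchemaError("empty table")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric value in numeric table: {exc}") from exc

    if schema == "asv_counts":
        if (values < 0).any() or not np.allclose(values, np.round(values)):
            raise SchemaError("ASV counts must be non-negative integers")
        return pd.DataFrame(
            values.astype(np.int64), index=[str(s) for s in df.index],
            columns=[str(c) for c in df.columns],
        )

    return FeatureMatrix(
        ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=values,
        feature_kind=feature_kind,
    )


def coordinates_to_bed(coords: pd.DataFrame) -> pd.DataFrame:
    """Inverse of the BED conversion: internal 1-based inclusive -> 0-based half-open."""
    return pd.DataFrame(
        {
            "chrom": coords["chrom"],
            "start": coords["start"] - 1,
            "end": coords["end"],
            "feature": coords["feature"],
        }
    )


# ---------------------------------------------------------------------------
# result output

FLOAT_FORMAT = "%.5e"  # 6 significant digits


def write_results(obj, path: str) -> None:
    """Serialize a result table to TSV with floats at 6 significant digits."""
    if isinstance(obj, FeatureMatrix):
        obj = obj.to_frame().rename_axis("id").reset_index()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    buf = io.StringIO()
    out = obj.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: FLOAT_FORMAT % v)
    out.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
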