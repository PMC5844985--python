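"""Domain containers and file I/O for genotype/phenotype regression.

Genotype dosages are held in a :class:`GenotypeMatrix` (samples x SNPs, raw
entries in {0,1,2} before standardization) together with variant metadata and
per-chromosome window assignments.  Readers accept VCF (GT-based dosages via
cyvcf2) or a plain tab-separated dialect; per-SNP mixture priors and functional
annotations are joined by variant identifier so outputs of external
fine-mapping tools can be supplied directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("mmpen")

__all__ = [
    "GenotypeMatrix",
    "Phenotype",
    "PriorSpec",
    "NoiseModel",
    "AnnotationTable",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_phenotype",
    "write_phenotype_tsv",
    "read_priors",
    "read_annotations",
    "standardize_genotypes",
    "make_windows",
]

ANNOTATION_CATEGORIES = ("Exon", "UTR3", "UTR5", "Intron", "Intergenic", "other")
ENRICHED_CATEGORIES = frozenset({"Exon", "UTR3", "UTR5"})


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """N x n dosage matrix with variant metadata.

    Parameters
    ----------
    dosages : ndarray of shape (N, n)
        Raw entries in {0, 1, 2}, or real values after standardization.
    variant_ids : ndarray of str, shape (n,)
    chromosome : ndarray of str, shape (n,)
    maf : ndarray of float, shape (n,)
        Minor allele frequencies in (0, 0.5].
    standardized : bool
        Whether columns have been centered/scaled.
    window_id : ndarray of int, shape (n,)
        Fitting-window assignment; -1 until :func:`make_windows` runs.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    chromosome: np.ndarray
    maf: np.ndarray
    standardized: bool = False
    window_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D samples x SNPs matrix")
        n_samples, n_snps = self.dosages.shape
        if n_samples < 2 or n_snps < 1:
            raise DataError(f"need N >= 2 samples and n >= 1 SNPs, got {n_samples} x {n_snps}")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        for name, arr in (("variant_ids", self.variant_ids),
                          ("chromosome", self.chromosome),
                          ("maf", self.maf)):
            if arr.shape != (n_snps,):
                raise DataError(f"{name} length {arr.shape} does not match n={n_snps}")
        if self.window_id is None:
            self.window_id = np.full(n_snps, -1, dtype=int)
        else:
            self.window_id = np.asarray(self.window_id, dtype=int)
            if self.window_id.shape != (n_snps,):
                raise DataError("window_id length mismatch")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving order of ``idx``."""
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variant_ids=self.variant_ids[idx],
            chromosome=self.chromosome[idx],
            maf=self.maf[idx],
            standardized=self.standardized,
            window_id=self.window_id[idx],
        )


@dataclass
class Phenotype:
    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 1 or self.sample_ids.shape != self.values.shape:
            raise DataError("phenotype values and sample_ids must be matching 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise DataError("phenotype contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PriorSpec:
    """Per-SNP spike-and-slab mixture prior.

    ``pi1[j]`` is the specified prior probability that SNP j is causal; the
    causal ("slab") component is normal with sd ``slab_sd[j]``; the null
    component is either a narrow normal spike of sd ``null_scale`` or a
    Laplace density of scale ``null_scale`` smoothed for differentiability
    (|b| replaced by sqrt(b^2 + smoothing_eps)).
    """

    pi1: np.ndarray
    slab_sd: np.ndarray
    null_family: str = "normal_spike"
    null_scale: float = 0.01
    smoothing_eps: float = 1e-8

    def __post_init__(self) -> None:
        self.pi1 = np.atleast_1d(np.asarray(self.pi1, dtype=float))
        self.slab_sd = np.atleast_1d(np.asarray(self.slab_sd, dtype=float))
        if self.slab_sd.shape != self.pi1.shape:
            if self.slab_sd.size == 1:
                self.slab_sd = np.full_like(self.pi1, float(self.slab_sd))
            else:
                raise DataError("pi1 and slab_sd length mismatch")
        if np.any((self.pi1 < 0) | (self.pi1 > 1)):
            raise DataError("pi1 must lie in [0, 1]")
        if np.any(self.slab_sd <= 0) or self.null_scale <= 0:
            raise DataError("prior scales must be positive")
        if self.null_family not in ("normal_spike", "laplace"):
            raise DataError(f"unknown null family {self.null_family!r}")
        if self.smoothing_eps < 0:
            raise DataError("smoothing_eps must be nonnegative")

    def __len__(self) -> int:
        return len(self.pi1)

    @classmethod
    def constant(cls, n: int, pi1: float = 0.01, slab_sd: float = 1.0,
                 null_family: str = "normal_spike", null_scale: float = 0.01,
                 smoothing_eps: float = 1e-8) -> "PriorSpec":
        return cls(np.full(n, pi1), np.full(n, slab_sd), null_family,
                   null_scale, smoothing_eps)

    def take(self, idx: np.ndarray) -> "PriorSpec":
        return replace(self, pi1=self.pi1[idx], slab_sd=self.slab_sd[idx])


@dataclass
class NoiseModel:
    """Diagonal residual covariance, one scalar variance per window."""

    sigma2: np.ndarray  # per-window residual variance; NaN until bound to y
    heritability_per_window: float = 0.0

    def __post_init__(self) -> None:
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        finite = self.sigma2[np.isfinite(self.sigma2)]
        if np.any(finite <= 0):
            raise DataError("residual variances must be positive")

    def bind_phenotype(self, y: np.ndarray) -> "NoiseModel":
        """Fill per-window variances as (1 - h2_window) * Var(y)."""
        var_y = float(np.var(np.asarray(y, dtype=float), ddof=1))
        sigma2 = np.full_like(self.sigma2, (1.0 - self.heritability_per_window) * var_y)
        return NoiseModel(sigma2, self.heritability_per_window)


@dataclass
class AnnotationTable:
    variant_ids: np.ndarray
    category: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.category = np.asarray(self.category, dtype=object)
        if self.category.shape != self.variant_ids.shape:
            raise DataError("annotation category length mismatch")
        bad = set(self.category) - set(ANNOTATION_CATEGORIES)
        if bad:
            raise DataError(f"unknown annotation categories: {sorted(bad)}")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise DataError("duplicate variant_ids in annotation table")

    @property
    def enriched(self) -> np.ndarray:
        return np.array([c in ENRICHED_CATEGORIES for c in self.category], dtype=bool)


# ---------------------------------------------------------------------------
# Readers / writers


def _finalize_genotypes(dosages: np.ndarray, variant_ids: list, chroms: list,
                        maf_min: float) -> GenotypeMatrix:
    """Impute missing entries, compute MAF, drop monomorphic / rare columns."""
    dosages = np.asarray(dosages, dtype=float)
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        logger.info("imputing %d missing genotypes to column means", n_missing)
        col_mean = np.nanmean(dosages, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = col_mean[idx[1]]

    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    polymorphic = dosages.var(axis=0) > 0
    keep = polymorphic & (maf > maf_min)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filtered %d variants (monomorphic or MAF <= %g)", n_drop, maf_min)
    if not keep.any():
        raise DataError("all variants removed by MAF/monomorphic filtering")
    keep_idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        dosages=dosages[:, keep_idx],
        variant_ids=np.asarray(variant_ids, dtype=object)[keep_idx],
        chromosome=np.asarray(chroms, dtype=object)[keep_idx],
        maf=maf[keep_idx],
    )


def _read_vcf(path: str) -> tuple[np.ndarray, list, list]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    cols, ids, chroms = [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic/non-SNV record at line ~{i + 1} "
                          f"({rec.CHROM}:{rec.POS})")
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(dos)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
    if not cols:
        raise DataError(f"no usable biallelic SNV records in {path}")
    return np.column_stack(cols), ids, chroms


def _read_tsv_genotypes(path: str) -> tuple[np.ndarray, list, list]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"cannot parse genotype TSV {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise DataError(f"genotype TSV {path} has no variant columns")
    ids = [str(c) for c in df.columns]
    # chromosome encoded as "chr:rest" prefix of the id when present, else "1"
    chroms = [i.split(":", 1)[0] if ":" in i else "1" for i in ids]
    mat = df.to_numpy(dtype=float)
    return mat, ids, chroms


def read_genotypes(path: str, format: str = "tsv", maf_min: float = 0.01) -> GenotypeMatrix:
    """Read raw dosages from a VCF or genotype TSV and apply the MAF filter.

    Variants with MAF <= ``maf_min`` or zero variance are removed; missing
    genotypes are imputed to the column mean of observed dosages (logged).
    Input variant order is preserved among the retained columns.
    """
    if format == "vcf":
        mat, ids, chroms = _read_vcf(path)
    elif format == "tsv":
        mat, ids, chroms = _read_tsv_genotypes(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    observed = mat[~np.isnan(mat)]
    if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
        raise DataError(f"raw dosages in {path} must be 0/1/2")
    return _finalize_genotypes(mat, ids, chroms, maf_min)


def write_genotypes_tsv(g: GenotypeMatrix, path: str) -> None:
    pd.DataFrame(g.dosages, columns=list(g.variant_ids)).to_csv(
        path, sep="\t", index=False,
        float_format=None if g.standardized else "%.10g")


def read_phenotype(path: str) -> Phenotype:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "value"} <= set(df.columns):
        raise DataError(f"phenotype TSV {path} needs columns sample_id, value")
    return Phenotype(df["value"].to_numpy(float), df["sample_id"].to_numpy())


def write_phenotype_tsv(y: Phenotype, path: str) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "value": y.values}).to_csv(
        path, sep="\t", index=False)


def read_priors(path: str, g: GenotypeMatrix, default_pi1: float = 0.01,
                default_slab_sd: float = 1.0, null_family: str = "normal_spike",
                null_scale: float = 0.01, smoothing_eps: float = 1e-8) -> PriorSpec:
    """Join a per-SNP prior table (variant_id, pi1[, slab_sd]) onto ``g``.

    Variants absent from the file receive the defaults.  pi1 values slightly
    outside [0,1] (within 0.1) are clipped with a warning; values further out
    raise, since that usually means the wrong column was exported.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty and "variant_id" not in df.columns:
        df = pd.DataFrame(columns=["variant_id", "pi1"])
    if "variant_id" not in df.columns or "pi1" not in df.columns:
        raise DataError(f"prior TSV {path} needs columns variant_id, pi1")
    pi1_raw = df["pi1"].to_numpy(float)
    if np.any((pi1_raw < -0.1) | (pi1_raw > 1.1)):
        raise DataError(f"pi1 values in {path} far outside [0,1]; wrong column?")
    if np.any((pi1_raw < 0) | (pi1_raw > 1)):
        warnings.warn(f"clipping {int(((pi1_raw < 0) | (pi1_raw > 1)).sum())} "
                      "pi1 values to [0,1]")
    df = df.assign(pi1=np.clip(pi1_raw, 0.0, 1.0))
    df = df.set_index(df["variant_id"].astype(str))

    pi1 = np.full(g.n_snps, default_pi1, dtype=float)
    slab = np.full(g.n_snps, default_slab_sd, dtype=float)
    have_slab = "slab_sd" in df.columns
    for j, vid in enumerate(g.variant_ids):
        key = str(vid)
        if key in df.index:
            pi1[j] = df.at[key, "pi1"]
            if have_slab and np.isfinite(df.at[key, "slab_sd"]):
                slab[j] = df.at[key, "slab_sd"]
    return PriorSpec(pi1, slab, null_family, null_scale, smoothing_eps)


def read_annotations(path: str) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    if not {"variant_id", "category"} <= set(df.columns):
        raise DataError(f"annotation TSV {path} needs columns variant_id, category")
    return AnnotationTable(df["variant_id"].astype(str).to_numpy(object),
                           df["category"].astype(str).to_numpy(object))


# ---------------------------------------------------------------------------
# Transforms


def standardize_genotypes(g: GenotypeMatrix) -> GenotypeMatrix:
    """Center each column to mean 0 and scale to unit sample variance (ddof=1)."""
    if g.standardized:
        raise DataError("genotypes already standardized")
    mean = g.dosages.mean(axis=0)
    sd = g.dosages.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DataError("zero-variance column; filter monomorphic variants first")
    return GenotypeMatrix(
        dosages=(g.dosages - mean) / sd,
        variant_ids=g.variant_ids,
        chromosome=g.chromosome,
        maf=g.maf,
        standardized=True,
        window_id=g.window_id,
    )


def make_windows(g: GenotypeMatrix, scheme: str = "per_chromosome",
                 size: int = 0, total_h2: float = 0.5) -> tuple[GenotypeMatrix, NoiseModel]:
    """Assign fitting windows and derive the per-window noise model.

    ``per_chromosome`` makes one window per contiguous chromosome block;
    ``fixed_size`` cuts blocks of ``size`` consecutive SNPs.  Per-window
    heritability is total_h2 / n_windows; residual variances stay unbound
    (NaN) until a phenotype is attached at fit time.
    """
    if scheme == "per_chromosome":
        window_id = np.empty(g.n_snps, dtype=int)
        current, wid = None, -1
        for j, chrom in enumerate(g.chromosome):
            if chrom != current:
                current, wid = chrom, wid + 1
            window_id[j] = wid
    elif scheme == "fixed_size":
        if size <= 0:
            raise ValueError("fixed_size windowing requires size > 0")
        window_id = np.arange(g.n_snps) // size
    else:
        raise ValueError(f"unknown windowing scheme {scheme!r}")
    n_windows = int(window_id.max()) + 1
    h2_window = total_h2 / n_windows
    noise = NoiseModel(np.full(n_windows, np.nan), h2_window)
    g2 = replace(g, window_id=window_id)
    return g2, noise
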