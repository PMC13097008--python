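"""Post-VCF genotype QC: depth masking, variant filters, LD pruning, imputation.

The pipeline assumes upstream variant calling and hard filtering have already
produced a VCF; this module applies the population-genetic filters on the
biallelic SNP set: per-genotype depth masking (DP < 5 -> missing), mean-depth /
minor-allele-frequency / missingness variant filters, sliding-window LD pruning
(50 variants, step 10, r-squared 0.1) and modal-dosage imputation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "mean_depth")
SAMPLE_COLUMNS = ("id", "lon", "lat", "site")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with variant and sample metadata.

    ``dosages`` is a float array with values {0, 1, 2} and NaN for missing.
    ``variants`` has one row per SNP (id, chrom, pos, ref, alt, mean_depth);
    ``samples`` one row per individual (id, lon, lat, site).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.dosages).mean()) if self.dosages.size else 0.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, on non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def take_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples,
        )


@dataclass
class QCReport:
    """Bookkeeping for a filter chain; counts are non-increasing."""

    n_input: int
    n_after_each_filter: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def record(self, name: str, n_after: int) -> None:
        prev = (
            list(self.n_after_each_filter.values())[-1]
            if self.n_after_each_filter else self.n_input
        )
        if n_after > prev:
            raise ValueError(f"filter {name!r} increased the variant count")
        self.n_after_each_filter[name] = int(n_after)

    @property
    def n_output(self) -> int:
        return (
            list(self.n_after_each_filter.values())[-1]
            if self.n_after_each_filter else self.n_input
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def load_genotypes(
    vcf_path: str | Path,
    min_gt_depth: int = 5,
    require_pass: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Load a VCF into a dosage matrix.

    Multi-allelic records are dropped; genotypes with DP below ``min_gt_depth``
    are set missing (skipped with a log message when the VCF carries no DP).
    Dosage is the count of alternate alleles.  Sample lon/lat/site metadata is
    filled with NaN/empty placeholders; attach coordinates separately.
    """
    from cyvcf2 import VCF

    vcf_path = str(vcf_path)
    try:
        vcf = VCF(vcf_path)
    except Exception as exc:
        raise IOError(f"cannot open VCF {vcf_path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    rows, meta = [], []
    n_total = n_multi = n_filtered = 0
    dp_missing_logged = False
    for var in vcf:
        n_total += 1
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if require_pass and var.FILTER is not None:  # cyvcf2: None means PASS
            n_filtered += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dp = var.format("DP")
        if dp is not None:
            dpv = dp.astype(float).ravel()[: len(dos)]
            dpv = np.where(dpv < 0, np.nan, dpv)
            dos = np.where(np.isnan(dpv) | (dpv < min_gt_depth), np.nan, dos)
            mean_depth = float(np.nanmean(dpv)) if not np.all(np.isnan(dpv)) else np.nan
        else:
            if not dp_missing_logged:
                logger.info("VCF %s has no DP FORMAT field; depth mask skipped", vcf_path)
                dp_missing_logged = True
            mean_depth = np.nan
        rows.append(dos)
        meta.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0], mean_depth)
        )
    vcf.close()

    variants = pd.DataFrame(meta, columns=list(VARIANT_COLUMNS))
    dosages = (
        np.vstack(rows).T if rows else np.empty((len(sample_ids), 0))
    )
    samples = pd.DataFrame(
        {"id": sample_ids, "lon": np.nan, "lat": np.nan, "site": ""}
    )
    gm = GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)
    report = QCReport(
        n_input=n_total,
        parameters={"min_gt_depth": min_gt_depth, "require_pass": require_pass},
    )
    report.record("biallelic", n_total - n_multi)
    if require_pass:
        report.record("filter_pass", n_total - n_multi - n_filtered)
    return gm, report


def filter_variants(
    gm: GenotypeMatrix,
    min_maf: float = 0.01,
    max_missing: float = 0.10,
    min_mean_depth: float = 5.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequentially drop SNPs by mean depth, MAF and missingness.

    A SNP is removed when its mean depth across samples is below
    ``min_mean_depth``, its minor allele frequency (on non-missing genotypes)
    is below ``min_maf``, or its missing fraction is >= ``max_missing`` (the
    boundary itself is removed).  Surviving SNP order is preserved.
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        n_input=gm.n_variants,
        parameters={
            "min_maf": min_maf, "max_missing": max_missing,
            "min_mean_depth": min_mean_depth,
        },
    )

    depth = gm.variants["mean_depth"].to_numpy(float)
    keep = ~(depth < min_mean_depth)  # NaN mean depth (no DP) passes
    gm = gm.take_variants(keep)
    report.record("mean_depth", gm.n_variants)

    keep = gm.maf() >= min_maf
    gm = gm.take_variants(np.nan_to_num(keep, nan=False).astype(bool))
    report.record("maf", gm.n_variants)

    miss = np.isnan(gm.dosages).mean(axis=0)
    gm = gm.take_variants(miss < max_missing)
    report.record("missingness", gm.n_variants)

    if gm.n_variants == 0:
        logger.warning("all SNPs removed by filter_variants")
    return gm, report


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns, pairwise-complete."""
    df = pd.DataFrame(block)
    r = df.corr(min_periods=2).to_numpy()
    r2 = r ** 2
    np.fill_diagonal(r2, 0.0)
    return np.nan_to_num(r2, nan=0.0)


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sliding-window LD pruning of the dosage matrix.

    Windows of ``window`` variants advance by ``step``; within a window, while
    any surviving pair exceeds ``r2_max`` in squared dosage correlation, the
    later-positioned member of the worst pair is removed (greedy,
    deterministic).  Missing dosages are allowed; correlations use pairwise
    complete observations.
    """
    if window < 2:
        raise ValueError("window must be >= 2 variants")
    report = QCReport(
        n_input=gm.n_variants,
        parameters={"window": window, "step": step, "r2_max": r2_max},
    )
    removed = np.zeros(gm.n_variants, dtype=bool)
    order = np.arange(gm.n_variants)  # variants already sorted by (chrom, pos)

    for chrom, grp in gm.variants.groupby("chrom", sort=False):
        idx_chrom = order[gm.variants["chrom"].to_numpy() == chrom]
        start = 0
        while start < len(idx_chrom):
            win = idx_chrom[start:start + window]
            live = win[~removed[win]]
            while len(live) > 1:
                r2 = _pairwise_r2(gm.dosages[:, live])
                flat = np.argmax(r2)
                i, j = np.unravel_index(flat, r2.shape)
                if r2[i, j] <= r2_max:
                    break
                # drop the later variant (columns are position-ordered)
                removed[live[max(i, j)]] = True
                live = win[~removed[win]]
            if start + window >= len(idx_chrom):
                break
            start += step

    pruned = gm.take_variants(~removed)
    report.record("ld_prune", pruned.n_variants)
    return pruned, report


def impute_major(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing genotype by the SNP's modal non-missing dosage.

    Ties between dosage classes break toward the smaller dosage.  A SNP with
    every genotype missing cannot be imputed and raises.
    """
    dos = gm.dosages.copy()
    for j in range(dos.shape[1]):
        col = dos[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"variant {gm.variants['id'].iloc[j]!r} is entirely missing")
        counts = np.array([(obs == d).sum() for d in (0.0, 1.0, 2.0)])
        col[miss] = float(np.argmax(counts))  # argmax takes the lowest dosage on ties
    return GenotypeMatrix(dosages=dos, variants=gm.variants, samples=gm.samples)


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    depth: np.ndarray | int = 30,
) -> Path:
    """Write the matrix as a minimal VCF 4.2 with GT and DP FORMAT fields.

    ``depth`` is either a constant or a samples x variants array; missing
    genotypes are written as ``./.`` with DP 0 so a depth-masking loader
    round-trips them as missing.
    """
    path = Path(path)
    n, m = gm.dosages.shape
    if np.isscalar(depth):
        depth = np.full((n, m), depth, dtype=int)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    contigs = list(dict.fromkeys(gm.variants["chrom"]))
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=adaptscape\n")
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in gm.samples["id"]) + "\n"
            )
            for j, var in enumerate(gm.variants.itertuples(index=False)):
                fields = [
                    str(var.chrom), str(int(var.pos)), str(var.id),
                    str(var.ref), str(var.alt), ".", "PASS", ".", "GT:DP",
                ]
                for i in range(n):
                    d = gm.dosages[i, j]
                    if np.isnan(d):
                        fields.append("./.:0")
                    else:
                        fields.append(f"{gt_of[float(d)]}:{int(depth[i, j])}")
                fh.write("\t".join(fields) + "\n")
    except OSError as exc:
        raise IOError(f"failed writing VCF to {path}: {exc}") from exc
    return path


def write_dosage_csv(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Plain samples x SNPs dosage table (NaN = missing)."""
    path = Path(path)
    df = pd.DataFrame(
        gm.dosages,
        index=pd.Index(gm.samples["id"], name="sample_id"),
        columns=gm.variants["id"],
    )
    df.to_csv(path, float_format="%.10g")
    return path
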