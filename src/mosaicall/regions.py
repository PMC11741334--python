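"""Callable-region construction, germline homozygous-reference sites, and
the sex-concordance check.

Callable regions start from padded capture targets, restricted to autosomes,
minus a union of exclusion masks (low-complexity, repeats, blacklists, ...).
Per-sample masks then keep sites with depth between 10x and five times the
sample median (both bounds inclusive); the number of retained bases is the
denominator of the normalized mutation burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .intervals import IntervalSet

AUTOSOMES = tuple(str(i) for i in range(1, 23)) + tuple(f"chr{i}" for i in range(1, 23))


def build_callable(
    targets: IntervalSet,
    padding: int = 10,
    exclusions: Sequence[IntervalSet] = (),
    autosomes_only: bool = True,
) -> IntervalSet:
    """Padded, merged targets minus the union of exclusion sets."""
    result = targets.pad(padding)
    if autosomes_only:
        result = result.restrict_chromosomes(AUTOSOMES)
    known = set(targets.chromosomes)
    for excl in exclusions:
        extra = set(excl.chromosomes) - known
        if extra:
            warnings.warn(
                f"exclusion chromosomes not in targets (build mismatch?): "
                f"{sorted(extra)}"
            )
        result = result.subtract(excl)
    return result


# --- germline hom-ref sites -------------------------------------------------

#: genotype codes in the matrix
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


def genotype_matrix_from_vcf(path, min_depth: int = 10) -> pd.DataFrame:
    """Sites x samples genotype codes from a multi-sample VCF.

    Cells with DP <= ``min_depth`` are set to missing, mirroring the
    genotype-confidence rule used when defining donor reference-homozygous
    sites.  Index is (chrom, pos) with 1-based positions.
    """
    records = []
    index = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            row = []
            for sample in samples:
                call = rec.samples[sample]
                dp = call.get("DP")
                gt = call.get("GT")
                if dp is not None and dp <= min_depth:
                    row.append(MISSING)
                elif gt is None or any(a is None for a in gt):
                    row.append(MISSING)
                elif all(a == 0 for a in gt):
                    row.append(HOM_REF)
                elif all(a != 0 for a in gt):
                    row.append(HOM_ALT)
                else:
                    row.append(HET)
            records.append(row)
            index.append((rec.chrom, rec.pos))
    return pd.DataFrame(
        records,
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"]),
        columns=samples,
        dtype=np.int8,
    )


def donor_hom_ref_sites(genotypes: pd.DataFrame, min_frac: float = 0.95) -> pd.Index:
    """Sites where at least ``min_frac`` of non-missing tissues are
    reference homozygous.

    The denominator counts non-missing tissues only; sites with zero
    non-missing tissues are dropped.
    """
    if genotypes.empty:
        return pd.Index([])
    values = genotypes.to_numpy()
    non_missing = (values != MISSING).sum(axis=1)
    hom_ref = (values == HOM_REF).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(non_missing > 0, hom_ref / np.maximum(non_missing, 1), np.nan)
    keep = (non_missing > 0) & (frac >= min_frac)
    return genotypes.index[keep]


# --- per-sample depth mask --------------------------------------------------

def sample_callable_mask(
    depths: pd.Series | np.ndarray,
    min_depth: int = 10,
    max_depth_factor: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Depth-based site mask and callable size for one sample.

    Keeps sites with ``min_depth <= depth <= max_depth_factor * median``
    (inclusive at both ends).  The median is the lower median for even
    counts, so the bound is integer-friendly and deterministic.  Returns the
    boolean mask and the number of kept bases (the burden denominator).
    """
    depths = np.asarray(depths)
    if depths.size == 0:
        return np.zeros(0, dtype=bool), 0
    median = float(np.sort(depths)[(depths.size - 1) // 2])
    mask = (depths >= min_depth) & (depths <= max_depth_factor * median)
    return mask, int(mask.sum())


# --- sex check ---------------------------------------------------------------

@dataclass(frozen=True)
class SexCheckResult:
    chry_cov10x: float
    chry_targeted_bases: float
    chrx_cov10x: float
    chrx_targeted_bases: float
    normalized_y: float
    call: str  # male | female | ambiguous
    flagged: bool = False


def sex_check(
    y_cov: float, y_len: float, x_cov: float, x_len: float,
    male_threshold: float = 0.8, female_threshold: float = 0.2,
) -> SexCheckResult:
    """Classify genetic sex from the chrY coverage fraction normalized by
    the chrX coverage fraction (non-PAR regions only).

    The statistic is (y_cov/y_len) / (x_cov/x_len); calls are male if
    strictly above ``male_threshold``, female if strictly below
    ``female_threshold``, otherwise ambiguous.
    """
    if y_len <= 0 or x_len <= 0:
        raise ValueError("targeted lengths must be positive")
    x_ratio = x_cov / x_len
    if x_ratio == 0:
        return SexCheckResult(y_cov, y_len, x_cov, x_len,
                              float("nan"), "ambiguous", flagged=True)
    normalized_y = (y_cov / y_len) / x_ratio
    if normalized_y > male_threshold:
        call = "male"
    elif normalized_y < female_threshold:
        call = "female"
    else:
        call = "ambiguous"
    return SexCheckResult(y_cov, y_len, x_cov, x_len, normalized_y, call)


def sex_check_report(results: dict[str, SexCheckResult], path) -> None:
    """Write a TSV report of per-sample sex checks."""
    rows = []
    for sample, r in results.items():
        rows.append({
            "sample": sample,
            "chrY_cov10x": r.chry_cov10x,
            "chrY_targeted": r.chry_targeted_bases,
            "chrX_cov10x": r.chrx_cov10x,
            "chrX_targeted": r.chrx_targeted_bases,
            "normalized_y": r.normalized_y,
            "call": r.call,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
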