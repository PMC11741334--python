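"""File-format boundaries: count tables, VCF-derived resources, call output.

Coordinates are 1-based in all tabular output; BED interval inputs are
0-based half-open and converted at this boundary only.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .pileup import COUNT_COLUMNS

_DTYPES = {"pos": "int64", "depth": "int64", "ac": "int64", "vaf": "float64"}


def write_counts(df: pd.DataFrame, path) -> None:
    """Write a count table as (gzipped, if *.gz) TSV with the canonical
    column order."""
    df = df[COUNT_COLUMNS]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a count table written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df.astype(_DTYPES)


def population_af_table(vcf_path) -> pd.DataFrame:
    """Population variants (chrom, pos, ref, af) from a VCF with an AF
    INFO field; af is the maximum over alternate alleles."""
    rows = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if af is None:
                continue
            af = max(af) if isinstance(af, tuple) else float(af)
            rows.append({"chrom": rec.chrom, "pos": rec.pos,
                         "ref": rec.ref, "af": float(af)})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "af"])


def germline_positions(vcf_path) -> dict[str, list[int]]:
    """Variant start positions per chromosome from a germline VCF (SNVs
    and indel starts alike)."""
    out: dict[str, list[int]] = {}
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            out.setdefault(rec.chrom, []).append(rec.pos)
    return out


# --- final call output -------------------------------------------------------

CALL_COLUMNS = ["donor", "sample", "chrom", "pos", "ref", "alt", "depth",
                "ac", "vaf", "p_value"]


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    calls[cols].to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls: pd.DataFrame, path,
                    contigs: Mapping[str, int] | None = None) -> None:
    """Minimal VCF for final calls: FILTER names the dropping filter (PASS
    for survivors), INFO carries DP, AC, VAF, PVAL and CONTEXT."""
    header = pysam.VariantHeader()
    header.add_line('##source=mosaicall')
    for name in ("strand_bias", "evidence", "germline_proximity",
                 "population_af", "reference_leakage",
                 "intra_sample_distance", "cross_individual_recurrence",
                 "alt_mapper_support", "any_donor_germline"):
        header.filters.add(name, None, None, f"failed {name} filter")
    header.info.add("DP", 1, "Integer", "Filtered depth")
    header.info.add("AC", 1, "Integer", "Alternative allele count")
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    header.info.add("PVAL", 1, "Float", "Beta-binomial upper-tail p-value")
    header.info.add("CONTEXT", 1, "String", "Reference trinucleotide context")
    if contigs:
        for name, length in contigs.items():
            header.contigs.add(name, length=length)
    else:
        for chrom in pd.unique(calls["chrom"]):
            header.contigs.add(str(chrom))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        ordered = calls.sort_values(["chrom", "pos"])
        for row in ordered.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom), start=row.pos - 1, stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            filt = getattr(row, "filter", "PASS")
            if filt and filt != "PASS":
                rec.filter.add(filt)
            else:
                rec.filter.add("PASS")
            rec.info["DP"] = int(row.depth)
            rec.info["AC"] = int(row.ac)
            rec.info["VAF"] = float(row.vaf)
            rec.info["PVAL"] = float(row.p_value)
            if hasattr(row, "context"):
                rec.info["CONTEXT"] = str(row.context)
            out.write(rec)
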