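"""Per-site allele counting from aligned reads, with read- and base-level
pre-filters.

Reads are screened whole (mapping quality, SAM flags, indels, mismatch and
soft-clip fractions); surviving reads contribute bases that pass a base
quality floor and are not within the end-trim margin.  Sites inside the
callable regions are emitted with per-base, per-strand counts, the reference
trinucleotide context, and the most frequent non-reference allele.

End trimming masks bases by *read* coordinate (position within the sequenced
read, including soft-clipped bases); alignments are never rewritten.
Overlapping mate pairs are counted once per read — there is no mate-overlap
deduplication, which can double-count fragments where mates overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Union

import numpy as np
import pandas as pd
import pysam

from .contexts import BASES
from .intervals import IntervalSet

#: Filter outcomes, in the order the rules are checked.
DROP_REASONS = ("mapq", "flags", "indel", "no_nm", "mismatch", "softclip")


class MalformedReadError(ValueError):
    """Read is missing a CIGAR or sequence."""


class UnsortedInputError(ValueError):
    """Alignment stream is not coordinate-sorted."""


@dataclass(frozen=True)
class CountConfig:
    """Thresholds for read and base pre-filtering and site emission."""

    min_mapq: int = 20
    min_baseq: int = 20
    n_trim: int = 5
    max_indel_ops: int = 0
    max_mismatch_frac: float = 0.1
    max_softclip_frac: float = 0.5
    require_flags: int = 2
    exclude_flags: int = 3844
    min_depth: int = 10
    max_alt_alleles: int = 1
    read_length: int = 75

    def __post_init__(self):
        if not (0 <= self.min_mapq <= 93 and 0 <= self.min_baseq <= 93):
            raise ValueError("min_mapq and min_baseq must be in [0, 93]")
        if not (0 <= self.max_mismatch_frac <= 1 and 0 <= self.max_softclip_frac <= 1):
            raise ValueError("fraction thresholds must be in [0, 1]")
        for name in ("n_trim", "max_indel_ops", "min_depth", "max_alt_alleles",
                     "read_length", "require_flags", "exclude_flags"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SiteCount:
    """Filtered allele counts at one reference position (1-based)."""

    chrom: str
    pos: int
    ref_base: str
    context: str
    depth: int
    counts: tuple  # ((A_fwd, A_rev), (C_fwd, C_rev), (G_fwd, G_rev), (T_fwd, T_rev))
    alt_base: str | None
    ac: int
    vaf: float

    def strand_counts(self, base: str) -> tuple[int, int]:
        return self.counts[BASES.index(base)]


# --- read-level filter ------------------------------------------------------

def read_passes_filters(read: pysam.AlignedSegment, config: CountConfig) -> str | None:
    """Return None if the read passes, otherwise the first failing rule.

    Rules are checked in a fixed order: mapping quality, SAM flags
    (exclude then require), indel content, mismatch fraction, soft-clip
    fraction.  Reads lacking an NM tag fail with reason ``"no_nm"``.
    """
    if read.cigartuples is None or read.query_sequence is None:
        raise MalformedReadError(f"read {read.query_name!r} lacks CIGAR or sequence")
    if read.mapping_quality < config.min_mapq:
        return "mapq"
    flag = read.flag
    if flag & config.exclude_flags:
        return "flags"
    if (flag & config.require_flags) != config.require_flags:
        return "flags"
    n_indel_ops = sum(1 for op, _ in read.cigartuples if op in (1, 2))
    if n_indel_ops > config.max_indel_ops:
        return "indel"
    aligned_len = sum(n for op, n in read.cigartuples if op == 0)
    ins_bases = sum(n for op, n in read.cigartuples if op == 1)
    del_bases = sum(n for op, n in read.cigartuples if op == 2)
    if not read.has_tag("NM"):
        return "no_nm"
    mismatches = read.get_tag("NM") - ins_bases - del_bases
    if aligned_len > 0 and mismatches / aligned_len > config.max_mismatch_frac:
        return "mismatch"
    soft = sum(n for op, n in read.cigartuples if op == 4)
    read_len = len(read.query_sequence)
    if read_len > 0 and soft / read_len > config.max_softclip_frac:
        return "softclip"
    return None


# --- reference access -------------------------------------------------------

Reference = Union[pysam.FastaFile, Mapping[str, str]]


def _fetch_context(reference: Reference, chrom: str, pos0: int) -> str | None:
    """Trinucleotide around 0-based ``pos0``; None if out of range or has N."""
    if isinstance(reference, pysam.FastaFile):
        if chrom not in reference.references:
            raise KeyError(f"chromosome {chrom!r} absent from reference")
        length = reference.get_reference_length(chrom)
        if pos0 < 1 or pos0 + 2 > length:
            return None
        ctx = reference.fetch(chrom, pos0 - 1, pos0 + 2).upper()
    else:
        if chrom not in reference:
            raise KeyError(f"chromosome {chrom!r} absent from reference")
        seq = reference[chrom]
        if pos0 < 1 or pos0 + 2 > len(seq):
            return None
        ctx = seq[pos0 - 1:pos0 + 2].upper()
    if len(ctx) != 3 or any(b not in BASES for b in ctx):
        return None
    return ctx


# --- tabulation -------------------------------------------------------------

def tabulate_counts(
    alignments: Union[str, pysam.AlignmentFile, Iterable[pysam.AlignedSegment]],
    regions: IntervalSet,
    reference: Reference,
    config: CountConfig = CountConfig(),
) -> Iterator[SiteCount]:
    """Tally filtered bases over callable regions into SiteCount records.

    The alignment stream must be coordinate-sorted.  A site is emitted only
    if its filtered depth is at least ``config.min_depth``, it has at most
    ``config.max_alt_alleles`` distinct non-reference bases, and its
    reference trinucleotide context contains no N.
    """
    own = None
    if isinstance(alignments, str):
        own = pysam.AlignmentFile(alignments, check_sq=False)
        reads: Iterable[pysam.AlignedSegment] = own.fetch(until_eof=True)
    elif isinstance(alignments, pysam.AlignmentFile):
        reads = alignments.fetch(until_eof=True)
    else:
        reads = alignments

    # validate that region chromosomes exist in the reference up front
    for chrom in regions.chromosomes:
        _fetch_context(reference, chrom, 1)

    # tally[chrom][pos0] = 4x2 int array (base x strand)
    tally: dict[str, dict[int, np.ndarray]] = {}
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    try:
        for read in reads:
            if read.is_unmapped:
                continue
            key = (read.reference_name, read.reference_start)
            if last is not None:
                if key[0] == last[0]:
                    if key[1] < last[1]:
                        raise UnsortedInputError(
                            f"read {read.query_name!r} out of order at "
                            f"{key[0]}:{key[1] + 1}"
                        )
                elif key[0] in seen_chroms:
                    raise UnsortedInputError(
                        f"chromosome {key[0]!r} appears in two blocks"
                    )
            seen_chroms.add(key[0])
            last = key
            if read_passes_filters(read, config) is not None:
                continue
            _tally_read(read, regions, config, tally)
    finally:
        if own is not None:
            own.close()

    for chrom in sorted(tally):
        for pos0 in sorted(tally[chrom]):
            site = _emit_site(chrom, pos0, tally[chrom][pos0], reference, config)
            if site is not None:
                yield site


def _tally_read(
    read: pysam.AlignedSegment,
    regions: IntervalSet,
    config: CountConfig,
    tally: dict[str, dict[int, np.ndarray]],
) -> None:
    seq = read.query_sequence
    quals = read.query_qualities
    read_len = len(seq)
    strand = 1 if read.is_reverse else 0
    chrom = read.reference_name
    chrom_tally = tally.setdefault(chrom, {})
    lo, hi = config.n_trim, read_len - config.n_trim
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if qpos < lo or qpos >= hi:
            continue
        if quals is not None and quals[qpos] < config.min_baseq:
            continue
        base = seq[qpos].upper()
        if base not in BASES:
            continue
        if (chrom, rpos) not in regions:
            continue
        cell = chrom_tally.get(rpos)
        if cell is None:
            cell = chrom_tally[rpos] = np.zeros((4, 2), dtype=np.int64)
        cell[BASES.index(base), strand] += 1


def _emit_site(
    chrom: str,
    pos0: int,
    counts: np.ndarray,
    reference: Reference,
    config: CountConfig,
) -> SiteCount | None:
    depth = int(counts.sum())
    if depth < config.min_depth:
        return None
    context = _fetch_context(reference, chrom, pos0)
    if context is None:
        return None
    ref_base = context[1]
    per_base = counts.sum(axis=1)
    ref_idx = BASES.index(ref_base)
    nonref = [(int(per_base[i]), BASES[i]) for i in range(4)
              if i != ref_idx and per_base[i] > 0]
    if len(nonref) > config.max_alt_alleles:
        return None
    if nonref:
        # most frequent alt; alphabetical order breaks ties
        ac, alt = max(nonref, key=lambda t: (t[0], -ord(t[1])))
    else:
        ac, alt = 0, None
    return SiteCount(
        chrom=chrom,
        pos=pos0 + 1,
        ref_base=ref_base,
        context=context,
        depth=depth,
        counts=tuple(tuple(int(x) for x in row) for row in counts),
        alt_base=alt,
        ac=ac,
        vaf=ac / depth,
    )


# --- tabular form -----------------------------------------------------------

COUNT_COLUMNS = [
    "chrom", "pos", "ref", "context", "depth",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
    "alt", "ac", "vaf",
]


def sites_to_frame(sites: Iterable[SiteCount]) -> pd.DataFrame:
    """Flatten SiteCount records into the count-table layout."""
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_base,
               "context": s.context, "depth": s.depth}
        for i, base in enumerate(BASES):
            row[f"{base}_fwd"], row[f"{base}_rev"] = s.counts[i]
        row["alt"] = s.alt_base if s.alt_base is not None else "."
        row["ac"] = s.ac
        row["vaf"] = s.vaf
        rows.append(row)
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
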