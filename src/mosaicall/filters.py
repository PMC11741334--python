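"""Post-filters that remove artifact candidate calls.

Each filter is a per-call predicate except the intra-sample distance and
cross-individual recurrence rules, which are evaluated on the pre-battery
candidate set so that the final call set does not depend on filter order.
The battery returns both the surviving calls and an attrition report whose
input counts telescope (n_in of filter k+1 equals n_in - n_dropped of
filter k).

Calls are rows of a DataFrame with columns: donor, sample, chrom, pos, ref,
alt, depth, ac, vaf, p_value plus per-strand counts ref_fwd, ref_rev,
alt_fwd, alt_rev.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .model import DEFAULT_P_THRESHOLD


@dataclass(frozen=True)
class FilterConfig:
    strand_p: float = 0.01
    min_ac: int = 3
    min_vaf: float = 0.005
    germline_window_bp: int = 5
    max_pop_af: float = 1e-4
    leak_run: int = 5
    min_intra_distance_bp: int = 20
    recurrence_p: float = DEFAULT_P_THRESHOLD
    min_alt_mapper_reads: int = 1

    def __post_init__(self):
        if not 0 < self.min_vaf < 1:
            raise ValueError("min_vaf must be in (0, 1)")
        for name in ("strand_p", "min_ac", "germline_window_bp", "max_pop_af",
                     "leak_run", "min_intra_distance_bp", "recurrence_p",
                     "min_alt_mapper_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterReport:
    """Ordered per-filter attrition; input counts telescope."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_dropped: int) -> None:
        if self.steps:
            prev_name, prev_in, prev_drop = self.steps[-1]
            if n_in != prev_in - prev_drop:
                raise ValueError(
                    f"count conservation violated at {name}: "
                    f"{n_in} != {prev_in} - {prev_drop}"
                )
        self.steps.append((name, n_in, n_dropped))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_in", "n_dropped"])


# --- individual predicates ---------------------------------------------------

def strand_bias_keep(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int,
                     threshold: float = 0.01) -> bool:
    """Keep unless the two-sided Fisher exact p on the ref/alt-by-strand
    table is below ``threshold``.  Zero-depth tables are kept."""
    if ref_fwd + ref_rev + alt_fwd + alt_rev == 0:
        return True
    _, p = fisher_exact([[ref_fwd, ref_rev], [alt_fwd, alt_rev]],
                        alternative="two-sided")
    return not (p < threshold)


def evidence_keep(ac: int, vaf: float, min_ac: int = 3,
                  min_vaf: float = 0.005) -> bool:
    """Minimum alt-read support: drop if ac < min_ac or vaf < min_vaf."""
    return not (ac < min_ac or vaf < min_vaf)


def reference_leakage_keep(flank_5p: str, flank_3p: str, run: int = 5) -> bool:
    """Drop variants flanked by a homopolymer run: all ``run`` reference
    bases immediately upstream identical, or all immediately downstream."""
    up = flank_5p[-run:]
    down = flank_3p[:run]
    return not ((len(up) == run and len(set(up)) == 1)
                or (len(down) == run and len(set(down)) == 1))


# --- set-level filters -------------------------------------------------------

def germline_proximity_mask(calls: pd.DataFrame,
                            germline_sites: Mapping[str, Iterable[int]],
                            window: int = 5) -> np.ndarray:
    """Keep-mask: False where |pos - any germline pos| <= window on the
    same chromosome (inclusive)."""
    keep = np.ones(len(calls), dtype=bool)
    sorted_sites = {c: np.sort(np.asarray(list(p), dtype=np.int64))
                    for c, p in germline_sites.items()}
    for i, (chrom, pos) in enumerate(zip(calls["chrom"], calls["pos"])):
        sites = sorted_sites.get(chrom)
        if sites is None or sites.size == 0:
            continue
        j = np.searchsorted(sites, pos)
        near = []
        if j < sites.size:
            near.append(abs(int(sites[j]) - pos))
        if j > 0:
            near.append(abs(int(sites[j - 1]) - pos))
        if near and min(near) <= window:
            keep[i] = False
    return keep


def population_af_mask(calls: pd.DataFrame,
                       pop_variants: pd.DataFrame,
                       max_af: float = 1e-4) -> np.ndarray:
    """Keep-mask: False where the call locus overlaps a population variant
    (SNV or the REF footprint of an indel) with AF strictly above ``max_af``.

    ``pop_variants`` columns: chrom, pos (1-based), ref, af.
    """
    frequent = pop_variants[pop_variants["af"] > max_af]
    spans: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, ref in zip(frequent["chrom"], frequent["pos"], frequent["ref"]):
        spans.setdefault(chrom, []).append((pos, pos + len(ref) - 1))
    keep = np.ones(len(calls), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(calls["chrom"], calls["pos"])):
        for lo, hi in spans.get(chrom, ()):
            if lo <= pos <= hi:
                keep[i] = False
                break
    return keep


def intra_sample_distance_mask(calls: pd.DataFrame,
                               min_dist: int = 20) -> np.ndarray:
    """Keep-mask over the candidate set: both members of any same-sample
    pair closer than ``min_dist`` bp are dropped."""
    keep = np.ones(len(calls), dtype=bool)
    for (_, _), idx in calls.groupby(["sample", "chrom"]).groups.items():
        pos = calls.loc[idx, "pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        close = np.diff(pos_sorted) < min_dist
        bad = np.zeros(pos.size, dtype=bool)
        bad[:-1] |= close
        bad[1:] |= close
        keep[calls.index.get_indexer(np.asarray(idx)[order][bad])] = False
    return keep


def cross_individual_recurrence_mask(calls: pd.DataFrame,
                                     candidates: pd.DataFrame,
                                     p_threshold: float = DEFAULT_P_THRESHOLD
                                     ) -> np.ndarray:
    """Keep-mask: False at loci that are candidates (p < threshold) in two
    or more distinct donors, judged on the pre-battery candidate set."""
    cand = candidates[candidates["p_value"] < p_threshold]
    donors_per_locus = cand.groupby(["chrom", "pos", "alt"])["donor"].nunique()
    recurrent = set(donors_per_locus[donors_per_locus >= 2].index)
    keep = np.array(
        [(c, p, a) not in recurrent
         for c, p, a in zip(calls["chrom"], calls["pos"], calls["alt"])],
        dtype=bool,
    )
    return keep


def any_donor_germline_mask(calls: pd.DataFrame,
                            germline_union: Mapping[str, Iterable[int]]
                            ) -> np.ndarray:
    """Keep-mask: False at loci equal to any donor's germline variant
    position."""
    sets = {c: set(int(x) for x in p) for c, p in germline_union.items()}
    return np.array(
        [pos not in sets.get(chrom, ()) for chrom, pos
         in zip(calls["chrom"], calls["pos"])],
        dtype=bool,
    )


def alt_mapper_support_mask(calls: pd.DataFrame,
                            evidence: Mapping[tuple, int],
                            min_reads: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Keep-mask from second-aligner evidence counts keyed by
    (sample, chrom, pos, alt).  Calls absent from the table count as 0 and
    are reported separately (second mask marks missing rows)."""
    keep = np.ones(len(calls), dtype=bool)
    missing = np.zeros(len(calls), dtype=bool)
    for i, key in enumerate(zip(calls["sample"], calls["chrom"],
                                calls["pos"], calls["alt"])):
        if key not in evidence:
            keep[i] = False
            missing[i] = True
        elif evidence[key] < min_reads:
            keep[i] = False
    return keep, missing


# --- the battery -------------------------------------------------------------

@dataclass
class FilterResources:
    """External inputs the battery consumes.

    germline_by_donor : donor -> chrom -> positions (SNV and indel starts)
    pop_variants : population variant table (chrom, pos, ref, af)
    reference : mapping chrom -> sequence, or pysam.FastaFile
    alt_mapper_evidence : (sample, chrom, pos, alt) -> alt-read count, or
        None to skip the second-aligner filter (e.g. in pure simulations)
    """

    germline_by_donor: Mapping[str, Mapping[str, Iterable[int]]] = field(
        default_factory=dict)
    pop_variants: pd.DataFrame | None = None
    reference: object = None
    alt_mapper_evidence: Mapping[tuple, int] | None = None


def _flanks(reference, chrom: str, pos: int, run: int) -> tuple[str, str]:
    import pysam

    if isinstance(reference, pysam.FastaFile):
        length = reference.get_reference_length(chrom)
        up = reference.fetch(chrom, max(pos - 1 - run, 0), pos - 1)
        down = reference.fetch(chrom, pos, min(pos + run, length))
    else:
        seq = reference[chrom]
        up = seq[max(pos - 1 - run, 0):pos - 1]
        down = seq[pos:pos + run]
    return up.upper(), down.upper()


def apply_all(
    calls: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    resources: FilterResources = FilterResources(),
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full post-filter battery in its canonical order.

    Returns the surviving calls and the attrition report.  The distance and
    recurrence rules are judged on the input candidate set, making the
    battery idempotent on its own output.
    """
    report = FilterReport()
    current = calls.reset_index(drop=True)
    pre_battery = current

    def step(name: str, keep: np.ndarray) -> None:
        nonlocal current
        report.add(name, len(current), int((~keep).sum()))
        current = current[keep].reset_index(drop=True)

    # 1. strand bias (Fisher exact, two-sided)
    keep = np.array([
        strand_bias_keep(r.ref_fwd, r.ref_rev, r.alt_fwd, r.alt_rev,
                         config.strand_p)
        for r in current.itertuples()
    ], dtype=bool) if len(current) else np.zeros(0, dtype=bool)
    step("strand_bias", keep)

    # 2. minimum evidence (ac, vaf)
    keep = np.array([
        evidence_keep(r.ac, r.vaf, config.min_ac, config.min_vaf)
        for r in current.itertuples()
    ], dtype=bool) if len(current) else np.zeros(0, dtype=bool)
    step("evidence", keep)

    # 3. proximity to same-donor germline variants
    keep = np.ones(len(current), dtype=bool)
    for donor, idx in current.groupby("donor").groups.items():
        sites = resources.germline_by_donor.get(donor, {})
        sub = current.loc[idx]
        keep[current.index.get_indexer(np.asarray(idx))] = \
            germline_proximity_mask(sub, sites, config.germline_window_bp)
    step("germline_proximity", keep)

    # 4. population allele frequency
    if resources.pop_variants is not None:
        keep = population_af_mask(current, resources.pop_variants,
                                  config.max_pop_af)
    else:
        keep = np.ones(len(current), dtype=bool)
    step("population_af", keep)

    # 5. reference leakage (flanking homopolymer)
    if resources.reference is not None:
        keep = np.array([
            reference_leakage_keep(
                *_flanks(resources.reference, r.chrom, r.pos, config.leak_run),
                config.leak_run)
            for r in current.itertuples()
        ], dtype=bool) if len(current) else np.zeros(0, dtype=bool)
    else:
        keep = np.ones(len(current), dtype=bool)
    step("reference_leakage", keep)

    # 6. intra-sample distance, judged on the pre-battery set
    dropped_pre = pre_battery[~intra_sample_distance_mask(
        pre_battery, config.min_intra_distance_bp)]
    bad_keys = set(zip(dropped_pre["sample"], dropped_pre["chrom"],
                       dropped_pre["pos"]))
    keep = np.array([
        (r.sample, r.chrom, r.pos) not in bad_keys for r in current.itertuples()
    ], dtype=bool) if len(current) else np.zeros(0, dtype=bool)
    step("intra_sample_distance", keep)

    # 7. recurrence across donors, judged on the pre-battery candidate set
    keep = cross_individual_recurrence_mask(current, pre_battery,
                                            config.recurrence_p) \
        if len(current) else np.zeros(0, dtype=bool)
    step("cross_individual_recurrence", keep)

    # 8. second-aligner support
    if resources.alt_mapper_evidence is not None:
        keep, _ = alt_mapper_support_mask(current,
                                          resources.alt_mapper_evidence,
                                          config.min_alt_mapper_reads)
    else:
        keep = np.ones(len(current), dtype=bool)
    step("alt_mapper_support", keep)

    # 9. overlap with any donor's germline variants
    union: dict[str, set[int]] = {}
    for donor_sites in resources.germline_by_donor.values():
        for chrom, positions in donor_sites.items():
            union.setdefault(chrom, set()).update(int(p) for p in positions)
    keep = any_donor_germline_mask(current, union) \
        if len(current) else np.zeros(0, dtype=bool)
    step("any_donor_germline", keep)

    return current, report
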