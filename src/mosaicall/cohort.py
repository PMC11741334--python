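"""Cohort-level statistics over a final multi-sample somatic call set.

Inputs are tidy tables of annotated calls (one row per donor, tissue and
variant) with optional gene, functional class, CDS position, CADD score and
germ-layer columns.  The statistics here are the bespoke ones: the 50-bp
Poisson cluster scan over coding sequence, mutational spectrum summaries,
within-donor sharing and germ-layer patterns, normalized burden, the
missense/synonymous ratio null models, orthogonal support (replication /
RNA validation) rates, region enrichment, and the CADD-based
deleteriousness split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, poisson
from statsmodels.stats.multitest import multipletests

from .contexts import CHANGE_CLASSES, canonical_class, change_class

WINDOW_BP = 50
CADD_DELETERIOUS = 30.0


# --- multiple testing --------------------------------------------------------

def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, permutation
    stable)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# --- cluster scan ------------------------------------------------------------

def cluster_scan(
    records: pd.DataFrame,
    cds_lengths: Mapping[str, int],
    window: int = WINDOW_BP,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Poisson test for somatic-mutation clusters in 50-bp CDS windows.

    For each gene, the CDS is split into non-overlapping windows; the
    expected count per window is lambda = (n_gene / L) x width, a uniform
    spread of the gene's mutations over its CDS.  The per-window p-value is
    the exact Poisson upper tail P(X >= k); BH adjustment runs across all
    windows of all tested genes; windows with q <= ``fdr`` are flagged.
    The final partial window keeps its true width in lambda.
    """
    tested = records.dropna(subset=["cds_pos"])
    rows = []
    for gene, grp in tested.groupby("gene"):
        if gene not in cds_lengths:
            continue
        length = int(cds_lengths[gene])
        pos = grp["cds_pos"].to_numpy(dtype=int)
        if (pos < 1).any() or (pos > length).any():
            raise ValueError(f"cds_pos outside CDS of length {length} for {gene}")
        n_gene = pos.size
        n_windows = math.ceil(length / window)
        counts = np.bincount((pos - 1) // window, minlength=n_windows)
        for w in range(n_windows):
            width = min(window, length - w * window)
            lam = (n_gene / length) * width
            k = int(counts[w])
            p = float(poisson.sf(k - 1, lam)) if k > 0 else 1.0
            rows.append({"gene": gene, "window_index": w,
                         "window_start": w * window + 1, "width": width,
                         "k": k, "lam": lam, "p": p})
    result = pd.DataFrame(
        rows, columns=["gene", "window_index", "window_start", "width",
                       "k", "lam", "p"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] <= fdr
    else:
        result["q"] = []
        result["significant"] = []
    return result


# --- spectrum ----------------------------------------------------------------

def record_classes(records: pd.DataFrame) -> pd.Series:
    """Canonical 96-class label per record (context, ref, alt columns)."""
    return pd.Series(
        [canonical_class(c, r, a)
         for c, r, a in zip(records["context"], records["ref"], records["alt"])],
        index=records.index,
    )


def mutational_spectrum(records: pd.DataFrame
                        ) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Six-class and 96-class spectrum proportions plus the per-sample
    CpG>T fraction.

    The CpG>T fraction of a sample is the count of C>T calls whose 3'
    neighbour is G (pyrimidine orientation) divided by all calls of that
    sample; empty samples give NaN, not 0.
    """
    from .contexts import CLASS_LABELS

    if records.empty:
        return (pd.Series(np.nan, index=list(CHANGE_CLASSES)),
                pd.Series(np.nan, index=list(CLASS_LABELS)),
                pd.Series(dtype=float))
    labels = record_classes(records)
    six = labels.map(change_class).value_counts().reindex(
        CHANGE_CLASSES, fill_value=0) / len(labels)
    ninety_six = labels.value_counts().reindex(
        CLASS_LABELS, fill_value=0) / len(labels)
    is_cpg_t = np.array([l[2:5] == "C>T" and l[6] == "G" for l in labels])
    cpg = pd.Series(is_cpg_t, index=records.index).groupby(
        records["sample"]).mean()
    return six, ninety_six, cpg


# --- sharing -----------------------------------------------------------------

def classify_shared(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variant sharing within donors.

    A variant (donor, chrom, pos, ref, alt) is shared when it is observed
    in two or more tissues of the same donor.  The germ-layer pattern is
    single-layer or multi-layer from the set of layers of the carrying
    tissues (when a germ_layer column is present).
    """
    keys = ["donor", "chrom", "pos", "ref", "alt"]
    has_layer = "germ_layer" in records.columns
    agg = {"tissue": "nunique"}
    grouped = records.groupby(keys)
    out = grouped.agg(n_tissues=("tissue", "nunique")).reset_index()
    out["shared"] = out["n_tissues"] >= 2
    if has_layer:
        layers = grouped["germ_layer"].agg(
            lambda s: frozenset(x for x in s if pd.notna(x)))
        out["layers"] = layers.to_numpy()
        out["layer_pattern"] = [
            "multi-layer" if len(l) > 1 else "single-layer" if len(l) == 1
            else "unknown"
            for l in out["layers"]
        ]
    return out


def multilayer_shared_proportion(shared_table: pd.DataFrame) -> float:
    """Fraction of shared variants whose carrying tissues span more than
    one germ layer; NaN when there are no shared variants."""
    shared = shared_table[shared_table["shared"]]
    if shared.empty:
        return float("nan")
    return float((shared["layer_pattern"] == "multi-layer").mean())


@dataclass(frozen=True)
class LayerSharingSummary:
    proportions: pd.Series  # per-layer shared fraction
    table: pd.DataFrame  # layer x (shared, unshared) counts
    chi2_p: float
    one_vs_rest_p: pd.Series


def germ_layer_sharing_summary(records: pd.DataFrame) -> LayerSharingSummary:
    """Per-germ-layer proportion of shared variants and chi-square tests.

    For each layer the denominator is all distinct within-donor variants
    observed in at least one tissue of that layer; the numerator is those
    that are shared (in >= 2 tissues of the donor, any layer).  A shared
    variant spanning layers counts once in each layer it touches.  Layers
    with no variants are NaN and excluded from the tests.
    """
    shared_table = classify_shared(records)
    key_cols = ["donor", "chrom", "pos", "ref", "alt"]
    shared_keys = set(map(tuple, shared_table.loc[shared_table["shared"],
                                                  key_cols].to_numpy()))
    per_layer: dict[str, tuple[int, int]] = {}
    for layer, grp in records.dropna(subset=["germ_layer"]).groupby("germ_layer"):
        variants = set(map(tuple, grp[key_cols].drop_duplicates().to_numpy()))
        n_shared = sum(1 for v in variants if v in shared_keys)
        per_layer[layer] = (n_shared, len(variants) - n_shared)
    table = pd.DataFrame(per_layer, index=["shared", "unshared"]).T
    nonempty = table[table.sum(axis=1) > 0]
    proportions = pd.Series({
        layer: (row["shared"] / row.sum()) if row.sum() else float("nan")
        for layer, row in table.iterrows()
    })
    if len(nonempty) >= 2 and nonempty.to_numpy().sum() > 0:
        chi2_p = float(chi2_contingency(nonempty.to_numpy() + 0.0,
                                        correction=False)[1]) \
            if (nonempty.sum(axis=0) > 0).all() else float("nan")
    else:
        chi2_p = float("nan")
    ovr = {}
    for layer in nonempty.index:
        rest = nonempty.drop(index=layer).sum(axis=0)
        tab = np.array([nonempty.loc[layer].to_numpy(), rest.to_numpy()])
        if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
            ovr[layer] = float(chi2_contingency(tab, correction=False)[1])
        else:
            ovr[layer] = float("nan")
    return LayerSharingSummary(proportions, table, chi2_p, pd.Series(ovr))


# --- burden ------------------------------------------------------------------

def normalized_burden(n_calls: int, callable_size_bases: int) -> float:
    """Somatic calls per megabase of sample-specific callable sequence;
    NaN (with a warning) when the callable size is zero."""
    if callable_size_bases <= 0:
        import warnings

        warnings.warn("callable size is zero; normalized burden undefined")
        return float("nan")
    return n_calls / (callable_size_bases / 1e6)


# --- missense/synonymous ratio null models -----------------------------------

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from itertools import product
        try:
            from Bio.Seq import Seq

            for codon in ("".join(c) for c in product("ACGT", repeat=3)):
                _CODON_TABLE[codon] = str(Seq(codon).translate())
        except ImportError:  # pragma: no cover - biopython is a std install
            raise
    return _CODON_TABLE


def classify_cds_mutation(seq: str, pos0: int, alt: str) -> str:
    """missense / synonymous / nonsense effect of a single-base change at
    0-based CDS position ``pos0``."""
    table = _codon_table()
    ci = pos0 // 3
    codon = seq[ci * 3:ci * 3 + 3]
    mutated = codon[:pos0 % 3] + alt + codon[pos0 % 3 + 1:]
    old_aa, new_aa = table[codon], table[mutated]
    if new_aa == "*" and old_aa != "*":
        return "nonsense"
    if old_aa == new_aa:
        return "synonymous"
    return "missense"


MS_MODELS = ("context_blind", "ref_alt", "exact_trinuc", "flank_only",
             "combined")


@dataclass(frozen=True)
class MsRatioResult:
    model: str
    observed_ratio: float
    simulated_ratios: np.ndarray
    n_fallback: int  # placements redrawn context-blind for lack of context


def _eligible_pairs(seq: str, model: str, ref: str, alt: str,
                    ctx: str | None) -> list[tuple[int, str]]:
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    L = len(seq)
    pairs: list[tuple[int, str]] = []
    if model == "context_blind":
        return [(p, a) for p in range(L) for a in others[seq[p]]]
    if model == "ref_alt":
        return [(p, alt) for p in range(L) if seq[p] == ref]
    if ctx is None:
        return []
    if model == "exact_trinuc":
        return [(p, a) for p in range(1, L - 1)
                if seq[p - 1:p + 2] == ctx for a in others[seq[p]]]
    if model == "flank_only":
        return [(p, a) for p in range(1, L - 1)
                if seq[p - 1] == ctx[0] and seq[p + 1] == ctx[2]
                for a in others[seq[p]]]
    if model == "combined":
        return [(p, alt) for p in range(1, L - 1) if seq[p - 1:p + 2] == ctx]
    raise ValueError(f"unknown model {model!r}")


def ms_ratio_models(
    gene_seqs: Mapping[str, str],
    observed: pd.DataFrame,
    model: str = "context_blind",
    n_iter: int = 1000,
    seed: int = 0,
) -> MsRatioResult:
    """Null distribution of the missense/synonymous ratio under a placement
    model.

    Per iteration, each observed coding mutation is re-placed uniformly at
    random among the (site, alt) pairs of its gene that satisfy the model's
    constraint (same nucleotide change, same trinucleotide context, same
    flanks, or their combination); placements creating a stop codon are
    classed nonsense and excluded from both ratio terms.  Mutations whose
    required context does not occur in the gene are re-drawn context-blind
    and counted in ``n_fallback``.

    ``observed`` columns: gene, cds_pos (1-based), ref, alt; ref/alt are on
    the CDS strand.
    """
    if model not in MS_MODELS:
        raise ValueError(f"model must be one of {MS_MODELS}")
    rng = np.random.default_rng(seed)
    placements: list[list[tuple[int, str]]] = []
    seqs: list[str] = []
    n_fallback = 0
    obs_counts = {"missense": 0, "synonymous": 0, "nonsense": 0}
    for row in observed.itertuples(index=False):
        seq = gene_seqs[row.gene].upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS of {row.gene} not in frame")
        pos0 = int(row.cds_pos) - 1
        if seq[pos0] != row.ref:
            raise ValueError(
                f"ref mismatch at {row.gene}:{row.cds_pos} "
                f"({seq[pos0]} != {row.ref})")
        obs_counts[classify_cds_mutation(seq, pos0, row.alt)] += 1
        ctx = seq[pos0 - 1:pos0 + 2] if 1 <= pos0 <= len(seq) - 2 else None
        pairs = _eligible_pairs(seq, model, row.ref, row.alt, ctx)
        if not pairs:
            pairs = _eligible_pairs(seq, "context_blind", row.ref, row.alt, ctx)
            n_fallback += 1
        placements.append(pairs)
        seqs.append(seq)
    observed_ratio = (obs_counts["missense"] / obs_counts["synonymous"]
                      if obs_counts["synonymous"] else float("nan"))
    ratios = np.empty(n_iter)
    for it in range(n_iter):
        n_mis = n_syn = 0
        for seq, pairs in zip(seqs, placements):
            pos0, alt = pairs[rng.integers(len(pairs))]
            effect = classify_cds_mutation(seq, pos0, alt)
            if effect == "missense":
                n_mis += 1
            elif effect == "synonymous":
                n_syn += 1
        ratios[it] = n_mis / n_syn if n_syn else (
            float("inf") if n_mis else float("nan"))
    return MsRatioResult(model, observed_ratio, ratios, n_fallback)


# --- orthogonal support (replication / RNA validation) -----------------------

@dataclass(frozen=True)
class SupportRateResult:
    rate: float
    n_supported: int
    n_total: int
    not_covered_fraction: float
    by_coverage: pd.DataFrame
    by_vaf: pd.DataFrame


def orthogonal_support_rate(
    discovery: pd.DataFrame,
    min_reads: int = 1,
    coverage_bins: Sequence[float] = (0, 5, 50, 300, 1000, np.inf),
    vaf_bins: Sequence[float] = (0, 0.01, 0.02, 0.03, 0.05, 1.0),
) -> SupportRateResult:
    """Fraction of discovery calls with alt-read support in a second assay.

    ``discovery`` columns: support_reads (alt reads in the validation
    sample), support_coverage (its depth there) and vaf (discovery VAF).
    Supported means support_reads >= ``min_reads``.  Calls with zero
    validation coverage count as unsupported in the overall rate but are
    also reported separately as the not-covered class.  Rates are NaN on an
    empty discovery set.
    """
    n = len(discovery)
    if n == 0:
        empty = pd.DataFrame(columns=["bin", "rate", "n"])
        return SupportRateResult(float("nan"), 0, 0, float("nan"),
                                 empty, empty)
    supported = discovery["support_reads"] >= min_reads
    not_covered = discovery["support_coverage"] == 0

    def stratify(values, bins):
        labels = pd.cut(values, bins=list(bins), right=False)
        grp = supported.groupby(labels, observed=False)
        return pd.DataFrame({
            "bin": grp.mean().index.astype(str),
            "rate": grp.mean().to_numpy(),
            "n": grp.size().to_numpy(),
        })

    return SupportRateResult(
        rate=float(supported.mean()),
        n_supported=int(supported.sum()),
        n_total=n,
        not_covered_fraction=float(not_covered.mean()),
        by_coverage=stratify(discovery["support_coverage"], coverage_bins),
        by_vaf=stratify(discovery["vaf"], vaf_bins),
    )


# --- region enrichment -------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    table: np.ndarray  # 2x2 (called x in-annotation)
    chi2_stat: float
    chi2_p: float
    boot_p: float
    n_boot: int
    observed_in_annotation: int


def region_enrichment(
    called: np.ndarray,
    in_annotation: np.ndarray,
    n_boot: int = 7000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of calls in an annotation over sufficiently-covered loci.

    Both arguments are boolean arrays over the covered loci.  The
    chi-square test (no continuity correction) uses the 2x2 called x
    in-annotation table; the bootstrap redistributes the observed number of
    calls uniformly (without replacement) across covered loci ``n_boot``
    times and reports the fraction of iterations with at least the observed
    number of annotated calls.
    """
    called = np.asarray(called, dtype=bool)
    in_annotation = np.asarray(in_annotation, dtype=bool)
    if called.shape != in_annotation.shape:
        raise ValueError("called and in_annotation must align")
    n_loci = called.size
    n_calls = int(called.sum())
    n_annot = int(in_annotation.sum())
    observed = int((called & in_annotation).sum())
    table = np.array([
        [observed, n_calls - observed],
        [n_annot - observed, (n_loci - n_calls) - (n_annot - observed)],
    ], dtype=float)
    if n_calls and n_annot and n_calls < n_loci and n_annot < n_loci:
        stat, p, _, _ = chi2_contingency(table, correction=False)
    else:
        stat, p = float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n_annot, n_loci - n_annot, n_calls,
                               size=n_boot) if n_calls else np.zeros(n_boot)
    boot_p = float((draws >= observed).mean())
    return EnrichmentResult(table, float(stat), float(p), boot_p, n_boot,
                            observed)


# --- deleteriousness ---------------------------------------------------------

def deleterious_classification(
    records: pd.DataFrame,
    threshold: float = CADD_DELETERIOUS,
) -> tuple[pd.Series, pd.DataFrame]:
    """CADD-based deleteriousness flags and per-functional-class
    proportions.

    A record is deleterious when its CADD score is at or above
    ``threshold`` (inclusive).  Records without a score are excluded from
    the proportions and tallied in the ``n_unscored`` column.
    """
    scored = records["cadd"].notna()
    flags = pd.Series(pd.NA, index=records.index, dtype="boolean")
    flags[scored] = records.loc[scored, "cadd"] >= threshold
    rows = []
    for fclass, grp in records.groupby("functional_class"):
        s = grp["cadd"].notna()
        rows.append({
            "functional_class": fclass,
            "n_scored": int(s.sum()),
            "n_unscored": int((~s).sum()),
            "prop_deleterious": float((grp.loc[s, "cadd"] >= threshold).mean())
            if s.any() else float("nan"),
        })
    return flags, pd.DataFrame(rows)
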