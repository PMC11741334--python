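"""Mixture power/FDR simulation and synthetic fixtures.

The mixture simulation emulates spiking a minor cell population into a
major one: at truth sites (alternative-homozygous in the notional minor
individual, reference-homozygous in the major) the expected alternative
count is the somatic fraction times depth; at background sites counts come
from the sequencing-error model alone.  The default grid — somatic
fractions 1%..10% in 0.25% steps, depths 50/100/300/500, ten iterations —
enumerates 1,480 mixed samples.

The background here is parametric (Beta-binomial error, mean 1e-4,
alpha 0.5) rather than resampled from real capture data, so absolute false
discovery rates at low depth are not comparable to what a caller sees on
real exomes; power and the orderings across frequency and depth are.

The cohort generator builds a random reference, per-sample count tables
with context-dependent Beta-binomial error, injected variants at chosen
VAFs, germline sites, duplicate sample pairs, and small valid SAM files
for end-to-end tests of the counting stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contexts import BASES
from .intervals import IntervalSet
from .model import BetaBinomialErrorModel, DEFAULT_P_THRESHOLD

DEFAULT_ERROR_MEAN = 1e-4
DEFAULT_ERROR_ALPHA = 0.5
DEFAULT_DEPTHS = (50, 100, 300, 500)


def error_beta(mean: float = DEFAULT_ERROR_MEAN,
               alpha: float = DEFAULT_ERROR_ALPHA) -> float:
    """Beta parameter matching a given mean error at fixed alpha."""
    return alpha * (1 - mean) / mean


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# --- the grid ---------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    freq: float
    depth: int
    iteration: int
    seed: int

    def __post_init__(self):
        if not 0 <= self.freq <= 1:
            raise ValueError("freq must be in [0, 1]")


def enumerate_grid(
    freq_min: float = 0.01,
    freq_max: float = 0.10,
    step: float = 0.0025,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    reps: int = 10,
    seed: int = 0,
) -> list[MixtureSpec]:
    """All (frequency, depth, iteration) mixture specs; the defaults yield
    the 37 x 4 x 10 = 1,480-sample study grid."""
    n_steps = (freq_max - freq_min) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must divide the frequency range")
    freqs = [freq_min + step * i for i in range(round(n_steps) + 1)]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(freqs) * len(depths) * reps)
    specs = []
    i = 0
    for freq in freqs:
        for depth in depths:
            for rep in range(reps):
                specs.append(MixtureSpec(
                    freq=freq, depth=int(depth), iteration=rep,
                    seed=int(children[i].generate_state(1)[0] % (2 ** 31)),
                ))
                i += 1
    return specs


# --- mixed samples ----------------------------------------------------------

def make_mixture(
    spec: MixtureSpec,
    n_background: int = 100_000,
    n_truth: int = 500,
    error_mean: float = DEFAULT_ERROR_MEAN,
    error_alpha: float = DEFAULT_ERROR_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated per-locus counts of one mixed sample plus its truth table.

    Truth sites get alt count round(freq x depth) — halves away from zero —
    plus a background-error draw (errors do not vanish at somatic loci);
    background sites draw from Beta-binomial error alone.  If freq x depth
    rounds to zero the site is retained with background counts only: the
    resulting power loss is real.
    """
    rng = np.random.default_rng(spec.seed)
    dp = spec.depth
    b = error_beta(error_mean, error_alpha)
    n = n_background + n_truth
    p_err = rng.beta(error_alpha, b, size=n)
    ac = rng.binomial(dp, p_err)
    is_truth = np.zeros(n, dtype=bool)
    is_truth[n_background:] = True
    true_vaf = np.zeros(n)
    if spec.freq > 0:
        signal = round_half_away(spec.freq * dp)
        ac[n_background:] = np.minimum(ac[n_background:] + signal, dp)
        true_vaf[n_background:] = spec.freq
    counts = pd.DataFrame({
        "site": np.arange(n),
        "depth": dp,
        "ac": ac,
        "vaf": ac / dp,
    })
    truth = pd.DataFrame({
        "site": np.arange(n),
        "label": np.where(is_truth & (true_vaf > 0), "somatic", "background"),
        "true_vaf": true_vaf,
    })
    return counts, truth


def evaluate_calls(called_sites: Iterable[int], truth: pd.DataFrame
                   ) -> tuple[float, float]:
    """(power, FDR) of a set of called site ids against the truth table.

    Power = called somatic / total somatic; FDR = called background / total
    called, with FDR defined as 0 when nothing is called.
    """
    called = set(called_sites)
    somatic = set(truth.loc[truth["label"] == "somatic", "site"])
    n_called = len(called)
    power = len(called & somatic) / len(somatic) if somatic else float("nan")
    fdr = len(called - somatic) / n_called if n_called else 0.0
    return power, fdr


def run_mixture(
    spec: MixtureSpec,
    n_background: int = 100_000,
    n_truth: int = 500,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    error_mean: float = DEFAULT_ERROR_MEAN,
    error_alpha: float = DEFAULT_ERROR_ALPHA,
) -> tuple[float, float]:
    """Simulate one mixed sample, fit the pooled null on its background
    sites, call at the threshold, and return (power, FDR).

    The null is fitted without contexts, matching how the mixture study
    analyses simulated counts.
    """
    counts, truth = make_mixture(spec, n_background, n_truth,
                                 error_mean, error_alpha)
    background = counts[truth["label"].to_numpy() == "background"]
    results = BetaBinomialErrorModel(background, min_depth=1,
                                     by_context=False).fit()
    calls = results.call(counts, p_threshold=p_threshold)
    called = counts.loc[calls["is_candidate"].to_numpy(), "site"]
    return evaluate_calls(called, truth)


def power_fdr_grid(
    freqs: Sequence[float],
    depths: Sequence[int] = DEFAULT_DEPTHS,
    reps: int = 10,
    seed: int = 0,
    n_background: int = 100_000,
    n_truth: int = 500,
    **kwargs,
) -> pd.DataFrame:
    """Power and FDR per (freq, depth, iteration) over a grid."""
    if len(freqs) == 1:
        specs = enumerate_grid(freqs[0], freqs[0], 1.0, depths, reps, seed)
    else:
        step = freqs[1] - freqs[0]
        specs = enumerate_grid(freqs[0], freqs[-1], step, depths, reps, seed)
    rows = []
    for spec in specs:
        power, fdr = run_mixture(spec, n_background, n_truth, **kwargs)
        rows.append({"freq": spec.freq, "depth": spec.depth,
                     "iteration": spec.iteration, "power": power, "fdr": fdr})
    return pd.DataFrame(rows)


def power_at_fraction(
    freq: float = 0.075,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    n_seeds: int = 10,
    seed: int = 0,
    n_background: int = 100_000,
    n_truth: int = 500,
    **kwargs,
) -> pd.DataFrame:
    """Detection power at one somatic fraction across depths and seeds.

    Per (depth, seed): simulate a mixed sample, fit the pooled null on its
    background, call at the default threshold, measure power and FDR.
    Returns the per-cell table; aggregate (e.g. minimum over seeds) as
    needed.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(depths) * n_seeds)
    rows = []
    i = 0
    for depth in depths:
        for rep in range(n_seeds):
            spec = MixtureSpec(
                freq=freq, depth=int(depth), iteration=rep,
                seed=int(children[i].generate_state(1)[0] % (2 ** 31)))
            power, fdr = run_mixture(spec, n_background, n_truth, **kwargs)
            rows.append({"depth": int(depth), "iteration": rep,
                         "power": power, "fdr": fdr})
            i += 1
    return pd.DataFrame(rows)


# --- synthetic cohorts ------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions for the parametric cohort generator.

    Depths are Gamma-Poisson (mean ``depth_mean``, dispersion
    ``depth_dispersion``), mimicking overdispersed capture coverage around
    the cohort's post-QC mean of ~140x.  Error rates are Beta-distributed
    per trinucleotide context (defaults: mean 1e-4, alpha 0.5 for every
    context, overridable per context).  ``injected`` lists
    (sample, site_index, vaf) somatic variants.
    """

    n_sites: int = 2000
    n_donors: int = 2
    n_tissues: int = 3
    depth_mean: float = 140.0
    depth_dispersion: float = 10.0
    error_mean: float = DEFAULT_ERROR_MEAN
    error_alpha: float = DEFAULT_ERROR_ALPHA
    context_errors: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    injected: tuple = ()  # of (sample_name, site_index, vaf)
    n_germline: int = 20
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.base_weights) - 1) > 1e-9:
            raise ValueError("base_weights must sum to 1")

    def sample_names(self) -> list[str]:
        return [f"D{d}_T{t}" for d in range(self.n_donors)
                for t in range(self.n_tissues)]

    def donor_of(self, sample: str) -> str:
        return sample.split("_")[0]


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    reference: dict[str, str]
    counts: dict[str, pd.DataFrame]  # sample -> count table
    truth: pd.DataFrame  # sample, chrom, pos, alt, true_vaf
    germline: dict[str, dict[str, list[int]]]  # donor -> chrom -> positions
    bed: IntervalSet
    site_positions: np.ndarray  # 1-based positions of simulated sites


def simulate_cohort_counts(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate per-sample count tables, truth, germline sites and a BED.

    Deterministic under the spec seed: identical specs give byte-identical
    outputs when serialized.
    """
    from .contexts import PURINES, revcomp
    from .pileup import COUNT_COLUMNS

    rng = np.random.default_rng(spec.seed)
    chrom = "sim1"
    ref_len = spec.n_sites + 2
    ref = "".join(rng.choice(list(BASES), size=ref_len,
                             p=list(spec.base_weights)))
    positions = np.arange(2, spec.n_sites + 2)  # 1-based, flanks exist
    contexts = np.array([ref[p - 2:p + 1] for p in positions])
    refs = np.array([c[1] for c in contexts])
    ctx_keys = np.array([revcomp(c) if c[1] in PURINES else c
                         for c in contexts])
    default_b = error_beta(spec.error_mean, spec.error_alpha)
    ab = np.array([
        spec.context_errors.get(k, (spec.error_alpha, default_b))
        for k in ctx_keys
    ])

    # germline sites, per donor: heterozygous in every tissue of the donor
    germ_idx = rng.choice(spec.n_sites, size=min(spec.n_germline, spec.n_sites),
                          replace=False)
    donors = [f"D{d}" for d in range(spec.n_donors)]
    germline: dict[str, dict[str, list[int]]] = {d: {chrom: []} for d in donors}
    for i, idx in enumerate(sorted(germ_idx)):
        donor = donors[i % len(donors)]
        germline[donor][chrom].append(int(positions[idx]))

    injected_by_sample: dict[str, list[tuple[int, float]]] = {}
    for sample, site_idx, vaf in spec.injected:
        injected_by_sample.setdefault(sample, []).append((site_idx, float(vaf)))

    counts: dict[str, pd.DataFrame] = {}
    truth_rows = []
    alt_choices = {b: [x for x in BASES if x != b] for b in BASES}
    for sample in spec.sample_names():
        donor = spec.donor_of(sample)
        lam = rng.gamma(spec.depth_dispersion,
                        spec.depth_mean / spec.depth_dispersion,
                        size=spec.n_sites)
        dp = np.maximum(rng.poisson(lam), 1)
        p_err = rng.beta(ab[:, 0], ab[:, 1])
        ac = rng.binomial(dp, p_err)
        germ_positions = set(germline[donor][chrom])
        is_germ = np.array([int(p) in germ_positions for p in positions])
        ac[is_germ] = rng.binomial(dp[is_germ], 0.5)
        alt = np.array([
            rng.choice(alt_choices[r]) if a > 0 else "."
            for r, a in zip(refs, ac)
        ], dtype=object)
        for site_idx, vaf in injected_by_sample.get(sample, ()):
            extra = rng.binomial(dp[site_idx], vaf)
            ac[site_idx] = min(ac[site_idx] + extra, dp[site_idx])
            if alt[site_idx] == ".":
                alt[site_idx] = rng.choice(alt_choices[refs[site_idx]])
            truth_rows.append({
                "sample": sample, "chrom": chrom,
                "pos": int(positions[site_idx]),
                "alt": alt[site_idx], "true_vaf": vaf,
            })
        ac = np.minimum(ac, dp)
        alt_fwd = rng.binomial(ac, 0.5)
        ref_fwd = rng.binomial(dp - ac, 0.5)
        table = {col: np.zeros(spec.n_sites, dtype=np.int64)
                 for col in ("A_fwd", "A_rev", "C_fwd", "C_rev",
                             "G_fwd", "G_rev", "T_fwd", "T_rev")}
        for i in range(spec.n_sites):
            r = refs[i]
            table[f"{r}_fwd"][i] += ref_fwd[i]
            table[f"{r}_rev"][i] += dp[i] - ac[i] - ref_fwd[i]
            if ac[i] > 0:
                table[f"{alt[i]}_fwd"][i] += alt_fwd[i]
                table[f"{alt[i]}_rev"][i] += ac[i] - alt_fwd[i]
        df = pd.DataFrame({
            "chrom": chrom, "pos": positions, "ref": refs,
            "context": contexts, "depth": dp, **table,
            "alt": alt, "ac": ac, "vaf": ac / dp,
        })[COUNT_COLUMNS]
        counts[sample] = df

    truth = pd.DataFrame(truth_rows,
                         columns=["sample", "chrom", "pos", "alt", "true_vaf"])
    bed = IntervalSet([(chrom, 1, spec.n_sites + 1)])
    return SyntheticCohort(spec, {chrom: ref}, counts, truth, germline, bed,
                           positions)


def simulate_duplicate_pair(
    n_sites: int = 1000,
    truth: Sequence[tuple[int, float]] = (),
    depth: int = 300,
    error_mean: float = DEFAULT_ERROR_MEAN,
    error_alpha: float = DEFAULT_ERROR_ALPHA,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two technical-replicate count tables conditioned on one shared truth.

    Both replicates share the true per-site VAFs (zero at background
    sites); sequencing noise is drawn independently per replicate, so the
    pair tests the replication-rate statistic.
    """
    rng = np.random.default_rng(seed)
    true_vaf = np.zeros(n_sites)
    for idx, vaf in truth:
        true_vaf[idx] = vaf
    b = error_beta(error_mean, error_alpha)
    out = []
    for _ in range(2):
        p_err = rng.beta(error_alpha, b, size=n_sites)
        ac = rng.binomial(depth, np.minimum(p_err + true_vaf, 1.0))
        out.append(pd.DataFrame({
            "site": np.arange(n_sites), "depth": depth, "ac": ac,
            "vaf": ac / depth, "true_vaf": true_vaf,
        }))
    return out[0], out[1]


# --- SAM fixtures -----------------------------------------------------------

def write_fasta(path, reference: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_sam_fixture(
    path,
    reference: Mapping[str, str],
    reads: Sequence[Mapping],
) -> None:
    """Write a minimal coordinate-sorted SAM.

    Each read dict has: name, chrom, start (0-based), and optionally
    length (75), flag (99), mapq (60), mismatches ({read_offset: base}),
    baseq (30), cigar (default full-match), quals (per-base list).
    NM is computed from the mismatches unless given explicitly as "nm".
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in reference.items()],
    }
    entries = []
    for spec_read in reads:
        entries.append(dict(spec_read))
    entries.sort(key=lambda r: (list(reference).index(r["chrom"]), r["start"]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in entries:
            length = r.get("length", 75)
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            a.flag = r.get("flag", 99)
            a.reference_id = list(reference).index(r["chrom"])
            a.reference_start = r["start"]
            a.mapping_quality = r.get("mapq", 60)
            cigar = r.get("cigar", f"{length}M")
            a.cigarstring = cigar
            seq = list(reference[r["chrom"]][r["start"]:r["start"] + length])
            for off, base in r.get("mismatches", {}).items():
                seq[off] = base
            a.query_sequence = "".join(seq)
            a.query_qualities = r.get(
                "quals", [r.get("baseq", 30)] * len(a.query_sequence))
            a.set_tag("NM", r.get("nm", len(r.get("mismatches", {}))))
            a.next_reference_id = a.reference_id
            a.next_reference_start = r.get("mate_start", r["start"])
            a.template_length = r.get("tlen", length)
            out.write(a)


def tiled_read_specs(
    chrom: str,
    region_start: int,
    region_end: int,
    depth_per_position: int,
    read_length: int = 75,
    alt_bases: Mapping[int, tuple[str, int]] = {},
    name_prefix: str = "r",
    margin: int = 5,
) -> list[dict]:
    """Read specs tiling a region so interior positions reach roughly the
    requested depth; ``alt_bases`` maps 0-based reference positions to
    (base, n_reads_carrying_it).  Alt bases are only placed at read offsets
    at least ``margin`` bases from either read end, so they survive default
    end trimming."""
    reads = []
    k = 0
    step = max(read_length // 2, 1)
    for start in range(region_start, max(region_end - read_length, region_start) + 1, step):
        for _ in range(depth_per_position):
            flag = 99 if k % 2 == 0 else 147
            reads.append({"name": f"{name_prefix}{k}", "chrom": chrom,
                          "start": start, "length": read_length, "flag": flag})
            k += 1
    remaining = {pos: list(spec) for pos, spec in alt_bases.items()}
    for read in reads:
        for pos, spec in remaining.items():
            base, n = spec
            if n > 0 and (read["start"] + margin <= pos
                          < read["start"] + read_length - margin):
                off = pos - read["start"]
                read.setdefault("mismatches", {})[off] = base
                spec[1] = n - 1
    for pos, (base, n) in ((p, tuple(s)) for p, s in remaining.items()):
        if n > 0:
            raise ValueError(f"could not place {n} alt reads at position {pos}")
    return reads
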