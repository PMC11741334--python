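"""Beta-binomial sequencing-error model and one-sided tail tests.

At a homozygous-reference site i with filtered depth DP_i, the alternative
allele count AC_i under the null (no somatic variant) is modelled as

    AC_i | p_j ~ Binomial(DP_i, p_j),      p_j ~ Beta(alpha_j, beta_j)

so marginally AC_i ~ BetaBinomial(DP_i, alpha_j, beta_j), where j indexes
the substitution-context class of the site (96 pyrimidine-centred
trinucleotide classes).  The Beta layer captures overdispersion of the
per-site error rate relative to a single binomial error; (alpha_j, beta_j)
are estimated by maximum likelihood independently per class.  A site is a
candidate somatic variant when the exact upper-tail probability
P(AC >= ac_obs) falls below a stringent threshold (1e-8 by default).

The model/results split follows the statsmodels convention:
``BetaBinomialErrorModel(counts).fit()`` returns a
``BetaBinomialErrorResults`` carrying per-class parameter estimates,
fit diagnostics, a ``summary()`` table, and the ``call()`` method that
computes per-site p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

from .contexts import CLASS_LABELS, canonical_class

LOG_BOUND = (np.log(1e-8), np.log(1e8))
DEFAULT_P_THRESHOLD = 1e-8


# --- exact Beta-binomial tail ------------------------------------------------

def betabin_logpmf(k, n, alpha: float, beta: float):
    """log P(AC = k) for AC ~ BetaBinomial(n, alpha, beta)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + alpha, n - k + beta)
        - betaln(alpha, beta)
    )


def betabin_tail(ac: int, dp: int, alpha: float, beta: float) -> float:
    """Exact upper tail P(AC >= ac) of BetaBinomial(dp, alpha, beta).

    Computed by direct log-space summation of the pmf from ac to dp, which
    keeps full relative precision for the small tail probabilities the
    caller thresholds on.  P(AC >= 0) is 1 by convention.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if ac < 0 or dp < 0 or ac > dp:
        raise ValueError(f"require 0 <= ac <= dp, got ac={ac}, dp={dp}")
    if ac == 0:
        return 1.0
    k = np.arange(ac, dp + 1)
    return float(np.exp(logsumexp(betabin_logpmf(k, dp, alpha, beta))))


# --- per-class MLE -----------------------------------------------------------

@dataclass(frozen=True)
class ContextModel:
    """Fitted Beta-binomial null for one substitution-context class."""

    class_label: str
    alpha: float
    beta: float
    n_sites: int
    loglik: float
    converged: bool
    flag: str = ""  # "", "pooled_fallback", "degenerate"

    @property
    def mean_error(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def _negloglik(logab: np.ndarray, ac: np.ndarray, dp: np.ndarray,
               w: np.ndarray) -> float:
    a, b = np.exp(logab)
    return -float(np.sum(w * betabin_logpmf(ac, dp, a, b)))


def _moment_start(ac: np.ndarray, dp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Method-of-moments (alpha, beta) start on the log scale.

    If the sample shows no overdispersion beyond binomial, start at a
    near-binomial parameterisation (alpha+beta = 1e6 at the observed mean).
    """
    n_tot = w.sum()
    vaf = ac / dp
    m = float(np.sum(w * vaf) / n_tot)
    m = min(max(m, 1e-8), 1 - 1e-8)
    v = float(np.sum(w * (vaf - m) ** 2) / n_tot)
    nbar = float(np.sum(w * dp) / n_tot)
    binom_v = m * (1 - m) / nbar
    if v > binom_v and nbar > 1:
        rho = (v - binom_v) / (m * (1 - m) * (1 - 1 / nbar))
        rho = min(max(rho, 1e-8), 1 - 1e-8)
        s = (1 - rho) / rho
    else:
        s = 1e6
    a = min(max(m * s, 1.1e-8), 9e7)
    b = min(max((1 - m) * s, 1.1e-8), 9e7)
    return np.log([a, b])


def fit_context_mle(
    ac: Sequence[int] | np.ndarray,
    dp: Sequence[int] | np.ndarray,
    class_label: str = "pooled",
    min_depth: int = 10,
    min_sites: int = 100,
    pooled: ContextModel | None = None,
) -> ContextModel:
    """Maximum-likelihood (alpha, beta) for one class of (ac, dp) pairs.

    Optimizes over (log alpha, log beta) with L-BFGS-B, bounded in
    [1e-8, 1e8], starting from method-of-moments estimates.  Identical
    (ac, dp) pairs are collapsed to weighted terms, so the cost scales with
    the number of distinct pairs rather than sites.  Classes with fewer than
    ``min_sites`` pairs fall back to the supplied pooled model (flagged);
    all-zero classes return a boundary fit flagged "degenerate".
    """
    ac = np.asarray(ac, dtype=np.int64)
    dp = np.asarray(dp, dtype=np.int64)
    keep = dp >= min_depth
    ac, dp = ac[keep], dp[keep]
    n = ac.size
    if n < min_sites:
        if pooled is None:
            raise ValueError(
                f"class {class_label!r} has {n} < {min_sites} sites and no "
                f"pooled fallback"
            )
        return ContextModel(class_label, pooled.alpha, pooled.beta, n,
                            float("nan"), pooled.converged, "pooled_fallback")
    pairs, w = np.unique(np.stack([ac, dp], axis=1), axis=0, return_counts=True)
    uac, udp = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
    w = w.astype(float)
    if ac.sum() == 0:
        # likelihood increases monotonically as the mean error goes to zero;
        # report the boundary fit
        a, b = 1e-8, 1.0
        ll = float(np.sum(w * betabin_logpmf(uac, udp, a, b)))
        return ContextModel(class_label, a, b, n, ll, True, "degenerate")
    x0 = _moment_start(uac, udp, w)
    res = minimize(
        _negloglik, x0, args=(uac, udp, w), method="L-BFGS-B",
        bounds=[LOG_BOUND, LOG_BOUND],
    )
    a, b = np.exp(res.x)
    return ContextModel(class_label, float(a), float(b), n, -float(res.fun),
                        bool(res.success))


# --- Model / Results ---------------------------------------------------------

class BetaBinomialErrorModel:
    """Per-context Beta-binomial null model of sequencing error counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Count table with at least columns ``ac``, ``depth`` and (unless
        ``by_context=False``) ``context``, ``ref`` and ``alt`` — the layout
        written by the counting stage.
    min_depth : int
        Sites below this depth are excluded from the fit.
    min_sites : int
        Minimum (ac, dp) pairs for a per-class fit; sparser classes fall
        back to the pooled all-class fit.
    by_context : bool
        If False, fit a single pooled model and use it for every site (the
        mode used by the mixture power/FDR simulation).
    """

    def __init__(self, counts: pd.DataFrame, min_depth: int = 10,
                 min_sites: int = 100, by_context: bool = True):
        required = {"ac", "depth"}
        if not required <= set(counts.columns):
            raise ValueError(f"counts table must have columns {sorted(required)}")
        self.counts = counts
        self.min_depth = min_depth
        self.min_sites = min_sites
        self.by_context = by_context

    @classmethod
    def from_counts_file(cls, path, **kwargs) -> "BetaBinomialErrorModel":
        from .io import read_counts
        return cls(read_counts(path), **kwargs)

    def fit(self) -> "BetaBinomialErrorResults":
        df = self.counts[self.counts["depth"] >= self.min_depth]
        pooled = fit_context_mle(
            df["ac"].to_numpy(), df["depth"].to_numpy(), "pooled",
            min_depth=self.min_depth, min_sites=1,
        )
        models: dict[str, ContextModel] = {}
        if self.by_context:
            labels = site_class_labels(df)
            ctx_keys = site_context_keys(df)
            for label in CLASS_LABELS:
                # ac=0 sites carry zero counts of every alt, so they enter
                # the likelihood of all three classes sharing their context
                sub = df[(labels == label)
                         | ((labels == "") & (ctx_keys == class_context(label)))]
                models[label] = fit_context_mle(
                    sub["ac"].to_numpy(), sub["depth"].to_numpy(), label,
                    min_depth=self.min_depth, min_sites=self.min_sites,
                    pooled=pooled,
                )
        return BetaBinomialErrorResults(self, pooled, models)


def site_class_labels(df: pd.DataFrame) -> pd.Series:
    """96-class label per site; sites with ac=0 (no alt allele) get ``""``."""
    labels = []
    for ref, ctx, alt in zip(df["ref"], df["context"], df["alt"]):
        if alt in (None, ".", "") or (isinstance(alt, float) and np.isnan(alt)):
            labels.append("")
        else:
            labels.append(canonical_class(ctx, ref, alt))
    return pd.Series(labels, index=df.index)


def site_context_keys(df: pd.DataFrame) -> pd.Series:
    """Pyrimidine-centred context per site (e.g. "ACG"), via revcomp when
    the reference base is a purine."""
    from .contexts import PURINES, revcomp

    keys = []
    for ref, ctx in zip(df["ref"], df["context"]):
        keys.append(revcomp(ctx) if ref in PURINES else ctx)
    return pd.Series(keys, index=df.index)


def class_context(label: str) -> str:
    """Context trinucleotide of a class label: "A[C>T]G" -> "ACG"."""
    return label[0] + label[2] + label[6]


class BetaBinomialErrorResults:
    """Fitted per-context Beta-binomial nulls with calling methods."""

    def __init__(self, model: BetaBinomialErrorModel, pooled: ContextModel,
                 context_models: dict[str, ContextModel]):
        self.model = model
        self.pooled = pooled
        self.context_models = context_models

    def model_for(self, class_label: str | None) -> ContextModel:
        if class_label and self.context_models:
            try:
                return self.context_models[class_label]
            except KeyError:
                raise KeyError(
                    f"no model for class {class_label!r} and no pooled fallback"
                ) from None
        return self.pooled

    @property
    def params(self) -> pd.DataFrame:
        """Per-class (alpha, beta) table, with the pooled fit last."""
        rows = [
            {"class_label": m.class_label, "alpha": m.alpha, "beta": m.beta,
             "mean_error": m.mean_error, "n_sites": m.n_sites,
             "loglik": m.loglik, "converged": m.converged, "flag": m.flag}
            for m in list(self.context_models.values()) + [self.pooled]
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.params
        n_fit = int((p["flag"] == "").sum())
        lines = [
            "Beta-binomial sequencing-error null model",
            "=" * 57,
            f"Sites in fit:          {len(self.model.counts)}",
            f"Classes fitted:        {n_fit} of {len(p) - 1}"
            if self.context_models else "Pooled fit only (no contexts)",
            f"Pooled mean error:     {self.pooled.mean_error:.3g}",
            f"Pooled (alpha, beta):  ({self.pooled.alpha:.4g}, {self.pooled.beta:.4g})",
            f"Pooled log-likelihood: {self.pooled.loglik:.4g}",
        ]
        return "\n".join(lines)

    def tail(self, ac: int, dp: int, class_label: str | None = None) -> float:
        m = self.model_for(class_label)
        return betabin_tail(ac, dp, m.alpha, m.beta)

    def call(
        self,
        sites: pd.DataFrame | None = None,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        nonzero_only: bool = False,
    ) -> pd.DataFrame:
        """Per-site upper-tail p-values and candidate flags.

        A site is a candidate iff p < ``p_threshold`` (strict).  Sites with
        ac = 0 get p = 1 and are dropped when ``nonzero_only`` is set.
        Distinct (class, ac, depth) triples are evaluated once and
        broadcast, so calling scales with the number of distinct triples.
        """
        if sites is None:
            sites = self.model.counts
        df = sites.copy()
        if self.context_models:
            df["class_label"] = site_class_labels(df)
        else:
            df["class_label"] = ""
        if nonzero_only:
            df = df[df["ac"] > 0].copy()
        triples = df[["class_label", "ac", "depth"]].drop_duplicates()
        pvals = {}
        for label, ac, dp in triples.itertuples(index=False):
            if ac == 0:
                pvals[(label, ac, dp)] = 1.0
            else:
                m = self.model_for(label or None)
                pvals[(label, ac, dp)] = betabin_tail(int(ac), int(dp),
                                                      m.alpha, m.beta)
        df["p_value"] = [
            pvals[(l, a, d)]
            for l, a, d in zip(df["class_label"], df["ac"], df["depth"])
        ]
        df["is_candidate"] = df["p_value"] < p_threshold
        return df

    def ab_table(self, path=None) -> pd.DataFrame:
        """The per-class alpha/beta TSV (class_label, alpha, beta, n_sites,
        loglik); written to ``path`` if given."""
        cols = ["class_label", "alpha", "beta", "n_sites", "loglik"]
        table = self.params[cols]
        if path is not None:
            table.to_csv(path, sep="\t", index=False)
        return table
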