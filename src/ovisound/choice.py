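"""Count and choice inference for two-choice oviposition experiments.

* :func:`fit_poisson_glmm` — nightly cluster counts, Poisson log-link mixed
  model with the playback/control indicator and the number of females as
  fixed effects and nested random intercepts.  The treatment coefficient is
  the preference estimate (a log rate ratio: exp of it is the fold-change in
  expected clusters on the treatment side).
* :func:`bayes_choice_posterior` — per-cluster 0/1 choices under a Gaussian
  likelihood with a N(0.5, 0.1^2) prior on the mean choice probability, an
  optional random intercept grouped by the experiment's female count, and
  half-normal(0, 1) priors on the residual and group SDs, sampled by Gibbs
  (slice steps for the SDs).
* :func:`pearson_chi2` — uncorrected Pearson chi-square on a 2x2 table
  (the deafening validation).
* :func:`laying_probability_comparison` — proportion of nights with any
  laying in two experiments, compared by Fisher's exact test (the exact
  construction of the original "binomial test" is not specified, so the
  output labels the method actually used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GlmmFit, fit_glmm
from .simulate import child_rng

__all__ = [
    "GlmmSpec",
    "ChoicePosterior",
    "Chi2Result",
    "LayingComparison",
    "nights_to_long",
    "exclude_empty_nights",
    "fit_poisson_glmm",
    "bayes_choice_posterior",
    "pearson_chi2",
    "laying_probability_comparison",
]


@dataclass
class GlmmSpec:
    """Model specification for the nightly cluster-count GLMM."""

    response: str = "clusters"
    fixed: Sequence[str] = ("treatment", "n_females")
    random_intercepts: Sequence[str] = ("arena_id", "repetition_id", "night_id")
    family: str = "poisson"

    def __post_init__(self) -> None:
        if self.family != "poisson":
            raise ValueError("cluster-count model family is Poisson")
        if "treatment" not in self.fixed:
            raise ValueError("fixed effects must include the treatment indicator")
        if not list(self.random_intercepts):
            raise ValueError("at least one grouping field required (use fit_glmm for a GLM)")


def exclude_empty_nights(nights: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop arena-nights with zero clusters on both sides; return (kept, n_dropped)."""
    empty = (nights["clusters_treatment"] + nights["clusters_control"]) == 0
    return nights.loc[~empty].reset_index(drop=True), int(empty.sum())


def nights_to_long(nights: pd.DataFrame) -> pd.DataFrame:
    """Reshape night records to one row per arena-side with a 0/1 treatment flag.

    Adds a ``night_id`` key nested within repetition within arena so the
    night-level random intercept has one level per physical night.
    """
    required = {
        "arena_id",
        "repetition_id",
        "night_index",
        "n_females",
        "clusters_treatment",
        "clusters_control",
    }
    missing = required - set(nights.columns)
    if missing:
        raise ValueError(f"night records missing columns: {sorted(missing)}")
    base = nights.copy()
    base["night_id"] = (
        base["arena_id"].astype(str)
        + "/"
        + base["repetition_id"].astype(str)
        + "/n"
        + base["night_index"].astype(str)
    )
    t = base.copy()
    t["treatment"] = 1
    t["clusters"] = base["clusters_treatment"]
    c = base.copy()
    c["treatment"] = 0
    c["clusters"] = base["clusters_control"]
    keep = [col for col in base.columns if col not in ("clusters_treatment", "clusters_control")]
    long = pd.concat([t, c], ignore_index=True)[keep + ["treatment", "clusters"]]
    return long


def fit_poisson_glmm(
    nights: pd.DataFrame,
    spec: Optional[GlmmSpec] = None,
    exclude_empty: bool = True,
) -> GlmmFit:
    """Fit the Poisson mixed model to nightly cluster counts.

    Both sides of one arena-night are equal-exposure observations; the
    number of females enters as a (centered) fixed covariate.  Nights with
    zero clusters on both sides are excluded first (the count of dropped
    nights is recorded in ``fit.notes``).
    """
    spec = spec or GlmmSpec()
    n_dropped = 0
    if exclude_empty:
        nights, n_dropped = exclude_empty_nights(nights)
    if len(nights) == 0:
        raise ValueError("no nights left after excluding empty ones")
    long = nights_to_long(nights)
    X = pd.DataFrame({"intercept": np.ones(len(long))})
    for name in spec.fixed:
        col = long[name].astype(float)
        if name == "n_females":
            col = col - col.mean()  # centering: conditioning only, slope unchanged
        if name != "treatment" and col.nunique() < 2:
            continue  # constant covariate carries no information
        X[name] = col
    groups = {g: long[g].to_numpy() for g in spec.random_intercepts}
    fit = fit_glmm(long["clusters"].to_numpy(), X, groups, family="poisson")
    fit.notes.append(f"excluded_empty_nights={n_dropped}")
    return fit


# ---------------------------------------------------------------------------
# Bayesian choice posterior
# ---------------------------------------------------------------------------


@dataclass
class ChoicePosterior:
    """Posterior over the probability-scale mean choice ``mu``."""

    draws: np.ndarray
    prior_mean: float
    prior_sd: float
    mean: float
    sd: float
    ci95: tuple[float, float]
    group_effect_sd: Optional[np.ndarray] = None
    resid_sd: Optional[np.ndarray] = None
    n_obs: int = 0

    def summary(self) -> Dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "n_obs": self.n_obs,
        }


def _slice_sample_log_sd(log_sd: float, logpost, rng, w: float = 1.0, m: int = 50) -> float:
    """One slice-sampling update (stepping out + shrinkage) on log(sd)."""
    f0 = logpost(log_sd)
    level = f0 + np.log(rng.random())
    lo = log_sd - w * rng.random()
    hi = lo + w
    j = int(m * rng.random())
    k = m - 1 - j
    while j > 0 and level < logpost(lo):
        lo -= w
        j -= 1
    while k > 0 and level < logpost(hi):
        hi += w
        k -= 1
    for _ in range(100):
        prop = lo + (hi - lo) * rng.random()
        if level < logpost(prop):
            return prop
        if prop < log_sd:
            lo = prop
        else:
            hi = prop
    return log_sd


def bayes_choice_posterior(
    choices,
    n_draws: int = 16000,
    seed: int = 0,
    prior_mean: float = 0.5,
    prior_sd: float = 0.1,
    include_random_effect: bool = True,
    resid_sd: Optional[float] = None,
    burn: int = 1000,
) -> ChoicePosterior:
    """Posterior for the mean choice probability from 0/1 cluster choices.

    ``choices`` is a DataFrame with columns ``choice01`` (1 = tested side)
    and, when the random effect is used, ``n_females`` (the grouping value),
    or a plain 0/1 sequence.  With no observations the posterior equals the
    prior (returned as draws, not an error).  Fix ``resid_sd`` to disable
    its half-normal prior (used by the conjugate-oracle checks).
    """
    if isinstance(choices, pd.DataFrame):
        y = choices["choice01"].to_numpy(dtype=float)
        group_vals = (
            choices["n_females"].to_numpy() if "n_females" in choices.columns else None
        )
    else:
        y = np.asarray(choices, dtype=float)
        group_vals = None
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = child_rng(seed, "gibbs")
    n = y.size

    if n == 0:
        draws = rng.normal(prior_mean, prior_sd, size=n_draws)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return ChoicePosterior(
            draws=draws,
            prior_mean=prior_mean,
            prior_sd=prior_sd,
            mean=float(draws.mean()),
            sd=float(draws.std(ddof=1)),
            ci95=(float(lo), float(hi)),
            n_obs=0,
        )

    use_re = include_random_effect and group_vals is not None
    if use_re:
        codes, uniques = pd.factorize(group_vals)
        G = len(uniques)
        if G < 2:
            use_re = False
    if use_re:
        counts = np.bincount(codes, minlength=G).astype(float)

    sigma = resid_sd if resid_sd is not None else 0.5
    tau = 0.3
    mu = prior_mean
    a = np.zeros(G) if use_re else 0.0

    mu_draws = np.empty(n_draws)
    tau_draws = np.empty(n_draws) if use_re else None
    sig_draws = np.empty(n_draws) if resid_sd is None else None

    prior_prec = 1.0 / prior_sd**2
    total = burn + n_draws
    for it in range(total):
        resid_off = a[codes] if use_re else 0.0
        # mu | rest : normal-normal
        prec = prior_prec + n / sigma**2
        m = (prior_mean * prior_prec + np.sum(y - resid_off) / sigma**2) / prec
        mu = rng.normal(m, 1.0 / np.sqrt(prec))
        # group intercepts
        if use_re:
            prec_a = 1.0 / tau**2 + counts / sigma**2
            m_a = (np.bincount(codes, weights=y - mu, minlength=G) / sigma**2) / prec_a
            a = rng.normal(m_a, 1.0 / np.sqrt(prec_a))
            resid_off = a[codes]
            # tau | a : half-normal(0,1) prior, slice step on log tau
            ssa = float(np.sum(a**2))

            def lp_tau(lt, _ssa=ssa, _G=G):
                t2 = np.exp(2.0 * lt)
                return -_G * lt - _ssa / (2.0 * t2) - t2 / 2.0 + lt  # +lt: log-scale Jacobian

            tau = float(np.exp(_slice_sample_log_sd(np.log(tau), lp_tau, rng)))
        # residual sd
        if resid_sd is None:
            ssr = float(np.sum((y - mu - resid_off) ** 2))

            def lp_sig(ls, _ssr=ssr, _n=n):
                s2 = np.exp(2.0 * ls)
                return -_n * ls - _ssr / (2.0 * s2) - s2 / 2.0 + ls

            sigma = float(np.exp(_slice_sample_log_sd(np.log(sigma), lp_sig, rng)))
        if it >= burn:
            k = it - burn
            mu_draws[k] = mu
            if use_re:
                tau_draws[k] = tau
            if resid_sd is None:
                sig_draws[k] = sigma

    lo, hi = np.percentile(mu_draws, [2.5, 97.5])
    return ChoicePosterior(
        draws=mu_draws,
        prior_mean=prior_mean,
        prior_sd=prior_sd,
        mean=float(mu_draws.mean()),
        sd=float(mu_draws.std(ddof=1)),
        ci95=(float(lo), float(hi)),
        group_effect_sd=tau_draws,
        resid_sd=sig_draws,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# 2x2 chi-square and laying-probability comparison
# ---------------------------------------------------------------------------


@dataclass
class Chi2Result:
    q: float
    df: int
    p: float


def pearson_chi2(table) -> Chi2Result:
    """Uncorrected Pearson chi-square on a 2x2 contingency table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square statistic undefined")
    q, p, df, _ = stats.chi2_contingency(t, correction=False)
    return Chi2Result(q=float(q), df=int(df), p=float(p))


@dataclass
class LayingComparison:
    prop_a: float
    prop_b: float
    n_a: int
    n_b: int
    p: float
    method: str = "fisher-exact-two-sided"


def laying_probability_comparison(
    nights_a: pd.DataFrame, nights_b: pd.DataFrame
) -> LayingComparison:
    """Compare the per-night probability of any laying between two experiments.

    Nights are labeled laid / not-laid before any exclusion; the two-sided
    exact test is Fisher's on the resulting 2x2 table.
    """
    if len(nights_a) == 0 or len(nights_b) == 0:
        raise ValueError("both night collections must be non-empty")

    def laid(df):
        return (df["clusters_treatment"] + df["clusters_control"] > 0).to_numpy()

    la, lb = laid(nights_a), laid(nights_b)
    table = [[int(la.sum()), int(len(la) - la.sum())], [int(lb.sum()), int(len(lb) - lb.sum())]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return LayingComparison(
        prop_a=float(la.mean()),
        prop_b=float(lb.mean()),
        n_a=len(la),
        n_b=len(lb),
        p=float(p),
    )
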