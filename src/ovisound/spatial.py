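"""Gradient-arena spatial analysis.

The 150 cm arena holds the speaker at -75 cm, the feeder at 0 and a silent
resistor at +75 cm.  Under the no-preference null the end holding the
speaker is arbitrary, so the null distribution of egg positions is built by
mirror-shuffling: each analysis unit's position x is replaced by s*x with a
fair random sign (the feeder at 0 is a fixed point).  The observed position
sample is compared with the pooled shuffle sample by the two-sample
Kolmogorov-Smirnov statistic D.

Because the pooled null shares its magnitudes |x| with the observed sample,
the classical asymptotic K-S p-value is conservative for this comparison
(the ECDF gap is a maximum of partial sums of fair signs, stochastically
smaller than the Brownian-bridge supremum).  The default p-value is
therefore an exact sign-randomization one: fresh shuffle replicates are
compared with the same pooled reference, and the observed D is ranked among
them — exchangeable under the null by construction.  The asymptotic formula
remains available as ``p_method="asymptotic"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import child_rng

__all__ = [
    "PermutationNullConfig",
    "KSResult",
    "mirror_shuffle_null",
    "ks_two_sample",
    "gradient_test",
    "spatial_density",
    "ARENA_HALFLENGTH",
]

ARENA_HALFLENGTH = 75.0


@dataclass
class PermutationNullConfig:
    """Settings for the mirror-shuffle null.

    ``unit`` selects the analysis unit whose sign is re-randomized: every
    laid egg (positions repeated by cluster egg count) or every cluster.
    """

    n_shuffles: int = 1000
    seed: int = 0
    unit: str = "egg"

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.unit not in ("egg", "cluster"):
            raise ValueError("unit must be 'egg' or 'cluster'")


@dataclass
class KSResult:
    d: float
    p: float
    n_obs: int
    n_null: int
    p_method: str = "asymptotic"


def _unit_positions(eggs: pd.DataFrame, unit: str) -> np.ndarray:
    pos = eggs["position_cm"].to_numpy(dtype=float)
    bad = np.abs(pos) > ARENA_HALFLENGTH
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        rec = eggs.iloc[i]
        raise ValueError(
            f"position {rec['position_cm']} cm of cluster "
            f"'{rec.get('cluster_id', i)}' exceeds the {ARENA_HALFLENGTH} cm arena bound"
        )
    if unit == "egg":
        pos = np.repeat(pos, eggs["n_eggs"].to_numpy(dtype=int))
    return pos


def mirror_shuffle_null(eggs: pd.DataFrame, config: PermutationNullConfig) -> np.ndarray:
    """Pooled mirror-shuffle null positions.

    For each shuffle replicate, every unit's position is sign-flipped with
    probability 1/2 (equivalent to re-randomizing which end holds the
    speaker); all replicates are pooled into one sample.
    """
    pos = _unit_positions(eggs, config.unit)
    if pos.size == 0:
        raise ValueError("no positions to shuffle")
    rng = child_rng(config.seed, "shuffle")
    signs = rng.choice([-1.0, 1.0], size=(config.n_shuffles, pos.size))
    return (signs * np.abs(pos)).ravel()


def _ks_d(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    """Sup-distance between two ECDFs (right-continuous convention).

    Evaluated at the jump points of ``a`` only, from both sides: between
    consecutive a-jumps F_a is constant and F_b monotone, so the supremum is
    attained at one of these endpoints.  O(n log m) per call, which matters
    because the permutation p-value recomputes D for many replicates against
    one large pooled sample.
    """
    n, m = a_sorted.size, b_sorted.size
    vals, counts = np.unique(a_sorted, return_counts=True)
    cum = np.cumsum(counts)
    fa_right = cum / n
    fa_left = (cum - counts) / n
    fb_right = np.searchsorted(b_sorted, vals, side="right") / m
    fb_left = np.searchsorted(b_sorted, vals, side="left") / m
    d_plus = np.abs(fa_right - fb_right).max()
    d_minus = np.abs(fa_left - fb_left).max()
    return float(max(d_plus, d_minus))


def ks_two_sample(a, b) -> KSResult:
    """Two-sample K-S test; p from the asymptotic formula at the effective n."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(
        d=float(res.statistic), p=float(res.pvalue), n_obs=a.size, n_null=b.size
    )


def first_night_subset(eggs: pd.DataFrame) -> pd.DataFrame:
    """Each female's clusters from her first night with laying."""
    firsts = eggs.groupby("female_id")["night_index"].transform("min")
    return eggs.loc[eggs["night_index"] == firsts].reset_index(drop=True)


def gradient_test(
    eggs: pd.DataFrame,
    config: Optional[PermutationNullConfig] = None,
    first_night_only: bool = False,
    weight_by_eggs: bool = True,
    p_method: str = "permutation",
    n_null_draws: Optional[int] = None,
) -> KSResult:
    """Mirror-shuffle K-S test of egg positions against the symmetric null.

    ``weight_by_eggs`` expands each cluster position by its egg count (the
    per-egg analysis); otherwise clusters are the unit.  The pooled null
    re-randomizes the same unit.  ``p_method="permutation"`` (default) ranks
    the observed D among ``n_null_draws`` fresh replicates (defaults to
    ``n_shuffles - 1`` so the test is exact at conventional levels).  The
    replicates flip signs per *cluster* and then expand by egg count: eggs
    of one cluster share a position, so a physical re-randomization of the
    speaker end moves them together, and only cluster-level flips make the
    replicates exchangeable with the observed sample under the null.
    ``"asymptotic"`` applies the classical two-sample formula to observed
    vs. pooled null instead.
    """
    config = config or PermutationNullConfig()
    if p_method not in ("permutation", "asymptotic"):
        raise ValueError("p_method must be 'permutation' or 'asymptotic'")
    if first_night_only:
        eggs = first_night_subset(eggs)
        if len(eggs) == 0:
            raise ValueError("first-night restriction left no clusters")
    unit = "egg" if weight_by_eggs else "cluster"
    config = replace(config, unit=unit)
    obs = _unit_positions(eggs, unit)
    if obs.size == 0:
        raise ValueError("no observed positions")
    pooled = np.sort(mirror_shuffle_null(eggs, config))
    obs_sorted = np.sort(obs)
    d_obs = _ks_d(obs_sorted, pooled)
    if p_method == "asymptotic":
        res = ks_two_sample(obs, pooled)
        return KSResult(
            d=d_obs, p=res.p, n_obs=obs.size, n_null=pooled.size, p_method="asymptotic"
        )
    m = n_null_draws if n_null_draws is not None else max(config.n_shuffles - 1, 19)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(5, 1))  # sub-stream of "shuffle"
    )
    abs_clu = np.abs(eggs["position_cm"].to_numpy(dtype=float))
    counts = (
        eggs["n_eggs"].to_numpy(dtype=int) if unit == "egg" else np.ones(len(eggs), dtype=int)
    )
    exceed = 0
    for _ in range(m):
        signs = rng.choice([-1.0, 1.0], size=abs_clu.size)
        rep = np.sort(np.repeat(signs * abs_clu, counts))
        if _ks_d(rep, pooled) >= d_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (m + 1.0)
    return KSResult(d=d_obs, p=float(p), n_obs=obs.size, n_null=pooled.size, p_method="permutation")


def spatial_density(
    eggs: pd.DataFrame,
    unit: str = "egg",
    bandwidth="scott",
    grid_n: int = 513,
) -> pd.DataFrame:
    """Gaussian-kernel density of positions over the arena.

    ``unit="egg"`` weights each cluster by its egg count.  ``bandwidth`` is
    either a KDE rule name accepted by scipy or a kernel SD in cm.  The
    curve is renormalized to integrate to 1 over [-75, 75] (the kernel mass
    outside the arena is folded back by rescaling).
    """
    if unit not in ("egg", "cluster"):
        raise ValueError("unit must be 'egg' or 'cluster'")
    pos = eggs["position_cm"].to_numpy(dtype=float)
    if np.unique(pos).size < 2:
        raise ValueError("need at least 2 distinct positions for a density")
    weights = eggs["n_eggs"].to_numpy(dtype=float) if unit == "egg" else None
    kde = stats.gaussian_kde(pos, weights=weights)
    if isinstance(bandwidth, (int, float)):
        wstd = np.sqrt(np.cov(pos, aweights=weights)) if weights is not None else pos.std(ddof=1)
        kde.set_bandwidth(float(bandwidth) / float(wstd))
    elif bandwidth != "scott":
        kde.set_bandwidth(bandwidth)
    grid = np.linspace(-ARENA_HALFLENGTH, ARENA_HALFLENGTH, grid_n)
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    dens = dens / area
    return pd.DataFrame({"position_cm": grid, "density": dens})
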