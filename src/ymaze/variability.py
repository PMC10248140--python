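"""Across-fly turn-bias variability: MAD, bootstrap SE, permutation tests.

The phenotype of interest is not a group's mean turn bias but its spread:
how unpredictable individual flies are. Spread is measured by the MAD — the
median of absolute deviations from the median, with no consistency scaling —
which is robust to the extreme "righties" and "lefties" in the tails.

Group differences in MAD are tested by permutation: pool the two groups'
per-fly biases, reshuffle group labels preserving group sizes, and compare
the observed |MAD(a) - MAD(b)| with its shuffled null distribution. Small
problems can be enumerated exhaustively. Families of pairwise comparisons
are Benjamini-Hochberg adjusted. Rank tests (Kruskal-Wallis across groups,
one-sample Wilcoxon against 0.5, pairwise Mann-Whitney on turn rate)
accompany the dispersion analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_CHUNK = 4096  # permutation matrix rows held in memory at once


@dataclass
class GroupVariability:
    """One group's turn-bias MAD with its bootstrap standard error."""

    group: str
    n_flies: int
    mad: float
    bootstrap_se: float
    n_boot: int
    seed: int | None = None


@dataclass
class PermutationResult:
    """Permutation test of the absolute MAD difference between two groups."""

    group_a: str
    group_b: str
    observed_abs_diff: float
    n_perm: int
    n_exceed: int
    p_raw: float
    p_adjusted: float | None = None
    seed: int | None = None
    method: str = "montecarlo"
    tie_rule: str = "ge"


def compute_mad(values) -> float:
    """Median absolute deviation from the median (no consistency scaling)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("MAD of an empty sample is undefined")
    return float(np.median(np.abs(v - np.median(v))))


def _mad_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise MAD of a 2-D array."""
    med = np.median(x, axis=1, keepdims=True)
    return np.median(np.abs(x - med), axis=1)


def bootstrap_mad_se(values, n_boot: int = 1000, seed=None) -> float:
    """SD of the MAD over with-replacement resamples of the original size."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap SE needs at least two observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(np.std(_mad_rows(v[idx]), ddof=1))


def _exceeds(null: np.ndarray, observed: float, tie_rule: str) -> int:
    if tie_rule == "ge":
        # float-tolerant >=: permutation statistics equal to the observed one
        # up to rounding must count as ties
        return int(np.sum(null >= observed - 1e-12))
    if tie_rule == "greater":
        return int(np.sum(null > observed + 1e-12))
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def permutation_test_mad(
    group_a,
    group_b,
    n_perm: int = 99_999,
    seed=None,
    tie_rule: str = "ge",
    method: str = "montecarlo",
    plus_one: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> PermutationResult:
    """Permutation test of |MAD(a) - MAD(b)| between two groups of biases.

    Parameters
    ----------
    tie_rule
        "ge" (default) counts shuffled statistics >= the observed one —
        conservative and well defined for degenerate data; "greater" counts
        strict exceedances only.
    method
        "montecarlo" draws ``n_perm`` random relabelings; "exact" enumerates
        every label assignment (the identity included) and ignores
        ``n_perm`` and ``seed``.
    plus_one
        Use the (b + 1) / (B + 1) small-sample correction instead of the
        plain exceedance proportion (Monte Carlo only).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two flies for a MAD")
    observed = abs(compute_mad(a) - compute_mad(b))
    pool = np.concatenate([a, b])
    n, na = pool.size, a.size

    if method == "exact":
        n_assign = math.comb(n, na)
        null = np.empty(n_assign)
        mask = np.zeros(n, dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), na)):
            mask[:] = False
            mask[list(combo)] = True
            null[i] = abs(compute_mad(pool[mask]) - compute_mad(pool[~mask]))
        n_exceed = _exceeds(null, observed, tie_rule)
        return PermutationResult(
            label_a, label_b, observed, n_assign, n_exceed,
            n_exceed / n_assign, seed=None, method="exact", tie_rule=tie_rule,
        )

    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_exceed = 0
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        perm = rng.permuted(np.tile(pool, (m, 1)), axis=1)
        null = np.abs(_mad_rows(perm[:, :na]) - _mad_rows(perm[:, na:]))
        n_exceed += _exceeds(null, observed, tie_rule)
        done += m
    p_raw = (n_exceed + 1) / (n_perm + 1) if plus_one else n_exceed / n_perm
    return PermutationResult(
        label_a, label_b, observed, n_perm, n_exceed, p_raw,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        method="montecarlo", tie_rule=tie_rule,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_variability(
    biases_by_group: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[GroupVariability]:
    """Per-group MAD with bootstrap SE (one independent substream per group)."""
    root = np.random.SeedSequence(seed)
    out = []
    for child, (label, biases) in zip(
        root.spawn(len(biases_by_group)), sorted(biases_by_group.items())
    ):
        v = np.asarray(biases, dtype=float)
        out.append(
            GroupVariability(
                group=label,
                n_flies=v.size,
                mad=compute_mad(v),
                bootstrap_se=bootstrap_mad_se(v, n_boot, np.random.default_rng(child)),
                n_boot=n_boot,
                seed=seed,
            )
        )
    return out


def compare_groups(
    biases_by_group: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    n_perm: int = 99_999,
    seed: int | None = None,
    tie_rule: str = "ge",
) -> list[PermutationResult]:
    """Pairwise MAD permutation tests with BH adjustment over the family.

    Each comparison pools the two groups involved and reshuffles labels
    between them only; the BH family is the set of pairs tested together.
    """
    root = np.random.SeedSequence(seed)
    results = []
    for child, (la, lb) in zip(root.spawn(len(pairs)), pairs):
        res = permutation_test_mad(
            biases_by_group[la],
            biases_by_group[lb],
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            tie_rule=tie_rule,
            label_a=la,
            label_b=lb,
        )
        res.seed = seed
        results.append(res)
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    logger.info("ran %d permutation comparisons of %d shuffles", len(pairs), n_perm)
    return results


def rank_tests(flies: pd.DataFrame) -> dict:
    """Rank-based companion tests on per-fly summaries.

    ``flies`` needs columns group, turn_bias, turn_rate. Returns a dict with
    a Kruskal-Wallis test of turn bias across groups, per-group one-sample
    Wilcoxon signed-rank tests of bias against 0.5, and pairwise
    Mann-Whitney tests on turn rate with BH-adjusted p-values. Groups with
    fewer than two flies are skipped with a warning.
    """
    groups = sorted(flies["group"].unique())
    by_group = {g: flies.loc[flies["group"] == g] for g in groups}
    usable = [g for g in groups if len(by_group[g]) >= 2]
    for g in set(groups) - set(usable):
        logger.warning("group %s has fewer than 2 flies; skipped in rank tests", g)

    report: dict = {"groups": usable}
    if len(usable) >= 2:
        h, p = stats.kruskal(*[by_group[g]["turn_bias"].to_numpy() for g in usable])
        report["kruskal_wallis"] = {"statistic": float(h), "p": float(p)}

    wilcoxon = {}
    for g in usable:
        d = by_group[g]["turn_bias"].to_numpy() - 0.5
        if np.allclose(d, 0):
            wilcoxon[g] = {"statistic": 0.0, "p": 1.0}
            continue
        w, p = stats.wilcoxon(d)
        wilcoxon[g] = {"statistic": float(w), "p": float(p)}
    report["wilcoxon_vs_half"] = wilcoxon

    pairs = list(itertools.combinations(usable, 2))
    raw = []
    mw = []
    for ga, gb in pairs:
        u, p = stats.mannwhitneyu(
            by_group[ga]["turn_rate"], by_group[gb]["turn_rate"],
            alternative="two-sided",
        )
        raw.append(p)
        mw.append({"pair": (ga, gb), "statistic": float(u), "p_raw": float(p)})
    if raw:
        for rec, q in zip(mw, bh_adjust(raw)):
            rec["p_adjusted"] = float(q)
    report["turn_rate_mannwhitney"] = mw
    return report


def plot_mad(
    variability: list[GroupVariability],
    ax=None,
):
    """Bar chart of group MADs with bootstrap-SE error bars."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = [g.group for g in variability]
    ax.bar(
        labels,
        [g.mad for g in variability],
        yerr=[g.bootstrap_se for g in variability],
        capsize=4,
        color="steelblue",
    )
    ax.set_ylabel("turn bias MAD")
    ax.set_xlabel("group (predator:drug)")
    ax.tick_params(axis="x", rotation=45)
    return ax
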