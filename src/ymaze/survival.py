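"""Jar-level survival analysis: balanced two-way ANOVA and Tukey HSD.

The survival experiment crosses rearing condition (predator present or not)
with dietary serotonin manipulation (none, 5-HTP, aMW): 2 x 3 groups, ten
jars per group, ten flies per jar, scored after 12 h with one jumping
spider. The experimental unit is the jar; the response is the raw per-jar
survival percentage (no arcsine or logit transform by default).

For a balanced design, cell means and SDs are sufficient statistics: every
sum of squares — hence every F — can be reconstructed from the six printed
(mean, SD, n) triples alone. ``anova_from_summary`` does exactly that, and
agrees with ``two_way_anova`` on raw data to floating tolerance.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .turns import DRUG_LEVELS, PREDATOR_LEVELS

_SURVIVAL_COLS = ["jar_id", "predator", "drug", "n_initial", "n_survived"]


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a jar-level survival table; reports imbalance but allows it."""
    missing = [c for c in _SURVIVAL_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"survival table is missing columns: {missing}")
    if (table["n_survived"] > table["n_initial"]).any():
        raise ValueError("n_survived exceeds n_initial in some jar")
    if (table["n_survived"] < 0).any() or (table["n_initial"] < 0).any():
        raise ValueError("negative counts")
    counts = table.groupby(["predator", "drug"]).size()
    if counts.nunique() > 1:
        import warnings

        warnings.warn("unbalanced design: unequal jar counts per cell", stacklevel=2)
    return table


def jar_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-jar survival percentage, 100 x survived / initial."""
    validate_survival_table(table)
    if (table["n_initial"] == 0).any():
        raise ValueError("jar with zero initial flies")
    out = table.copy()
    out["percent"] = 100.0 * out["n_survived"] / out["n_initial"]
    return out


def _anova_table(
    ss: dict[str, float], df: dict[str, int], degenerate: bool = False
) -> pd.DataFrame:
    """Assemble term-wise df/SS/MS/F/p; residual MS of zero flags degeneracy."""
    terms = ["predator", "drug", "predator:drug", "residual"]
    ms = {t: ss[t] / df[t] if df[t] > 0 else np.nan for t in terms}
    rows = []
    for t in terms:
        if t == "residual" or degenerate or ms["residual"] == 0:
            f = np.nan
            p = np.nan
        else:
            f = ms[t] / ms["residual"]
            p = stats.f.sf(f, df[t], df["residual"])
        rows.append(
            {"term": t, "df": df[t], "sum_sq": ss[t], "mean_sq": ms[t], "F": f, "p": p}
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["degenerate"] = bool(degenerate or ms["residual"] == 0)
    return out


def two_way_anova(data: pd.DataFrame, response: str = "percent") -> pd.DataFrame:
    """Balanced two-way ANOVA (predator x drug) with interaction.

    Requires a fully crossed, balanced layout with at least two replicates
    per cell; unbalanced data is rejected rather than silently re-weighted.
    In the balanced case all classical ANOVA types coincide, so the direct
    sums-of-squares decomposition below is exact.
    """
    for col in ("predator", "drug", response):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    a_levels = sorted(data["predator"].unique())
    b_levels = sorted(data["drug"].unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("need at least two levels per factor")
    sizes = data.groupby(["predator", "drug"]).size()
    if len(sizes) != len(a_levels) * len(b_levels):
        raise ValueError("design is not fully crossed (missing cell)")
    if sizes.nunique() > 1:
        raise ValueError("unbalanced design is not supported")
    n = int(sizes.iloc[0])
    if n < 2:
        raise ValueError("need at least two replicates per cell")

    y = data[response].astype(float)
    grand = y.mean()
    cell_means = data.groupby(["predator", "drug"])[response].mean()
    a_means = data.groupby("predator")[response].mean()
    b_means = data.groupby("drug")[response].mean()
    a, b = len(a_levels), len(b_levels)

    ss_a = b * n * float(((a_means - grand) ** 2).sum())
    ss_b = a * n * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    fitted = data.set_index(["predator", "drug"]).index.map(cell_means)
    ss_res = float(((y.to_numpy() - fitted.to_numpy()) ** 2).sum())

    ss = {"predator": ss_a, "drug": ss_b, "predator:drug": ss_ab, "residual": ss_res}
    df = {
        "predator": a - 1,
        "drug": b - 1,
        "predator:drug": (a - 1) * (b - 1),
        "residual": a * b * (n - 1),
    }
    return _anova_table(ss, df)


def summarize(data: pd.DataFrame, response: str = "percent") -> pd.DataFrame:
    """Cell summaries (mean, sd, n) — the sufficient statistics for the ANOVA."""
    g = data.groupby(["predator", "drug"])[response]
    out = g.agg(mean="mean", sd="std", n="size").reset_index()
    return out


def anova_from_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct the balanced two-way ANOVA from cell means and SDs.

    ``cells`` needs one row per (predator, drug) cell with columns mean, sd,
    n. Within-cell SS is sum (n-1) sd^2; between-cell SS come from the
    means alone. Requires the full 2x3 (or axb) cross with equal n >= 2.
    """
    for col in ("predator", "drug", "mean", "sd", "n"):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    a_levels = sorted(cells["predator"].unique())
    b_levels = sorted(cells["drug"].unique())
    if len(cells) != len(a_levels) * len(b_levels):
        raise ValueError("summary must cover every factor-level combination")
    if cells["n"].nunique() > 1:
        raise ValueError("unbalanced summaries are not supported")
    n = int(cells["n"].iloc[0])
    if n < 2:
        raise ValueError("need n >= 2 per cell")
    if (cells["sd"] < 0).any():
        raise ValueError("negative SD")

    a, b = len(a_levels), len(b_levels)
    means = cells.set_index(["predator", "drug"])["mean"]
    grand = float(means.mean())  # balanced: unweighted mean of cell means
    a_means = means.groupby("predator").mean()
    b_means = means.groupby("drug").mean()

    ss_a = b * n * float(((a_means - grand) ** 2).sum())
    ss_b = a * n * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = float(((cells["n"] - 1) * cells["sd"] ** 2).sum())

    ss = {"predator": ss_a, "drug": ss_b, "predator:drug": ss_ab, "residual": ss_res}
    df = {
        "predator": a - 1,
        "drug": b - 1,
        "predator:drug": (a - 1) * (b - 1),
        "residual": a * b * (n - 1),
    }
    return _anova_table(ss, df)


def tukey_hsd(data: pd.DataFrame, response: str = "percent") -> pd.DataFrame:
    """Tukey honest-significance pairwise comparisons of the six cells.

    The 2x3 layout is flattened into one six-level factor; each of the 15
    pairs is tested with the studentized range using the pooled within-cell
    mean square and its residual degrees of freedom.
    """
    data = data.copy()
    data["cell"] = data["predator"].astype(str) + ":" + data["drug"].astype(str)
    groups = sorted(data["cell"].unique())
    k = len(groups)
    sizes = data.groupby("cell")[response].size()
    if sizes.nunique() > 1:
        raise ValueError("unbalanced design is not supported")
    n = int(sizes.iloc[0])
    if n < 2:
        raise ValueError("need at least two replicates per cell")
    means = data.groupby("cell")[response].mean()
    ss_within = float(
        data.groupby("cell")[response]
        .apply(lambda v: ((v - v.mean()) ** 2).sum())
        .sum()
    )
    df_res = k * (n - 1)
    mse = ss_within / df_res
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        diff = float(means[gb] - means[ga])
        if mse == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / np.sqrt(mse / n)
            p = float(stats.studentized_range.sf(q, k, df_res))
        rows.append(
            {"group_a": ga, "group_b": gb, "mean_diff": diff, "q": q, "p_adj": p}
        )
    return pd.DataFrame(rows)


def survival_report(table: pd.DataFrame) -> dict:
    """Full survival analysis: proportions, ANOVA, Tukey HSD, as plain dicts."""
    props = jar_proportions(table)
    anova = two_way_anova(props)
    tukey = tukey_hsd(props)
    return {
        "n_jars": int(len(props)),
        "cell_summary": summarize(props).to_dict(orient="records"),
        "anova": anova.reset_index().to_dict(orient="records"),
        "tukey": tukey.to_dict(orient="records"),
        "degenerate": bool(anova.attrs.get("degenerate", False)),
    }
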