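"""Relative qPCR quantification (2^-ddCt) and Dunnett many-to-one tests.

Fold changes: per biological replicate, the target gene's threshold cycle
is normalized to the reference gene (dCt = Ct_target - Ct_reference) and
calibrated to the control group's mean dCt (ddCt); expression relative to
the calibrator is 2^-ddCt. Technical replicates are averaged on the Ct
(log) scale first.

Group contrasts use Dunnett's test: pooled-variance t statistics of every
treatment group against the control, with the family-wise adjusted p-value
taken from the equicorrelated multivariate t distribution of the maximum
absolute statistic under the null. The multivariate-t tail probability is
evaluated by seeded Monte-Carlo integration, so results are deterministic
given the seed and free of platform-specific quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeResult",
    "DunnettResult",
    "fold_change",
    "dunnett_test",
    "significance_stars",
]

DEFAULT_MC_DRAWS = 100_000
DEFAULT_MC_SEED = 20210618  # fixed default so repeated analyses agree


@dataclass
class FoldChangeResult:
    """Per-replicate dCt/ddCt/fold table plus per-group summaries."""

    per_replicate: pd.DataFrame  # group, sample, delta_ct, delta_delta_ct, fold
    per_group: pd.DataFrame      # group, mean fold, sd, n
    target: str
    reference: str
    calibrator: str


@dataclass
class DunnettResult:
    """Many-to-one comparison table: one row per non-control group."""

    table: pd.DataFrame  # group, mean_diff, t, p_adjusted, significant_* flags
    control: str
    df: int
    n_draws: int


def fold_change(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> FoldChangeResult:
    """2^-ddCt relative quantification from a tidy Ct table.

    ``table`` needs columns (group, sample, gene, ct); repeated
    (group, sample, gene) rows are technical replicates and are averaged on
    the Ct scale before anything else. Every sample must carry both genes.
    """
    required = {"group", "sample", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if calibrator not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not in table")

    mean_ct = (
        table.groupby(["group", "sample", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in (target, reference):
        missing = mean_ct.index[mean_ct.get(gene, pd.Series(dtype=float)).isna()] \
            if gene in mean_ct.columns else mean_ct.index
        if gene not in mean_ct.columns or len(missing):
            who = list(missing)[:3] if gene in mean_ct.columns else "all samples"
            raise ValueError(f"gene {gene!r} missing for replicate(s): {who}")

    per = mean_ct.reset_index()
    per["delta_ct"] = per[target] - per[reference]
    cal_mean = per.loc[per["group"] == calibrator, "delta_ct"].mean()
    per["delta_delta_ct"] = per["delta_ct"] - cal_mean
    per["fold"] = 2.0 ** (-per["delta_delta_ct"])
    per = per[["group", "sample", "delta_ct", "delta_delta_ct", "fold"]]

    grp = (
        per.groupby("group", sort=False)["fold"]
        .agg(mean_fold="mean", sd_fold="std", n="size")
        .reset_index()
    )
    return FoldChangeResult(per, grp, target, reference, calibrator)


@lru_cache(maxsize=32)
def _null_max_abs_t(
    df: int, lambdas: tuple[float, ...], n_draws: int, seed: int
) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    T_i = (lambda_i Z0 + sqrt(1-lambda_i^2) Z_i) / sqrt(W/df) with
    independent standard normals and W ~ chi2(df): the usual one-factor
    representation of the equicorrelated multivariate t with
    corr(T_i, T_j) = lambda_i lambda_j. Cached per key; draws depend only
    on the key, never on the data, so caching changes nothing.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(lambdas)
    k = lam.size
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, k))
    w = rng.chisquare(df, n_draws) / df
    t = (lam * z0[:, None] + np.sqrt(1.0 - lam**2) * z) / np.sqrt(w)[:, None]
    out = np.abs(t).max(axis=1)
    out.sort()
    return out


def dunnett_test(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    control: str,
    alpha: tuple[float, ...] = (0.05, 0.001),
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = DEFAULT_MC_SEED,
) -> DunnettResult:
    """Two-sided Dunnett comparisons of each group against ``control``.

    ``groups`` maps group name to a 1-D sample array (or a long DataFrame
    with columns ``group``/``value``). Each group needs >= 2 observations.
    Adjusted p-values are P(max_j |T_j| >= |t_i|) under the joint null,
    estimated from ``n_draws`` seeded Monte-Carlo draws of the
    equicorrelated multivariate t.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {g: sub["value"].to_numpy() for g, sub in groups.groupby("group")}
    data = {g: np.asarray(v, dtype=np.float64) for g, v in groups.items()}
    if control not in data:
        raise ValueError(f"control group {control!r} missing")
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    others = [g for g in data if g != control]
    if not others:
        raise ValueError("need at least one non-control group")
    x0 = data[control]
    n0 = x0.size
    ns = np.array([data[g].size for g in others])
    df = int(sum(v.size - 1 for v in data.values()))
    ss = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    s2 = ss / df
    if s2 <= 0:
        # all observations identical: no evidence of any difference
        t_stats = np.zeros(len(others))
    else:
        diffs = np.array([data[g].mean() - x0.mean() for g in others])
        t_stats = diffs / np.sqrt(s2 * (1.0 / ns + 1.0 / n0))

    lam = tuple(float(np.sqrt(n / (n + n0))) for n in ns)
    null = _null_max_abs_t(df, lam, int(n_draws), int(seed))
    # upper-tail MC probability with add-one smoothing keeps p in (0, 1]
    idx = np.searchsorted(null, np.abs(t_stats), side="left")
    p_adj = (len(null) - idx + 1.0) / (len(null) + 1.0)

    rows = []
    for g, t, p in zip(others, t_stats, p_adj):
        row = {
            "group": g,
            "mean_diff": float(data[g].mean() - x0.mean()),
            "t": float(t),
            "p_adjusted": float(p),
        }
        for a in alpha:
            row[f"significant_{a:g}"] = bool(p < a)
        rows.append(row)
    return DunnettResult(pd.DataFrame(rows), control, df, int(n_draws))


def significance_stars(p: float, thresholds: tuple[float, float] = (0.05, 0.001)) -> str:
    """Star annotation: '***' below the stricter threshold, '*' below the
    looser one, '' otherwise."""
    hi, lo = max(thresholds), min(thresholds)
    if p < lo:
        return "***"
    if p < hi:
        return "*"
    return ""
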