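"""Dagum Gini decomposition and beta-convergence panel regressions.

The Gini coefficient of a cross-section of provincial scores is split,
following Dagum, into three additive parts: within-region inequality G_w,
net between-region inequality G_nb, and the transvariation intensity G_t
that captures the overlap between regional distributions (low-value
provinces inside high-mean regions and vice versa).  The discrete pairwise
estimators are used throughout, so the identity G = G_w + G_nb + G_t holds
to machine precision.

Convergence is assessed by regressing annual log-growth on the lagged log
level with two-way (province and year) fixed effects; a negative beta means
laggards catch up.  The conditional variant appends five province-year
controls.  The convergence speed is reported as v = -ln(1+beta)/T over the
T annual transitions of the sample, the per-year rate at which the gap to
the steady state closes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import ControlPanel, RegionScheme


# ---------------------------------------------------------------------------
# Dagum Gini decomposition

@dataclass
class GroupedScores:
    """One year's provincial scores grouped by region.

    Regions are re-indexed so their means are non-decreasing, the ordering
    the decomposition's transvariation terms assume.  Mean ties keep the
    declaration order (stable sort).
    """

    groups: dict[str, np.ndarray]  # region -> scores, mean-ascending order

    @classmethod
    def from_scores(cls, scores: pd.Series, scheme: RegionScheme
                    ) -> "GroupedScores":
        groups = {r: [] for r in scheme.regions}
        for prov, val in scores.items():
            groups[scheme.region_of(prov)].append(float(val))
        for r, vals in groups.items():
            if not vals:
                raise ValueError(f"region {r!r} has no provinces in scores")
        ordered = sorted(groups, key=lambda r: float(np.mean(groups[r])))
        return cls({r: np.asarray(groups[r], dtype=float) for r in ordered})

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.groups.values()))

    @property
    def n(self) -> int:
        return len(self.pooled)


def overall_gini(scores: np.ndarray | GroupedScores) -> float:
    """Gini coefficient: mean absolute difference over 2 * mean.

    Computed over all ordered pairs, G = sum_ij |y_i - y_j| / (2 n^2 ybar).
    """
    y = scores.pooled if isinstance(scores, GroupedScores) else \
        np.asarray(scores, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("Gini needs at least 2 observations")
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError("Gini undefined for non-positive mean")
    diff = np.abs(y[:, None] - y[None, :]).sum()
    return float(diff / (2.0 * n * n * ybar))


@dataclass
class GiniDecomposition:
    """G = G_w + G_nb + G_t with all intermediate terms.

    ``gini_within[j]`` is region j's own Gini; ``gini_between[(j,h)]`` the
    cross-region Gini; ``D[(j,h)]`` the relative economic affluence (1 = no
    overlap between the two regional distributions, 0 = identical).
    Contribution rates are percentages of G.
    """

    G: float
    G_w: float
    G_nb: float
    G_t: float
    gini_within: dict[str, float]
    gini_between: dict[tuple[str, str], float]
    D: dict[tuple[str, str], float]
    p_shares: dict[str, float]
    s_shares: dict[str, float]

    @property
    def contribution_within(self) -> float:
        return 100.0 * self.G_w / self.G if self.G > 0 else np.nan

    @property
    def contribution_between(self) -> float:
        return 100.0 * self.G_nb / self.G if self.G > 0 else np.nan

    @property
    def contribution_transvariation(self) -> float:
        return 100.0 * self.G_t / self.G if self.G > 0 else np.nan


def _cross_moments(yj: np.ndarray, yh: np.ndarray) -> tuple[float, float]:
    """(d_jh, p_jh): mean positive gaps over all cross pairs.

    With j the higher-mean region, d_jh averages (y_j - y_h) over pairs
    where region j's member is larger, p_jh the reverse — the discrete
    counterparts of the Dagum gross-affluence integrals.
    """
    diff = yj[:, None] - yh[None, :]
    n_pairs = diff.size
    d = float(np.where(diff > 0, diff, 0.0).sum() / n_pairs)
    p = float(np.where(diff < 0, -diff, 0.0).sum() / n_pairs)
    return d, p


def dagum_decompose(scores: GroupedScores) -> GiniDecomposition:
    """Exact discrete Dagum decomposition of the Gini coefficient."""
    regions = list(scores.groups)
    if len(regions) < 2:
        # degenerate but well-defined: everything is within-region
        pass
    y_all = scores.pooled
    n = len(y_all)
    ybar = float(y_all.mean())
    if ybar <= 0:
        raise ValueError("Gini undefined for non-positive mean")

    p_sh = {r: len(scores.groups[r]) / n for r in regions}
    s_sh = {r: len(scores.groups[r]) * float(scores.groups[r].mean())
            / (n * ybar) for r in regions}

    gini_within: dict[str, float] = {}
    for r in regions:
        yr = scores.groups[r]
        nr = len(yr)
        mr = float(yr.mean())
        if nr == 1 or mr == 0:
            gini_within[r] = 0.0
        else:
            gini_within[r] = float(
                np.abs(yr[:, None] - yr[None, :]).sum()
                / (2.0 * nr * nr * mr))

    G_w = sum(gini_within[r] * p_sh[r] * s_sh[r] for r in regions)

    gini_between: dict[tuple[str, str], float] = {}
    D: dict[tuple[str, str], float] = {}
    G_nb = 0.0
    G_t = 0.0
    # regions are mean-ascending, so in each pair the later one is richer
    for h_idx, j_idx in combinations(range(len(regions)), 2):
        h, j = regions[h_idx], regions[j_idx]  # mean(h) <= mean(j)
        yh, yj = scores.groups[h], scores.groups[j]
        gjh = float(np.abs(yj[:, None] - yh[None, :]).sum()
                    / (len(yj) * len(yh)
                       * (float(yj.mean()) + float(yh.mean()))))
        d, p = _cross_moments(yj, yh)
        djh = (d - p) / (d + p) if (d + p) > 0 else 0.0
        gini_between[(j, h)] = gjh
        D[(j, h)] = djh
        weight = p_sh[j] * s_sh[h] + p_sh[h] * s_sh[j]
        G_nb += gjh * weight * djh
        G_t += gjh * weight * (1.0 - djh)

    G = G_w + G_nb + G_t
    return GiniDecomposition(G, G_w, G_nb, G_t, gini_within, gini_between,
                             D, p_sh, s_sh)


def gini_series(scores: pd.Series, scheme: RegionScheme
                ) -> tuple[pd.DataFrame, dict]:
    """Per-year Dagum decomposition and the endpoint trend summary.

    ``scores`` is a (province, year)-indexed series.  Returns a tidy frame
    (one row per year) and a summary dict with the endpoint decline rate
    100*(G_first - G_last)/G_first.
    """
    years = np.sort(scores.index.get_level_values("year").unique())
    if len(years) < 2:
        raise ValueError("need at least 2 years for a Gini series")
    rows = []
    decomps = {}
    for year in years:
        g = GroupedScores.from_scores(scores.xs(year, level="year"), scheme)
        d = dagum_decompose(g)
        decomps[int(year)] = d
        row = {"year": int(year), "G": d.G, "G_w": d.G_w, "G_nb": d.G_nb,
               "G_t": d.G_t,
               "contrib_within_pct": d.contribution_within,
               "contrib_between_pct": d.contribution_between,
               "contrib_transvariation_pct": d.contribution_transvariation}
        for r, v in d.gini_within.items():
            row[f"G_{r}"] = v
        for (j, h), v in d.gini_between.items():
            row[f"G_{j}_{h}"] = v
            row[f"D_{j}_{h}"] = d.D[(j, h)]
        rows.append(row)
    frame = pd.DataFrame(rows)
    summary = {
        "G_first": frame["G"].iloc[0],
        "G_last": frame["G"].iloc[-1],
        "decline_rate_pct": decline_rate(frame["G"].iloc[0],
                                         frame["G"].iloc[-1]),
        "decompositions": decomps,
    }
    return frame, summary


def decline_rate(g_first: float, g_last: float) -> float:
    """Endpoint decline rate in percent: 100*(G_first - G_last)/G_first."""
    if g_first <= 0:
        raise ValueError("initial Gini must be positive")
    return 100.0 * (g_first - g_last) / g_first


# ---------------------------------------------------------------------------
# Beta convergence

@dataclass
class ConvergenceResult:
    """Fitted beta-convergence regression.

    ``beta`` is the coefficient on the lagged log level; ``speed`` is
    v = -ln(1+beta)/T with T the number of annual transitions.  Control
    coefficients are present only for the conditional model.  Standard
    errors are clustered by province unless conventional ones were
    requested.
    """

    beta: float
    beta_se: float
    alpha: float
    alpha_se: float
    controls: dict[str, tuple[float, float]]
    n_obs: int
    adj_r2: float
    speed: float
    n_transitions: int
    pvalue_beta: float

    @property
    def stars(self) -> str:
        p = self.pvalue_beta
        return "***" if p < 0.01 else "**" if p < 0.05 else \
            "*" if p < 0.10 else ""


def convergence_speed(beta: float, n_transitions: int) -> float:
    """Convergence speed v = -ln(1 + beta) / T.

    T is the number of annual transitions the panel spans (years - 1);
    beta must exceed -1 for the log to exist.
    """
    if beta <= -1:
        raise ValueError("beta must be > -1")
    if n_transitions < 1:
        raise ValueError("need at least one transition")
    return float(-np.log1p(beta) / n_transitions)


def beta_convergence(scores: pd.Series,
                     controls: ControlPanel | None = None,
                     provinces: list[str] | None = None,
                     cluster: bool = True) -> ConvergenceResult:
    """Two-way fixed-effects regression of log-growth on lagged log level.

    ln(y_{i,t+1}/y_it) = alpha + beta ln y_it [+ controls] + mu_i + eta_t
    + eps.  Fixed effects enter as explicit indicator regressors with one
    province and one year level dropped.  Pass ``provinces`` to restrict
    the scope to one region's panel.
    """
    s = scores
    if provinces is not None:
        s = s.loc[s.index.get_level_values("province").isin(set(provinces))]
    if (s <= 0).any():
        bad = s[s <= 0].index[0]
        raise ValueError(f"non-positive score at {bad}; log undefined")

    wide = s.unstack("year").sort_index(axis=1)
    years = list(wide.columns)
    if len(years) < 3:
        raise ValueError("need T >= 3 years for the panel regression")
    ln_y = np.log(wide.to_numpy(float))
    growth = ln_y[:, 1:] - ln_y[:, :-1]

    provs = list(wide.index)
    n_p, n_t = len(provs), len(years) - 1
    rows = []
    for i, p in enumerate(provs):
        for t in range(n_t):
            rows.append({"province": p, "year": years[t],
                         "growth": growth[i, t], "ln_y": ln_y[i, t]})
    df = pd.DataFrame(rows)

    if controls is not None:
        cv = controls.values
        idx = pd.MultiIndex.from_frame(df[["province", "year"]])
        missing = ~idx.isin(cv.index)
        if missing.any():
            raise ValueError(
                f"controls missing for {idx[missing][0]}")
        for c in ControlPanel.COLUMNS:
            df[c] = cv.loc[idx, c].to_numpy()

    X = pd.DataFrame({"const": 1.0, "ln_y": df["ln_y"]})
    if controls is not None:
        for c in ControlPanel.COLUMNS:
            X[c] = df[c]
    prov_d = pd.get_dummies(df["province"], prefix="prov",
                            drop_first=True, dtype=float)
    year_d = pd.get_dummies(df["year"], prefix="year",
                            drop_first=True, dtype=float)
    X = pd.concat([X, prov_d, year_d], axis=1)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify one offending column for the error message
        keep: list[str] = []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) < len(keep) + 1:
                raise ValueError(f"design matrix is rank deficient; "
                                 f"column {col!r} is collinear")
            keep.append(col)

    model = sm.OLS(df["growth"].to_numpy(), X.to_numpy())
    if cluster and df["province"].nunique() > 1:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": df["province"].to_numpy()})
    else:
        res = model.fit()

    names = list(X.columns)
    coef = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))
    ctrl = {c: (coef[c], se[c]) for c in ControlPanel.COLUMNS
            if c in coef} if controls is not None else {}

    beta = float(coef["ln_y"])
    return ConvergenceResult(
        beta=beta, beta_se=float(se["ln_y"]),
        alpha=float(coef["const"]), alpha_se=float(se["const"]),
        controls=ctrl, n_obs=int(res.nobs), adj_r2=float(res.rsquared_adj),
        speed=convergence_speed(beta, n_t), n_transitions=n_t,
        pvalue_beta=float(pvals["ln_y"]))
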