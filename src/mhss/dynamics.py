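"""Distributional dynamics: kernel densities and (spatial) Markov chains.

Provinces are classified each year into quartile classes I-IV of the
cross-sectional score distribution (per-year cuts remove the common upward
trend, so classes measure relative position).  Annual class transitions
give a 4x4 row-stochastic matrix; conditioning transitions on the origin
year's spatial-lag class (the contiguity-weighted neighbour average,
classified on the same score cuts) yields the spatial Markov matrices that
reveal neighbourhood effects on mobility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASS_LABELS = ["I", "II", "III", "IV"]


# ---------------------------------------------------------------------------
# Kernel density estimation

@dataclass
class DensityCurve:
    """Gaussian-kernel density on an evaluation grid."""

    x: np.ndarray
    f: np.ndarray
    bandwidth: float
    tag: str = ""

    def integral(self) -> float:
        return float(np.trapezoid(self.f, self.x))

    def n_modes(self) -> int:
        """Local maxima of the curve (sign changes of the derivative)."""
        d = np.diff(self.f)
        sign = np.sign(d)
        sign = sign[sign != 0]
        return int(np.sum((sign[:-1] > 0) & (sign[1:] < 0)))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("auto bandwidth needs at least 2 observations")
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("sample has zero spread; bandwidth undefined")
    return float(0.9 * spread * n ** (-0.2))


def kde(values, bandwidth: float | None = None, grid_size: int = 512,
        tag: str = "") -> DensityCurve:
    """Gaussian kernel density estimate f(x) = 1/(Nh) sum K((X_i - x)/h).

    The grid spans [min - 3h, max + 3h] so the trapezoid integral of the
    curve captures essentially all the mass.  ``bandwidth=None`` applies
    Silverman's rule.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_size)
    z = (v[None, :] - grid[:, None]) / h
    f = np.exp(-0.5 * z ** 2).sum(axis=1) / (len(v) * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid, f, h, tag)


# ---------------------------------------------------------------------------
# Quartile classes

@dataclass
class MarkovClasses:
    """Quartile class (1..4) per province-year plus the cuts used."""

    classes: pd.Series  # (province, year) -> int in {1,2,3,4}
    cuts: pd.DataFrame  # year -> [Q1, Q2, Q3]

    def label(self, cls: int) -> str:
        return CLASS_LABELS[cls - 1]


def _classify(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Class 1..4 with boundary values assigned to the lower class."""
    return np.searchsorted(cuts, values, side="left") + 1


def classify_quartiles(scores: pd.Series, pooled: bool = False
                       ) -> MarkovClasses:
    """Quartile classes of provinces, by default within each year.

    Cuts are the empirical 25/50/75% quantiles (linear interpolation);
    a value exactly equal to a cut goes to the lower class.  ``pooled``
    computes one set of cuts over all province-years instead.
    """
    years = np.sort(scores.index.get_level_values("year").unique())
    assigned: dict[tuple, int] = {}
    cut_rows = {}
    if pooled:
        pooled_cuts = np.quantile(scores.to_numpy(float), [0.25, 0.5, 0.75])
    for year in years:
        s = scores.xs(year, level="year")
        if len(s) < 4:
            raise ValueError(f"year {year}: need >= 4 provinces to form "
                             "quartile classes")
        cuts = pooled_cuts if pooled else np.quantile(
            s.to_numpy(float), [0.25, 0.5, 0.75])
        if s.nunique() == 1:
            warnings.warn(f"year {year}: all provinces tied; "
                          "all assigned class I")
            cls = np.ones(len(s), dtype=int)
        else:
            cls = _classify(s.to_numpy(float), cuts)
        for prov, c in zip(s.index, cls):
            assigned[(prov, year)] = int(c)
        cut_rows[int(year)] = cuts
    out = pd.Series([assigned[k] for k in scores.index],
                    index=scores.index, dtype=int)
    cuts_df = pd.DataFrame.from_dict(cut_rows, orient="index",
                                     columns=["Q1", "Q2", "Q3"])
    return MarkovClasses(out, cuts_df)


# ---------------------------------------------------------------------------
# Transition matrices

@dataclass
class TransitionMatrix:
    """Class-transition counts and row-stochastic probabilities."""

    counts: np.ndarray  # 4x4 integer counts
    labels: list[str]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.row_totals
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot[:, None] > 0, self.counts / tot[:, None], 0.0)
        return p

    @property
    def unvisited_states(self) -> list[str]:
        return [lbl for lbl, t in zip(self.labels, self.row_totals)
                if t == 0]

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, index=self.labels,
                          columns=self.labels)
        df.insert(0, "N", self.row_totals)
        return df


def transition_matrix(classes: MarkovClasses) -> TransitionMatrix:
    """Counts of annual class transitions pooled over provinces and years."""
    cls = classes.classes
    years = np.sort(cls.index.get_level_values("year").unique())
    if len(years) < 2:
        raise ValueError("need >= 2 consecutive years for transitions")
    if np.any(np.diff(years) != 1):
        raise ValueError("years must be consecutive for annual transitions")
    wide = cls.unstack("year").sort_index(axis=1)
    a = wide.to_numpy(int)
    counts = np.zeros((4, 4), dtype=int)
    for t in range(a.shape[1] - 1):
        np.add.at(counts, (a[:, t] - 1, a[:, t + 1] - 1), 1)
    return TransitionMatrix(counts, list(CLASS_LABELS))


def spatial_lag(scores: pd.Series, weights: pd.DataFrame) -> pd.Series:
    """Row-standardized contiguity lag of the score per province-year.

    ``weights`` is a symmetric binary matrix indexed by province; each
    province must have at least one neighbour.
    """
    provinces = list(scores.index.get_level_values("province").unique())
    W = weights.loc[provinces, provinces].to_numpy(float)
    if not np.allclose(W, W.T):
        raise ValueError("contiguity matrix must be symmetric")
    deg = W.sum(axis=1)
    isolated = [p for p, d in zip(provinces, deg) if d == 0]
    if isolated:
        raise ValueError(f"isolated province(s) with no neighbours: "
                         f"{isolated}")
    Wn = W / deg[:, None]
    wide = scores.unstack("year").loc[provinces]
    lag = pd.DataFrame(Wn @ wide.to_numpy(float), index=wide.index,
                       columns=wide.columns)
    s = lag.stack()
    s.index.names = ["province", "year"]
    return s


@dataclass
class SpatialTransitionMatrices:
    """One transition matrix per origin-year spatial-lag class."""

    conditionals: dict[str, TransitionMatrix]  # lag class label -> matrix
    unconditional: TransitionMatrix

    def check_conservation(self) -> bool:
        total = sum(m.counts for m in self.conditionals.values())
        return bool(np.array_equal(total, self.unconditional.counts))


def spatial_transition_matrices(classes: MarkovClasses, lags: pd.Series
                                ) -> SpatialTransitionMatrices:
    """Transitions binned by the origin year's spatial-lag class.

    The lag is classified with the SAME per-year score cuts as the
    provinces themselves, so "adjacent to type III" reads on the score
    scale.  The four conditional count matrices partition the
    unconditional counts.
    """
    cls = classes.classes
    years = np.sort(cls.index.get_level_values("year").unique())
    if len(years) < 2 or np.any(np.diff(years) != 1):
        raise ValueError("need consecutive years for annual transitions")
    wide = cls.unstack("year").sort_index(axis=1)
    lag_wide = lags.unstack("year").loc[wide.index, wide.columns]

    lag_cls = np.zeros(wide.shape, dtype=int)
    for jy, year in enumerate(wide.columns):
        cuts = classes.cuts.loc[int(year)].to_numpy(float)
        lag_cls[:, jy] = _classify(lag_wide[year].to_numpy(float), cuts)

    a = wide.to_numpy(int)
    counts = {lbl: np.zeros((4, 4), dtype=int) for lbl in CLASS_LABELS}
    for t in range(a.shape[1] - 1):
        for i in range(a.shape[0]):
            lbl = CLASS_LABELS[lag_cls[i, t] - 1]
            counts[lbl][a[i, t] - 1, a[i, t + 1] - 1] += 1
    conditionals = {lbl: TransitionMatrix(c, list(CLASS_LABELS))
                    for lbl, c in counts.items()}
    return SpatialTransitionMatrices(conditionals,
                                     transition_matrix(classes))


def _chi2_stat(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square statistic and dof of a contingency table
    (no continuity correction), after dropping all-zero rows/columns."""
    t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, dof


def homogeneity_test(matrices: SpatialTransitionMatrices,
                     n_permutations: int = 0,
                     seed: int | None = None) -> float:
    """Chi-square test that transition rows are homogeneous across lag
    classes.

    For each origin state, the (lag class) x (destination) count table is
    tested for independence; statistics are summed over origin states and
    returned as one combined p-value.  With ``n_permutations=0`` the
    asymptotic chi-square reference is used; transition tables are often
    sparse (expected counts below 5), where the asymptotic p-value is
    anti-conservative, so a permutation-calibrated p-value (destinations
    shuffled across lag classes within each origin state) is available and
    preferred for inference.
    """
    tables = []
    for i in range(4):
        table = np.array([m.counts[i] for m in
                          matrices.conditionals.values()])
        tables.append(table)

    obs_stat = 0.0
    obs_dof = 0
    for table in tables:
        s, d = _chi2_stat(table)
        obs_stat += s
        obs_dof += d
    if obs_dof == 0:
        return 1.0
    if n_permutations <= 0:
        return float(stats.chi2.sf(obs_stat, obs_dof))

    rng = np.random.default_rng(seed)
    # per origin state: expand to (lag label, destination) pairs
    pairs = []
    for table in tables:
        lag_idx, dest_idx = np.nonzero(table)
        reps = table[lag_idx, dest_idx]
        pairs.append((np.repeat(lag_idx, reps), np.repeat(dest_idx, reps)))
    exceed = 0
    for _ in range(n_permutations):
        stat = 0.0
        for (lags_i, dests_i), table in zip(pairs, tables):
            if len(dests_i) == 0:
                continue
            perm = rng.permutation(dests_i)
            t = np.zeros_like(table)
            np.add.at(t, (lags_i, perm), 1)
            s, _ = _chi2_stat(t)
            stat += s
        if stat >= obs_stat - 1e-12:
            exceed += 1
    return float((1 + exceed) / (1 + n_permutations))


def stationary_distribution(matrix: TransitionMatrix) -> np.ndarray:
    """Long-run class shares: left eigenvector of P for eigenvalue 1.

    States never visited are excluded from the chain.  If the stationary
    distribution is not unique (e.g. an identity matrix), a warning is
    emitted and the uniform distribution over the visited states is
    returned (zeros for unvisited states).  Absorbing chains return the
    absorbing mass profile.
    """
    visited = matrix.row_totals > 0
    P = matrix.probabilities[np.ix_(visited, visited)]
    if P.shape[0] == 0:
        raise ValueError("no visited states")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("probability rows must sum to 1 for visited states")
    vals, vecs = np.linalg.eig(P.T)
    one = np.isclose(vals, 1.0, atol=1e-8)
    k = int(one.sum())
    full = np.zeros(len(matrix.labels))
    if k == 0:
        raise ValueError("no unit eigenvalue; matrix is not stochastic")
    if k > 1:
        warnings.warn("stationary distribution is not unique; "
                      "returning the uniform distribution")
        full[visited] = 1.0 / P.shape[0]
        return full
    v = np.real(vecs[:, one][:, 0])
    v = np.abs(v)
    full[visited] = v / v.sum()
    return full
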