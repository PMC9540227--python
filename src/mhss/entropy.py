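"""Two-stage nested entropy weighting and the composite supply index.

The composite medical-and-health-services-supply (MHSS) score is built in
two stages that respect the index hierarchy (indicator layer nested in a
dimension layer):

1. Each raw indicator is min-max normalized over the *pooled* panel (all
   provinces and years jointly), with negative-attribute (cost) indicators
   reversed so that 1 is always best.  Within each dimension, indicators
   receive entropy weights: an indicator whose normalized shares are widely
   dispersed carries more information (lower Shannon entropy) and hence
   more weight.  The weighted sum gives a dimension score per province-year.
2. The dimension scores are themselves entropy-weighted across dimensions
   by the same device, and the weighted sum of dimension scores is the
   composite score M_it in [0, 1].

Pooling the min-max frame across years makes scores comparable over time,
which the trend, convergence and transition analyses all rely on.

A constant indicator carries no information: it is assigned entropy 1
(weight 0) and a neutral normalized value of 0.5, with a warning, rather
than aborting the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import NEGATIVE, IndicatorPanel


@dataclass
class NormalizedPanel:
    """Min-max normalized values and their pooled shares.

    ``minmax`` holds p' in [0,1] per (province, year) x indicator;
    ``shares`` holds each indicator's column rescaled to sum to 1 over all
    province-years (the probability vector the entropy is taken over).
    ``constant`` lists indicators with zero pooled range.
    """

    minmax: pd.DataFrame
    shares: pd.DataFrame
    specs: list
    constant: list[str]

    @property
    def n_cells(self) -> int:
        """T*N, the number of province-year cells."""
        return len(self.minmax.index)


def normalize(panel: IndicatorPanel) -> NormalizedPanel:
    """Min-max normalize each indicator over the pooled panel.

    Positive-attribute cells map by (x-min)/(max-min), negative by
    (max-x)/(max-min); min and max are pooled over all provinces and years.
    Shares then rescale each column to sum to 1.
    """
    if panel.n_missing:
        raise ValueError(
            f"panel has {panel.n_missing} missing cell(s); run "
            "interpolate_missing first"
        )
    vals = panel.values
    out = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
    constant: list[str] = []
    for spec in panel.specs:
        col = vals[spec.indicator_id].to_numpy(float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            constant.append(spec.indicator_id)
            out[spec.indicator_id] = 0.5
            continue
        if spec.attribute == NEGATIVE:
            out[spec.indicator_id] = (hi - col) / (hi - lo)
        else:
            out[spec.indicator_id] = (col - lo) / (hi - lo)
    if constant:
        warnings.warn(
            f"constant indicator(s) carry no information: {constant}; "
            "normalized to 0.5 and assigned zero weight"
        )
    shares = _as_shares(out)
    return NormalizedPanel(out, shares, list(panel.specs), constant)


def _as_shares(df: pd.DataFrame) -> pd.DataFrame:
    """Rescale each column to sum to 1 (columns summing to 0 stay 0)."""
    tot = df.sum(axis=0)
    shares = df.div(tot.where(tot > 0, 1.0), axis=1)
    return shares


def _entropy(shares: np.ndarray, n_cells: int) -> float:
    """Shannon entropy of a share vector, normalized by ln(T*N).

    Uses the convention 0*ln(0) = 0; no epsilon shift is applied to the
    data, so the closed forms (uniform -> 1, degenerate -> 0) are exact.
    """
    if n_cells < 2:
        raise ValueError("entropy undefined for a single cell (ln(TN)=0)")
    p = np.asarray(shares, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n_cells))


def indicator_entropy(norm: NormalizedPanel) -> pd.Series:
    """Entropy e_jk in [0,1] of each indicator's pooled shares."""
    n = norm.n_cells
    e = {}
    for spec in norm.specs:
        k = spec.indicator_id
        if k in norm.constant:
            e[k] = 1.0
        else:
            e[k] = _entropy(norm.shares[k].to_numpy(), n)
    return pd.Series(e, name="entropy")


@dataclass
class EntropyWeights:
    """The fitted two-level weight hierarchy.

    ``indicator_weights`` sum to 1 within each dimension;
    ``dimension_weights`` sum to 1 across dimensions.  ``dimension_scores``
    are the stage-1 aggregates s_itj per province-year.
    """

    indicator_entropy: pd.Series
    indicator_weights: pd.Series
    dimension_scores: pd.DataFrame
    dimension_entropy: pd.Series
    dimension_weights: pd.Series

    def table(self) -> pd.DataFrame:
        """Two-level weight report with percentage weights."""
        rows = []
        for dim in self.dimension_weights.index:
            for ind in self.indicator_weights.index:
                if self._dim_of.get(ind) != dim:
                    continue
                rows.append({
                    "dimension": dim,
                    "dimension_weight_pct": 100 * self.dimension_weights[dim],
                    "indicator_id": ind,
                    "indicator_entropy": self.indicator_entropy[ind],
                    "indicator_weight_within_dimension":
                        self.indicator_weights[ind],
                })
        return pd.DataFrame(rows)

    _dim_of: dict = None  # type: ignore[assignment]


def fit_weights(norm: NormalizedPanel) -> EntropyWeights:
    """Fit the nested weight hierarchy from a normalized panel.

    Stage 1: within dimension j, w_jk = (1-e_jk) / sum_k (1-e_jk) and the
    dimension score is s_itj = sum_k w_jk p'_itjk.  Stage 2: the dimension
    scores are re-shared over province-years, their entropy e_j computed
    the same way, and W_j = (1-e_j) / sum_j (1-e_j).
    """
    e_jk = indicator_entropy(norm)
    dims: dict[str, list[str]] = {}
    for spec in norm.specs:
        dims.setdefault(spec.dimension, []).append(spec.indicator_id)

    w_jk = pd.Series(0.0, index=e_jk.index)
    for dim, inds in dims.items():
        info = (1.0 - e_jk[inds])
        tot = info.sum()
        if tot <= 0:
            raise ValueError(
                f"dimension {dim!r}: every indicator has entropy 1 "
                "(no information); cannot weight"
            )
        w_jk[inds] = info / tot

    s_itj = pd.DataFrame(
        {dim: norm.minmax[inds].to_numpy() @ w_jk[inds].to_numpy()
         for dim, inds in dims.items()},
        index=norm.minmax.index,
    )

    n = norm.n_cells
    dim_shares = _as_shares(s_itj)
    e_j = pd.Series({dim: _entropy(dim_shares[dim].to_numpy(), n)
                     for dim in dims}, name="entropy")
    info_j = 1.0 - e_j
    if info_j.sum() <= 0:
        raise ValueError("all dimensions have entropy 1; cannot weight")
    W_j = info_j / info_j.sum()

    ew = EntropyWeights(e_jk, w_jk, s_itj, e_j, W_j)
    ew._dim_of = {spec.indicator_id: spec.dimension for spec in norm.specs}
    return ew


@dataclass
class ScoreSeries:
    """Composite score M_it per province-year plus the weights used."""

    scores: pd.Series  # MultiIndex (province, year) -> M in [0, 1]
    weights: EntropyWeights

    @property
    def provinces(self) -> list[str]:
        return list(self.scores.index.get_level_values(0).unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.scores.index.get_level_values(1).unique())

    def year_slice(self, year: int) -> pd.Series:
        """Scores of all provinces in one year, indexed by province."""
        return self.scores.xs(year, level=1)

    def frame(self) -> pd.DataFrame:
        return self.scores.rename("M").reset_index()


def score(panel: IndicatorPanel) -> ScoreSeries:
    """Composite MHSS score: normalize, weight, aggregate.

    M_it = sum_j W_j * s_itj, bounded in [0, 1] because every s_itj is a
    convex combination of min-max values and the W_j sum to 1.
    """
    norm = normalize(panel)
    ew = fit_weights(norm)
    m = ew.dimension_scores @ ew.dimension_weights
    m.name = "M"
    return ScoreSeries(m, ew)


def scores_from_frame(df: pd.DataFrame) -> pd.Series:
    """Build a score series from a (province, year, M) frame (CSV import)."""
    s = df.set_index(["province", "year"])["M"].astype(float)
    s.name = "M"
    return s
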