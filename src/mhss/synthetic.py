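"""Synthetic provincial panels with known convergence dynamics.

The generator emulates the structure of the study data — 31 provinces in
three regions observed over 16 consecutive years (496 province-year
records) with 18 indicators in 6 dimensions of mixed attribute sign — while
recording the latent ground truth so that downstream stages can be tested
as parameter-recovery problems.

The latent log-score evolves by the convergence recursion

    ln y_{i,t+1} = ln y_it + alpha + beta * ln y_it
                   + rho * (W ln y)_it + mu_i + eta_t + eps_it

with province effects mu_i, year effects eta_t, i.i.d. Gaussian noise, and
an optional spatial spillover through the row-standardized contiguity lag.
Each indicator is a sign-consistent monotone loading of y = exp(ln y) plus
indicator noise, so the entropy-weighted composite score is a monotone
read-out of the latent level when noise is switched off.

Region level offsets follow the qualitative pattern the analysis expects
(eastern highest, then western, central lowest); their magnitudes are
synthetic choices, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import china
from .panel import (ControlPanel, IndicatorPanel, IndicatorSpec,
                    RegionScheme, china_contiguity)

#: Dimension layout mirroring the 18-indicator index: (dimension, n_indicators,
#: attribute signs). "+" benefit, "-" cost.
DEFAULT_LAYOUT = [
    ("human_resources", ["+", "+", "+", "-"]),
    ("facilities", ["+", "+", "+"]),
    ("healing_ability", ["-", "-", "+"]),
    ("primary_care", ["+", "+"]),
    ("service_utilization", ["+", "+", "+", "-"]),
    ("disease_control", ["-", "-"]),
]


@dataclass
class SynthConfig:
    """Configuration of the synthetic panel generator.

    Defaults reproduce the study layout: 11/8/12 provinces in the
    eastern/central/western regions, years 2005-2020, and the 4/3/3/2/4/2
    indicator-per-dimension layout with mixed signs.  ``beta_true`` in
    (-1, 0] is the convergence coefficient; ``alpha_true`` sets the steady
    state; ``sigma_eps`` the latent innovation s.d.; ``rho`` the spatial
    spillover on the contiguity lag (0 = independent provinces);
    ``region_levels`` the initial mean log-score per region.
    """

    n_provinces: tuple[int, int, int] = (11, 8, 12)
    years: tuple[int, int] = (2005, 2020)
    layout: list = field(default_factory=lambda: [
        (d, list(signs)) for d, signs in DEFAULT_LAYOUT])
    region_levels: tuple[float, float, float] = (-1.4, -2.0, -1.8)
    alpha_true: float = -0.276
    beta_true: float = -0.2
    sigma_eps: float = 0.05
    sigma_mu: float = 0.01
    sigma_eta: float = 0.005
    sigma_level: float = 0.25
    rho: float = 0.0
    loading_range: tuple[float, float] = (0.8, 1.2)
    sigma_indicator: float = 0.02
    missing_rate: float = 0.01
    use_china_names: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 < self.beta_true <= 0.0):
            raise ValueError("beta_true must lie in (-1, 0]")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if not (0.0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.years[1] <= self.years[0]:
            raise ValueError("years must span at least two calendar years")
        if any(n < 1 for n in self.n_provinces):
            raise ValueError("each region needs at least one province")

    @property
    def province_names(self) -> list[str]:
        ne, nc, nw = self.n_provinces
        if (self.use_china_names and (ne, nc, nw) == (11, 8, 12)):
            return list(china.PROVINCES)
        names = [f"E{i+1:02d}" for i in range(ne)]
        names += [f"C{i+1:02d}" for i in range(nc)]
        names += [f"W{i+1:02d}" for i in range(nw)]
        return names

    @property
    def region_scheme(self) -> RegionScheme:
        ne, nc, nw = self.n_provinces
        names = self.province_names
        mapping = {p: "eastern" for p in names[:ne]}
        mapping.update({p: "central" for p in names[ne:ne + nc]})
        mapping.update({p: "western" for p in names[ne + nc:]})
        return RegionScheme(mapping, ["eastern", "central", "western"])

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SynthTruth:
    """Ground truth recorded alongside a generated panel."""

    log_latent: pd.DataFrame  # provinces x years, ln y_it
    alpha_true: float
    beta_true: float
    rho: float
    region_scheme: RegionScheme
    adjacency: pd.DataFrame

    def latent_series(self) -> pd.Series:
        """ln y_it as a (province, year) series aligned to panel indexing."""
        s = self.log_latent.stack()
        s.index.names = ["province", "year"]
        return s


def _rngs(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Independent per-component generators derived from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_adjacency(config: SynthConfig, seed: int = 0) -> pd.DataFrame:
    """Symmetric binary contiguity for the configured provinces.

    The default 31-province configuration uses the bundled queen-contiguity
    neighbour list for mainland China.  Other sizes get a ring within each
    region plus one chord per region and a few cross-region bridges —
    connected by construction.
    """
    names = config.province_names
    if config.use_china_names and len(names) == 31:
        return china_contiguity(names)
    n = len(names)
    if n < 2:
        raise ValueError("adjacency needs at least 2 provinces")
    A = pd.DataFrame(0.0, index=names, columns=names)
    ne, nc, nw = config.n_provinces
    blocks = [names[:ne], names[ne:ne + nc], names[ne + nc:]]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for block in blocks:
        m = len(block)
        for i in range(m):
            a, b = block[i], block[(i + 1) % m]
            if a != b:
                A.loc[a, b] = A.loc[b, a] = 1.0
        if m >= 4:  # one chord
            A.loc[block[0], block[m // 2]] = A.loc[block[m // 2], block[0]] = 1.0
    for b1, b2 in zip(blocks[:-1], blocks[1:]):
        if b1 and b2:
            a = b1[int(rng.integers(len(b1)))]
            b = b2[int(rng.integers(len(b2)))]
            A.loc[a, b] = A.loc[b, a] = 1.0
    if A.to_numpy().sum() == 0:
        raise ValueError("generated adjacency has no edges")
    return A


def generate_coordinates(config: SynthConfig, seed: int = 0) -> pd.DataFrame:
    """Reproducible planar coordinates with region clusters laid west-east.

    Units are arbitrary projected units; the eastern cluster sits at the
    largest x, the western at the smallest, mimicking the real geography's
    gross layout.
    """
    rng = _rngs(seed, "coords")["coords"]
    names = config.province_names
    scheme = config.region_scheme
    centers = {"western": (0.0, 0.0), "central": (6.0, 0.5),
               "eastern": (12.0, 0.0)}
    rows = []
    for p in names:
        cx, cy = centers[scheme.region_of(p)]
        rows.append({"province": p,
                     "x": cx + rng.normal(0, 1.5),
                     "y": cy + rng.normal(0, 2.0)})
    return pd.DataFrame(rows).set_index("province")


def _simulate_latent(config: SynthConfig, rngs, adjacency: pd.DataFrame
                     ) -> pd.DataFrame:
    names = config.province_names
    years = config.year_list
    scheme = config.region_scheme
    level0 = {"eastern": config.region_levels[0],
              "central": config.region_levels[1],
              "western": config.region_levels[2]}

    W = adjacency.loc[names, names].to_numpy(float)
    rs = W.sum(axis=1, keepdims=True)
    Wn = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)

    rng = rngs["latent"]
    mu = rng.normal(0.0, config.sigma_mu, size=len(names)) \
        if config.sigma_mu > 0 else np.zeros(len(names))
    eta = rng.normal(0.0, config.sigma_eta, size=len(years) - 1) \
        if config.sigma_eta > 0 else np.zeros(len(years) - 1)

    ln_y = np.empty((len(names), len(years)))
    start = np.array([level0[scheme.region_of(p)] for p in names])
    jitter = rng.normal(0.0, config.sigma_level, size=len(names)) \
        if config.sigma_level > 0 else 0.0
    ln_y[:, 0] = start + jitter
    for t in range(len(years) - 1):
        drift = (config.alpha_true + config.beta_true * ln_y[:, t]
                 + config.rho * (Wn @ ln_y[:, t]) + mu + eta[t])
        eps = rng.normal(0.0, config.sigma_eps, size=len(names)) \
            if config.sigma_eps > 0 else 0.0
        ln_y[:, t + 1] = ln_y[:, t] + drift + eps
    return pd.DataFrame(ln_y, index=names, columns=years)


def _emit_indicators(config: SynthConfig, rngs, ln_y: pd.DataFrame
                     ) -> IndicatorPanel:
    rng = rngs["indicators"]
    names, years = list(ln_y.index), list(ln_y.columns)
    y = np.exp(ln_y.to_numpy())  # provinces x years

    specs: list[IndicatorSpec] = []
    cols: dict[str, np.ndarray] = {}
    lo, hi = config.loading_range
    for dim, signs in config.layout:
        for k, sign in enumerate(signs):
            ind_id = f"{dim}_{k+1}"
            attr = "positive" if sign == "+" else "negative"
            specs.append(IndicatorSpec(ind_id, dim, attr))
            b = rng.uniform(lo, hi)
            base = b * y
            if attr == "negative":
                base = -base  # cost indicators decrease in y
            noise = (rng.normal(0.0, config.sigma_indicator, size=y.shape)
                     if config.sigma_indicator > 0 else 0.0)
            cols[ind_id] = (base + noise).ravel()

    index = pd.MultiIndex.from_product([names, years],
                                       names=["province", "year"])
    values = pd.DataFrame(cols, index=index)

    if config.missing_rate > 0:
        mask = rngs["missing"].random(values.shape) < config.missing_rate
        # keep first and last year observed so every series stays anchorable
        year_pos = np.array([years.index(t) for t in
                             index.get_level_values("year")])
        mask[(year_pos == 0) | (year_pos == len(years) - 1), :] = False
        values = values.mask(mask)
    return IndicatorPanel(specs, values)


def _emit_controls(config: SynthConfig, rngs, ln_y: pd.DataFrame
                   ) -> ControlPanel:
    """Controls loosely correlated with the latent level and a time trend."""
    rng = rngs["controls"]
    names, years = list(ln_y.index), list(ln_y.columns)
    scheme = config.region_scheme
    t_idx = {t: i for i, t in enumerate(years)}
    region_gdp = {"eastern": 1.2, "central": 0.7, "western": 0.4}
    rows = []
    for p in names:
        g0 = region_gdp[scheme.region_of(p)] + rng.normal(0, 0.2)
        ur0 = np.clip(45 + 18 * (g0 - 0.7) + rng.normal(0, 5), 21, 80)
        for t in years:
            tt = t_idx[t]
            lnpgdp = g0 + 0.06 * tt + rng.normal(0, 0.05)
            ur = np.clip(ur0 + 1.2 * tt + rng.normal(0, 1.0), 0, 100)
            fss = np.clip(0.35 + 0.25 * (g0 - 0.4) + rng.normal(0, 0.05),
                          0.05, 0.97)
            isu = max(0.42, 0.8 + 0.4 * (g0 - 0.7) + 0.01 * tt
                      + rng.normal(0, 0.1))
            lnpfdi = 1.5 + 1.2 * g0 + 0.05 * tt + rng.normal(0, 0.3)
            rows.append({"province": p, "year": t, "lnPGDP": lnpgdp,
                         "UR": ur, "FSS": fss, "ISU": isu,
                         "lnPFDI": lnpfdi})
    df = pd.DataFrame(rows).set_index(["province", "year"])
    return ControlPanel(df)


def generate_panel(config: SynthConfig | None = None, seed: int = 0
                   ) -> tuple[IndicatorPanel, ControlPanel, RegionScheme,
                              SynthTruth]:
    """Generate an indicator panel, controls, region scheme and truth.

    Fully reproducible: one seed drives a splittable generator whose
    per-component streams (latent path, indicator noise, missingness,
    controls) are derived deterministically.
    """
    config = config or SynthConfig()
    rngs = _rngs(seed, "latent", "indicators", "missing", "controls")
    adjacency = generate_adjacency(config, seed=seed)
    ln_y = _simulate_latent(config, rngs, adjacency)
    panel = _emit_indicators(config, rngs, ln_y)
    controls = _emit_controls(config, rngs, ln_y)
    truth = SynthTruth(ln_y, config.alpha_true, config.beta_true,
                       config.rho, config.region_scheme, adjacency)
    return panel, controls, config.region_scheme, truth


def noiseless(config: SynthConfig | None = None, **overrides) -> SynthConfig:
    """A copy of ``config`` with every stochastic component switched off."""
    config = config or SynthConfig()
    return replace(config, sigma_eps=0.0, sigma_mu=0.0, sigma_eta=0.0,
                   sigma_indicator=0.0, missing_rate=0.0, rho=0.0,
                   **overrides)
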