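"""Data model and I/O for provincial indicator panels.

The canonical on-disk form is a long (tidy) CSV with columns
``province,year,indicator_id,value`` plus a companion indicator-spec CSV
``indicator_id,dimension,attribute,units``.  In memory a panel is a wide
:class:`pandas.DataFrame` indexed by (province, year) with one column per
indicator; missing observations are ``NaN``.

Province names are matched case-sensitively after whitespace trimming.
Years must be consecutive calendar years: the downstream convergence and
Markov stages assume annual transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import china

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for one indicator: its dimension and attribute sign.

    ``attribute`` is ``"positive"`` for benefit indicators (more is better)
    and ``"negative"`` for cost indicators (less is better, e.g. a mortality
    rate).
    """

    indicator_id: str
    dimension: str
    attribute: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.attribute not in (POSITIVE, NEGATIVE):
            raise ValueError(
                f"indicator {self.indicator_id!r}: attribute must be "
                f"'positive' or 'negative', got {self.attribute!r}"
            )


@dataclass
class IndicatorPanel:
    """Province x year x indicator observations plus indicator metadata.

    ``values`` is a wide DataFrame with a (province, year) MultiIndex and
    one float column per indicator; NaN flags a missing cell.
    """

    specs: list[IndicatorSpec]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [s.indicator_id for s in self.specs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate indicator_id in spec: {dup!r}")
        extra = [c for c in self.values.columns if c not in set(ids)]
        if extra:
            raise ValueError(
                f"indicator {extra[0]!r} present in data but absent from spec"
            )
        self.values = self.values.reindex(columns=ids).astype(float)
        years = self.years
        if len(self.provinces) < 1 or len(years) < 1:
            raise ValueError("panel must contain at least one province-year")
        if len(years) > 1 and np.any(np.diff(years) != 1):
            raise ValueError(f"years must be consecutive, got {list(years)}")

    @property
    def provinces(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.values.index.get_level_values(1).unique())

    @property
    def indicator_ids(self) -> list[str]:
        return [s.indicator_id for s in self.specs]

    @property
    def dimensions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.specs:
            seen.setdefault(s.dimension, None)
        return list(seen)

    def spec_of(self, indicator_id: str) -> IndicatorSpec:
        for s in self.specs:
            if s.indicator_id == indicator_id:
                return s
        raise KeyError(indicator_id)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "IndicatorPanel":
        return IndicatorPanel(list(self.specs), self.values.copy())


@dataclass
class RegionScheme:
    """Partition of provinces into named regions."""

    mapping: dict[str, str]
    regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.regions:
            seen: dict[str, None] = {}
            for r in self.mapping.values():
                seen.setdefault(r, None)
            self.regions = list(seen)
        for r in self.regions:
            if r not in self.mapping.values():
                raise ValueError(f"region {r!r} has no provinces")

    def region_of(self, province: str) -> str:
        try:
            return self.mapping[province]
        except KeyError:
            raise ValueError(
                f"province {province!r} is not covered by the region scheme"
            ) from None


def default_region_scheme() -> RegionScheme:
    """The standard eastern/central/western partition of mainland China."""
    return RegionScheme(dict(china.REGION_OF), list(china.REGION_LABELS))


@dataclass
class ControlPanel:
    """Province-year control covariates for conditional convergence.

    Columns: lnPGDP (log per-capita GDP), UR (urbanization rate, percent),
    FSS (fiscal self-sufficiency, fraction), ISU (industrial structure
    upgrading ratio), lnPFDI (log per-capita foreign direct investment).
    """

    COLUMNS = ["lnPGDP", "UR", "FSS", "ISU", "lnPFDI"]

    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.values.columns]
        if missing:
            raise ValueError(f"control panel lacks columns: {missing}")
        self.values = self.values[self.COLUMNS].astype(float)
        ur = self.values["UR"]
        if ((ur < 0) | (ur > 100)).any():
            raise ValueError("UR must lie in [0, 100]")
        fss = self.values["FSS"]
        if ((fss < 0) | (fss > 1)).any():
            raise ValueError("FSS must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O

def _clean_name(s: object) -> str:
    return str(s).strip()


def read_indicator_specs(spec_path) -> list[IndicatorSpec]:
    df = pd.read_csv(spec_path, dtype=str)
    needed = {"indicator_id", "dimension", "attribute"}
    if not needed.issubset(df.columns):
        raise ValueError(f"spec file must have columns {sorted(needed)}")
    specs = []
    for _, row in df.iterrows():
        specs.append(IndicatorSpec(
            indicator_id=_clean_name(row["indicator_id"]),
            dimension=_clean_name(row["dimension"]),
            attribute=_clean_name(row["attribute"]),
            units=_clean_name(row.get("units", "")) if "units" in df.columns else "",
        ))
    return specs


def read_panel(path, spec_path) -> IndicatorPanel:
    """Read a long-format panel CSV plus its indicator-spec CSV.

    Unparseable numeric cells become missing.  Duplicate
    (province, year, indicator) rows and indicators absent from the spec
    are errors.
    """
    specs = read_indicator_specs(spec_path)
    df = pd.read_csv(path, dtype={"province": str, "indicator_id": str})
    needed = {"province", "year", "indicator_id", "value"}
    if not needed.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(needed)}")
    df["province"] = df["province"].map(_clean_name)
    df["indicator_id"] = df["indicator_id"].map(_clean_name)
    df["year"] = df["year"].astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    dup = df.duplicated(subset=["province", "year", "indicator_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            "duplicate row for "
            f"({r['province']!r}, {r['year']}, {r['indicator_id']!r})"
        )
    wide = df.pivot(index=["province", "year"], columns="indicator_id",
                    values="value")
    wide.columns.name = None
    # preserve first-appearance province order, sorted years within
    order = list(dict.fromkeys(df["province"]))
    wide = wide.reindex(
        pd.MultiIndex.from_product([order, np.sort(df["year"].unique())],
                                   names=["province", "year"])
    )
    return IndicatorPanel(specs, wide)


def write_panel(panel: IndicatorPanel, path, spec_path=None) -> None:
    """Write a panel back to the long CSV dialect (and optionally its spec)."""
    long = (panel.values
            .reset_index()
            .melt(id_vars=["province", "year"], var_name="indicator_id",
                  value_name="value"))
    long = long.sort_values(["province", "year", "indicator_id"],
                            key=lambda s: (s.map({p: i for i, p in
                                                  enumerate(panel.provinces)})
                                           if s.name == "province" else s))
    long.to_csv(path, index=False)
    if spec_path is not None:
        pd.DataFrame([{
            "indicator_id": s.indicator_id, "dimension": s.dimension,
            "attribute": s.attribute, "units": s.units,
        } for s in panel.specs]).to_csv(spec_path, index=False)


def read_region_scheme(path) -> RegionScheme:
    df = pd.read_csv(path, dtype=str)
    if not {"province", "region"}.issubset(df.columns):
        raise ValueError("region scheme CSV needs columns province,region")
    mapping = {_clean_name(p): _clean_name(r)
               for p, r in zip(df["province"], df["region"])}
    return RegionScheme(mapping)


def read_controls(path) -> ControlPanel:
    df = pd.read_csv(path)
    df["province"] = df["province"].map(_clean_name)
    df["year"] = df["year"].astype(int)
    return ControlPanel(df.set_index(["province", "year"]))


def read_coordinates(path) -> pd.DataFrame:
    """Read projected planar coordinates: columns province,x,y."""
    df = pd.read_csv(path)
    df["province"] = df["province"].map(_clean_name)
    return df.set_index("province")[["x", "y"]].astype(float)


def read_contiguity(path, provinces: list[str]) -> pd.DataFrame:
    """Read an edge-list CSV (province_a,province_b) into a binary matrix."""
    df = pd.read_csv(path, dtype=str)
    A = pd.DataFrame(0.0, index=provinces, columns=provinces)
    for a, b in zip(df["province_a"], df["province_b"]):
        a, b = _clean_name(a), _clean_name(b)
        if a not in A.index or b not in A.index:
            raise ValueError(f"contiguity edge ({a!r}, {b!r}) names an "
                             "unknown province")
        A.loc[a, b] = A.loc[b, a] = 1.0
    return A


def china_contiguity(provinces: list[str] | None = None) -> pd.DataFrame:
    """Queen-contiguity matrix for mainland China's 31 provincial units."""
    provinces = list(provinces) if provinces is not None else list(china.PROVINCES)
    A = pd.DataFrame(0.0, index=provinces, columns=provinces)
    for a, b in china.CONTIGUITY_EDGES:
        if a in A.index and b in A.index:
            A.loc[a, b] = A.loc[b, a] = 1.0
    return A


# ---------------------------------------------------------------------------
# Transformations

def interpolate_missing(panel: IndicatorPanel) -> IndicatorPanel:
    """Fill missing cells by linear interpolation in year.

    Interior gaps in each (province, indicator) series are linearly
    interpolated; leading/trailing gaps take the nearest observed value
    (flat fill).  A series with fewer than two observations cannot anchor a
    line and is an error.
    """
    out = panel.copy()
    years = out.years
    for prov in out.provinces:
        block = out.values.loc[prov]
        block = block.reindex(years)
        for col in block.columns:
            s = block[col]
            n_obs = int(s.notna().sum())
            if n_obs == len(s):
                continue
            if n_obs < 2:
                raise ValueError(
                    f"series ({prov!r}, {col!r}) has {n_obs} observation(s); "
                    "need at least 2 to interpolate"
                )
            filled = s.interpolate(method="index", limit_direction="both",
                                   limit_area="inside")
            filled = filled.ffill().bfill()
            out.values.loc[(prov, slice(None)), col] = filled.to_numpy()
    return out


def assign_regions(panel: IndicatorPanel, scheme: RegionScheme
                   ) -> dict[str, list[str]]:
    """Group the panel's provinces by region, preserving panel order."""
    groups: dict[str, list[str]] = {r: [] for r in scheme.regions}
    for p in panel.provinces:
        groups[scheme.region_of(p)].append(p)
    empty = [r for r, ps in groups.items() if not ps]
    if empty:
        warnings.warn(f"regions with no panel provinces: {empty}")
        for r in empty:
            del groups[r]
    return groups


@dataclass
class ValidationReport:
    constant_indicators: list[str]
    n_missing: int
    missing_by_indicator: dict[str, int]
    year_gaps: list[int]

    @property
    def issues(self) -> list[str]:
        out = []
        for ind in self.constant_indicators:
            out.append(f"indicator {ind!r} is constant over the pooled panel")
        if self.n_missing:
            out.append(f"{self.n_missing} missing cell(s)")
        if self.year_gaps:
            out.append(f"missing years: {self.year_gaps}")
        return out


def validate_panel(panel: IndicatorPanel) -> ValidationReport:
    """Report-only audit: constant indicators, missing cells, year gaps."""
    vals = panel.values
    const = [c for c in vals.columns
             if vals[c].notna().any() and vals[c].max() == vals[c].min()]
    miss = {c: int(vals[c].isna().sum()) for c in vals.columns
            if vals[c].isna().any()}
    years = panel.years
    gaps = ([] if len(years) < 2 else
            [int(y) for y in range(int(years[0]), int(years[-1]) + 1)
             if y not in set(int(v) for v in years)])
    return ValidationReport(const, panel.n_missing, miss, gaps)
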