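"""Data structures, I/O, validation and trait derivations for MET phenotype data.

A multi-environment trial (MET) dataset is a long-format table of plot-level
phenotype records. Each year x location combination is one *environment* (and
one trial); genotypes are evaluated in randomized complete blocks (replicates)
within each trial. Trait conventions: fresh root yield (FRY), shoot yield
(ShY) and dry root yield (DRY) in t/ha, dry matter content (DMC) in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

TRAITS = ("FRY", "ShY", "DRY", "DMC")

#: canonical long-format columns for plot records
RECORD_COLUMNS = ["environment", "year", "location", "genotype",
                  "replicate", "block", "trait", "value"]
_REQUIRED = ["environment", "genotype", "replicate", "value"]


class SchemaError(ValueError):
    """Input file is missing required columns or has a malformed layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. DMC outside (0, 100))."""


# ---------------------------------------------------------------------------
# trait derivations

def derive_dmc(weight_in_air: float, weight_in_water: float) -> float:
    """Dry matter content (%) from the gravimetric hydrostatic balance method.

    DMC = 158.3 * w_air / (w_air - w_water) - 142.0, with both weights in
    grams for a standard root sample. The buoyancy difference must be
    positive.
    """
    wa, ww = float(weight_in_air), float(weight_in_water)
    if not (wa > ww > 0):
        raise ValueError(
            f"require weight_in_air > weight_in_water > 0, got ({wa}, {ww})")
    return 158.3 * wa / (wa - ww) - 142.0


def derive_dry(fry: float, dmc: float) -> float:
    """Dry root yield (t/ha) = FRY * DMC/100 (DMC is a percentage)."""
    if not np.isfinite(fry) or fry < 0:
        raise ValueError(f"FRY must be finite and >= 0, got {fry}")
    if not (0.0 < dmc < 100.0):
        raise ValueError(f"DMC must lie in (0, 100), got {dmc}")
    return fry * dmc / 100.0


# ---------------------------------------------------------------------------
# containers

@dataclass
class MetDataset:
    """Plot-level phenotype records for one trait across environments.

    ``records`` is a long-format DataFrame with columns ``RECORD_COLUMNS``;
    missing plot values are retained as NaN (never dropped at read time,
    unbalance-aware fitting needs them explicit).
    """

    records: pd.DataFrame
    trait: str

    def __post_init__(self):
        missing = [c for c in _REQUIRED if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing required columns: {missing}")
        for col in RECORD_COLUMNS:
            if col not in self.records.columns:
                self.records[col] = "" if col in ("location", "block") else np.nan
        if self.trait not in TRAITS:
            raise ValidationError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        reps = self.records["replicate"]
        if (pd.to_numeric(reps, errors="coerce") < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        if self.trait == "DMC":
            v = self.records["value"].dropna()
            bad = v[(v <= 0) | (v >= 100)]
            if len(bad):
                raise ValidationError(
                    f"DMC values outside (0, 100): {bad.iloc[0]} (row {bad.index[0]})")

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].astype(str).unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype"].astype(str).unique())

    @property
    def incidence(self) -> pd.DataFrame:
        """Genotype x environment presence table (True where any non-missing plot)."""
        obs = self.records.dropna(subset=["value"])
        tab = obs.groupby(["genotype", "environment"]).size().unstack(fill_value=0)
        tab = tab.reindex(index=self.genotypes, columns=self.environments, fill_value=0)
        return tab > 0

    def subset_environment(self, env: str) -> pd.DataFrame:
        return self.records[self.records["environment"] == env]

    def write(self, path) -> None:
        self.records.to_csv(path, index=False, columns=RECORD_COLUMNS)


@dataclass
class CovariateTable:
    """Environment-level covariates (one row per environment).

    Standard columns follow weather-station variables: Tmax, Tmin, Tav (degC),
    Rain (mm), Rh (%), Wspeed (m/s), Solrad (MJ/m2/day), Altitude (m); extra
    numeric columns are carried along as additional covariates.
    """

    table: pd.DataFrame  # indexed by environment

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate environment key {dup!r}")
        if not np.isfinite(self.table.to_numpy(float)).all():
            raise ValidationError("covariate table contains non-finite values")

    @property
    def environments(self) -> list[str]:
        return list(self.table.index.astype(str))

    @property
    def covariates(self) -> list[str]:
        return list(self.table.columns)

    def write(self, path) -> None:
        self.table.to_csv(path, index_label="environment")


@dataclass
class ConnectivityReport:
    """Design connectivity of a MET: shared genotypes and coverage."""

    shared_counts: pd.DataFrame          # env x env shared-genotype counts
    coverage: pd.Series                  # per-genotype fraction of environments
    weak_pairs: list[tuple[str, str]]    # env pairs sharing < 2 genotypes
    low_coverage: list[str]              # genotypes below the coverage threshold
    components: list[set[str]]           # connected components of env-sharing graph

    @property
    def connected(self) -> bool:
        return len(self.components) <= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "genotype": self.coverage.index,
            "coverage": self.coverage.values,
            "flag_low_coverage": [g in set(self.low_coverage) for g in self.coverage.index],
        })


# ---------------------------------------------------------------------------
# I/O

def read_phenotypes(path, trait: str, na_values=("", "NA", "NaN")) -> MetDataset:
    """Read a long-format phenotype CSV into a validated :class:`MetDataset`.

    The file must name at least environment, genotype, replicate and value
    columns; ``trial`` is accepted as an alias of ``environment``. Rows with
    missing values are retained as explicit-missing cells.
    """
    text_cols = {c: str for c in ("trial", "environment", "genotype",
                                  "location", "block", "trait", "set_or_block")}
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True,
                     dtype=text_cols)
    if "environment" not in df.columns and "trial" in df.columns:
        df = df.rename(columns={"trial": "environment"})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "trait" in df.columns:
        df = df[df["trait"].fillna(trait) == trait]
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df["value"].notna() & vals.isna()
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(f"{path}: non-numeric value {df.loc[row, 'value']!r} at row {row}")
    df = df.assign(value=vals, trait=trait)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    return MetDataset(records=df.reset_index(drop=True), trait=trait)


def read_covariates(path) -> CovariateTable:
    """Read an environment-keyed covariate CSV (one row per environment)."""
    df = pd.read_csv(path)
    key = "environment" if "environment" in df.columns else df.columns[0]
    df = df.set_index(key)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and df[col].notna().any():
            bad = df[col][coerced.isna() & df[col].notna()]
            raise SchemaError(
                f"{path}: non-numeric covariate {col!r} value {bad.iloc[0]!r} "
                f"for environment {bad.index[0]!r}")
        df[col] = coerced
    return CovariateTable(table=df)


# ---------------------------------------------------------------------------
# connectivity

def connectivity_report(data: MetDataset, coverage_threshold: float = 0.5,
                        min_shared: int = 2) -> ConnectivityReport:
    """Pairwise shared-genotype counts and per-genotype environment coverage.

    Environments sharing fewer than ``min_shared`` genotypes are flagged as
    weakly connected; genotypes evaluated in fewer than
    ``coverage_threshold`` of all environments are flagged (the focal-set
    convention is presence in at least half the environments).
    """
    if data.records.empty:
        raise ValidationError("empty dataset")
    inc = data.incidence
    B = inc.to_numpy(int)
    shared = B.T @ B
    envs = list(inc.columns)
    shared_df = pd.DataFrame(shared, index=envs, columns=envs)
    coverage = pd.Series(B.sum(axis=1) / len(envs), index=inc.index, name="coverage")
    weak, g = [], nx.Graph()
    g.add_nodes_from(envs)
    for a in range(len(envs)):
        for b in range(a + 1, len(envs)):
            if shared[a, b] >= 1:
                g.add_edge(envs[a], envs[b])
            if shared[a, b] < min_shared:
                weak.append((envs[a], envs[b]))
    comps = [set(c) for c in nx.connected_components(g)]
    low = list(coverage.index[coverage < coverage_threshold])
    return ConnectivityReport(shared_counts=shared_df, coverage=coverage,
                              weak_pairs=weak, low_coverage=low, components=comps)
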