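"""County-year panel container and file-format contracts.

A :class:`CountyYearPanel` holds the under-five mortality rate (U5M, deaths
per 1,000 livebirths) and intervention-coverage values for every
county-year of a baseline window.  Coverage is stored internally on the
proportion scale in (0, 1); CSV files at the I/O boundary use percent, the
scale the field reports coverage on.  The conversion happens only in
:meth:`CountyYearPanel.to_csv` / :meth:`CountyYearPanel.from_csv`.

Adjacency between counties (for the spatially structured random effect) is
an undirected :class:`networkx.Graph` with integer nodes ``0..n-1``,
serialized as a whitespace-delimited edge list.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["CountyYearPanel", "read_adjacency", "write_adjacency", "SCHEMA_PREFIX"]

SCHEMA_PREFIX = "# u5mproj-schema:"


def _schema_line(name: str, version: int = 1) -> str:
    return f"{SCHEMA_PREFIX} {name}-v{version}\n"


@dataclass
class CountyYearPanel:
    """Long-format panel of U5M and coverage, one row per county-year.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``county_id`` (int), ``year`` (int), ``u5m`` (deaths per
        1,000 livebirths) and one column per factor holding coverage
        proportions in (0, 1).
    factors : list of str
        Names of the factor columns, in model order.
    """

    data: pd.DataFrame
    factors: list = field(default_factory=list)

    def __post_init__(self):
        required = {"county_id", "year", "u5m"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        missing_f = [f for f in self.factors if f not in self.data.columns]
        if missing_f:
            raise ValueError(f"panel missing factor columns: {missing_f}")
        self.data = self.data.sort_values(["county_id", "year"]).reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def counties(self) -> np.ndarray:
        return np.sort(self.data["county_id"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def is_complete(self) -> bool:
        """True when every county-year combination is present exactly once."""
        return len(self.data) == self.n_counties * self.n_years and not (
            self.data.duplicated(["county_id", "year"]).any()
        )

    # -- wide views used by the model and the scenario engine -----------
    def u5m_wide(self) -> pd.DataFrame:
        """U5M as a (county x year) table."""
        return self.data.pivot(index="county_id", columns="year", values="u5m")

    def factor_wide(self, factor: str) -> pd.DataFrame:
        """One factor's coverage proportions as a (county x year) table."""
        if factor not in self.factors:
            raise KeyError(f"unknown factor {factor!r}")
        return self.data.pivot(index="county_id", columns="year", values=factor)

    def design_arrays(self, factors=None):
        """Return (z, X) with z = log(u5m/1000), shape (C, T), X shape (C, T, K).

        Rows/columns follow sorted county and year order.  Requires a
        complete panel.
        """
        if not self.is_complete():
            raise ValueError("panel must be complete over counties x years")
        factors = list(self.factors if factors is None else factors)
        z = np.log(self.u5m_wide().to_numpy() / 1000.0)
        X = np.stack(
            [self.factor_wide(f).to_numpy() for f in factors], axis=-1
        ) if factors else np.empty((self.n_counties, self.n_years, 0))
        return z, X

    # -- I/O (percent at the boundary) ----------------------------------
    def to_csv(self, path) -> None:
        out = self.data.copy()
        for f in self.factors:
            out[f] = out[f] * 100.0
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_schema_line("panel"))
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountyYearPanel":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith(SCHEMA_PREFIX):
                fh.seek(0)
            df = pd.read_csv(fh)
        factors = [c for c in df.columns if c not in ("county_id", "year", "u5m")]
        for f in factors:
            df[f] = df[f] / 100.0
        return cls(df, factors)


def write_adjacency(graph: nx.Graph, path) -> None:
    """Write an undirected graph as a ``i j`` edge list (0-based ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_schema_line("adjacency"))
        for i, j in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{i} {j}\n")


def read_adjacency(path) -> nx.Graph:
    """Read an edge-list adjacency file written by :func:`write_adjacency`."""
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j = line.split()
            g.add_edge(int(i), int(j))
    return g
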