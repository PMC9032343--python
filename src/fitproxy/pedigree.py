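"""Pedigree, breeding-record and census containers with parsing and validation.

The pedigree is a directed acyclic graph of parent->offspring links derived
from sire/dam columns.  Founders (both parents unknown) and half-founders
(exactly one parent unknown) are the roots of the lineages that the
gene-dropping simulation tracks.  Years are plain integers; the census
convention (adults counted on 1st April) is metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING = {"", "NA", "NaN", "nan", "None"}

SEXES = ("male", "female", "unknown")


class PedigreeError(ValueError):
    """Raised on a structurally invalid pedigree, breeding table or census."""


@dataclass(frozen=True)
class Individual:
    """One pedigree entry.

    ``death_year`` is the last year the individual was alive.  An individual
    is an *adult* in years ``birth_year + 1 .. death_year`` and *alive*
    (juvenile or adult) in years ``birth_year .. death_year``.
    """

    id: str
    sire: Optional[str]
    dam: Optional[str]
    sex: str
    birth_year: int
    death_year: int
    origin: str = "native"

    @property
    def n_unknown_parents(self) -> int:
        return (self.sire is None) + (self.dam is None)


@dataclass(frozen=True)
class FounderEntry:
    """Roster row for one lineage root (founder or half-founder)."""

    id: str
    origin: str
    status: str  # "founder" | "half-founder"
    n_root_alleles: int  # 2 iff both parents unknown, 1 iff exactly one
    cohort_year: int


class FounderRoster:
    """Cohort of lineage roots selected by birth-year window."""

    def __init__(self, entries: Iterable[FounderEntry]):
        self.entries = list(entries)
        self._by_id = {e.id: e for e in self.entries}
        if len(self._by_id) != len(self.entries):
            raise PedigreeError("duplicate ids in founder roster")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> FounderEntry:
        return self._by_id[ind_id]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.id, e.origin, e.status, e.n_root_alleles, e.cohort_year)
                for e in self.entries
            ],
            columns=["id", "origin", "status", "n_root_alleles", "cohort_year"],
        )


class Pedigree:
    """Validated collection of :class:`Individual` with parent->offspring edges."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id: {ind.id!r}")
            self.individuals[ind.id] = ind
        self._validate()
        self.graph = self._build_graph()
        self._check_acyclic()
        self._check_parent_years()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        fixed: dict[str, Individual] = {}
        for ind in self.individuals.values():
            for parent, role in ((ind.sire, "sire"), (ind.dam, "dam")):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise PedigreeError(
                        f"unknown parent id {parent!r} ({role} of {ind.id!r})"
                    )
            if ind.sex not in SEXES:
                raise PedigreeError(f"invalid sex {ind.sex!r} for {ind.id!r}")
            if ind.birth_year > ind.death_year:
                raise PedigreeError(
                    f"{ind.id!r}: birth_year {ind.birth_year} > death_year "
                    f"{ind.death_year}"
                )
        # sex consistency with parent roles; unknown-sex parents get the
        # implied sex with a logged warning rather than failing the file
        for ind in self.individuals.values():
            for parent_id, implied in ((ind.sire, "male"), (ind.dam, "female")):
                if parent_id is None:
                    continue
                parent = fixed.get(parent_id, self.individuals[parent_id])
                wrong = "female" if implied == "male" else "male"
                if parent.sex == wrong:
                    role = "sire" if implied == "male" else "dam"
                    raise PedigreeError(
                        f"{parent_id!r} is {parent.sex} but appears as {role} "
                        f"of {ind.id!r}"
                    )
                if parent.sex == "unknown":
                    logger.warning(
                        "individual %r has unknown sex but appears as a %s; "
                        "assigning sex %r",
                        parent_id,
                        "sire" if implied == "male" else "dam",
                        implied,
                    )
                    fixed[parent_id] = Individual(
                        parent.id, parent.sire, parent.dam, implied,
                        parent.birth_year, parent.death_year, parent.origin,
                    )
        self.individuals.update(fixed)

    def _build_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    g.add_edge(parent, ind.id)
        return g

    def _check_acyclic(self) -> None:
        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeError(f"pedigree contains a cycle: {path}")

    def _check_parent_years(self) -> None:
        for ind in self.individuals.values():
            for parent_id in (ind.sire, ind.dam):
                if parent_id is None:
                    continue
                parent = self.individuals[parent_id]
                if parent.birth_year >= ind.birth_year:
                    raise PedigreeError(
                        f"parent {parent_id!r} (born {parent.birth_year}) not "
                        f"older than offspring {ind.id!r} (born {ind.birth_year})"
                    )

    # -- queries -------------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def children_of(self, ind_id: str) -> list[str]:
        return sorted(self.graph.successors(ind_id))

    def descendants_of(self, ind_id: str) -> set[str]:
        return nx.descendants(self.graph, ind_id)

    def alive(self, year: int) -> list[str]:
        """Ids alive (juvenile or adult) in ``year``."""
        return [
            i.id for i in self.individuals.values()
            if i.birth_year <= year <= i.death_year
        ]

    def adults(self, year: int) -> list[str]:
        """Ids that are adults in ``year`` (born before, still alive)."""
        return [
            i.id for i in self.individuals.values()
            if i.birth_year < year <= i.death_year
        ]

    @property
    def year_range(self) -> tuple[int, int]:
        births = [i.birth_year for i in self.individuals.values()]
        deaths = [i.death_year for i in self.individuals.values()]
        return min(births), max(deaths)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i.id, i.sire, i.dam, i.sex, i.birth_year, i.death_year, i.origin)
            for i in self.individuals.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["id", "sire", "dam", "sex", "birth_year", "death_year", "origin"],
        )


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _parse_missing(token: str) -> Optional[str]:
    token = token.strip()
    return None if token in _MISSING else token


def read_pedigree(path: str | Path, last_census_year: Optional[int] = None) -> Pedigree:
    """Parse a delimited pedigree file into a validated :class:`Pedigree`.

    Expected header columns: id, sire, dam, sex, birth_year, death_year;
    an optional ``origin`` column is carried through.  ``NA`` and empty cells
    mark missing parents.  A missing death_year means "alive through the last
    census year" and requires ``last_census_year``.
    """
    df = _read_table(path)
    required = {"id", "sire", "dam", "sex", "birth_year", "death_year"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing_cols)}")
    inds = []
    for row in df.itertuples(index=False):
        death = _parse_missing(str(row.death_year))
        if death is None:
            if last_census_year is None:
                raise PedigreeError(
                    f"{row.id!r} has no death_year and no last_census_year given"
                )
            death_year = last_census_year
        else:
            death_year = int(death)
        sex = str(row.sex).strip().lower()
        if sex in ("m", "f"):
            sex = {"m": "male", "f": "female"}[sex]
        if _parse_missing(sex) is None:
            sex = "unknown"
        inds.append(
            Individual(
                id=str(row.id).strip(),
                sire=_parse_missing(str(row.sire)),
                dam=_parse_missing(str(row.dam)),
                sex=sex,
                birth_year=int(row.birth_year),
                death_year=death_year,
                origin=str(getattr(row, "origin", "native")).strip() or "native",
            )
        )
    return Pedigree(inds)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    df = ped.to_frame().copy()
    df["sire"] = df["sire"].fillna("NA")
    df["dam"] = df["dam"].fillna("NA")
    df.to_csv(path, index=False)


STAGE_COLUMNS = ("eggs", "hatchlings", "fledglings", "recruits", "broods")


class BreedingTable:
    """Per-parent per-year offspring counts at each developmental stage."""

    def __init__(self, df: pd.DataFrame):
        required = {"parent_id", "year", *STAGE_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"breeding table missing columns: {sorted(missing)}")
        df = df.copy()
        df["parent_id"] = df["parent_id"].astype(str)
        for col in ("year", *STAGE_COLUMNS):
            df[col] = df[col].astype(int)
        for col in STAGE_COLUMNS:
            if (df[col] < 0).any():
                raise PedigreeError(f"negative count in column {col!r}")
        bad = ~(
            (df["recruits"] <= df["fledglings"])
            & (df["fledglings"] <= df["hatchlings"])
            & (df["hatchlings"] <= df["eggs"])
        )
        if bad.any():
            row = df[bad].iloc[0]
            raise PedigreeError(
                "stage counts must satisfy recruits <= fledglings <= hatchlings "
                f"<= eggs; violated for parent {row['parent_id']!r} year "
                f"{row['year']}"
            )
        self.df = df.sort_values(["parent_id", "year"]).reset_index(drop=True)

    def records_for(self, parent_id: str) -> pd.DataFrame:
        return self.df[self.df["parent_id"] == str(parent_id)]

    def __len__(self) -> int:
        return len(self.df)


def read_breeding(path: str | Path) -> BreedingTable:
    return BreedingTable(pd.read_csv(path, sep=None, engine="python"))


def write_breeding(table: BreedingTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


class CensusSeries:
    """Adult population size per year (N_t), over a contiguous year range."""

    def __init__(self, counts: Mapping[int, int]):
        if not counts:
            raise PedigreeError("empty census series")
        years = sorted(counts)
        if years != list(range(years[0], years[-1] + 1)):
            raise PedigreeError("census years must be contiguous")
        for y in years:
            if int(counts[y]) < 1:
                raise PedigreeError(f"census count for year {y} must be >= 1")
        self.series = pd.Series(
            [int(counts[y]) for y in years], index=pd.Index(years, name="year"),
            name="n_adults",
        )

    def __getitem__(self, year: int) -> int:
        if year not in self.series.index:
            raise PedigreeError(f"year {year} not in census series")
        return int(self.series.loc[year])

    @property
    def years(self) -> list[int]:
        return list(self.series.index)

    @property
    def final_year(self) -> int:
        return int(self.series.index[-1])

    def growth_ratio(self, year: int) -> float:
        """w_t = N_{t+1} / N_t."""
        return self[year + 1] / self[year]


def read_census(path: str | Path) -> CensusSeries:
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"year", "n_adults"} <= set(df.columns):
        raise PedigreeError("census file must have columns year, n_adults")
    return CensusSeries(dict(zip(df["year"].astype(int), df["n_adults"].astype(int))))


def write_census(census: CensusSeries, path: str | Path) -> None:
    census.series.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# founder identification and ordering


def identify_founders(
    ped: Pedigree, cohort_window: tuple[int, int]
) -> FounderRoster:
    """Select founders/half-founders born inside ``cohort_window`` (inclusive).

    A founder has both parents unknown and roots two novel alleles; a
    half-founder has exactly one unknown parent and roots one.
    """
    lo, hi = cohort_window
    entries = []
    for ind_id in sorted(ped.individuals):
        ind = ped[ind_id]
        k = ind.n_unknown_parents
        if k == 0 or not (lo <= ind.birth_year <= hi):
            continue
        entries.append(
            FounderEntry(
                id=ind.id,
                origin=ind.origin,
                status="founder" if k == 2 else "half-founder",
                n_root_alleles=k,
                cohort_year=ind.birth_year,
            )
        )
    if not entries:
        logger.warning("founder roster is empty for window %s", cohort_window)
    return FounderRoster(entries)


def topological_order(ped: Pedigree) -> list[str]:
    """Ids ordered so every parent precedes its offspring; ties broken by id."""
    return list(nx.lexicographical_topological_sort(ped.graph, key=str))
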