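"""Individual-based simulator of an isolated, overlapping-generation songbird
population with stage-structured offspring mortality.

The generator emulates a small island passerine system: founders of mixed
origin (native / experimentally introduced), monogamous random annual
re-pairing, overdispersed clutch production, fixed egg->hatchling->fledgling
->recruit survival probabilities, geometric adult survival, density-
regulated fecundity fluctuating around a carrying capacity, a mid-study
bottleneck year, and half-founders arising as recruits with an unidentified
sire.

The pedigree records adults only (founders and recruits); eggs, hatchlings
and fledglings that never recruited exist solely as counts in the breeding
table, which is how field pedigrees of reproducing individuals are built.
The census counts adults alive each year; a recruit born in year t enters
the adult census in year t+1.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import (
    BreedingTable,
    CensusSeries,
    Individual,
    Pedigree,
    write_breeding,
    write_census,
    write_pedigree,
)


@dataclass
class SimConfig:
    """Study conditions for a synthetic population.

    Stage survival defaults reproduce the observed per-stage fractions
    (85% of eggs hatch, 881/1746 of hatchlings fledge, 294/881 of fledglings
    recruit, compounding to ~14% egg-to-recruit survival).  Adult survival
    2/3 gives a mean adult lifespan of 3 years under geometric survival, and
    the default egg rate of 8 per female-year yields lifetime egg production
    near 24 for founders breeding below carrying capacity.
    """

    n_founders: int = 90
    introduced_fraction: float = 0.2
    years: int = 20
    start_year: int = 2000
    egg_rate: float = 8.0          # mean eggs per paired female per year
    brood_rate: float = 2.0        # mean broods per breeding female per year
    egg_dispersion: float = 6.0    # negative-binomial shape (smaller = more overdispersed)
    p_hatch: float = 0.85
    p_fledge_given_hatch: float = 881 / 1746
    p_recruit_given_fledge: float = 294 / 881
    adult_annual_survival: float = 2 / 3
    carrying_capacity: int = 140
    density_steepness: float = 3.0
    bottleneck: tuple[int, float] | None = (2010, 0.4)
    immigration_rate: float = 2.0  # expected unknown-sire recruits per year
    seed: int = 20220422

    def __post_init__(self) -> None:
        probs = (self.p_hatch, self.p_fledge_given_hatch,
                 self.p_recruit_given_fledge, self.adult_annual_survival,
                 self.introduced_fraction)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.years < 3:
            raise ValueError("simulation needs at least 3 years")
        if self.n_founders < 4:
            raise ValueError("need at least 4 founders (both sexes)")

    @property
    def final_year(self) -> int:
        return self.start_year + self.years - 1

    @property
    def cohort_window(self) -> tuple[int, int]:
        """Birth-year window defining the founder cohort (founders enter the
        first census as age-1 adults, so they are born the year before)."""
        return (self.start_year - 1, self.start_year + 2)


@dataclass
class SimOutput:
    pedigree: Pedigree
    breeding: BreedingTable
    census: CensusSeries
    truth: dict
    config: SimConfig
    extinct: bool = False


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def _density_factor(n: int, cfg: SimConfig) -> float:
    """Logistic down-regulation of fecundity as N approaches carrying capacity."""
    x = cfg.density_steepness * (n - cfg.carrying_capacity) / cfg.carrying_capacity
    return 1.0 / (1.0 + math.exp(x))


def simulate_population(cfg: SimConfig) -> SimOutput:
    """Run the demographic simulation; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    inds: dict[str, dict] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    # founders: adults in the first census year, exactly half male
    n_intro = int(round(cfg.n_founders * cfg.introduced_fraction))
    origins = np.array(["introduced"] * n_intro
                       + ["native"] * (cfg.n_founders - n_intro))
    rng.shuffle(origins)
    sexes = np.array(["male", "female"] * (cfg.n_founders // 2)
                     + ["male"] * (cfg.n_founders % 2))
    rng.shuffle(sexes)
    adults: list[str] = []
    for k in range(cfg.n_founders):
        iid = new_id()
        inds[iid] = dict(id=iid, sire=None, dam=None, sex=sexes[k],
                         birth_year=cfg.start_year - 1, death_year=None,
                         origin=origins[k])
        adults.append(iid)

    breeding_rows: list[tuple] = []
    census: dict[int, int] = {}
    truth_eggs = truth_hatch = truth_fledge = truth_recruit = 0
    extinct = False

    for year in range(cfg.start_year, cfg.final_year + 1):
        if len(adults) == 0:
            # census series carries only years with living adults
            extinct = True
            break
        census[year] = len(adults)

        # monogamous random annual re-pairing
        males = [i for i in adults if inds[i]["sex"] == "male"]
        females = [i for i in adults if inds[i]["sex"] == "female"]
        rng.shuffle(males)
        rng.shuffle(females)
        f = _density_factor(len(adults), cfg)
        recruits_this_year: list[str] = []
        for sire, dam in zip(males, females):
            mean_eggs = cfg.egg_rate * f
            k = cfg.egg_dispersion
            eggs = int(rng.negative_binomial(k, k / (k + mean_eggs)))
            broods = int(1 + rng.poisson(max(cfg.brood_rate - 1, 0))) if eggs else 0
            hatch = int(rng.binomial(eggs, cfg.p_hatch))
            fledge = int(rng.binomial(hatch, cfg.p_fledge_given_hatch))
            recruit = int(rng.binomial(fledge, cfg.p_recruit_given_fledge))
            truth_eggs += eggs
            truth_hatch += hatch
            truth_fledge += fledge
            truth_recruit += recruit
            breeding_rows.append((sire, year, eggs, hatch, fledge, recruit, broods))
            breeding_rows.append((dam, year, eggs, hatch, fledge, recruit, broods))
            for _ in range(recruit):
                iid = new_id()
                inds[iid] = dict(
                    id=iid, sire=sire, dam=dam,
                    sex="male" if rng.random() < 0.5 else "female",
                    birth_year=year, death_year=None,
                    origin=inds[dam]["origin"],
                )
                recruits_this_year.append(iid)

        # half-founders: recruits of a local dam and an unidentified sire
        if cfg.immigration_rate > 0 and females:
            for _ in range(rng.poisson(cfg.immigration_rate)):
                dam = females[rng.integers(len(females))]
                iid = new_id()
                inds[iid] = dict(
                    id=iid, sire=None, dam=dam,
                    sex="male" if rng.random() < 0.5 else "female",
                    birth_year=year, death_year=None,
                    origin=inds[dam]["origin"],
                )
                breeding_rows.append((dam, year, 1, 1, 1, 1, 1))
                truth_eggs += 1
                truth_hatch += 1
                truth_fledge += 1
                truth_recruit += 1
                recruits_this_year.append(iid)

        # adult survival to next April; bottleneck multiplies survival one year
        s = cfg.adult_annual_survival
        if cfg.bottleneck is not None and year == cfg.bottleneck[0]:
            s *= cfg.bottleneck[1]
        survivors = []
        for iid in adults:
            if year < cfg.final_year and rng.random() < s:
                survivors.append(iid)
            elif year >= cfg.final_year:
                inds[iid]["death_year"] = cfg.final_year
            else:
                inds[iid]["death_year"] = year
        if year >= cfg.final_year:
            for iid in recruits_this_year:
                inds[iid]["death_year"] = year
            break
        adults = survivors + recruits_this_year

    for iid in inds:
        if inds[iid]["death_year"] is None:
            inds[iid]["death_year"] = cfg.final_year

    ped = Pedigree(Individual(**rec) for rec in inds.values())
    breeding = BreedingTable(pd.DataFrame(
        breeding_rows,
        columns=["parent_id", "year", "eggs", "hatchlings", "fledglings",
                 "recruits", "broods"],
    ))
    census_series = CensusSeries(census)

    # realised generation time: mean parent age over parent->offspring links
    parent_ages = []
    for ind in ped.individuals.values():
        for pid in (ind.sire, ind.dam):
            if pid is not None:
                parent_ages.append(ind.birth_year - ped[pid].birth_year)
    dead = [i for i in ped.individuals.values() if i.death_year < cfg.final_year]
    truth = {
        "realised_p_hatch": truth_hatch / truth_eggs if truth_eggs else float("nan"),
        "realised_p_fledge_given_hatch": (
            truth_fledge / truth_hatch if truth_hatch else float("nan")),
        "realised_p_recruit_given_fledge": (
            truth_recruit / truth_fledge if truth_fledge else float("nan")),
        "realised_egg_to_recruit": (
            truth_recruit / truth_eggs if truth_eggs else float("nan")),
        "total_eggs": truth_eggs,
        "total_hatchlings": truth_hatch,
        "total_fledglings": truth_fledge,
        "total_recruits": truth_recruit,
        "generation_time": (
            float(np.mean(parent_ages)) if parent_ages else float("nan")),
        "mean_adult_lifespan": (
            float(np.mean([i.death_year - i.birth_year for i in dead]))
            if dead else float("nan")),
        "census": {int(y): int(n) for y, n in census.items()},
        "n_individuals": len(ped),
        "extinct": extinct,
    }
    return SimOutput(pedigree=ped, breeding=breeding, census=census_series,
                     truth=truth, config=cfg, extinct=extinct)


def truth_report(out: SimOutput) -> dict:
    """Realised demographic summary of a completed simulation."""
    return dict(out.truth)


def write_sim(out: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write pedigree.csv, breeding.csv, census.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": directory / "pedigree.csv",
        "breeding": directory / "breeding.csv",
        "census": directory / "census.csv",
        "truth": directory / "truth.json",
    }
    write_pedigree(out.pedigree, paths["pedigree"])
    write_breeding(out.breeding, paths["breeding"])
    write_census(out.census, paths["census"])
    truth = dict(out.truth)
    truth["config"] = asdict(out.config)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
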