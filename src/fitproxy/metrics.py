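"""Short-term fitness proxies: stage-specific LRS, IGR and de-lifed fitness.

LRS at stage s is the lifetime sum of offspring counted at that
developmental stage (eggs, hatchlings, fledglings, recruits) or of broods.

IGR is the dominant eigenvalue of an individual population transition
matrix: the sub-diagonal holds 1s (the individual survived those years) and
the first row holds per-age offspring counts divided by two, because a
parent contributes half of each offspring's alleles.

De-lifed fitness is the individual's annual contribution to realised
population growth:

    p_ti = (xi_t(i) - w_t) / (N_t - 1)

where xi_t(i) counts the individual's offspring surviving to the end of the
time step (weighted by ``offspring_weight``) plus 1 if the individual itself
survived, w_t = N_{t+1}/N_t is the realised annual growth ratio and N_t the
adult census.  Lifetime de-lifed fitness sums the annual values over the
individual's adult years.
"""

from __future__ import annotations

import logging

import numpy as np

from .pedigree import STAGE_COLUMNS, BreedingTable, CensusSeries, Pedigree

logger = logging.getLogger(__name__)

OFFSPRING_STAGES = ("eggs", "hatchlings", "fledglings", "recruits")


def lrs(breeding: BreedingTable, individual: str, stage: str) -> int:
    """Lifetime production at ``stage`` (a stage column or 'broods')."""
    if stage not in STAGE_COLUMNS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGE_COLUMNS}")
    records = breeding.records_for(individual)
    if records.empty:
        logger.info("no breeding records for %r; LRS = 0", individual)
        return 0
    return int(records[stage].sum())


def build_transition_matrix(
    breeding: BreedingTable, ped: Pedigree, individual: str, stage: str
) -> np.ndarray:
    """Individual transition matrix over breeding ages 1..L.

    L = death_year - birth_year (years lived past the year of birth); ages
    with no breeding record contribute 0 to the fecundity row.
    """
    if stage not in OFFSPRING_STAGES:
        raise ValueError(f"unknown offspring stage {stage!r}")
    ind = ped[individual]
    lifespan = ind.death_year - ind.birth_year
    if lifespan < 1:
        raise ValueError(
            f"{individual!r} has zero breeding lifespan (died as juvenile)"
        )
    m = np.zeros((lifespan, lifespan))
    if lifespan > 1:
        m[np.arange(1, lifespan), np.arange(lifespan - 1)] = 1.0
    for rec in breeding.records_for(individual).itertuples(index=False):
        age = rec.year - ind.birth_year
        if not 1 <= age <= lifespan:
            raise ValueError(
                f"breeding record for {individual!r} in year {rec.year} outside "
                f"ages 1..{lifespan}"
            )
        m[0, age - 1] += getattr(rec, stage) / 2.0
    return m


def igr(matrix: np.ndarray) -> float:
    """Dominant eigenvalue of a transition matrix.

    By Perron-Frobenius the spectral radius of this nonnegative matrix is
    itself an eigenvalue, real and nonnegative; no diagonalisability is
    assumed.  A zero fecundity row gives a nilpotent matrix and IGR 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1] or matrix.size == 0:
        raise ValueError("transition matrix must be square and non-empty")
    if (matrix < 0).any():
        raise ValueError("transition matrix must be nonnegative")
    eigvals = np.linalg.eigvals(matrix)
    real = eigvals.real[np.abs(eigvals.imag) <= 1e-9]
    dominant = float(real.max()) if real.size else 0.0
    return max(dominant, 0.0)


def _surviving_offspring(ped: Pedigree, individual: str, year: int) -> int:
    """Offspring born in ``year`` that are alive as adults in ``year + 1``."""
    n = 0
    for child_id in ped.children_of(individual):
        child = ped[child_id]
        if child.birth_year == year and child.death_year >= year + 1:
            n += 1
    return n


def delifed_annual(
    breeding: BreedingTable,
    census: CensusSeries,
    ped: Pedigree,
    individual: str,
    year: int,
    offspring_weight: float = 1.0,
) -> float:
    """Annual de-lifed fitness p_ti = (xi_t(i) - w_t) / (N_t - 1).

    With ``offspring_weight = 0.5`` (each offspring split between its two
    parents) the values sum to zero over all adults each year, provided every
    new adult has both parents in the census.  The default weight 1 counts
    each surviving offspring fully for each parent.
    """
    n_t = census[year]
    if n_t < 2:
        raise ValueError(f"de-lifing undefined for N_t < 2 (year {year})")
    w_t = census.growth_ratio(year)  # raises if year+1 missing
    ind = ped[individual]
    if not (ind.birth_year < year <= ind.death_year):
        raise ValueError(f"{individual!r} is not an adult in year {year}")
    xi = offspring_weight * _surviving_offspring(ped, individual, year)
    xi += 1.0 if ind.death_year >= year + 1 else 0.0
    return (xi - w_t) / (n_t - 1)


def adult_years(ped: Pedigree, census: CensusSeries, individual: str) -> list[int]:
    """Adult years of ``individual`` for which an annual value is computable
    (both t and t+1 must be censused)."""
    ind = ped[individual]
    last = min(ind.death_year, census.final_year - 1)
    first = max(ind.birth_year + 1, census.years[0])
    return list(range(first, last + 1))


def delifed_lifetime(
    breeding: BreedingTable,
    census: CensusSeries,
    ped: Pedigree,
    individual: str,
    offspring_weight: float = 1.0,
) -> float:
    """Lifetime de-lifed fitness: sum of annual values over adult years."""
    return sum(
        delifed_annual(breeding, census, ped, individual, y, offspring_weight)
        for y in adult_years(ped, census, individual)
    )


def annual_delifed_by_age(
    breeding: BreedingTable,
    census: CensusSeries,
    ped: Pedigree,
    individual: str,
    offspring_weight: float = 1.0,
) -> dict[int, float]:
    """Annual de-lifed fitness keyed by age (year - birth_year), one entry per
    adult age attained."""
    ind = ped[individual]
    return {
        y - ind.birth_year: delifed_annual(
            breeding, census, ped, individual, y, offspring_weight
        )
        for y in adult_years(ped, census, individual)
    }
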