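"""Monte-Carlo gene dropping through a pedigree.

Each founder carries two unique root alleles and each half-founder carries
one unique root allele plus one allele inherited from its known parent.
Every fully-parented individual receives one allele drawn uniformly at
random from each parent's two alleles, processed in topological order, so
every allele in the population traces back to exactly one lineage root.

The *reproductive value* of a root in year Y is the mean, over replicates,
of the number of root-derived allele copies carried by individuals alive in
year Y (absolute counts, not normalised by population size).  The *allele
survival probability* is the fraction of replicates in which at least one
root allele persists to the final year.

Individuals with an unknown parent born outside the cohort window still
root novel alleles; they are tracked under "noncohort" roots so that allele
copies are conserved: in every replicate and year the copy counts over all
roots sum to twice the number of individuals alive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import FounderRoster, Pedigree, topological_order


@dataclass
class GeneDropResult:
    """Per-replicate, per-root, per-year allele copy counts.

    ``counts[rep, root_index, year_index]`` is the number of allele copies
    descending from that root carried by individuals alive in that year.
    """

    roots: list[str]
    root_status: dict[str, str]  # "founder" | "half-founder" | "noncohort"
    years: np.ndarray
    counts: np.ndarray  # (n_reps, n_roots, n_years), unsigned int
    n_reps: int
    final_year: int
    seed: int
    alive_counts: np.ndarray = field(default=None)  # per-year alive individuals

    def __post_init__(self) -> None:
        self._root_index = {r: k for k, r in enumerate(self.roots)}
        self._year_index = {int(y): k for k, y in enumerate(self.years)}

    @property
    def cohort_roots(self) -> list[str]:
        return [r for r in self.roots if self.root_status[r] != "noncohort"]

    def _ri(self, root: str) -> int:
        try:
            return self._root_index[root]
        except KeyError:
            raise KeyError(f"unknown lineage root: {root!r}") from None

    def _yi(self, year: int) -> int:
        try:
            return self._year_index[int(year)]
        except KeyError:
            raise KeyError(f"year {year} outside simulated range") from None

    def reproductive_value(self, root: str, year: int) -> float:
        """Mean root-allele copy count among individuals alive in ``year``."""
        return float(self.counts[:, self._ri(root), self._yi(year)].mean())

    def allele_survival_probability(self, root: str) -> float:
        """Fraction of replicates with >= 1 root allele copy in the final year."""
        final = self.counts[:, self._ri(root), self._yi(self.final_year)]
        return float((final > 0).mean())

    def rv_table(self, roots: list[str] | None = None) -> pd.DataFrame:
        """Mean copy counts (roots x years); defaults to cohort roots only."""
        roots = self.cohort_roots if roots is None else roots
        idx = [self._ri(r) for r in roots]
        means = self.counts[:, idx, :].mean(axis=0)
        return pd.DataFrame(means, index=pd.Index(roots, name="root"),
                            columns=[int(y) for y in self.years])


def run_gene_drop(
    ped: Pedigree,
    roster: FounderRoster,
    n_reps: int,
    seed: int,
    final_year: int | None = None,
) -> GeneDropResult:
    """Drop alleles through ``ped`` ``n_reps`` times; deterministic in ``seed``.

    Mendelian transmission is simulated for all replicates at once: for each
    individual in topological order, one allele is drawn uniformly from each
    known parent's pair, independently per offspring and replicate (no
    linkage, no mutation).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    order = topological_order(ped)
    y0, y1 = ped.year_range if ped.individuals else (0, 0)
    if final_year is None:
        final_year = y1
    years = np.arange(y0, final_year + 1)

    # roots: every individual with >= 1 unknown parent owns one; status from roster
    roots: list[str] = []
    root_status: dict[str, str] = {}
    for ind_id in order:
        if ped[ind_id].n_unknown_parents > 0:
            roots.append(ind_id)
            root_status[ind_id] = roster[ind_id].status if ind_id in roster else "noncohort"
    root_index = {r: k for k, r in enumerate(roots)}

    rng = np.random.default_rng(seed)
    n_ind = len(order)
    row = {ind_id: k for k, ind_id in enumerate(order)}
    # allele root indices, paternal (slot 0, from sire) and maternal (slot 1)
    a0 = np.empty((n_ind, n_reps), dtype=np.int32)
    a1 = np.empty((n_ind, n_reps), dtype=np.int32)
    for ind_id in order:
        ind = ped[ind_id]
        r = row[ind_id]
        for slot, parent in ((0, ind.sire), (1, ind.dam)):
            target = a0 if slot == 0 else a1
            if parent is None:
                target[r, :] = root_index[ind_id]
            else:
                p = row[parent]
                pick = rng.integers(0, 2, size=n_reps)
                target[r, :] = np.where(pick == 0, a0[p], a1[p])

    births = np.array([ped[i].birth_year for i in order])
    deaths = np.array([ped[i].death_year for i in order])
    n_roots = len(roots)
    counts = np.zeros((n_reps, n_roots, len(years)), dtype=np.uint32)
    alive_counts = np.zeros(len(years), dtype=np.int64)
    rep_offsets = np.arange(n_reps, dtype=np.int64) * n_roots
    for yi, year in enumerate(years):
        alive = np.flatnonzero((births <= year) & (year <= deaths))
        alive_counts[yi] = alive.size
        if alive.size == 0:
            continue
        arr = np.concatenate([a0[alive], a1[alive]], axis=0).astype(np.int64)
        flat = (arr + rep_offsets[None, :]).ravel()
        bc = np.bincount(flat, minlength=n_reps * n_roots)
        counts[:, :, yi] = bc.reshape(n_reps, n_roots)

    return GeneDropResult(
        roots=roots,
        root_status=root_status,
        years=years,
        counts=counts,
        n_reps=n_reps,
        final_year=int(final_year),
        seed=seed,
        alive_counts=alive_counts,
    )


def reproductive_value(res: GeneDropResult, root: str, year: int) -> float:
    return res.reproductive_value(root, year)


def allele_survival_probability(res: GeneDropResult, root: str) -> float:
    return res.allele_survival_probability(root)


def lineage_longevity(ped: Pedigree, root: str, final_year: int) -> int:
    """Years from the root's birth to the last year a genealogical descendant
    (or the root itself) is alive, capped at ``final_year``."""
    if root not in ped:
        raise KeyError(f"unknown individual: {root!r}")
    members = {root} | ped.descendants_of(root)
    last_alive = max(ped[m].death_year for m in members)
    return min(last_alive, final_year) - ped[root].birth_year


def lineage_survives(ped: Pedigree, root: str, final_year: int) -> bool:
    """True iff the root or any genealogical descendant is alive in final_year."""
    members = {root} | ped.descendants_of(root)
    return any(
        ped[m].birth_year <= final_year <= ped[m].death_year for m in members
    )


def stabilisation_time(G: float, N: float) -> float:
    """Predicted years for reproductive values to stabilise: G * log2(N).

    ``G`` is the generation time in years; ``N`` the population size.
    """
    if G <= 0:
        raise ValueError("generation time G must be positive")
    if N <= 1:
        raise ValueError("population size N must exceed 1")
    return float(G * np.log2(N))


def stabilisation_curve(
    res: GeneDropResult, final_year: int | None = None
) -> pd.DataFrame:
    """Pearson correlation, per year, between cohort-root reproductive values
    in that year and in the final year.

    Years where either vector has zero variance yield a missing correlation.
    The final-year entry is exactly 1 whenever defined.
    """
    final_year = res.final_year if final_year is None else int(final_year)
    rv = res.rv_table()  # cohort roots x years
    ref = rv[final_year].to_numpy(dtype=float)
    out = []
    for year in rv.columns:
        cur = rv[year].to_numpy(dtype=float)
        if cur.std() == 0 or ref.std() == 0 or len(cur) < 2:
            r = np.nan
        else:
            r = float(np.corrcoef(cur, ref)[0, 1])
        out.append((int(year), r))
    return pd.DataFrame(out, columns=["year", "correlation"])
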