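"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: the gene-drop
oracle enumerates every Mendelian transmission outcome exhaustively, the
eigenvalue oracles use bracketed root-finding on the characteristic
polynomial and power iteration, and the Fisher oracle sums hypergeometric
terms directly.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def enumerate_gene_drop(individuals, years, final_year):
    """Exact gene-drop distribution by enumerating all transmission outcomes.

    ``individuals``: iterable of (id, sire, dam, birth, death) with parents
    ``None`` when unknown.  Returns (mean, var, surv): mean[root][year] and
    var[root][year] of copy counts, and surv[root], the probability that a
    root allele persists to ``final_year``.
    """
    inds = {i[0]: i for i in individuals}
    # topological order: repeatedly emit individuals whose parents are placed
    placed, order = set(), []
    pending = sorted(inds)
    while pending:
        progress = False
        for iid in list(pending):
            _, sire, dam, _, _ = inds[iid]
            if (sire is None or sire in placed) and (dam is None or dam in placed):
                order.append(iid)
                placed.add(iid)
                pending.remove(iid)
                progress = True
        assert progress, "cycle in oracle pedigree"

    roots = [iid for iid in order
             if inds[iid][1] is None or inds[iid][2] is None]
    # one binary choice per (individual, known-parent slot)
    slots = []
    for iid in order:
        _, sire, dam, _, _ = inds[iid]
        for parent in (sire, dam):
            if parent is not None:
                slots.append((iid, parent))

    acc = {r: {y: [] for y in years} for r in roots}
    surv_hits = {r: 0 for r in roots}
    n_outcomes = 0
    for choice in itertools.product((0, 1), repeat=len(slots)):
        n_outcomes += 1
        alleles = {}
        ci = 0
        for iid in order:
            _, sire, dam, _, _ = inds[iid]
            pair = []
            for parent in (sire, dam):
                if parent is None:
                    pair.append(iid)  # own root allele
                else:
                    pair.append(alleles[parent][choice[ci]])
                    ci += 1
            alleles[iid] = tuple(pair)
        for y in years:
            alive = [iid for iid in order
                     if inds[iid][3] <= y <= inds[iid][4]]
            counts = {r: 0 for r in roots}
            for iid in alive:
                for a in alleles[iid]:
                    counts[a] += 1
            for r in roots:
                acc[r][y].append(counts[r])
        final_alive = [iid for iid in order
                       if inds[iid][3] <= final_year <= inds[iid][4]]
        for r in roots:
            if any(a == r for iid in final_alive for a in alleles[iid]):
                surv_hits[r] += 1

    mean = {r: {y: float(np.mean(acc[r][y])) for y in years} for r in roots}
    var = {r: {y: float(np.var(acc[r][y])) for y in years} for r in roots}
    surv = {r: surv_hits[r] / n_outcomes for r in roots}
    return mean, var, surv


def power_iteration_dominant(matrix, iters=20_000, tol=1e-13):
    """Dominant eigenvalue of a nonnegative matrix by power iteration."""
    m = np.asarray(matrix, dtype=float)
    x = np.ones(m.shape[0])
    lam = 0.0
    for _ in range(iters):
        y = m @ x
        norm = np.linalg.norm(y)
        if norm < 1e-300:
            return 0.0
        y /= norm
        new_lam = float(y @ (m @ y))
        if abs(new_lam - lam) < tol:
            return new_lam
        lam, x = new_lam, y
    return lam


def cubic_dominant_root(b, c, d, lo=0.0, hi=100.0):
    """Largest real root of x^3 + b x^2 + c x + d on [lo, hi] by bisection."""
    def f(x):
        return ((x + b) * x + c) * x + d

    assert f(hi) > 0
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def fisher_two_sided(table):
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)
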