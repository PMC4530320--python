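"""Independent oracles for the test suite.

These deliberately avoid the package's quadrature path.  The marginal
likelihood of a contingency dataset under a graph (uniform prior, noisy-OR)
is a polynomial in the failure probabilities (1 - w_i): each cell contributes
(1 - U)^k U^m with U a monomial, so binomial expansion turns the whole
integrand into a finite sum of separable monomials.  Exact rational moments of
either the continuous unit interval (1/(A+1)) or a finite trapezoid grid then
give the integral, or the trapezoid sum on an arbitrarily fine grid, without
any floating-point cancellation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
from scipy.special import betaln, digamma


def _cell_expansions(dataset, graph):
    """Per cell: monomial exponent pattern over (u, v, t) and binomial expansion terms."""
    per_cell = []
    for cell in dataset:
        pattern = (
            1,
            1 if (graph.target_link and cell.config.target_present) else 0,
            1 if (graph.alternative_link and cell.config.alternative_present) else 0,
        )
        k, m = cell.n_effect, cell.n_no_effect
        options = [(comb(k, j) * (-1) ** j, m + j) for j in range(k + 1)]
        per_cell.append((pattern, options))
    return per_cell


def _terms(dataset, graph):
    """Collapse the product of cell expansions into {exponent-triple: integer coeff}."""
    per_cell = _cell_expansions(dataset, graph)
    terms: dict[tuple[int, int, int], int] = {}
    for combo in product(*[options for _, options in per_cell]):
        coeff = 1
        exps = [0, 0, 0]
        for (pattern, _), (c, power) in zip(per_cell, combo):
            coeff *= c
            for i in range(3):
                exps[i] += pattern[i] * power
        key = tuple(exps)
        terms[key] = terms.get(key, 0) + coeff
    return terms


def _continuous_moment(a: int) -> Fraction:
    """∫_0^1 u^a du."""
    return Fraction(1, a + 1)


def _trapezoid_moment_table(max_a: int, n_points: int) -> list[Fraction]:
    """Exact trapezoid-rule sums Σ_i W_i (i/N)^a on the uniform grid, a = 0..max_a."""
    N = n_points - 1
    table = []
    for a in range(max_a + 1):
        inner = sum(j**a for j in range(1, N))
        num = 2 * inner + N**a + (1 if a == 0 else 0)
        table.append(Fraction(num, 2 * N ** (a + 1)))
    return table


def exact_marginal(dataset, graph) -> float:
    """Exact marginal likelihood (uniform prior, noisy-OR) by rational integration."""
    total = Fraction(0)
    for (a, b, c), coeff in _terms(dataset, graph).items():
        total += coeff * _continuous_moment(a) * _continuous_moment(b) * _continuous_moment(c)
    return float(total)


def trapezoid_grid_marginal(dataset, graph, n_points: int = 1001) -> float:
    """The trapezoid-rule quadrature sum on an n_points-per-dimension grid, exactly.

    This is the value a dense brute-force trapezoid evaluation of the mesh
    would produce, computed by exact rational arithmetic instead of iterating
    the full mesh (identical sum, no discretisation shortcut).
    """
    terms = _terms(dataset, graph)
    max_a = max(max(e) for e in terms) if terms else 0
    table = _trapezoid_moment_table(max_a, n_points)
    total = Fraction(0)
    for (a, b, c), coeff in terms.items():
        total += coeff * table[a] * table[b] * table[c]
    return float(total)


def exact_posterior_mean(dataset, graph) -> float:
    """Exact posterior mean of the target strength w_C under one target-link graph."""
    if not graph.target_link:
        raise ValueError("posterior mean of w_C needs a target-link graph")
    num = Fraction(0)
    den = Fraction(0)
    for (a, b, c), coeff in _terms(dataset, graph).items():
        base = _continuous_moment(a) * _continuous_moment(c)
        den += coeff * base * _continuous_moment(b)
        # extra factor w_C = 1 - v in the numerator
        num += coeff * base * (_continuous_moment(b) - _continuous_moment(b + 1))
    return float(num / den)


def brute_force_grid_marginal(dataset, graph, n_points: int) -> float:
    """Dense float trapezoid evaluation of the mesh (cross-checks the rational path)."""
    grid = np.linspace(0.0, 1.0, n_points)
    w = np.full(n_points, 1.0 / (n_points - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    dims = graph.free_dims
    ndim = len(dims)
    axes = np.meshgrid(*([grid] * ndim), indexing="ij", sparse=True)
    lik = np.ones((1,) * ndim)
    for cell in dataset:
        q = 1.0 - axes[0]
        if "C" in dims and cell.config.target_present:
            q = q * (1.0 - axes[dims.index("C")])
        if "A" in dims and cell.config.alternative_present:
            q = q * (1.0 - axes[dims.index("A")])
        p = 1.0 - q
        lik = lik * p**cell.n_effect * q**cell.n_no_effect
    weight = np.ones((1,) * ndim)
    for i in range(ndim):
        shape = [1] * ndim
        shape[i] = -1
        weight = weight * w.reshape(shape)
    return float(np.sum(lik * weight))


def brute_force_posterior_density(dataset, graph, n_points: int = 1001) -> tuple[np.ndarray, np.ndarray]:
    """Dense float posterior density of w_C under one target-link graph (trapezoid-normalised)."""
    if not graph.target_link:
        raise ValueError("needs a target-link graph")
    grid = np.linspace(0.0, 1.0, n_points)
    w = np.full(n_points, 1.0 / (n_points - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    dims = graph.free_dims
    ndim = len(dims)
    c_axis = dims.index("C")
    axes = np.meshgrid(*([grid] * ndim), indexing="ij", sparse=True)
    lik = np.ones((1,) * ndim)
    for cell in dataset:
        q = 1.0 - axes[0]
        if cell.config.target_present:
            q = q * (1.0 - axes[c_axis])
        if "A" in dims and cell.config.alternative_present:
            q = q * (1.0 - axes[dims.index("A")])
        p = 1.0 - q
        lik = lik * p**cell.n_effect * q**cell.n_no_effect
    lik = np.broadcast_to(lik, (n_points,) * ndim).copy()
    for i in range(ndim):
        if i == c_axis:
            continue
        shape = [1] * ndim
        shape[i] = -1
        lik = lik * w.reshape(shape)
    reduce_axes = tuple(i for i in range(ndim) if i != c_axis)
    density = lik.sum(axis=reduce_axes)
    return grid, density / np.trapezoid(density, grid)


def mc_marginal(dataset, graph, n_draws: int = 10**6, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo marginal likelihood (uniform prior): estimate and standard error."""
    rng = np.random.default_rng(seed)
    wB = rng.uniform(size=n_draws)
    wC = rng.uniform(size=n_draws) if graph.target_link else np.zeros(n_draws)
    wA = rng.uniform(size=n_draws) if graph.alternative_link else np.zeros(n_draws)
    lik = np.ones(n_draws)
    for cell in dataset:
        c = cell.config.target_present
        a = cell.config.alternative_present
        p = 1.0 - (1.0 - wB) * (1.0 - wC * c) * (1.0 - wA * a)
        lik *= p**cell.n_effect * (1.0 - p) ** cell.n_no_effect
    return float(lik.mean()), float(lik.std(ddof=1) / np.sqrt(n_draws))


def beta_differential_entropy(a: float, b: float) -> float:
    """Closed-form differential entropy (nats) of a Beta(a, b) density."""
    return float(
        betaln(a, b) - (a - 1) * digamma(a) - (b - 1) * digamma(b) + (a + b - 2) * digamma(a + b)
    )
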