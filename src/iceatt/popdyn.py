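"""Competition between cells carrying an ICE at its primary versus a
secondary attachment site.

Cells with the element stuck in a secondary site pay a per-generation cost:
a fraction D of them dies each generation (spontaneous activation of element
gene expression followed by lethal rolling-circle replication of an element
that cannot excise). Cells with the element at the primary site excise
cleanly and pay no cost. With discrete doubling generations,

    P(G) = P0 * 2^G * (1 - D)^G

for the secondary-site population, so the ratio of primary- to
secondary-site population sizes after G generations is

    R(G) = (P0 * 2^G) / (P0 * 2^G * (1 - D)^G) = 1 / (1 - D)^G,

and the generations needed to reach a given ratio are

    G(R) = log(1/R) / log(1 - D).

With an activation frequency of ~1e-4 per generation and all activated
secondary-site cells dying (D = 1e-4), R = 10 takes ~23,000 generations; at
D = 1e-3 it takes ~2,300. The death fraction can optionally be decomposed
as D = a * (1 - v): activation frequency a times the fraction (1 - v) of
activated cells that die, so partial viability v upon activation softens
the cost (v = 0 recovers the all-die model).

A stochastic simulator provides the finite-population counterpart: both
subpopulations double each generation, each secondary-site cell dies
independently with probability D, and a neutral multinomial bottleneck caps
the total population at desk scale. Its expectation matches the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CompetitionParams",
    "SimulationResult",
    "population_size",
    "ratio",
    "generations_to_ratio",
    "effective_death",
    "simulate_competition",
    "round_sig",
]


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (headline reporting style,
    e.g. 23025 -> 23000)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1))


def _check_death(D: float) -> None:
    if not 0.0 <= D < 1.0:
        raise ValueError(f"death fraction D must satisfy 0 <= D < 1, got {D}")


@dataclass(frozen=True)
class CompetitionParams:
    """Parameters of the primary-vs-secondary-site competition model.

    Attributes
    ----------
    P0 : float
        Initial size of each subpopulation (cells).
    D : float
        Per-generation dead fraction among secondary-site cells, in [0, 1).
        Either given directly or derived as a * (1 - v).
    a, v : float, optional
        Decomposition of D into activation frequency per generation and
        viability upon activation. When both are given, D must equal
        a * (1 - v).
    """

    P0: float = 1.0
    D: float = 1e-4
    a: float | None = None
    v: float | None = None

    def __post_init__(self) -> None:
        if not self.P0 > 0:
            raise ValueError("P0 must be positive")
        _check_death(self.D)
        if (self.a is None) != (self.v is None):
            raise ValueError("a and v must be given together or not at all")
        if self.a is not None:
            expected = effective_death(self.a, self.v)
            if not math.isclose(self.D, expected, rel_tol=1e-9, abs_tol=1e-15):
                raise ValueError(
                    f"inconsistent decomposition: D={self.D} but a*(1-v)={expected}"
                )

    @classmethod
    def from_activation(
        cls, a: float, v: float = 0.0, *, P0: float = 1.0
    ) -> "CompetitionParams":
        """Build params from activation frequency and viability (v = 0 is the
        all-activated-cells-die model)."""
        return cls(P0=P0, D=effective_death(a, v), a=a, v=v)


def population_size(P0: float, G: float, D: float) -> float:
    """Size of a population after G doubling generations with per-generation
    dead fraction D: P = P0 * 2^G * (1 - D)^G."""
    if not P0 > 0:
        raise ValueError("P0 must be positive")
    if G < 0:
        raise ValueError("G must be non-negative")
    _check_death(D)
    return P0 * 2.0**G * (1.0 - D) ** G


def ratio(G: float, D: float) -> float:
    """Ratio R of primary- to secondary-site population size after G
    generations: R = 1 / (1 - D)^G. Independent of P0 (the doubling terms
    cancel)."""
    if G < 0:
        raise ValueError("G must be non-negative")
    _check_death(D)
    return (1.0 - D) ** (-G)


def generations_to_ratio(R: float, D: float) -> float:
    """Generations needed for the primary-site population to outnumber the
    secondary-site population R-fold: G = log(1/R) / log(1 - D).

    Base-independent. Use :func:`round_sig` for two-significant-figure
    headline reporting (e.g. ~23,000 at R = 10, D = 1e-4).

    Raises
    ------
    ValueError
        If R < 1, or if D = 0 with R > 1 (no finite solution: a costless
        secondary site is never outcompeted).
    """
    if R < 1:
        raise ValueError("R must be >= 1 under the model")
    _check_death(D)
    if R == 1:
        return 0.0
    if D == 0:
        raise ValueError("D = 0 with R > 1 has no finite solution")
    return math.log(1.0 / R) / math.log(1.0 - D)


def effective_death(a: float, v: float) -> float:
    """Effective per-generation death fraction D = a * (1 - v) from an
    activation frequency a and viability v upon activation."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation frequency a must be in [0, 1]")
    if not 0.0 <= v <= 1.0:
        raise ValueError("viability v must be in [0, 1]")
    return a * (1.0 - v)


@dataclass(frozen=True)
class SimulationResult:
    """Stochastic competition trajectories and their ratio summary.

    Attributes
    ----------
    counts : (n_replicates, generations + 1, 2) int array
        Per-generation subpopulation sizes; column 0 is the primary-site
        population, column 1 the secondary-site population. Generation 0 is
        the initial state.
    ratio_mean, ratio_se : (generations + 1,) arrays
        Mean and standard error over replicates of the estimated ratio
        R-hat = primary / secondary at each generation.
    seed : int
        The base seed; replicate r draws from seed + r.
    """

    counts: np.ndarray
    ratio_mean: np.ndarray
    ratio_se: np.ndarray
    seed: int

    @property
    def final_ratio_mean(self) -> float:
        return float(self.ratio_mean[-1])

    @property
    def final_ratio_se(self) -> float:
        return float(self.ratio_se[-1])


def simulate_competition(
    params: CompetitionParams,
    generations: int,
    n_replicates: int = 50,
    population_cap: int = 1_000_000,
    seed: int = 0,
) -> SimulationResult:
    """Stochastic counterpart of the closed-form competition model.

    Each generation, both subpopulations double; each secondary-site cell
    then dies independently with probability D (a binomial draw). When the
    total exceeds ``population_cap`` the population is down-sampled to the
    cap by a neutral multinomial bottleneck — pure bookkeeping to keep the
    exponentially growing populations at desk scale, adding drift but no
    bias in expectation. Identical seeds give identical output; replicate r
    uses seed + r.

    Raises
    ------
    ValueError
        If the cap cannot hold both initial subpopulations or is under 1e3
        (resampling noise would swamp the signal).
    """
    if population_cap < 1_000:
        raise ValueError("population_cap must be >= 1000 to control drift")
    n0 = int(params.P0)
    if 2 * n0 > population_cap:
        raise ValueError(
            f"population_cap {population_cap} cannot hold both initial "
            f"subpopulations of {n0} cells"
        )
    if generations < 0:
        raise ValueError("generations must be non-negative")
    D = params.D
    counts = np.zeros((n_replicates, generations + 1, 2), dtype=np.int64)
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        primary, secondary = n0, n0
        counts[r, 0] = (primary, secondary)
        for g in range(1, generations + 1):
            primary *= 2
            secondary *= 2
            if D > 0 and secondary > 0:
                secondary -= int(rng.binomial(secondary, D))
            total = primary + secondary
            if total > population_cap:
                # neutral bottleneck: hypergeometric-free multinomial thinning
                primary = int(
                    rng.binomial(population_cap, primary / total)
                )
                secondary = population_cap - primary
            counts[r, g] = (primary, secondary)
    with np.errstate(divide="ignore"):
        rhat = counts[:, :, 0] / np.maximum(counts[:, :, 1], 1)
        rhat[counts[:, :, 1] == 0] = np.inf
    mean = rhat.mean(axis=0)
    se = rhat.std(axis=0, ddof=1) / math.sqrt(n_replicates) if n_replicates > 1 else np.zeros_like(mean)
    return SimulationResult(counts=counts, ratio_mean=mean, ratio_se=se, seed=seed)
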