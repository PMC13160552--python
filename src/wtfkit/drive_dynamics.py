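"""Population dynamics of poison-antidote spore killers.

Haploid-dominant life cycle with obligate outcross mating: each generation,
haploids pair at random, each pair undergoes meiosis producing a tetrad of
four spores, every spore is exposed to every poison made in its tetrad, and
only spores whose own genes encode a matching antidote are protected
(unprotected spores die with probability ``c``, the killing efficiency).
Surviving spores are the gamete pool for Wright-Fisher sampling of the next
generation of N haploids.

Three canonical scenarios:

* ``novel_driver`` — a driver with a poison nobody else can detoxify invades
  a naive population (drives, deterministically p' = p / (1 - c p (1-p)));
* ``duplicate_same_specificity`` — a duplicate whose poison is detoxified by
  the fixed ancestral family member: exactly neutral, duplication alone
  cannot drive;
* ``recombinant_novel_specificity`` — a chimera coupling a novel poison with
  its own antidote, which drives against the fixed ancestral background.

Carrying a driver is cost-free by default (a ``cost`` parameter exists).
Survival multiplies independently across distinct poisons.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np


@dataclasses.dataclass(frozen=True)
class Specificity:
    """Poison made (or None for antidote-only suppressor genes) and the set
    of poisons this gene's antidote neutralizes."""
    poison_id: str | None
    antidote_ids: frozenset[str]


@dataclasses.dataclass(frozen=True)
class GeneDef:
    name: str
    locus: str
    specificity: Specificity


Genotype = frozenset  # of gene names


@dataclasses.dataclass
class DriveParams:
    N: int = 1000
    c: float = 1.0
    generations: int = 100
    p0: float = 0.05
    seed: int = 0
    cost: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0={self.p0} outside [0, 1]")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c={self.c} outside [0, 1]")
        if self.N < 2:
            raise ValueError("N must be >= 2")


@dataclasses.dataclass
class DriveState:
    scenario: str
    params: DriveParams
    trajectory: np.ndarray  # driver frequency per generation, index 0 = p0


@dataclasses.dataclass(frozen=True)
class Scenario:
    name: str
    genes: Mapping[str, GeneDef]
    driver_genotype: Genotype
    resident_genotype: Genotype
    focal: str  # the segregating gene whose frequency is tracked


def _spec(poison, antidotes) -> Specificity:
    return Specificity(poison, frozenset(antidotes))


def make_scenario(name: str) -> Scenario:
    if name == "novel_driver":
        genes = {"D": GeneDef("D", "l1", _spec("pD", {"pD"}))}
        return Scenario(name, genes, frozenset({"D"}), frozenset(), "D")
    if name == "duplicate_same_specificity":
        genes = {
            "A": GeneDef("A", "l0", _spec("pA", {"pA"})),
            "Adup": GeneDef("Adup", "l1", _spec("pA", {"pA"})),
        }
        return Scenario(name, genes, frozenset({"A", "Adup"}),
                        frozenset({"A"}), "Adup")
    if name == "recombinant_novel_specificity":
        genes = {
            "B": GeneDef("B", "l0", _spec("pB", {"pB"})),
            "R": GeneDef("R", "l1", _spec("pR", {"pR"})),
        }
        return Scenario(name, genes, frozenset({"B", "R"}),
                        frozenset({"B"}), "R")
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("novel_driver", "duplicate_same_specificity",
             "recombinant_novel_specificity")


def spore_survival(parental_genotypes: tuple[Genotype, Genotype],
                   spore_genotype: Genotype,
                   genes: Mapping[str, GeneDef], c: float) -> float:
    """Probability the spore survives all poisons expressed in its tetrad.

    Every poison carried by either parent is present in the ascus; the spore
    is protected from a poison iff one of its own genes' antidotes covers it,
    otherwise it dies with probability c.  Independent across poisons.
    """
    pa, pb = parental_genotypes
    _check_meiotic_product(pa, pb, spore_genotype, genes)
    poisons = {
        genes[g].specificity.poison_id
        for g in pa | pb
        if genes[g].specificity.poison_id is not None
    }
    surv = 1.0
    covered = set()
    for g in spore_genotype:
        covered |= genes[g].specificity.antidote_ids
    for poison in poisons:
        if poison not in covered:
            surv *= (1.0 - c)
    return surv


def _check_meiotic_product(pa: Genotype, pb: Genotype, spore: Genotype,
                           genes: Mapping[str, GeneDef]) -> None:
    loci = {genes[g].locus for g in pa | pb}
    by_locus_a = {genes[g].locus: g for g in pa}
    by_locus_b = {genes[g].locus: g for g in pb}
    by_locus_s = {genes[g].locus: g for g in spore}
    for locus in loci:
        allowed = {by_locus_a.get(locus), by_locus_b.get(locus)}
        if by_locus_s.get(locus) not in allowed:
            raise ValueError(
                f"spore genotype not a meiotic product of the parents at locus {locus}")
    if not spore <= pa | pb:
        raise ValueError("spore carries genes absent from both parents")


def next_gen_deterministic(p: float, c: float) -> float:
    """Expected next-generation driver frequency under infinite N.

    Closed form p / (1 - c p (1-p)); equals the exhaustive enumeration of the
    three mating classes with per-spore killing (see expected_next_frequency).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c={c} outside [0, 1]")
    return p / (1.0 - c * p * (1.0 - p))


def expected_next_frequency(scenario: Scenario, p: float, c: float,
                            cost: float = 0.0) -> float:
    """Expected post-killing driver-gamete share by full mating enumeration.

    Mating classes driver x driver (p^2), driver x resident (2p(1-p)) and
    resident x resident ((1-p)^2); each tetrad holds two spores of each
    parental genotype; spores survive per spore_survival; driver spores are
    additionally weighted by (1 - cost).
    """
    if p in (0.0, 1.0):
        return p
    genes = scenario.genes
    gd, gr = scenario.driver_genotype, scenario.resident_genotype
    matings = [((gd, gd), p * p), ((gd, gr), 2 * p * (1 - p)),
               ((gr, gr), (1 - p) * (1 - p))]
    driver_mass = total_mass = 0.0
    for parents, w in matings:
        for spore in parents:  # two spores of each parental genotype
            s = 2 * spore_survival(parents, spore, genes, c)
            if scenario.focal in spore:
                s_d = s * (1.0 - cost)
                driver_mass += w * s_d
                total_mass += w * s_d
            else:
                total_mass += w * s
    if total_mass == 0.0:
        return 0.0
    return driver_mass / total_mass


def simulate_wf(params: DriveParams, scenario: str | Scenario) -> DriveState:
    """Wright-Fisher trajectory of the focal driver under the given scenario."""
    params.validate()
    sc = make_scenario(scenario) if isinstance(scenario, str) else scenario
    rng = np.random.default_rng(params.seed)
    p = params.p0
    traj = [p]
    for _ in range(params.generations):
        p_exp = expected_next_frequency(sc, p, params.c, params.cost)
        p = rng.binomial(params.N, p_exp) / params.N
        traj.append(p)
        if p in (0.0, 1.0):
            break
    return DriveState(sc.name, params, np.asarray(traj))


@dataclasses.dataclass
class FixationEstimate:
    probability: float
    standard_error: float
    replicates: int
    fixed: int


def estimate_fixation_prob(params: DriveParams, scenario: str | Scenario,
                           replicates: int) -> FixationEstimate:
    """Monte-Carlo fixation fraction with binomial standard error.

    Replicates run vectorized until absorption (or a safety cap of
    max(params.generations, 50 N) generations; unabsorbed runs count as
    not fixed).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params.validate()
    sc = make_scenario(scenario) if isinstance(scenario, str) else scenario
    if params.p0 == 1.0:
        return FixationEstimate(1.0, 0.0, replicates, replicates)
    if params.p0 == 0.0:
        return FixationEstimate(0.0, 0.0, replicates, 0)
    rng = np.random.default_rng(params.seed)
    N = params.N
    cap = max(params.generations, 50 * N)
    p = np.full(replicates, params.p0)
    active = np.ones(replicates, dtype=bool)
    # p -> expected p' is a scalar map; cache it on the N+1 frequency grid
    grid = np.arange(N + 1) / N
    pmap = np.array([expected_next_frequency(sc, x, params.c, params.cost)
                     for x in grid])
    idx = np.rint(p * N).astype(int)
    for _ in range(cap):
        if not active.any():
            break
        exp_p = pmap[idx[active]]
        idx[active] = rng.binomial(N, exp_p)
        absorbed = (idx == 0) | (idx == N)
        active &= ~absorbed
    fixed = int(np.sum(idx == N))
    prob = fixed / replicates
    se = math.sqrt(prob * (1 - prob) / replicates)
    return FixationEstimate(prob, se, replicates, fixed)


def deterministic_trajectory(p0: float, c: float, generations: int) -> np.ndarray:
    """Iterate the infinite-N drive recursion."""
    traj = [p0]
    p = p0
    for _ in range(generations):
        p = next_gen_deterministic(p, c)
        traj.append(p)
    return np.asarray(traj)
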