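"""Elitist genetic algorithm for interaction-weight quantification.

The literature-derived network fixes the topology: gene j may regulate gene i
only if a filtered predication asserts it. The strength of each allowed
interaction is a weight in [-1, 1] (-1 greatest inhibition, +1 greatest
stimulation, 0 none), trained per target gene by an elitist GA whose fitness
is the squared one-step-ahead prediction error of a linear-activation
weighted-sum neuron:

    x_i(t+1) ~ sum_j w_ij * x_j(t)

summed over every usable (replicate, time) transition. Off-topology weights
are pinned at zero and never altered by crossover or mutation. Per generation
the fittest ``elite_fraction`` of the population is copied unchanged and the
remainder is produced by single-point crossover of uniformly chosen parents
followed by per-locus mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .expression import ExpressionDataset, Transition, transition_design, \
    usable_transitions
from .netbuild import InteractionNetwork
from .predications import ValidationError


@dataclass
class Topology:
    """Which regulator -> target pairs the literature permits.

    ``allowed[i, j]`` is True iff gene j may regulate gene i. ``sign_hint``
    carries the literature sign (+1/-1/0) for reporting only: trained weights
    are free to oppose it.
    """

    genes: list[str]
    allowed: np.ndarray                 # (n, n) bool
    sign_hint: np.ndarray | None = None  # (n, n) int in {-1, 0, +1}

    def __post_init__(self) -> None:
        n = len(self.genes)
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.shape != (n, n):
            raise ValidationError("allowed matrix must be n x n")
        if self.sign_hint is not None:
            self.sign_hint = np.asarray(self.sign_hint, dtype=int)
            if self.sign_hint.shape != (n, n):
                raise ValidationError("sign_hint matrix must be n x n")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def topology_from_network(net: InteractionNetwork,
                          genes: Sequence[str] | None = None) -> Topology:
    """Topology over ``genes`` (default: sorted network nodes) from edges.

    An edge source -> target in the network allows source to regulate target.
    """
    gene_list = sorted(net.nodes) if genes is None else list(genes)
    index = {g: i for i, g in enumerate(gene_list)}
    n = len(gene_list)
    allowed = np.zeros((n, n), dtype=bool)
    sign_hint = np.zeros((n, n), dtype=int)
    for (s, t), e in net.edges.items():
        if s in index and t in index:
            allowed[index[t], index[s]] = True
            sign_hint[index[t], index[s]] = e.sign
    return Topology(genes=gene_list, allowed=allowed, sign_hint=sign_hint)


@dataclass
class GAConfig:
    """Evolutionary hyperparameters.

    Defaults follow the full-scale study configuration: a population of 2000
    weight vectors evolved for 200 generations, the fittest 20% copied
    unchanged each generation, and a per-locus mutation probability of 0.25%.
    """

    population_size: int = 2000
    generations: int = 200
    elite_fraction: float = 0.2
    mutation_rate: float = 0.0025
    activation: Literal["linear"] = "linear"
    mutation_mode: Literal["resample", "gaussian"] = "resample"
    mutation_sigma: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.elite_fraction < 1:
            raise ValidationError("elite_fraction must be in (0, 1)")
        if not 0 <= self.mutation_rate <= 1:
            raise ValidationError("mutation_rate must be in [0, 1]")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if self.activation != "linear":
            raise ValidationError("only the linear activation is supported")

    @property
    def n_elite(self) -> int:
        return max(1, int(self.elite_fraction * self.population_size))


@dataclass
class WeightVector:
    """Inbound interaction weights for one target gene."""

    target: int                # index of the target gene
    w: np.ndarray              # (n,) floats in [-1, 1]; 0 off-topology

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(np.abs(self.w) > 1):
            raise ValidationError("weights must lie in [-1, 1]")


def predict_next(x_t: np.ndarray, wv: WeightVector) -> float:
    """One-step prediction for the target gene: the weighted sum of all genes.

    The activation is linear and the prediction is not clipped.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != wv.w.shape:
        raise ValidationError(
            f"shape mismatch: x has {x_t.shape}, weights have {wv.w.shape}")
    return float(wv.w @ x_t)


def fitness(wv: WeightVector, ds: ExpressionDataset,
            transitions: list[Transition] | None = None) -> float:
    """Sum of squared one-step prediction errors over usable transitions."""
    X, Y = transition_design(ds, transitions)
    resid = Y[:, wv.target] - X @ wv.w
    return float(resid @ resid)


def _population_fitness(pop: np.ndarray, X: np.ndarray,
                        y: np.ndarray) -> np.ndarray:
    resid = X @ pop.T - y[:, None]          # (m, P)
    return np.einsum("mp,mp->p", resid, resid)


def init_population(topology: Topology, target: int, config: GAConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Initial population: allowed loci i.i.d. uniform on [-1, 1], rest 0.

    Returns an array of shape (population_size, n_genes).
    """
    mask = topology.allowed[target]
    pop = np.zeros((config.population_size, topology.n_genes))
    k = int(mask.sum())
    if k:
        pop[:, mask] = rng.uniform(-1.0, 1.0,
                                   size=(config.population_size, k))
    return pop


def select_elite(population: np.ndarray, fitnesses: np.ndarray,
                 elite_fraction: float) -> np.ndarray:
    """Copy of the fittest max(1, floor(fraction*size)) members.

    Smaller fitness is fitter; ties break by input order (stable sort).
    """
    if len(population) != len(fitnesses):
        raise ValidationError("population and fitnesses must align")
    n_elite = max(1, int(elite_fraction * len(population)))
    order = np.argsort(fitnesses, kind="stable")
    return population[order[:n_elite]].copy()


def crossover(parent_a: np.ndarray, parent_b: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Single-point crossover: loci up to the cut from a, the rest from b.

    The cut point is uniform over the n-1 internal boundaries; with a single
    locus the child is a copy of parent a. Zero-masked loci are zero in both
    parents and therefore remain zero.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("parents must share shape (and mask)")
    n = a.size
    if n == 1:
        return a.copy()
    k = int(rng.integers(1, n))         # child = a[:k] + b[k:]
    return np.concatenate([a[:k], b[k:]])


def mutate(wv: np.ndarray, mutation_rate: float, rng: np.random.Generator,
           allowed: np.ndarray | None = None,
           mode: str = "resample", sigma: float = 0.1) -> np.ndarray:
    """Point mutation: each allowed locus independently perturbed.

    ``resample`` (default) redraws the locus uniform on [-1, 1];
    ``gaussian`` adds N(0, sigma^2) noise clipped to the bounds.
    """
    w = np.asarray(wv, dtype=float).copy()
    if allowed is None:
        allowed = w != 0  # conservative fallback: only touch active loci
    hit = (rng.random(w.shape) < mutation_rate) & allowed
    k = int(hit.sum())
    if k:
        if mode == "resample":
            w[hit] = rng.uniform(-1.0, 1.0, size=k)
        elif mode == "gaussian":
            w[hit] = np.clip(w[hit] + rng.normal(0.0, sigma, size=k), -1, 1)
        else:
            raise ValidationError(f"unknown mutation mode {mode!r}")
    return w


def evolve_gene(ds: ExpressionDataset, topology: Topology, target: int,
                config: GAConfig,
                rng: np.random.Generator | None = None,
                transitions: list[Transition] | None = None,
                ) -> tuple[WeightVector, np.ndarray]:
    """Train the inbound weights of one target gene.

    Each generation copies the elite unchanged and fills the rest of the
    population with mutated single-point crossovers of uniformly random parent
    pairs. Returns the all-time best weight vector and the per-generation
    best-so-far fitness trace (monotone non-increasing, length generations+1
    including the initial population).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if transitions is None:
        transitions = usable_transitions(ds)
    X, Y = transition_design(ds, transitions)
    y = Y[:, target]
    mask = topology.allowed[target]
    n = topology.n_genes

    pop = init_population(topology, target, config, rng)
    if not mask.any():
        wv = WeightVector(target=target, w=np.zeros(n))
        best = float(y @ y)
        return wv, np.full(config.generations + 1, best)

    fit = _population_fitness(pop, X, y)
    best_idx = int(np.argmin(fit))
    best_w = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    trace = [best_fit]

    n_children = config.population_size - config.n_elite
    for _ in range(config.generations):
        elite = select_elite(pop, fit, config.elite_fraction)
        ia = rng.integers(0, config.population_size, size=n_children)
        ib = rng.integers(0, config.population_size, size=n_children)
        if n >= 2:
            cut = rng.integers(1, n, size=n_children)
        else:
            cut = np.ones(n_children, dtype=int)
        take_a = np.arange(n)[None, :] < cut[:, None]
        children = np.where(take_a, pop[ia], pop[ib])
        hit = (rng.random(children.shape) < config.mutation_rate) & mask
        k = int(hit.sum())
        if k:
            if config.mutation_mode == "resample":
                children[hit] = rng.uniform(-1.0, 1.0, size=k)
            else:
                children[hit] = np.clip(
                    children[hit] + rng.normal(0.0, config.mutation_sigma,
                                               size=k), -1, 1)
        pop = np.vstack([elite, children])
        fit = _population_fitness(pop, X, y)
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_w = pop[gen_best].copy()
        trace.append(best_fit)

    return WeightVector(target=target, w=best_w), np.asarray(trace)


def evolve_network(ds: ExpressionDataset, topology: Topology,
                   config: GAConfig,
                   transitions: list[Transition] | None = None) -> np.ndarray:
    """Train all target genes independently; returns the (n, n) weight matrix.

    Row i holds the inbound weights of gene i. Per-gene RNG substreams are
    seeded ``config.rng_seed + i`` so results are reproducible and independent
    of gene evaluation order.
    """
    missing = [g for g in topology.genes if g not in ds.genes]
    if missing:
        raise ValidationError(
            "topology genes absent from dataset: " + ", ".join(missing))
    if topology.genes != ds.genes:
        ds = _reorder_dataset(ds, topology.genes)
    n = topology.n_genes
    W = np.zeros((n, n))
    for i in range(n):
        rng = np.random.default_rng(config.rng_seed + i)
        wv, _ = evolve_gene(ds, topology, i, config, rng,
                            transitions=transitions)
        W[i] = wv.w
    return W


def _reorder_dataset(ds: ExpressionDataset,
                     genes: Sequence[str]) -> ExpressionDataset:
    idx = [ds.genes.index(g) for g in genes]
    return ExpressionDataset(genes=list(genes), values=ds.values[idx],
                             present=ds.present.copy())


def bounded_least_squares(X: np.ndarray, y: np.ndarray,
                          mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Box-constrained least squares on the allowed columns.

    The optimum of the GA's own objective over the feasible set
    ``w in [-1, 1]^n, w[~mask] = 0``; used as a reference optimum when
    assessing GA convergence. Returns (w, sum of squared residuals).
    """
    n = X.shape[1]
    w = np.zeros(n)
    if mask.any():
        res = lsq_linear(X[:, mask], y, bounds=(-1.0, 1.0),
                         tol=1e-12, method="bvls")
        w[mask] = res.x
    resid = y - X @ w
    return w, float(resid @ resid)
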