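"""Coalescent simulator for constant-size and sudden-expansion demographies.

Time is measured directly in *mutational units*, the same units as the
expansion parameter τ = 2ut (u = per-sequence per-generation mutation
rate, t = generations).  In these units, with scaled population-mutation
parameter θ = 2Nu:

* j lineages coalesce at rate C(j, 2) / θ(epoch),
* mutations accrue on each lineage at rate 1/2 per unit time,

so that under constant size the expected pairwise difference equals θ and
the expected number of segregating sites equals θ·a1 — the standard
identities — while a population that changed instantaneously from θ0 to
θ1 a mutational time τ ago is modelled by switching the coalescence rate
from 1/θ1 to 1/θ0 (per pair) at time τ backward from the present.
θ0 = 0 is allowed and collapses all surviving lineages at exactly τ
(a star genealogy), the limit in which pairwise differences are
Poisson(τ)-distributed.

Mutations follow the infinite-sites model by default: every mutation
creates a new binary column in the genotype matrix.  Export to sequences
maps the columns onto distinct positions of a k-bp reference (default
1140 bp); a finite-sites Jukes–Cantor export that permits repeat hits is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .seq_io import Alignment

__all__ = [
    "DemographyConfig",
    "SimulatedSample",
    "ConfigError",
    "simulate",
    "simulate_expansion_panel",
    "fixed_s_sample",
    "fixed_s_null",
    "mismatch_counts_from_matrix",
]

_BASES = "ACGT"


class ConfigError(ValueError):
    """Invalid demography parameters."""


@dataclass(frozen=True)
class DemographyConfig:
    """Parameters of the simulated demography.

    theta0, theta1 are the scaled mutation parameters (2Nu per sequence)
    before and after the expansion, tau the expansion age in mutational
    units; the ``constant`` model requires theta0 == theta1 and tau is
    ignored.
    """

    model: Literal["constant", "sudden_expansion"]
    theta0: float
    theta1: float
    tau: float
    n: int
    k: int = 1140
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("constant", "sudden_expansion"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.theta0 < 0 or self.theta1 < 0:
            raise ConfigError("require theta0 >= 0 and theta1 >= 0")
        if self.tau < 0:
            raise ConfigError("require tau >= 0")
        if self.n < 2:
            raise ConfigError("require n >= 2")
        if self.model == "constant" and self.theta0 != self.theta1:
            raise ConfigError("constant model requires theta0 == theta1")


@dataclass
class SimulatedSample:
    """One simulated sample: a binary genotype matrix plus provenance.

    ``genotypes`` has shape (n, S) with one column per (infinite-sites)
    mutation; ``genotypes[i, j] == 1`` when sample i carries mutation j.
    """

    genotypes: np.ndarray
    config: DemographyConfig
    seed: int

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def S(self) -> int:
        return self.genotypes.shape[1]

    def to_alignment(
        self, prefix: str = "s", finite_sites: bool = False
    ) -> Alignment:
        """Render the genotype matrix as aligned k-bp sequences.

        Infinite sites (default): each mutation occupies its own position,
        drawn without replacement from the k available sites, ancestral and
        derived bases drawn at random.  ``finite_sites=True`` instead drops
        mutations onto positions *with* replacement, each changing the
        current base to a random different base (Jukes–Cantor-style repeat
        hits), which can erase earlier mutations.
        """
        k = self.config.k
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 0xA11C])
        )
        n, S = self.genotypes.shape
        if not finite_sites and S > k:
            raise ConfigError(
                f"{S} mutations cannot occupy {k} sites without collision; "
                "use finite_sites=True or a larger k"
            )
        ancestral = rng.integers(0, 4, size=k)
        seqs = np.tile(ancestral, (n, 1))
        if finite_sites:
            positions = rng.integers(0, k, size=S)
        else:
            positions = rng.choice(k, size=S, replace=False)
        for j in range(S):
            pos = positions[j]
            carriers = self.genotypes[:, j] == 1
            current = seqs[carriers, pos]
            # derived base differs from the (possibly already-mutated) base
            shift = rng.integers(1, 4)
            seqs[carriers, pos] = (current + shift) % 4
        width = len(str(n))
        records = [
            (
                f"{prefix}{i + 1:0{width}d}",
                "".join(_BASES[b] for b in seqs[i]),
            )
            for i in range(n)
        ]
        return Alignment(records=records)


def _coalescent_times(
    n: int, theta0: float, theta1: float, tau: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a genealogy: returns (parent, node_time, order).

    Nodes 0..n-1 are leaves (time 0); nodes n..2n-2 internal, created in
    coalescence order.  Rate per pair is 1/theta1 for time < tau, then
    1/theta0 (theta0 == 0 collapses every surviving lineage at tau).
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    next_node = n
    in_recent_epoch = True
    while len(active) > 1:
        j = len(active)
        npairs = j * (j - 1) / 2.0
        if in_recent_epoch:
            wait = rng.exponential(theta1 / npairs)
            if t + wait >= tau:
                t = tau
                in_recent_epoch = False
                continue
            t += wait
        else:
            if theta0 == 0.0:
                # instantaneous collapse: merge everything at time tau
                wait = 0.0
            else:
                wait = rng.exponential(theta0 / npairs)
            t += wait
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        active = [x for x in active if x not in (a, b)]
        active.append(next_node)
        next_node += 1
    return parent, time, np.arange(n_nodes)


def _leaf_sets(parent: np.ndarray, n: int) -> np.ndarray:
    """Boolean (n_nodes, n) matrix: which leaves descend from each node."""
    n_nodes = len(parent)
    below = np.zeros((n_nodes, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    # internal nodes are numbered in increasing time order, so a single
    # ascending pass accumulates children before parents
    for v in range(n_nodes - 1):
        p = parent[v]
        if p >= 0:
            below[p] |= below[v]
    return below


def _genotypes_from_tree(
    parent: np.ndarray,
    time: np.ndarray,
    n: int,
    mutations_per_branch: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    below = _leaf_sets(parent, n)
    cols: list[np.ndarray] = []
    for v in range(len(parent)):
        m = int(mutations_per_branch[v])
        if m > 0:
            col = below[v].astype(np.int8)
            cols.extend([col] * m)
    if not cols:
        return np.zeros((n, 0), dtype=np.int8)
    return np.column_stack(cols)


def simulate(config: DemographyConfig) -> SimulatedSample:
    """Draw one sample under the configured demography.

    Reproducible: the same config (including seed) returns an identical
    genotype matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E0]))
    if config.model == "constant":
        theta0 = theta1 = config.theta1
        tau = np.inf
    else:
        theta0, theta1, tau = config.theta0, config.theta1, config.tau
    if theta1 == 0.0:  # degenerate: no variation possible
        return SimulatedSample(
            genotypes=np.zeros((config.n, 0), dtype=np.int8),
            config=config,
            seed=config.seed,
        )
    parent, time, _ = _coalescent_times(config.n, theta0, theta1, tau, rng)
    lengths = np.where(parent >= 0, time[parent] - time, 0.0)
    muts = rng.poisson(lengths / 2.0)
    genotypes = _genotypes_from_tree(parent, time, config.n, muts, rng)
    return SimulatedSample(genotypes=genotypes, config=config, seed=config.seed)


def simulate_expansion_panel(
    theta0: float,
    theta1: float,
    tau: float,
    n: int,
    reps: int,
    seed: int = 0,
) -> list[SimulatedSample]:
    """``reps`` independent sudden-expansion samples with derived sub-seeds."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    out = []
    for b in range(reps):
        sub = int(
            np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31)
        )
        cfg = DemographyConfig(
            model="sudden_expansion",
            theta0=theta0,
            theta1=theta1,
            tau=tau,
            n=n,
            seed=sub,
        )
        out.append(simulate(cfg))
    return out


def fixed_s_sample(n: int, S: int, seed: int = 0) -> SimulatedSample:
    """A constant-size genealogy with exactly S mutations.

    Conditional-on-S simulation: the tree is drawn from the constant-size
    coalescent (the tree law does not depend on θ) and S mutations are
    placed on branches with probability proportional to branch length.
    """
    if S < 0:
        raise ConfigError("S must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    parent, time, _ = _coalescent_times(n, 1.0, 1.0, np.inf, rng)
    lengths = np.where(parent >= 0, time[parent] - time, 0.0)
    muts = np.zeros(len(parent), dtype=np.int64)
    if S > 0:
        total = lengths.sum()
        branch_for = rng.choice(len(parent), size=S, p=lengths / total)
        for b in branch_for:
            muts[b] += 1
    genotypes = _genotypes_from_tree(parent, time, n, muts, rng)
    cfg = DemographyConfig(
        model="constant", theta0=1.0, theta1=1.0, tau=0.0, n=n, seed=seed
    )
    return SimulatedSample(genotypes=genotypes, config=cfg, seed=seed)


def fixed_s_null(
    n: int, S: int, reps: int, seed: int = 0
) -> list[SimulatedSample]:
    """``reps`` conditional-on-S constant-size samples."""
    return [
        fixed_s_sample(
            n,
            S,
            int(np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31)),
        )
        for b in range(reps)
    ]


def mismatch_counts_from_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Counts of pairwise differences d = 0..d_max from a genotype matrix."""
    n = genotypes.shape[0]
    x = genotypes.astype(np.int64)
    if genotypes.shape[1] == 0:
        counts = np.zeros(1, dtype=np.int64)
        counts[0] = n * (n - 1) // 2
        return counts
    row = x.sum(axis=1)
    cross = x @ x.T
    d = row[:, None] + row[None, :] - 2 * cross
    iu = np.triu_indices(n, k=1)
    return np.bincount(d[iu])
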