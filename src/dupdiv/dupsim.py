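"""Forward-time Wright–Fisher simulator of a fixed two-copy segmental
duplication undergoing interlocus gene conversion (IGC), plus a single-copy
control block.

Model
-----
Each of the 2N chromosomes in a population of N diploids carries three
homologous blocks of length B bp: a ``single_copy`` control block, and an
``original``/``duplicated`` block pair.  The duplication is fixed from
generation 0 (no pre-fixation phase).  Evolution is neutral under the
infinite-sites model with real-valued mutation positions on [0, B):

* mutation: per chromosome per block per generation, a Poisson number of
  new mutations with mean ``theta_site * B / (4N)``, so that the
  population-scaled rate per site is ``theta_site`` in coalescent units;
* crossover: restricted to the single-copy block, one breakpoint uniform on
  [0, B), with per-gamete probability ``R / (4N)`` — the original and
  duplicated blocks are inherited intact from the first parent chromosome;
* IGC: with per-chromosome probability ``C / (4N)`` a conversion tract of
  geometric length (mean ``igc_tract_mean`` bp, truncated at block edges)
  starting uniformly on [0, B) is copied between the original and
  duplicated blocks, direction chosen with probability 1/2 each and no
  sequence-similarity requirement.

Samples are drawn as `single_copy` / `original` / `duplicated` block
matrices, or as a `collapsed` sample that mimics reads from both copies
being mapped to one reference locus: half the sampled chromosomes
contribute their original block and half their duplicated block.

Internally the population is a set of boolean chromosome-by-site matrices
(one for the single-copy block, a position-aligned pair for the two
duplicates so conversion tracts can be copied column-wise).  The equivalent
per-chromosome set semantics are exposed via :class:`ChromosomeState`,
:func:`igc_transfer` and :func:`crossover_gamete`, which double as oracles
for the matrix engine in the test-suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .msio import HaplotypeMatrix

BLOCKS = ("single_copy", "original", "duplicated")


@dataclass
class SimConfig:
    """All simulator parameters, in population-scaled (coalescent) units.

    C, R and theta_site are the usual 4N-scaled IGC, crossover and per-site
    mutation rates, directly comparable across population sizes.
    """

    N: int = 1000
    B: float = 5000.0
    t: int = 100_000
    z: int = 50
    C: float = 1.0
    R: float = 10.0
    theta_site: float = 0.001
    igc_tract_mean: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1 or self.B <= 0 or self.t < 0:
            raise ValueError("N, B must be positive; t non-negative")
        if not 1 <= self.z <= 2 * self.N:
            raise ValueError("sample size z must satisfy 1 <= z <= 2N")
        if min(self.C, self.R, self.theta_site) < 0:
            raise ValueError("rates must be non-negative")
        if self.igc_tract_mean <= 0:
            raise ValueError("igc_tract_mean must be positive")

    # unscaled per-chromosome per-generation rates
    @property
    def mu_block(self) -> float:
        return self.theta_site * self.B / (4.0 * self.N)

    @property
    def r_crossover(self) -> float:
        return self.R / (4.0 * self.N)

    @property
    def c_igc(self) -> float:
        return self.C / (4.0 * self.N)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


@dataclass
class ChromosomeState:
    """One chromosome as three sets of derived-mutation positions in [0, B)."""

    single_copy: set = field(default_factory=set)
    original: set = field(default_factory=set)
    duplicated: set = field(default_factory=set)


def igc_transfer(donor_block: set, acceptor_block: set,
                 tract_start: float, tract_length: float) -> set:
    """Non-reciprocal conversion: the acceptor's content inside the tract
    window [tract_start, tract_start+tract_length) is replaced by the
    donor's.  The donor is unchanged; positions outside the tract are kept.
    """
    lo = tract_start
    hi = tract_start + tract_length
    kept = {p for p in acceptor_block if not lo <= p < hi}
    moved = {p for p in donor_block if lo <= p < hi}
    return kept | moved


def crossover_gamete(parent_a: ChromosomeState, parent_b: ChromosomeState,
                     breakpoint: float) -> ChromosomeState:
    """Gamete with a single-copy crossover at ``breakpoint``; the duplication
    pair is inherited intact from ``parent_a`` (crossover is limited to the
    single-copy region)."""
    sc = {p for p in parent_a.single_copy if p < breakpoint} | {
        p for p in parent_b.single_copy if p >= breakpoint
    }
    return ChromosomeState(
        single_copy=sc,
        original=set(parent_a.original),
        duplicated=set(parent_a.duplicated),
    )


class Population:
    """2N chromosomes stored as boolean matrices over segregating columns.

    ``S`` (single-copy) has its own position vector; ``O`` and ``D`` share
    one (``OD_pos``) so that an IGC tract is a column range copied between
    the two matrices.  Columns fixed or lost population-wide (jointly in
    O and D) are pruned every generation.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        twoN = 2 * config.N
        self.S = np.zeros((twoN, 0), dtype=bool)
        self.S_pos = np.empty(0)
        self.O = np.zeros((twoN, 0), dtype=bool)
        self.D = np.zeros((twoN, 0), dtype=bool)
        self.OD_pos = np.empty(0)
        self.generation = 0
        self.mutation_count = {b: 0 for b in BLOCKS}

    @property
    def twoN(self) -> int:
        return 2 * self.config.N

    # -- conversions to/from the per-chromosome set representation ---------

    @classmethod
    def from_states(cls, states, config: SimConfig,
                    rng: np.random.Generator | None = None) -> "Population":
        if len(states) != 2 * config.N:
            raise ValueError("need exactly 2N chromosome states")
        pop = cls(config, rng)
        s_pos = sorted({p for st in states for p in st.single_copy})
        od_pos = sorted({p for st in states for p in st.original | st.duplicated})
        pop.S_pos = np.array(s_pos)
        pop.OD_pos = np.array(od_pos)
        s_idx = {p: j for j, p in enumerate(s_pos)}
        od_idx = {p: j for j, p in enumerate(od_pos)}
        pop.S = np.zeros((pop.twoN, len(s_pos)), dtype=bool)
        pop.O = np.zeros((pop.twoN, len(od_pos)), dtype=bool)
        pop.D = np.zeros((pop.twoN, len(od_pos)), dtype=bool)
        for i, st in enumerate(states):
            for p in st.single_copy:
                pop.S[i, s_idx[p]] = True
            for p in st.original:
                pop.O[i, od_idx[p]] = True
            for p in st.duplicated:
                pop.D[i, od_idx[p]] = True
        return pop

    def to_states(self) -> list[ChromosomeState]:
        out = []
        for i in range(self.twoN):
            out.append(
                ChromosomeState(
                    single_copy=set(self.S_pos[self.S[i]]),
                    original=set(self.OD_pos[self.O[i]]),
                    duplicated=set(self.OD_pos[self.D[i]]),
                )
            )
        return out

    # -- elementary events --------------------------------------------------

    def igc_event(self, chrom: int, tract_start: float, tract_length: float,
                  original_to_duplicated: bool) -> None:
        """Apply one conversion event to chromosome ``chrom`` in place."""
        mask = (self.OD_pos >= tract_start) & (self.OD_pos < tract_start + tract_length)
        if not mask.any():
            return
        if original_to_duplicated:
            self.D[chrom, mask] = self.O[chrom, mask]
        else:
            self.O[chrom, mask] = self.D[chrom, mask]

    # -- one Wright–Fisher generation ---------------------------------------

    def step(self) -> None:
        cfg = self.config
        rng = self.rng
        twoN = self.twoN

        # each offspring chromosome is a gamete of one random diploid parent
        par = rng.integers(cfg.N, size=twoN)
        which = rng.integers(2, size=twoN)
        a = 2 * par + which

        S_new = self.S[a]
        r = cfg.r_crossover
        if r > 0 and self.S_pos.size:
            for i in np.nonzero(rng.random(twoN) < r)[0]:
                bp = rng.random() * cfg.B
                m = self.S_pos >= bp
                S_new[i, m] = self.S[2 * par[i] + 1 - which[i], m]
        self.S = S_new
        self.O = self.O[a]
        self.D = self.D[a]

        c = cfg.c_igc
        if c > 0:
            for i in np.nonzero(rng.random(twoN) < c)[0]:
                start = rng.random() * cfg.B
                length = float(rng.geometric(1.0 / cfg.igc_tract_mean))
                self.igc_event(i, start, length, bool(rng.random() < 0.5))

        self._mutate()
        self._prune()
        self.generation += 1

    def _mutate(self) -> None:
        cfg = self.config
        rng = self.rng
        twoN = self.twoN
        mean = twoN * cfg.mu_block
        if mean == 0:
            return
        nS, nO, nD = rng.poisson(mean, size=3)
        if nS:
            self.S, self.S_pos = self._add_columns(self.S, self.S_pos, nS)
            self.mutation_count["single_copy"] += int(nS)
        k = nO + nD
        if k:
            new_pos = rng.random(k) * cfg.B
            rows = rng.integers(twoN, size=k)
            o_cols = np.zeros((twoN, k), dtype=bool)
            d_cols = np.zeros((twoN, k), dtype=bool)
            o_cols[rows[:nO], np.arange(nO)] = True
            d_cols[rows[nO:], np.arange(nO, k)] = True
            self.O = np.concatenate([self.O, o_cols], axis=1)
            self.D = np.concatenate([self.D, d_cols], axis=1)
            self.OD_pos = np.concatenate([self.OD_pos, new_pos])
            self.mutation_count["original"] += int(nO)
            self.mutation_count["duplicated"] += int(nD)

    def _add_columns(self, mat: np.ndarray, pos: np.ndarray, n_new: int):
        rng = self.rng
        new_pos = rng.random(n_new) * self.config.B
        cols = np.zeros((self.twoN, n_new), dtype=bool)
        cols[rng.integers(self.twoN, size=n_new), np.arange(n_new)] = True
        return np.concatenate([mat, cols], axis=1), np.concatenate([pos, new_pos])

    def _prune(self) -> None:
        twoN = self.twoN
        if self.S_pos.size:
            cnt = self.S.sum(axis=0)
            keep = (cnt > 0) & (cnt < twoN)
            if not keep.all():
                self.S = self.S[:, keep]
                self.S_pos = self.S_pos[keep]
        if self.OD_pos.size:
            co = self.O.sum(axis=0)
            cd = self.D.sum(axis=0)
            # a site fixed in one copy but not the other is still informative
            keep = ~(((co == 0) & (cd == 0)) | ((co == twoN) & (cd == twoN)))
            if not keep.all():
                self.O = self.O[:, keep]
                self.D = self.D[:, keep]
                self.OD_pos = self.OD_pos[keep]

    def run(self, generations: int) -> "Population":
        for _ in range(generations):
            self.step()
        return self

    # -- sampling ------------------------------------------------------------

    def _finalize(self, sub: np.ndarray, pos: np.ndarray, label: str) -> HaplotypeMatrix:
        z = sub.shape[0]
        cnt = sub.sum(axis=0)
        keep = (cnt > 0) & (cnt < z)
        sub = sub[:, keep]
        pos = pos[keep]
        order = np.argsort(pos)
        return HaplotypeMatrix(
            sub[:, order].astype(np.uint8),
            pos[order] / self.config.B,
            label=label,
            block_length=self.config.B,
        )

    def sample_block(self, z: int, block: str,
                     rng: np.random.Generator | None = None) -> HaplotypeMatrix:
        """z chromosomes without replacement, restricted to sites segregating
        in the sample; derived (0/1) coding preserved."""
        if z > self.twoN:
            raise ValueError("z cannot exceed 2N")
        if block not in BLOCKS:
            raise ValueError(f"unknown block {block!r}")
        rng = rng if rng is not None else self.rng
        rows = rng.choice(self.twoN, size=z, replace=False)
        if block == "single_copy":
            return self._finalize(self.S[rows], self.S_pos, "single_copy")
        mat = self.O if block == "original" else self.D
        return self._finalize(mat[rows], self.OD_pos, block)

    def collapsed_sample(self, z: int, rng: np.random.Generator | None = None,
                         paired: bool = False) -> HaplotypeMatrix:
        """Collapsed-duplication sample: half the sequences come from the
        original block and half from the duplicated block.

        By default z distinct chromosomes are drawn, the first z/2
        contributing their original block and the rest their duplicated
        block.  With ``paired=True`` only z/2 chromosomes are drawn and each
        contributes both copies.
        """
        if z % 2:
            raise ValueError("collapsed sampling requires even z")
        rng = rng if rng is not None else self.rng
        if paired:
            rows = rng.choice(self.twoN, size=z // 2, replace=False)
            sub = np.vstack([self.O[rows], self.D[rows]])
        else:
            rows = rng.choice(self.twoN, size=z, replace=False)
            sub = np.vstack([self.O[rows[: z // 2]], self.D[rows[z // 2 :]]])
        return self._finalize(sub, self.OD_pos, "collapsed")


def wf_generation(population: Population) -> Population:
    """Advance the population by one Wright–Fisher generation (in place)."""
    population.step()
    return population


def simulate(config: SimConfig,
             rng: np.random.Generator | None = None) -> dict[str, HaplotypeMatrix]:
    """Run ``config.t`` generations from a mutation-free duplication-fixed
    population and return the four sampled matrices, keyed by
    ``single_copy`` / ``original`` / ``duplicated`` / ``collapsed``.
    Deterministic given ``config.seed`` (or an explicit ``rng``)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pop = Population(config, rng)
    pop.run(config.t)
    out = {b: pop.sample_block(config.z, b) for b in BLOCKS}
    out["collapsed"] = pop.collapsed_sample(config.z)
    return out


def simulate_batch(config: SimConfig, reps: int,
                   seed: int | None = None) -> list[dict[str, HaplotypeMatrix]]:
    """Independent replicates with per-replicate RNG streams spawned from one
    seed (``seed`` overrides ``config.seed``)."""
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    return [
        simulate(config, rng=np.random.default_rng(child))
        for child in root.spawn(reps)
    ]
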