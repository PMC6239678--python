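"""Forward Wright–Fisher simulator of a single-copy region with one
selected site, providing sweep and balancing-selection comparators.

A neutral single-copy block (same mutation/crossover model as
:mod:`dupdiv.dupsim`) is evolved to mutation–drift equilibrium; then a
beneficial derived allele is introduced as a single copy at the block
midpoint and the population is run forward under diploid viability
selection with genotype fitnesses

    w(aa) = 1,   w(aA) = 1 + SaA/(2N),   w(AA) = 1 + SAA/(2N),

where SAA and SaA are the 2N-scaled selection coefficients (the
conventional ``-SAA``/``-SaA`` parameterization of coalescent selection
simulators).  The allele-frequency trajectory is conditioned per scenario
by rejection: runs in which the allele is lost (or, for balancing
selection, fixed) restart from the equilibrium snapshot.

Scenarios
---------
* ``complete_sweep`` (SAA=40, SaA=0): sample at fixation of the allele.
* ``incomplete_sweep`` (SAA=40, SaA=20): sample when the derived frequency
  first reaches ``incomplete_freq`` (default 0.8).
* ``balancing`` (SAA=0, SaA=40): heterozygote advantage; sample after a
  further ``10 N`` generations of maintained polymorphism.
* ``neutral`` (0, 0): sample at the end of the burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dupsim import SimConfig
from .msio import HaplotypeMatrix

SCENARIO_COEFFS = {
    "complete_sweep": (40.0, 0.0),
    "incomplete_sweep": (40.0, 20.0),
    "balancing": (0.0, 40.0),
    "neutral": (0.0, 0.0),
}


@dataclass
class SelectionScenario:
    kind: str
    SAA: float
    SaA: float
    incomplete_freq: float = 0.8
    balancing_hold: float = 10.0  # generations held = balancing_hold * N
    restart_cap: int = 2000

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_COEFFS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        neutral = self.SAA == 0 and self.SaA == 0
        if (self.kind == "neutral") != neutral:
            raise ValueError("neutral scenario requires SAA = SaA = 0 (and only then)")
        if not 0 < self.incomplete_freq <= 1:
            raise ValueError("incomplete_freq must be in (0, 1]")

    @classmethod
    def from_kind(cls, kind: str, **kwargs) -> "SelectionScenario":
        saa, sah = SCENARIO_COEFFS[kind]
        return cls(kind=kind, SAA=saa, SaA=sah, **kwargs)


class ConvergenceError(RuntimeError):
    """Trajectory conditioning failed within the restart cap."""


class _Block:
    """Single neutral block + a selected-site allele vector over 2N chromosomes."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        twoN = 2 * cfg.N
        self.S = np.zeros((twoN, 0), dtype=bool)
        self.pos = np.empty(0)
        self.sel = np.zeros(twoN, dtype=bool)
        self.sel_pos = cfg.B / 2.0

    def step(self, fitness: np.ndarray | None = None) -> None:
        cfg = self.cfg
        rng = self.rng
        twoN = 2 * cfg.N
        if fitness is None:
            par = rng.integers(cfg.N, size=twoN)
        else:
            g = self.sel[0::2].astype(np.int64) + self.sel[1::2]
            w = fitness[g]
            par = rng.choice(cfg.N, size=twoN, p=w / w.sum())
        which = rng.integers(2, size=twoN)
        a = 2 * par + which
        S_new = self.S[a]
        sel_new = self.sel[a]
        r = cfg.r_crossover
        if r > 0:
            for i in np.nonzero(rng.random(twoN) < r)[0]:
                bp = rng.random() * cfg.B
                bi = 2 * par[i] + 1 - which[i]
                if self.pos.size:
                    m = self.pos >= bp
                    S_new[i, m] = self.S[bi, m]
                if self.sel_pos >= bp:
                    sel_new[i] = self.sel[bi]
        self.S = S_new
        self.sel = sel_new
        n_mut = rng.poisson(twoN * cfg.mu_block)
        if n_mut:
            new_pos = rng.random(n_mut) * cfg.B
            cols = np.zeros((twoN, n_mut), dtype=bool)
            cols[rng.integers(twoN, size=n_mut), np.arange(n_mut)] = True
            self.S = np.concatenate([self.S, cols], axis=1)
            self.pos = np.concatenate([self.pos, new_pos])
        cnt = self.S.sum(axis=0)
        keep = (cnt > 0) & (cnt < twoN)
        if not keep.all():
            self.S = self.S[:, keep]
            self.pos = self.pos[keep]

    def sample(self, z: int, label: str = "single_copy") -> HaplotypeMatrix:
        cfg = self.cfg
        rows = self.rng.choice(2 * cfg.N, size=z, replace=False)
        sub = self.S[rows]
        cnt = sub.sum(axis=0)
        keep = (cnt > 0) & (cnt < z)
        sub = sub[:, keep]
        pos = self.pos[keep]
        sel = self.sel[rows]
        k = int(sel.sum())
        if 0 < k < z:  # selected site segregating in the sample
            sub = np.concatenate([sub, sel[:, None]], axis=1)
            pos = np.concatenate([pos, [self.sel_pos]])
        order = np.argsort(pos)
        return HaplotypeMatrix(
            sub[:, order].astype(np.uint8),
            pos[order] / cfg.B,
            label=label,
            block_length=cfg.B,
        )


def simulate_selection(
    config: SimConfig,
    scenario: SelectionScenario,
    rng: np.random.Generator | None = None,
) -> HaplotypeMatrix:
    """One replicate under ``scenario``; deterministic given ``config.seed``
    (or an explicit ``rng``).  Raises :class:`ConvergenceError` if the
    conditioning rule is not met within ``scenario.restart_cap`` restarts."""
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    twoN = 2 * cfg.N
    block = _Block(cfg, rng)
    for _ in range(cfg.t):  # neutral burn-in to mutation-drift equilibrium
        block.step()
    if scenario.kind == "neutral":
        return block.sample(cfg.z)

    fitness = np.array(
        [1.0, 1.0 + scenario.SaA / twoN, 1.0 + scenario.SAA / twoN]
    )
    snap_S, snap_pos = block.S.copy(), block.pos.copy()
    target = math.ceil(scenario.incomplete_freq * twoN)
    hold = int(scenario.balancing_hold * cfg.N)

    for attempt in range(scenario.restart_cap):
        block.S, block.pos = snap_S.copy(), snap_pos.copy()
        block.sel = np.zeros(twoN, dtype=bool)
        block.sel[rng.integers(twoN)] = True
        gens = 0
        while True:
            block.step(fitness)
            gens += 1
            k = int(block.sel.sum())
            if scenario.kind == "complete_sweep":
                if k == 0:
                    break
                if k == twoN:
                    return block.sample(cfg.z)
            elif scenario.kind == "incomplete_sweep":
                if k == 0:
                    break
                if k >= target:
                    return block.sample(cfg.z)
            else:  # balancing
                if k == 0 or k == twoN:
                    break
                if gens >= hold:
                    return block.sample(cfg.z)
    raise ConvergenceError(
        f"{scenario.kind}: allele trajectory not accepted in "
        f"{scenario.restart_cap} attempts (N={cfg.N}, SAA={scenario.SAA}, "
        f"SaA={scenario.SaA})"
    )


def simulate_selection_batch(
    config: SimConfig,
    scenario: SelectionScenario,
    reps: int,
    seed: int | None = None,
) -> list[HaplotypeMatrix]:
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    return [
        simulate_selection(config, scenario, rng=np.random.default_rng(child))
        for child in root.spawn(reps)
    ]
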