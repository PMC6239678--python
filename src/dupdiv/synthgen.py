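"""Synthetic 1000-Genomes-like cohorts for exercising the CNV diversity audit.

A cohort is a set of diploid samples with (i) per-chromosome copy-number
genotypes at a set of CNV regions laid out on one chromosome, (ii)
background SNVs in Hardy–Weinberg proportions with derived-allele counts
drawn from the neutral frequency spectrum (P(count = i) ∝ 1/i), in the CNV
and both flanking regions alike, and (iii) paralogous sequence variants
(PSVs): positions inside the CNV where the two duplicate copies carry fixed
differences, so that every duplication carrier — whose reads from both
copies are collapsed onto the reference locus — is called heterozygous,
while every reference-copy-number sample is homozygous reference.

PSVs are the mechanism by which collapsed duplications inflate diversity
and break HWE in carriers; :func:`spike_igc_like_variants` adds the
confounder channel of historical interlocus gene conversion, which raises
carrier diversity through ordinary in-HWE intermediate-frequency variants
and therefore survives HWE filtering.

The generator plants a :class:`SynthTruth` channel (PSV positions, carrier
ids, the closed-form expected per-site Δπ) against which pipeline recovery
is tested.  Background SNVs are independent sites — no linkage
disequilibrium — which is sufficient for pipeline testing; mechanistic
haplotype structure lives in :mod:`dupdiv.dupsim`.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnvdiv import CNStatus, classify_cn
from .msio import CNVTable, GenotypeMatrix, write_cnv_table, write_vcf
from .sumstats import harmonic


@dataclass
class SynthConfig:
    """Cohort-level generator parameters.

    ``dup_freq`` is the per-chromosome frequency of the duplicated (CN2)
    allele; ``psv_count`` the number of fixed paralog differences planted
    per CNV; ``theta_site`` the per-site scaled diversity of the background
    SNVs.  Flanks follow the audit's rule: same length as the CNV, separated
    by ``flank_gap``.
    """

    n_samples: int = 100
    n_cnvs: int = 60
    cnv_length: int = 5000
    dup_freq: float = 0.3
    psv_count: int = 2
    theta_site: float = 0.001
    flank_gap: int = 1000
    deletion_freq: float = 0.0
    chrom: str = "chr1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.dup_freq < 1:
            raise ValueError("dup_freq must be in (0, 1)")
        if self.psv_count < 0 or self.n_cnvs < 1 or self.n_samples < 2:
            raise ValueError("invalid cohort sizes")
        if self.deletion_freq < 0 or self.dup_freq + self.deletion_freq >= 1:
            raise ValueError("deletion_freq + dup_freq must be < 1")

    @property
    def expected_cnr(self) -> float:
        return self.n_samples * (1 - self.dup_freq - self.deletion_freq) ** 2

    @property
    def expected_cnplus(self) -> float:
        return self.n_samples * (1 - (1 - self.dup_freq) ** 2)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SynthTruth:
    """Planted parameters per CNV, the recovery target for pipeline tests."""

    psv_positions: dict[str, list[int]]
    igc_positions: dict[str, list[int]]
    carriers: dict[str, list[str]]
    expected_delta_pi: dict[str, float]
    config: SynthConfig

    def to_json(self, path) -> None:
        payload = {
            "psv_positions": self.psv_positions,
            "igc_positions": self.igc_positions,
            "carriers": self.carriers,
            "expected_delta_pi": self.expected_delta_pi,
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            psv_positions={k: list(v) for k, v in d["psv_positions"].items()},
            igc_positions={k: list(v) for k, v in d["igc_positions"].items()},
            carriers={k: list(v) for k, v in d["carriers"].items()},
            expected_delta_pi=d["expected_delta_pi"],
            config=SynthConfig(**d["config"]),
        )


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    cnv_table: CNVTable
    truth: SynthTruth
    config: SynthConfig


def expected_psv_delta_pi(k: int, length: float, m: int = 20) -> float:
    """Closed-form per-site Δπ(CN+ − CNr) from k obligate-heterozygote PSVs:
    each contributes 2m/(2m−1) · 2 · 0.5 · 0.5 to the CN+ group of m diploids
    and nothing to CNr."""
    if m < 1:
        return 0.0
    return k * (2.0 * m / (2.0 * m - 1)) * 0.5 / length


def _neutral_spectrum_counts(rng: np.random.Generator, n_alleles: int,
                             size: int) -> np.ndarray:
    i = np.arange(1, n_alleles)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def generate_cohort(config: SynthConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Generate one cohort; deterministic given ``config.seed`` (or ``rng``).

    Warns (and flags nothing else) when the expected CNr or CN+ group size
    is below 20, since the audit's eligibility rule would then starve.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if min(config.expected_cnr, config.expected_cnplus) < 20:
        warnings.warn(
            "expected group sizes below 20; most CNVs will be ineligible",
            stacklevel=2,
        )
    n = config.n_samples
    L = config.cnv_length
    gap = config.flank_gap
    sample_ids = [f"s{i:04d}" for i in range(n)]

    # CNV slots spaced so that no flank overlaps a neighboring CNV footprint
    period = 3 * L + 2 * gap + 1000
    first = L + gap + 1000

    mean_snvs = config.theta_site * L * harmonic(2 * n - 1)

    cnv_rows = []
    psv_positions: dict[str, list[int]] = {}
    carriers: dict[str, list[str]] = {}
    expected: dict[str, float] = {}
    all_pos: list[np.ndarray] = []
    all_gts: list[np.ndarray] = []

    allele_choices = np.array([0, 1, 2])
    allele_p = np.array(
        [config.deletion_freq, 1 - config.deletion_freq - config.dup_freq,
         config.dup_freq]
    )

    for j in range(config.n_cnvs):
        rid = f"cnv{j + 1}"
        start = first + j * period
        end = start + L
        cn = rng.choice(allele_choices, size=(n, 2), p=allele_p)
        statuses = [classify_cn((int(a), int(b))) for a, b in cn]
        carrier_ids = [
            s for s, st in zip(sample_ids, statuses) if st is CNStatus.CN_PLUS
        ]
        carriers[rid] = carrier_ids
        is_carrier = np.array([st is CNStatus.CN_PLUS for st in statuses])
        for s, (a, b) in zip(sample_ids, cn):
            cnv_rows.append((rid, config.chrom, start, end, s, int(a), int(b)))

        regions = {
            "flank5": start - gap - L,
            "cnv": start,
            "flank3": end + gap,
        }
        for rtype, r_start in regions.items():
            n_bg = rng.poisson(mean_snvs)
            n_psv = config.psv_count if rtype == "cnv" else 0
            total = n_bg + n_psv
            if total == 0:
                if rtype == "cnv":
                    psv_positions[rid] = []
                continue
            offs = rng.choice(L, size=total, replace=False)
            pos = np.sort(offs[:n_bg]) + r_start
            gts = np.empty((n_bg, n), dtype=np.int8)
            if n_bg:
                derived = _neutral_spectrum_counts(rng, 2 * n, n_bg)
                p = derived / (2.0 * n)
                gts = rng.binomial(2, p[:, None], size=(n_bg, n)).astype(np.int8)
            if n_psv:
                psv_pos = np.sort(offs[n_bg:]) + r_start
                psv_positions[rid] = [int(p_) for p_ in psv_pos]
                psv_gts = np.where(is_carrier[None, :], 1, 0).astype(np.int8)
                psv_gts = np.repeat(psv_gts, n_psv, axis=0)
                pos = np.concatenate([pos, psv_pos])
                gts = np.concatenate([gts, psv_gts], axis=0)
            elif rtype == "cnv":
                psv_positions[rid] = []
            all_pos.append(pos)
            all_gts.append(gts)
        expected[rid] = expected_psv_delta_pi(config.psv_count, L)

    if all_pos:
        pos = np.concatenate(all_pos)
        gts = np.vstack(all_gts)
        order = np.argsort(pos)
        pos, gts = pos[order], gts[order]
    else:
        pos = np.empty(0, dtype=np.int64)
        gts = np.zeros((0, n), dtype=np.int8)

    gm = GenotypeMatrix(sample_ids, config.chrom, pos, gts)
    table = CNVTable(
        pd.DataFrame(cnv_rows, columns=list(CNVTable.REQUIRED))
    )
    truth = SynthTruth(
        psv_positions=psv_positions,
        igc_positions={rid: [] for rid in psv_positions},
        carriers=carriers,
        expected_delta_pi=expected,
        config=config,
    )
    return Cohort(genotypes=gm, cnv_table=table, truth=truth, config=config)


def spike_igc_like_variants(cohort: Cohort, rate: float,
                            rng: np.random.Generator | None = None) -> Cohort:
    """Add a Poisson(``rate``) number per CNV of intermediate-frequency,
    in-HWE variants segregating among duplication carriers only — the
    signature of historical gene conversion between copies, which inflates
    carrier π without breaking HWE.  ``rate=0`` returns an identical cohort.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(cohort.config.seed)
    gm = cohort.genotypes
    new_pos: list[int] = []
    new_gts: list[np.ndarray] = []
    igc_positions = {k: list(v) for k, v in cohort.truth.igc_positions.items()}
    if rate > 0:
        sample_index = {s: i for i, s in enumerate(gm.sample_ids)}
        taken = set(gm.positions.tolist())
        for _, row in cohort.cnv_table.regions().iterrows():
            rid = str(row["region_id"])
            start, end = int(row["start"]), int(row["end"])
            k = rng.poisson(rate)
            carrier_cols = [sample_index[s] for s in cohort.truth.carriers[rid]]
            for _ in range(k):
                while True:
                    p_pos = int(rng.integers(start, end))
                    if p_pos not in taken:
                        taken.add(p_pos)
                        break
                freq = rng.uniform(0.25, 0.75)
                g = np.zeros(gm.n_samples, dtype=np.int8)
                if carrier_cols:
                    g[carrier_cols] = rng.binomial(2, freq, size=len(carrier_cols))
                new_pos.append(p_pos)
                new_gts.append(g)
                igc_positions[rid].append(p_pos)

    if new_pos:
        pos = np.concatenate([gm.positions, np.array(new_pos, dtype=np.int64)])
        gts = np.vstack([gm.alt_counts, np.vstack(new_gts)])
        order = np.argsort(pos)
        gm = GenotypeMatrix(gm.sample_ids, gm.chrom, pos[order], gts[order])
    else:
        gm = GenotypeMatrix(
            list(gm.sample_ids), gm.chrom, gm.positions.copy(),
            gm.alt_counts.copy(),
        )
    truth = SynthTruth(
        psv_positions={k: list(v) for k, v in cohort.truth.psv_positions.items()},
        igc_positions=igc_positions,
        carriers={k: list(v) for k, v in cohort.truth.carriers.items()},
        expected_delta_pi=dict(cohort.truth.expected_delta_pi),
        config=cohort.config,
    )
    return Cohort(
        genotypes=gm, cnv_table=cohort.cnv_table, truth=truth,
        config=cohort.config,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write cohort.vcf, cnvs.tsv and truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "cnv": outdir / "cnvs.tsv",
        "truth": outdir / "truth.json",
    }
    contig_len = (
        int(cohort.cnv_table.df["end"].max())
        + cohort.config.cnv_length
        + cohort.config.flank_gap
        + 1
        if len(cohort.cnv_table.df)
        else None
    )
    write_vcf(cohort.genotypes, paths["vcf"], contig_length=contig_len)
    write_cnv_table(cohort.cnv_table, paths["cnv"])
    cohort.truth.to_json(paths["truth"])
    return paths
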