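"""CNV-stratified nucleotide-diversity audit.

Given SNV genotypes and per-sample copy-number genotypes over a set of CNV
regions, the pipeline asks whether SNV diversity inside each CNV differs
between duplication carriers and reference-copy-number samples — the
signature expected when reads from unresolved duplicate copies are
collapsed onto one reference locus.

Procedure, per population:

1. classify every sample at every CNV as CN− (deletion carrier), CNr
   (CN1/CN1 reference) or CN+ (at least one duplicated chromosome);
2. keep CNVs with at least ``min_group`` CNr and CN+ samples, and draw one
   random group of ``n_per_group`` samples from each status;
3. build 5′/3′ flanking regions of the same length as the CNV, separated
   from it by a ``flank_gap`` buffer; flank SNVs overlapping any other CNV
   are masked out;
4. compute per-site π per region (5′ flank / CNV / 3′ flank) and group;
   CNVs with fewer than ``min_snvs`` SNVs in any region are excluded;
5. compare CN+ against CNr per region type with a paired t test over CNVs;
6. within the CNV region, compute per group the fraction of polymorphic
   SNVs failing the Hardy–Weinberg exact test at ``hwe_alpha``, compare the
   fractions (all CNVs, and excluding CNVs whose CNr fraction is zero), and
   recompute π restricted to SNVs in HWE within the group.

CN− samples are classified but excluded from all comparisons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import msio
from .msio import MISSING, CNVTable, GenotypeMatrix
from .sumstats import genotype_pi, hwe_exact_test

REGION_TYPES = ("flank5", "cnv", "flank3")
GROUPS = ("CNr", "CN+")


class CNStatus(enum.Enum):
    CN_MINUS = "CN-"
    CN_REF = "CNr"
    CN_PLUS = "CN+"


class FlankError(ValueError):
    """A flank region cannot be constructed (e.g. runs below coordinate 0)."""


def classify_cn(cn_allele_pair: tuple[int, int]) -> CNStatus:
    """Copy-number status from a per-chromosome CN allele pair.

    CN− : carries a deletion and no duplication (CN0/CN0 or CN0/CN1);
    CNr : reference single copy on both chromosomes (CN1/CN1);
    CN+ : at least one chromosome with two or more copies.
    """
    a, b = cn_allele_pair
    if a < 0 or b < 0:
        raise ValueError("CN alleles must be non-negative")
    if max(a, b) >= 2:
        return CNStatus.CN_PLUS
    if min(a, b) == 0:
        return CNStatus.CN_MINUS
    return CNStatus.CN_REF


def classify_samples(
    cnv_table: CNVTable, region_id: str, samples: Sequence[str] | None = None
) -> dict[str, CNStatus]:
    alleles = cnv_table.alleles(region_id)
    if samples is not None:
        alleles = {s: alleles[s] for s in samples if s in alleles}
    return {s: classify_cn(pair) for s, pair in alleles.items()}


def select_eligible_cnvs(
    cnv_table: CNVTable,
    population_samples: Sequence[str] | None = None,
    min_group: int = 20,
) -> list[str]:
    """CNVs with at least ``min_group`` CNr and CN+ samples in the population."""
    out = []
    for rid in cnv_table.region_ids:
        statuses = classify_samples(cnv_table, rid, population_samples)
        vals = list(statuses.values())
        if (
            vals.count(CNStatus.CN_REF) >= min_group
            and vals.count(CNStatus.CN_PLUS) >= min_group
        ):
            out.append(rid)
    return out


def draw_groups(
    statuses: Mapping[str, CNStatus],
    n_per_group: int = 20,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Uniform draws without replacement of CNr and CN+ sample groups.

    Deterministic given ``seed`` (or an explicit ``rng``); sample ids are
    sorted before drawing so determinism does not depend on dict order.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    cnr = sorted(s for s, st in statuses.items() if st is CNStatus.CN_REF)
    cnp = sorted(s for s, st in statuses.items() if st is CNStatus.CN_PLUS)
    if len(cnr) < n_per_group or len(cnp) < n_per_group:
        raise ValueError(
            f"insufficient samples: {len(cnr)} CNr, {len(cnp)} CN+ "
            f"(need {n_per_group} each)"
        )
    return (
        list(rng.choice(cnr, size=n_per_group, replace=False)),
        list(rng.choice(cnp, size=n_per_group, replace=False)),
    )


def define_flanks(
    cnv_region: tuple[str, int, int],
    cnv_table: CNVTable,
    region_id: str | None = None,
    flank_gap: int = 1000,
) -> tuple[tuple[str, int, int], tuple[str, int, int], list[tuple[int, int]]]:
    """Same-length flanks ``flank_gap`` bp away from the CNV boundaries.

    Returns (flank5, flank3, masked_intervals) where masked_intervals are the
    stretches of either flank overlapping other CNVs in the table — SNVs
    there must not enter π.  Raises :class:`FlankError` if the 5′ flank would
    extend below coordinate 0.
    """
    chrom, start, end = cnv_region
    length = end - start
    f5 = (chrom, start - flank_gap - length, start - flank_gap)
    f3 = (chrom, end + flank_gap, end + flank_gap + length)
    if f5[1] < 0:
        raise FlankError(f"5' flank of {cnv_region} extends below coordinate 0")
    masked: list[tuple[int, int]] = []
    for _, row in cnv_table.regions().iterrows():
        if region_id is not None and row["region_id"] == region_id:
            continue
        if str(row["chrom"]) != chrom:
            continue
        o_start, o_end = int(row["start"]), int(row["end"])
        if region_id is None and (o_start, o_end) == (start, end):
            continue
        for _, lo, hi in (f5, f3):
            a, b = max(lo, o_start), min(hi, o_end)
            if a < b:
                masked.append((a, b))
    return f5, f3, masked


def apply_min_snv_filter(counts: pd.DataFrame, min_snvs: int = 2) -> list[str]:
    """Retain CNVs whose flank5, cnv and flank3 regions each have at least
    ``min_snvs`` SNVs.  ``counts`` needs columns cnv_id, region_type, n_snvs."""
    if not len(counts):
        return []
    wide = counts.pivot_table(
        index="cnv_id", columns="region_type", values="n_snvs", aggfunc="min"
    )
    ok = wide.reindex(columns=list(REGION_TYPES)).fillna(0).min(axis=1) >= min_snvs
    return [str(i) for i in wide.index[ok]]


@dataclass
class HWEFractionResult:
    cnv_id: str
    group: str
    fraction: float
    n_snvs: int
    p_values: np.ndarray = field(repr=False, default=None)


def _site_genotype_counts(alt_counts: np.ndarray):
    valid = alt_counts != MISSING
    m = valid.sum(axis=1)
    g = np.where(valid, alt_counts, 0)
    n_het = (g == 1).sum(axis=1)
    n_alt_hom = np.where(valid, alt_counts == 2, False).sum(axis=1)
    n_ref_hom = m - n_het - n_alt_hom
    return n_ref_hom, n_het, n_alt_hom, m


def hwe_fractions(
    genotypes: GenotypeMatrix | np.ndarray,
    cnv_id: str = "",
    group: str = "",
    alpha: float = 0.05,
) -> HWEFractionResult | None:
    """Fraction of the group's polymorphic SNVs failing the exact HWE test.

    Sites monomorphic within the group are excluded from the denominator.
    Returns None when the group has no polymorphic SNV in the region (the
    CNV is then dropped from the HWE comparison).
    """
    arr = (
        genotypes.alt_counts
        if isinstance(genotypes, GenotypeMatrix)
        else np.asarray(genotypes)
    )
    if arr.shape[0] == 0:
        return None
    n_ref, n_het, n_alt, m = _site_genotype_counts(arr)
    alt_alleles = n_het + 2 * n_alt
    poly = (alt_alleles > 0) & (alt_alleles < 2 * m)
    if not poly.any():
        return None
    pvals = np.array(
        [
            hwe_exact_test(int(r), int(h), int(a))
            for r, h, a in zip(n_ref[poly], n_het[poly], n_alt[poly])
        ]
    )
    return HWEFractionResult(
        cnv_id=cnv_id,
        group=group,
        fraction=float((pvals < alpha).mean()),
        n_snvs=int(poly.sum()),
        p_values=pvals,
    )


def hwe_filtered_pi(
    genotypes: GenotypeMatrix | np.ndarray,
    region_length: float,
    alpha: float = 0.05,
) -> float:
    """Per-site π restricted to SNVs in HWE (p >= alpha) within the group."""
    arr = (
        genotypes.alt_counts
        if isinstance(genotypes, GenotypeMatrix)
        else np.asarray(genotypes)
    )
    if arr.shape[0] == 0:
        return 0.0
    n_ref, n_het, n_alt, _ = _site_genotype_counts(arr)
    keep = np.array(
        [
            hwe_exact_test(int(r), int(h), int(a)) >= alpha
            for r, h, a in zip(n_ref, n_het, n_alt)
        ]
    )
    return genotype_pi(arr[keep], region_length)


@dataclass
class PairedComparison:
    """Paired CN+ vs CNr contrast over CNVs (deltas are CN+ − CNr)."""

    n: int
    mean_difference: float
    percent_increase: float
    t_statistic: float
    p_value: float

    @property
    def df(self) -> int:
        return self.n - 1


def paired_comparison(
    values_cnr: Sequence[float], values_cnplus: Sequence[float]
) -> PairedComparison:
    """Two-sided paired t test of per-CNV values; percent increase is the
    ratio of the mean delta to the mean CNr value (x100)."""
    x = np.asarray(values_cnr, dtype=float)
    y = np.asarray(values_cnplus, dtype=float)
    if x.shape != y.shape:
        raise ValueError("groups must be aligned per CNV")
    if x.size < 2:
        raise ValueError("paired comparison needs at least 2 CNVs")
    deltas = y - x
    mean_diff = float(deltas.mean())
    pct = 100.0 * mean_diff / x.mean() if x.mean() != 0 else np.nan
    sd = deltas.std(ddof=1)
    if sd == 0:
        return PairedComparison(x.size, mean_diff, float(pct), np.nan, np.nan)
    t, p = sps.ttest_rel(y, x)
    return PairedComparison(x.size, mean_diff, float(pct), float(t), float(p))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineReport:
    """All pipeline outputs as tidy DataFrames plus the seed that fixed the
    group draws."""

    region_pi: pd.DataFrame
    paired_tests: pd.DataFrame
    hwe_fractions: pd.DataFrame
    hwe_tests: pd.DataFrame
    filtered_tests: pd.DataFrame
    exclusions: pd.DataFrame
    flanks: pd.DataFrame
    seed: int

    def summary(self) -> str:
        lines = [f"cnvdiv pipeline report (seed={self.seed})"]
        n_cnvs = self.region_pi[["population", "cnv_id"]].drop_duplicates().shape[0]
        lines.append(
            f"analyzed {n_cnvs} CNV x population combinations; "
            f"{len(self.exclusions)} excluded"
        )
        for _, r in self.paired_tests.iterrows():
            lines.append(
                f"  pi {r['scope']:>8s} {r['region_type']:>6s}: "
                f"mean d(pi) = {r['mean_difference']:+.3e} "
                f"({r['percent_increase']:+.1f}%), paired t p = {r['p_value']:.3g} "
                f"(n={int(r['n'])})"
            )
        for _, r in self.hwe_tests.iterrows():
            lines.append(
                f"  HWE-failure fraction {r['scope']:>8s} [{r['subset']}]: "
                f"d = {r['mean_difference']:+.3f}, p = {r['p_value']:.3g} "
                f"(n={int(r['n'])})"
            )
        for _, r in self.filtered_tests.iterrows():
            lines.append(
                f"  HWE-filtered pi {r['scope']:>8s} cnv: "
                f"d(pi) = {r['mean_difference']:+.3e}, p = {r['p_value']:.3g} "
                f"(n={int(r['n'])})"
            )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.region_pi.to_csv(outdir / "region_pi.tsv", sep="\t", index=False)
        self.paired_tests.to_csv(outdir / "paired_tests.tsv", sep="\t", index=False)
        self.hwe_fractions.to_csv(outdir / "hwe_fractions.tsv", sep="\t", index=False)
        self.hwe_tests.to_csv(outdir / "hwe_tests.tsv", sep="\t", index=False)
        self.filtered_tests.to_csv(
            outdir / "filtered_tests.tsv", sep="\t", index=False
        )
        self.exclusions.to_csv(outdir / "exclusions.log", sep="\t", index=False)
        if len(self.flanks):
            msio.write_bed(self.flanks, outdir / "flanks.bed")
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def _normalize_populations(
    populations, cnv_table: CNVTable
) -> dict[str, list[str]]:
    if populations is None:
        return {"ALL": cnv_table.samples}
    if isinstance(populations, Mapping):
        return {str(k): list(v) for k, v in populations.items()}
    return {"ALL": list(populations)}


def run_pipeline(
    snv_source,
    cnv_table: CNVTable,
    populations=None,
    seed: int = 0,
    n_per_group: int = 20,
    min_group: int = 20,
    hwe_alpha: float = 0.05,
    flank_gap: int = 1000,
    min_snvs: int = 2,
) -> PipelineReport:
    """Run the full audit.  ``snv_source`` is a VCF path, a
    :class:`GenotypeMatrix` or a chrom -> matrix dict; ``populations`` is a
    name -> sample-list mapping (or a flat list, or None for all samples in
    the CNV table).  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    pops = _normalize_populations(populations, cnv_table)
    if isinstance(snv_source, (str, Path)):
        snv_source = msio.load_vcf_by_chrom(snv_source)

    pi_rows, excl_rows, hwe_rows, filt_rows, flank_rows = [], [], [], [], []
    filtered_pi: dict[tuple[str, str], dict[str, float]] = {}

    for pop_name, pop_samples in pops.items():
        eligible = select_eligible_cnvs(cnv_table, pop_samples, min_group=min_group)
        for cnv_id in sorted(eligible):
            chrom, start, end = cnv_table.region(cnv_id)
            length = end - start
            statuses = classify_samples(cnv_table, cnv_id, pop_samples)
            cnr_ids, cnp_ids = draw_groups(statuses, n_per_group, rng=rng)
            try:
                f5, f3, masked = define_flanks(
                    (chrom, start, end), cnv_table, region_id=cnv_id,
                    flank_gap=flank_gap,
                )
            except FlankError as exc:
                excl_rows.append((pop_name, cnv_id, f"unusable_flank: {exc}"))
                continue
            flank_rows.append((chrom, f5[1], f5[2], f"{cnv_id}_flank5"))
            flank_rows.append((chrom, f3[1], f3[2], f"{cnv_id}_flank3"))

            regions = {"flank5": f5, "cnv": (chrom, start, end), "flank3": f3}
            group_gm: dict[tuple[str, str], GenotypeMatrix] = {}
            union_counts: dict[str, int] = {}
            cand_rows = []
            for rtype, reg in regions.items():
                gm = msio.read_snv_genotypes(snv_source, reg)
                if rtype != "cnv" and masked:
                    in_mask = np.zeros(gm.n_sites, dtype=bool)
                    for lo, hi in masked:
                        in_mask |= (gm.positions >= lo) & (gm.positions < hi)
                    gm = gm.drop_positions(in_mask)
                union = gm.subset_samples(cnr_ids + cnp_ids)
                _, het, alt_hom, m = _site_genotype_counts(union.alt_counts)
                alt = het + 2 * alt_hom
                union_counts[rtype] = int(((alt > 0) & (alt < 2 * m)).sum())
                for group, ids in (("CNr", cnr_ids), ("CN+", cnp_ids)):
                    sub = gm.subset_samples(ids)
                    group_gm[(rtype, group)] = sub
                    _, ghet, galt_hom, gm_ = _site_genotype_counts(sub.alt_counts)
                    galt = ghet + 2 * galt_hom
                    n_poly = int(((galt > 0) & (galt < 2 * gm_)).sum())
                    cand_rows.append(
                        dict(
                            population=pop_name,
                            cnv_id=cnv_id,
                            region_type=rtype,
                            group=group,
                            pi=genotype_pi(sub, length),
                            n_snvs=n_poly,
                            n_samples=len(ids),
                        )
                    )
            if min(union_counts.values()) < min_snvs:
                excl_rows.append(
                    (
                        pop_name,
                        cnv_id,
                        "min_snv_filter: "
                        + ", ".join(f"{k}={v}" for k, v in union_counts.items()),
                    )
                )
                continue
            pi_rows.extend(cand_rows)

            frs = {
                g: hwe_fractions(
                    group_gm[("cnv", g)], cnv_id=cnv_id, group=g, alpha=hwe_alpha
                )
                for g in GROUPS
            }
            if any(fr is None for fr in frs.values()):
                excl_rows.append(
                    (pop_name, cnv_id, "zero_snv_group: HWE comparison skipped")
                )
            else:
                for g, fr in frs.items():
                    hwe_rows.append(
                        dict(
                            population=pop_name,
                            cnv_id=cnv_id,
                            group=g,
                            fraction=fr.fraction,
                            n_snvs=fr.n_snvs,
                        )
                    )
            filtered_pi[(pop_name, cnv_id)] = {
                g: hwe_filtered_pi(group_gm[("cnv", g)], length, alpha=hwe_alpha)
                for g in GROUPS
            }

    region_pi = pd.DataFrame(
        pi_rows,
        columns=[
            "population", "cnv_id", "region_type", "group", "pi", "n_snvs",
            "n_samples",
        ],
    )
    hwe_df = pd.DataFrame(
        hwe_rows, columns=["population", "cnv_id", "group", "fraction", "n_snvs"]
    )
    exclusions = pd.DataFrame(
        excl_rows, columns=["population", "cnv_id", "reason"]
    )
    flanks = pd.DataFrame(flank_rows, columns=["chrom", "start", "end", "name"])

    scopes = [("pooled", None)]
    if len(pops) > 1:
        scopes += [(p, p) for p in pops]

    paired_rows = []
    for scope, pop in scopes:
        sub = region_pi if pop is None else region_pi[region_pi["population"] == pop]
        for rtype in REGION_TYPES:
            rsub = sub[sub["region_type"] == rtype]
            piv = rsub.pivot_table(
                index=["population", "cnv_id"], columns="group", values="pi"
            )
            if len(piv) < 2 or piv.isna().any().any():
                continue
            cmp_ = paired_comparison(piv["CNr"], piv["CN+"])
            paired_rows.append(
                dict(
                    scope=scope,
                    region_type=rtype,
                    n=cmp_.n,
                    mean_difference=cmp_.mean_difference,
                    percent_increase=cmp_.percent_increase,
                    t_statistic=cmp_.t_statistic,
                    p_value=cmp_.p_value,
                )
            )
    paired_tests = pd.DataFrame(
        paired_rows,
        columns=[
            "scope", "region_type", "n", "mean_difference", "percent_increase",
            "t_statistic", "p_value",
        ],
    )

    hwe_test_rows = []
    for scope, pop in scopes:
        sub = hwe_df if pop is None else hwe_df[hwe_df["population"] == pop]
        piv = sub.pivot_table(
            index=["population", "cnv_id"], columns="group", values="fraction"
        )
        if not len(piv):
            continue
        piv = piv.dropna()
        for subset_name, piv_sub in (
            ("all", piv),
            ("cnr_fraction_nonzero", piv[piv["CNr"] > 0]),
        ):
            if len(piv_sub) < 2:
                continue
            cmp_ = paired_comparison(piv_sub["CNr"], piv_sub["CN+"])
            hwe_test_rows.append(
                dict(
                    scope=scope,
                    subset=subset_name,
                    n=cmp_.n,
                    mean_difference=cmp_.mean_difference,
                    t_statistic=cmp_.t_statistic,
                    p_value=cmp_.p_value,
                )
            )
    hwe_tests = pd.DataFrame(
        hwe_test_rows,
        columns=["scope", "subset", "n", "mean_difference", "t_statistic", "p_value"],
    )

    filt_test_rows = []
    filt_df = pd.DataFrame(
        [
            dict(population=p, cnv_id=c, CNr=v["CNr"], CNplus=v["CN+"])
            for (p, c), v in filtered_pi.items()
            # only CNVs that survived the min-SNV filter enter the comparison
            if c in set(region_pi[region_pi["population"] == p]["cnv_id"])
        ]
    )
    for scope, pop in scopes:
        sub = filt_df if pop is None else filt_df[filt_df["population"] == pop]
        if len(sub) < 2:
            continue
        cmp_ = paired_comparison(sub["CNr"], sub["CNplus"])
        filt_test_rows.append(
            dict(
                scope=scope,
                region_type="cnv",
                n=cmp_.n,
                mean_difference=cmp_.mean_difference,
                percent_increase=cmp_.percent_increase,
                t_statistic=cmp_.t_statistic,
                p_value=cmp_.p_value,
            )
        )
    filtered_tests = pd.DataFrame(
        filt_test_rows,
        columns=[
            "scope", "region_type", "n", "mean_difference", "percent_increase",
            "t_statistic", "p_value",
        ],
    )

    return PipelineReport(
        region_pi=region_pi,
        paired_tests=paired_tests,
        hwe_fractions=hwe_df,
        hwe_tests=hwe_tests,
        filtered_tests=filtered_tests,
        exclusions=exclusions,
        flanks=flanks,
        seed=seed,
    )
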