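"""Readers and writers for the package's file formats.

This is the only I/O boundary of the package.  It handles

* Hudson ``ms``-format haplotype samples (the lingua franca of coalescent
  and forward simulators),
* SNV genotypes from VCF 4.x (via :mod:`cyvcf2`),
* copy-number genotype tables (canonical TSV, or symbolic-allele VCF),
* BED3 interval files.

All genomic intervals are half-open and 0-based internally; VCF positions
(1-based) are converted on read and write.  Missing genotypes are carried
as ``-1`` and excluded per-site from allele counts downstream — they are
never imputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MATRIX_LABELS = frozenset(
    {"single_copy", "original", "duplicated", "collapsed", "empirical"}
)

MISSING = -1


class MsParseError(ValueError):
    """Raised when ms-format text violates the segsites/positions/row contract."""


@dataclass(eq=False)
class HaplotypeMatrix:
    """Binary haplotype sample: sequences x segregating sites.

    ``alleles`` is an (n_sequences, n_sites) array of 0/1 with 0 = ancestral
    and 1 = derived.  ``positions`` are strictly increasing site coordinates:
    fractions of the block in [0, 1) for simulator output, or base pairs for
    empirical data.  ``label`` records the sampling mode that produced the
    matrix; ``block_length`` the length in bp of the region the sites live on
    (used to turn region-wise statistics into per-site ones).
    """

    alleles: np.ndarray
    positions: np.ndarray
    label: str = "empirical"
    block_length: float = 1.0

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D array")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError(
                f"{self.positions.size} positions for {self.alleles.shape[1]} columns"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        if self.label not in MATRIX_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.block_length <= 0:
            raise ValueError("block_length must be positive")

    @property
    def n_sequences(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.alleles.shape == other.alleles.shape
            and np.array_equal(self.alleles, other.alleles)
            and np.allclose(self.positions, other.positions, rtol=0, atol=0)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HaplotypeMatrix(n_sequences={self.n_sequences}, "
            f"n_sites={self.n_sites}, label={self.label!r})"
        )


# ---------------------------------------------------------------------------
# ms format
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^[01]+$")


def parse_ms(
    text: str, label: str = "empirical", block_length: float = 1.0
) -> list[HaplotypeMatrix]:
    """Parse Hudson ms-format text into one :class:`HaplotypeMatrix` per replicate.

    The first line is treated as the command line; its second whitespace token,
    when integral, fixes the expected number of sequences per replicate (ms
    prints no haplotype rows when ``segsites: 0``, so the row count must come
    from the header in that case).
    """
    lines = text.splitlines()
    default_n: int | None = None
    if lines:
        toks = lines[0].split()
        if len(toks) >= 3 and toks[1].isdigit() and toks[2].isdigit():
            default_n = int(toks[1])

    # replicate blocks are delimited by lines that are exactly "//"
    starts = [i for i, ln in enumerate(lines) if ln.strip() == "//"]
    out: list[HaplotypeMatrix] = []
    for rep, start in enumerate(starts):
        stop = starts[rep + 1] if rep + 1 < len(starts) else len(lines)
        block = [ln.strip() for ln in lines[start + 1 : stop] if ln.strip()]
        if not block or not block[0].startswith("segsites:"):
            raise MsParseError(f"replicate {rep}: missing 'segsites:' line")
        try:
            segsites = int(block[0].split(":", 1)[1])
        except ValueError as exc:
            raise MsParseError(f"replicate {rep}: bad segsites line") from exc

        if segsites == 0:
            n = default_n if default_n is not None else 0
            out.append(
                HaplotypeMatrix(
                    np.zeros((n, 0), dtype=np.uint8),
                    np.empty(0),
                    label=label,
                    block_length=block_length,
                )
            )
            continue

        if len(block) < 2 or not block[1].startswith("positions:"):
            raise MsParseError(f"replicate {rep}: missing 'positions:' line")
        positions = np.array(block[1].split(":", 1)[1].split(), dtype=float)
        if positions.size != segsites:
            raise MsParseError(
                f"replicate {rep}: {positions.size} positions for "
                f"segsites: {segsites}"
            )
        rows = []
        for ln in block[2:]:
            if not _ROW_RE.match(ln):
                break
            if len(ln) != segsites:
                raise MsParseError(
                    f"replicate {rep}: haplotype row of length {len(ln)} "
                    f"for segsites: {segsites}"
                )
            rows.append(np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0"))
        if default_n is not None and len(rows) != default_n:
            raise MsParseError(
                f"replicate {rep}: {len(rows)} haplotype rows, header says {default_n}"
            )
        if not rows:
            raise MsParseError(f"replicate {rep}: no haplotype rows")
        out.append(
            HaplotypeMatrix(
                np.vstack(rows), positions, label=label, block_length=block_length
            )
        )
    return out


def write_ms(matrices: Sequence[HaplotypeMatrix], header_comment: str = "") -> str:
    """Serialize matrices as ms-format text (inverse of :func:`parse_ms`).

    Positions are printed with 8 decimals; matrices whose positions carry more
    precision will round-trip only to that precision.
    """
    n = matrices[0].n_sequences if matrices else 0
    parts = [f"ms {n} {len(matrices)}"]
    if header_comment:
        parts.append(f"# {header_comment}")
    for m in matrices:
        parts.append("")
        parts.append("//")
        parts.append(f"segsites: {m.n_sites}")
        if m.n_sites:
            parts.append("positions: " + " ".join(f"{p:.8f}" for p in m.positions))
            for row in m.alleles:
                parts.append("".join("1" if a else "0" for a in row))
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# VCF SNV genotypes
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class GenotypeMatrix:
    """Unphased diploid SNV genotypes for one chromosome.

    ``alt_counts`` is (n_sites, n_samples) holding the number of alternate
    alleles per diploid genotype in {0, 1, 2}, with -1 marking a missing call.
    ``positions`` are 0-based bp, strictly increasing.  Only biallelic SNVs
    are ever stored.
    """

    sample_ids: list[str]
    chrom: str
    positions: np.ndarray
    alt_counts: np.ndarray
    ref: list[str] | None = None
    alt: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int8)
        if self.alt_counts.shape != (self.positions.size, len(self.sample_ids)):
            raise ValueError("alt_counts shape does not match positions x samples")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alt_counts.size:
            vals = np.unique(self.alt_counts)
            if not np.isin(vals, (MISSING, 0, 1, 2)).all():
                raise ValueError("genotype counts must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        unknown = [s for s in samples if s not in index]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        cols = [index[s] for s in samples]
        return GenotypeMatrix(
            list(samples),
            self.chrom,
            self.positions,
            self.alt_counts[:, cols],
            ref=self.ref,
            alt=self.alt,
        )

    def slice_region(self, start: int, end: int) -> "GenotypeMatrix":
        """Sites with start <= pos < end (half-open, 0-based)."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        sl = slice(lo, hi)
        return GenotypeMatrix(
            self.sample_ids,
            self.chrom,
            self.positions[sl],
            self.alt_counts[sl],
            ref=self.ref[sl.start : sl.stop] if self.ref is not None else None,
            alt=self.alt[sl.start : sl.stop] if self.alt is not None else None,
        )

    def drop_positions(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a copy without the sites where ``mask`` is True."""
        keep = ~np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.sample_ids,
            self.chrom,
            self.positions[keep],
            self.alt_counts[keep],
            ref=[r for r, k in zip(self.ref, keep) if k] if self.ref else None,
            alt=[a for a, k in zip(self.alt, keep) if k] if self.alt else None,
        )


def _vcf_has_gt(path: str) -> bool:
    from cyvcf2 import VCF

    return "##FORMAT=<ID=GT" in VCF(path).raw_header


def load_vcf_by_chrom(
    vcf_path: str | Path, samples: Sequence[str] | None = None
) -> dict[str, GenotypeMatrix]:
    """Load all biallelic SNVs of a VCF into per-chromosome genotype matrices.

    Multiallelic and non-SNV records are dropped; the dropped count is logged.
    Raises if the VCF has no GT FORMAT field or if requested samples are absent.
    """
    from cyvcf2 import VCF

    path = str(vcf_path)
    if not _vcf_has_gt(path):
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    vcf = VCF(path, gts012=True)
    if samples is not None:
        missing = set(samples) - set(vcf.samples)
        if missing:
            raise KeyError(f"{path}: unknown samples requested: {sorted(missing)}")
        vcf.set_samples(list(samples))
    ids = list(vcf.samples)

    per_chrom: dict[str, dict[str, list]] = {}
    dropped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.ALT[0] not in "ACGT"
            or rec.REF not in "ACGT"
        ):
            dropped += 1
            continue
        acc = per_chrom.setdefault(
            rec.CHROM, {"pos": [], "gt": [], "ref": [], "alt": []}
        )
        gt = rec.gt_types.astype(np.int8)  # 0/1/2 alt copies, 3 unknown
        gt[gt == 3] = MISSING
        acc["pos"].append(rec.start)  # cyvcf2 .start is 0-based
        acc["gt"].append(gt)
        acc["ref"].append(rec.REF)
        acc["alt"].append(rec.ALT[0])
    if dropped:
        log.info("%s: dropped %d multiallelic/non-SNV records", path, dropped)

    out = {}
    for chrom, acc in per_chrom.items():
        pos = np.array(acc["pos"], dtype=np.int64)
        gts = np.vstack(acc["gt"]) if acc["gt"] else np.zeros((0, len(ids)), np.int8)
        order = np.argsort(pos, kind="stable")
        out[chrom] = GenotypeMatrix(
            ids,
            chrom,
            pos[order],
            gts[order],
            ref=[acc["ref"][i] for i in order],
            alt=[acc["alt"][i] for i in order],
        )
    return out


def read_snv_genotypes(
    vcf_source: str | Path | GenotypeMatrix | dict,
    region: tuple[str, int, int],
    samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Biallelic SNV genotypes overlapping ``region`` = (chrom, start, end).

    ``vcf_source`` may be a VCF path, a preloaded :class:`GenotypeMatrix`, or
    a chrom -> matrix dict as returned by :func:`load_vcf_by_chrom`.
    """
    chrom, start, end = region
    if isinstance(vcf_source, (str, Path)):
        by_chrom = load_vcf_by_chrom(vcf_source, samples=samples)
        gm = by_chrom.get(chrom)
        if gm is None:
            gm = GenotypeMatrix(
                list(samples) if samples else [], chrom, np.empty(0, np.int64),
                np.zeros((0, len(samples) if samples else 0), np.int8),
            )
        return gm.slice_region(start, end)
    if isinstance(vcf_source, dict):
        gm = vcf_source.get(chrom)
        if gm is None:
            any_gm = next(iter(vcf_source.values()))
            gm = GenotypeMatrix(
                any_gm.sample_ids, chrom, np.empty(0, np.int64),
                np.zeros((0, any_gm.n_samples), np.int8),
            )
    else:
        gm = vcf_source
        if gm.chrom != chrom:
            raise ValueError(f"matrix is for {gm.chrom}, region is on {chrom}")
    if samples is not None:
        gm = gm.subset_samples(samples)
    return gm.slice_region(start, end)


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_length: int | None = None) -> None:
    """Write a genotype matrix as an uncompressed VCF 4.2 file."""
    length = contig_length or (int(gm.positions[-1]) + 1 if gm.n_sites else 1)
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for i in range(gm.n_sites):
            ref = gm.ref[i] if gm.ref else "A"
            alt = gm.alt[i] if gm.alt else "G"
            gts = "\t".join(code[int(g)] for g in gm.alt_counts[i])
            fh.write(
                f"{gm.chrom}\t{gm.positions[i] + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# CNV genotype tables
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class CNVTable:
    """Per-sample copy-number genotypes for a set of CNV regions.

    ``df`` is long-format with columns
    ``region_id, chrom, start, end, sample, cn_a, cn_b`` — one row per
    (region, sample), the CN alleles being per-chromosome copy numbers
    (CN1 = reference single copy).
    """

    df: pd.DataFrame

    REQUIRED = ("region_id", "chrom", "start", "end", "sample", "cn_a", "cn_b")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"CNV table missing columns: {sorted(missing)}")
        df = self.df
        if len(df):
            if (df["cn_a"] < 0).any() or (df["cn_b"] < 0).any():
                raise ValueError("negative CN allele")
            if (df["start"] >= df["end"]).any():
                raise ValueError("CNV with start >= end")

    @property
    def region_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["region_id"]))

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def regions(self) -> pd.DataFrame:
        return (
            self.df[["region_id", "chrom", "start", "end"]]
            .drop_duplicates("region_id")
            .reset_index(drop=True)
        )

    def region(self, region_id: str) -> tuple[str, int, int]:
        row = self.df.loc[self.df["region_id"] == region_id].iloc[0]
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    def alleles(self, region_id: str) -> dict[str, tuple[int, int]]:
        sub = self.df.loc[self.df["region_id"] == region_id]
        return {
            str(r["sample"]): (int(r["cn_a"]), int(r["cn_b"]))
            for _, r in sub.iterrows()
        }


_CN_RE = re.compile(r"^(?:CN)?(\d+)[/|](?:CN)?(\d+)$")


def read_cnv_table(source: str | Path) -> CNVTable:
    """Read CNV genotypes from canonical TSV or from a symbolic-allele VCF.

    The TSV schema is ``region_id chrom start end sample cn`` with ``cn``
    like ``CN1/CN2`` (or ``1/2``).  A file starting with ``##fileformat``
    is parsed as a VCF whose ALT alleles are ``<CNk>`` symbols.
    """
    path = Path(source)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat"):
        return _read_cnv_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "sample": str})
    if not len(df):
        return CNVTable(
            pd.DataFrame(columns=list(CNVTable.REQUIRED)).astype(
                {"start": np.int64, "end": np.int64, "cn_a": np.int64, "cn_b": np.int64}
            )
        )
    pairs = df["cn"].map(_parse_cn_pair)
    df = df.drop(columns=["cn"]).assign(
        cn_a=[p[0] for p in pairs], cn_b=[p[1] for p in pairs]
    )
    return CNVTable(df.reset_index(drop=True))


def _parse_cn_pair(text: str) -> tuple[int, int]:
    m = _CN_RE.match(str(text).strip())
    if not m:
        raise ValueError(f"cannot parse CN genotype {text!r}")
    return int(m.group(1)), int(m.group(2))


def _read_cnv_vcf(path: Path) -> CNVTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows = []
    for k, rec in enumerate(vcf):
        # REF allele means the reference single-copy state, CN1
        allele_cn = [1]
        for alt in rec.ALT:
            m = re.match(r"^<CN(\d+)>$", alt)
            if not m:
                raise ValueError(f"{path}: non-CN symbolic allele {alt!r}")
            allele_cn.append(int(m.group(1)))
        end = rec.INFO.get("END", rec.end)
        rid = rec.ID or f"cnv{k + 1}"
        for sample, gt in zip(ids, rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue  # missing CN genotype: sample not classifiable here
            rows.append(
                (rid, rec.CHROM, rec.start, int(end), sample,
                 allele_cn[a], allele_cn[b])
            )
    df = pd.DataFrame(rows, columns=list(CNVTable.REQUIRED))
    return CNVTable(df)


def write_cnv_table(table: CNVTable, path: str | Path) -> None:
    df = table.df.copy()
    df["cn"] = [f"CN{a}/CN{b}" for a, b in zip(df["cn_a"], df["cn_b"])]
    df[["region_id", "chrom", "start", "end", "sample", "cn"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3(+name) into a DataFrame with 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            toks = ln.split("\t")
            rows.append(
                (toks[0], int(toks[1]), int(toks[2]), toks[3] if len(toks) > 3 else "")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def inspect(path: str | Path) -> dict[str, int]:
    """Record counts for any supported file, keyed by record kind."""
    path = Path(path)
    text_head = open(path).readline()
    if text_head.startswith("##fileformat"):
        if "<CN" in open(path).read():
            tab = read_cnv_table(path)
            return {"cnv_regions": len(tab.region_ids), "samples": len(tab.samples)}
        by_chrom = load_vcf_by_chrom(path)
        return {
            "snvs": sum(g.n_sites for g in by_chrom.values()),
            "samples": next(iter(by_chrom.values())).n_samples if by_chrom else 0,
            "chromosomes": len(by_chrom),
        }
    if path.suffix == ".bed":
        return {"intervals": len(read_bed(path))}
    if text_head.startswith("region_id"):
        tab = read_cnv_table(path)
        return {"cnv_regions": len(tab.region_ids), "samples": len(tab.samples)}
    mats = parse_ms(open(path).read())
    return {
        "replicates": len(mats),
        "sequences": mats[0].n_sequences if mats else 0,
        "segregating_sites": sum(m.n_sites for m in mats),
    }
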