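"""Genotype input/output and site filtering.

The central data structure is :class:`GenotypeMatrix`: an (n_sites, n_samples)
matrix of diploid alternate-allele dosages (0, 1, 2, or :data:`MISSING`)
together with per-site metadata (chromosome, position, alleles, quality).
Phase is deliberately discarded: every downstream statistic in this package is
frequency- or dosage-based.

Coordinates are 1-based inclusive throughout (VCF convention); BED output
converts to 0-based half-open at the serialization boundary only.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "PopulationMap",
    "FilterReport",
    "VcfParseError",
    "DataError",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_chrom_lengths",
    "apply_site_filters",
    "group_allele_freq",
]

#: Sentinel dosage for a missing diploid genotype call.
MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class DataError(ValueError):
    """Raised when inputs violate a structural invariant (sorting, duplicates, ...)."""


class VariantSite(NamedTuple):
    """One variant record: position, alleles, quality, and per-sample dosages."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    dosages: np.ndarray  # int8, length n_samples, values in {0,1,2,MISSING}


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid allele-dosage matrix (sites x samples) with site metadata.

    Attributes
    ----------
    samples:
        Ordered sample identifiers; the column order of ``dosages``.
    chrom, pos, ref, alts, qual:
        Per-site arrays/lists, sorted by (chromosome, position). ``alts`` holds
        a tuple of alternate alleles per site (multiallelic records keep all).
    dosages:
        int8 array of shape (n_sites, n_samples); entries in {0, 1, 2, MISSING}.
    chrom_lengths:
        Mapping chromosome -> length in bp. Chromosomes without an entry fall
        back to the largest observed position when windows are built.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str]
    alts: list[tuple[str, ...]]
    qual: np.ndarray
    dosages: np.ndarray
    chrom_lengths: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape != (len(self.pos), len(self.samples)):
            raise DataError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        self._check_sorted_unique()

    def _check_sorted_unique(self) -> None:
        order = self.chrom_order()
        last: tuple[int, int] | None = None
        for i, (c, p) in enumerate(zip(order, self.pos)):
            key = (int(c), int(p))
            if last is not None and key <= last:
                if key == last:
                    raise DataError(f"duplicate site at {self.chrom[i]}:{p}")
                raise DataError("sites not sorted by (chrom, pos)")
            last = key
        if np.any(self.pos < 1):
            raise DataError("positions must be 1-based (>= 1)")

    def chrom_order(self) -> np.ndarray:
        """Integer code per site following first-appearance chromosome order."""
        codes: dict[str, int] = {}
        out = np.empty(len(self.chrom), dtype=np.int64)
        for i, c in enumerate(self.chrom):
            out[i] = codes.setdefault(c, len(codes))
        return out

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_length(self, chrom: str) -> int:
        if chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        mask = self.chrom == chrom
        if not mask.any():
            raise KeyError(chrom)
        return int(self.pos[mask].max())

    def site(self, i: int) -> VariantSite:
        return VariantSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=self.ref[i],
            alts=tuple(self.alts[i]),
            qual=float(self.qual[i]),
            dosages=self.dosages[i],
        )

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"sample {exc.args[0]!r} not present in genotype matrix") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=[self.ref[i] for i in index],
            alts=[self.alts[i] for i in index],
            qual=self.qual[index],
            dosages=self.dosages[index],
            chrom_lengths=dict(self.chrom_lengths),
        )


@dataclasses.dataclass
class PopulationMap:
    """Assignment of samples to named groups.

    ``groups`` preserves first-appearance order of the labels.
    """

    assignment: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str | Iterable[str]) -> list[str]:
        """Samples mapped to ``group`` (a label or an iterable of labels)."""
        labels = {group} if isinstance(group, str) else set(group)
        unknown = labels - set(self.groups)
        if unknown:
            raise DataError(f"unknown group label(s): {sorted(unknown)}")
        return [s for s, g in self.assignment.items() if g in labels]


@dataclasses.dataclass
class FilterReport:
    """Accounting of :func:`apply_site_filters`.

    A site failing several rules is attributed to the first failing rule in the
    fixed order: biallelic, qual, missing-rate, maf. Hence
    ``n_input == n_kept + sum(n_dropped_by_rule.values())`` always holds.
    """

    n_input: int
    n_kept: int
    n_dropped_by_rule: dict[str, int]

    def __post_init__(self) -> None:
        total = self.n_kept + sum(self.n_dropped_by_rule.values())
        if total != self.n_input:
            raise DataError("filter report does not reconcile with input site count")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Diploid GT fields are mapped to dosages: 0/0 -> 0, 0/1 or 1/0 -> 1,
    1/1 -> 2; any missing allele gives :data:`MISSING`. For multiallelic
    records the dosage counts non-reference alleles; such records are retained
    as-is (filtering them is :func:`apply_site_filters`'s job).

    Parameters
    ----------
    path:
        Path to an uncompressed or bgzipped VCF with a GT FORMAT field.
    sample_subset:
        Optional list of sample IDs to keep (in the given order).

    Raises
    ------
    VcfParseError
        If the file cannot be parsed as VCF.
    DataError
        If any genotype is not diploid, or sites are unsorted/duplicated.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports open/parse failures opaquely
        raise VcfParseError(f"cannot parse {path!r} as VCF: {exc}") from exc
    try:
        if sample_subset is not None:
            vcf.set_samples(list(sample_subset))
        samples = list(vcf.samples)
        chrom_lengths: dict[str, int] = {}
        try:
            for name, length in zip(vcf.seqnames, vcf.seqlens):
                chrom_lengths[name] = int(length)
        except Exception:  # no contig headers in file
            chrom_lengths = {}

        chroms: list[str] = []
        poss: list[int] = []
        refs: list[str] = []
        alts: list[tuple[str, ...]] = []
        quals: list[float] = []
        rows: list[np.ndarray] = []
        for var in vcf:
            gts = var.genotypes
            row = np.empty(len(samples), dtype=np.int8)
            for j, gt in enumerate(gts):
                alleles = gt[:-1]  # last element is the phased flag
                if len(alleles) != 2:
                    raise DataError(
                        f"non-diploid genotype for sample {samples[j]!r} "
                        f"at {var.CHROM}:{var.POS}"
                    )
                a, b = alleles
                if a < 0 or b < 0:
                    row[j] = MISSING  # includes half-calls like ./1
                else:
                    row[j] = int(a > 0) + int(b > 0)
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(tuple(var.ALT))
            quals.append(var.QUAL if var.QUAL is not None else np.nan)
            rows.append(row)
    finally:
        vcf.close()

    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=refs,
        alts=alts,
        qual=np.array(quals, dtype=float),
        dosages=dosages,
        chrom_lengths=chrom_lengths,
    )


def _format_qual(q: float) -> str:
    if np.isnan(q):
        return "."
    if float(q).is_integer():
        return str(int(q))
    return f"{q:.6g}"


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str, source: str = "popscan") -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    Heterozygotes are emitted unphased as ``0/1`` (phase is not modelled).
    Multiallelic dosages of 1/2 are emitted against the first alternate
    allele, which round-trips the dosage but not the allele identity.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for name, length in gm.chrom_lengths.items():
            fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            alt = ",".join(gm.alts[i]) if gm.alts[i] else "."
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosages[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{alt}\t"
                f"{_format_qual(float(gm.qual[i]))}\tPASS\t.\tGT\t{gts}\n"
            )


def read_popmap(path: str) -> PopulationMap:
    """Read a 2-column TSV (sample, group) into a :class:`PopulationMap`."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{ln}: expected 2 tab-separated columns")
            sample, group = parts
            if sample in assignment:
                raise DataError(f"{path}:{ln}: duplicate sample {sample!r}")
            assignment[sample] = group
    return PopulationMap(assignment=assignment)


def write_popmap(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, group in pm.assignment.items():
            fh.write(f"{sample}\t{group}\n")


def read_chrom_lengths(path: str) -> dict[str, int]:
    """Read a 2-column TSV (chromosome, length-bp)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{ln}: expected 2 tab-separated columns")
            out[parts[0]] = int(parts[1])
    return out


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def apply_site_filters(
    gm: GenotypeMatrix,
    qual_min: float = 30.0,
    mr_max: float = 0.25,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the four site-retention rules, in order.

    A site is kept iff it is biallelic (exactly one alternate allele), has
    quality strictly greater than ``qual_min``, a missing-genotype fraction
    strictly below ``mr_max``, and a minor allele frequency (computed from
    non-missing calls only) strictly above ``maf_min``. All inequalities are
    strict. A dropped site is attributed to the first failing rule in the
    order biallelic, qual, missing-rate, maf.

    Returns the filtered matrix (site order preserved) and a
    :class:`FilterReport`.
    """
    if gm.n_sites == 0:
        return gm, FilterReport(0, 0, {"biallelic": 0, "qual": 0, "missing_rate": 0, "maf": 0})

    n_samples = gm.n_samples
    biallelic = np.array([len(a) == 1 for a in gm.alts], dtype=bool)
    with np.errstate(invalid="ignore"):
        qual_ok = gm.qual > qual_min  # NaN quality fails

    missing = gm.dosages == MISSING
    n_missing = missing.sum(axis=1)
    mr = n_missing / n_samples if n_samples else np.ones(gm.n_sites)
    mr_ok = mr < mr_max

    n_called = n_samples - n_missing
    alt_sum = np.where(missing, 0, gm.dosages).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    # all-missing sites have already failed the missing-rate rule (mr = 1)
    maf_ok = np.where(np.isnan(maf), False, maf > maf_min)

    keep = biallelic & qual_ok & mr_ok & maf_ok
    first_fail = np.full(gm.n_sites, -1, dtype=np.int8)
    for code, ok in enumerate((biallelic, qual_ok, mr_ok, maf_ok)):
        first_fail = np.where((first_fail == -1) & ~ok, code, first_fail)

    rule_names = ("biallelic", "qual", "missing_rate", "maf")
    drops = {name: int((first_fail == code).sum()) for code, name in enumerate(rule_names)}
    report = FilterReport(
        n_input=gm.n_sites, n_kept=int(keep.sum()), n_dropped_by_rule=drops
    )
    return gm.take_sites(np.flatnonzero(keep)), report


def group_allele_freq(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str | Iterable[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alternate-allele frequency within a group.

    Returns ``(freq, n)`` where ``n`` is the effective allele count
    (2 x non-missing samples in the group) and ``freq`` is NaN where
    ``n == 0`` (undefined).
    """
    sample_ids = pm.samples_in(group)
    idx = gm.sample_indices(sample_ids)
    if len(idx) == 0:
        raise DataError(f"group {group!r} has no samples in the matrix")
    sub = gm.dosages[:, idx]
    missing = sub == MISSING
    n = 2 * (sub.shape[1] - missing.sum(axis=1))
    alt = np.where(missing, 0, sub).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return freq.astype(float), n.astype(np.int64)
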