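"""Windowed FST/ROD contrast between two pools and the sweep-region caller.

FST uses the Weir & Cockerham (1984) allele-frequency (two-level) variance
decomposition with ratio-of-sums windowing: window FST = sum(a) / sum(a+b)
over usable sites. Small negative window values are retained so the top-decile
rule operates on the estimator's native scale.

A window qualifies as swept iff fst > fst_abs AND fst >= the (1-q) upper
quantile of defined window FST values AND rod > rod_min; overlapping or
book-ended qualifying windows are merged into maximal regions.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from popscan.diversity import WindowSpec, windows_for, site_pi
from popscan.genotype_io import DataError, GenotypeMatrix, PopulationMap, group_allele_freq

__all__ = [
    "site_fst_wc",
    "window_scan",
    "call_sweeps",
    "read_gene_intervals",
    "annotate_regions",
]


def site_fst_wc(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components for biallelic loci, two populations.

    Allele-count formulation (no within-individual component): returns the
    per-site among-population component ``a`` and total ``a + b``. Sites where
    either group has fewer than 2 alleles yield NaN and must be skipped by the
    caller. The per-site estimate is a/(a+b); windowed estimates should use
    the ratio of sums.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    usable = (n1 >= 2) & (n2 >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_tot = n1 + n2
        n_bar = n_tot / 2.0
        nc = n_tot - (n1**2 + n2**2) / n_tot  # r - 1 = 1
        p_bar = (n1 * p1 + n2 * p2) / n_tot
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        inner = p_bar * (1.0 - p_bar) - s2 / 2.0
        a = (n_bar / nc) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * inner
    a = np.where(usable, a, np.nan)
    d = np.where(usable, a + b, np.nan)
    return a, d


def window_scan(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    wild: str | Iterable[str],
    dom: str | Iterable[str],
    spec: WindowSpec = WindowSpec(100_000, 10_000),
) -> pd.DataFrame:
    """Windowed FST, per-pool diversity, and ROD along the genome.

    ``wild`` / ``dom`` are group labels (or iterables of labels to pool).
    Columns: chrom, start, end, n_sites, fst, pi_wild, pi_dom, rod, pi_ratio.
    ``rod = 1 - pi_dom / pi_wild`` (NaN when pi_wild == 0); ``pi_ratio`` is
    the raw pi_wild / pi_dom. Windows with no usable site have NaN fst.
    """
    fw, nw = group_allele_freq(gm, pm, wild)
    fd, nd = group_allele_freq(gm, pm, dom)
    a, d = site_fst_wc(fw, nw, fd, nd)
    usable = ~np.isnan(d)
    a_f = np.where(usable, a, 0.0)
    d_f = np.where(usable, d, 0.0)

    pi_w = np.asarray(site_pi(fw, nw), dtype=float)
    pi_d = np.asarray(site_pi(fd, nd), dtype=float)
    pi_w = np.where(np.isnan(pi_w), 0.0, pi_w)
    pi_d = np.where(np.isnan(pi_d), 0.0, pi_d)

    rows: list[dict] = []
    for chrom in gm.chromosomes():
        cmask = gm.chrom == chrom
        cpos = gm.pos[cmask]
        c_a = np.concatenate(([0.0], np.cumsum(a_f[cmask])))
        c_d = np.concatenate(([0.0], np.cumsum(d_f[cmask])))
        c_u = np.concatenate(([0], np.cumsum(usable[cmask].astype(np.int64))))
        c_pw = np.concatenate(([0.0], np.cumsum(pi_w[cmask])))
        c_pd = np.concatenate(([0.0], np.cumsum(pi_d[cmask])))
        for start, end in windows_for(gm.chrom_length(chrom), spec):
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            length = end - start + 1
            n_use = int(c_u[hi] - c_u[lo])
            den = c_d[hi] - c_d[lo]
            fst = (c_a[hi] - c_a[lo]) / den if n_use and den != 0 else np.nan
            piw = (c_pw[hi] - c_pw[lo]) / length
            pid = (c_pd[hi] - c_pd[lo]) / length
            rod = 1.0 - pid / piw if piw > 0 else np.nan
            ratio = piw / pid if pid > 0 else np.nan
            rows.append(
                dict(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_sites=n_use,
                    fst=fst,
                    pi_wild=piw,
                    pi_dom=pid,
                    rod=rod,
                    pi_ratio=ratio,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "fst", "pi_wild", "pi_dom", "rod", "pi_ratio"],
    )


def call_sweeps(
    windows: pd.DataFrame,
    fst_abs: float = 0.15,
    fst_quantile: float = 0.90,
    rod_min: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three selection criteria and merge qualifying windows.

    A window qualifies iff ``fst > fst_abs`` and ``fst >=`` the
    ``fst_quantile`` quantile of windows with defined FST and ``rod > rod_min``.
    Qualifying windows that overlap or touch (book-ended) are merged per
    chromosome into maximal regions.

    Returns ``(regions, windows)`` where ``windows`` is the input with
    pass_fst_abs / pass_fst_top / pass_rod / qualifies columns added and
    ``regions`` has columns chrom, start, end, n_windows, max_fst, max_rod.
    """
    wt = windows.copy()
    fst = wt["fst"].to_numpy(dtype=float)
    rod = wt["rod"].to_numpy(dtype=float)
    defined = ~np.isnan(fst)
    if defined.sum() == 0:
        warnings.warn("all windows have undefined FST; no sweep regions called")
        wt["pass_fst_abs"] = False
        wt["pass_fst_top"] = False
        wt["pass_rod"] = False
        wt["qualifies"] = False
        return (
            pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "max_fst", "max_rod"]),
            wt,
        )
    if defined.sum() < 10:
        raise DataError("need >= 10 windows with defined FST for the quantile rule")
    threshold = float(np.quantile(fst[defined], fst_quantile))
    with np.errstate(invalid="ignore"):
        wt["pass_fst_abs"] = defined & (fst > fst_abs)
        wt["pass_fst_top"] = defined & (fst >= threshold)
        wt["pass_rod"] = ~np.isnan(rod) & (rod > rod_min)
    wt["qualifies"] = wt["pass_fst_abs"] & wt["pass_fst_top"] & wt["pass_rod"]

    regions: list[dict] = []
    for chrom, sub in wt[wt["qualifies"]].groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur: dict | None = None
        for _, row in sub.iterrows():
            if cur is not None and row["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(row["end"]))
                cur["n_windows"] += 1
                cur["max_fst"] = max(cur["max_fst"], float(row["fst"]))
                cur["max_rod"] = max(cur["max_rod"], float(row["rod"]))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = dict(
                    chrom=chrom,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_windows=1,
                    max_fst=float(row["fst"]),
                    max_rod=float(row["rod"]),
                )
        if cur is not None:
            regions.append(cur)
    reg = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_windows", "max_fst", "max_rod"]
    )
    return reg, wt


def read_gene_intervals(path: str) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    Returns a DataFrame with columns chrom, start, end, gene_id using 1-based
    inclusive coordinates. For GFF3 only ``gene`` features are kept; the gene
    ID comes from the ID= attribute (falling back to Name=, then to a
    positional label).
    """
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return _read_gff3_genes(path)
    return _read_bed(path)


def _read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{ln}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            rows.append(
                dict(chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]), gene_id=name)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _read_gff3_genes(path: str) -> pd.DataFrame:
    import gzip

    opener = gzip.open if path.endswith(".gz") else open
    rows = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}:{ln}: GFF3 needs 9 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"gene_{ln}"
            rows.append(
                dict(chrom=parts[0], start=int(parts[3]), end=int(parts[4]), gene_id=gene_id)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def annotate_regions(
    regions: pd.DataFrame, genes: pd.DataFrame, known_chroms: Iterable[str] | None = None
) -> pd.DataFrame:
    """Attach overlapping gene IDs to each region (>= 1 bp overlap).

    ``genes`` must have columns chrom, start, end, gene_id in 1-based
    inclusive coordinates. Genes on chromosomes absent from ``known_chroms``
    (when given) are skipped with a warning. A gene spanning several regions
    is listed in each. Adds ``genes`` (comma-joined IDs) and ``n_genes``.
    """
    if known_chroms is not None:
        known = set(known_chroms)
        bad = sorted(set(genes["chrom"]) - known)
        if bad:
            warnings.warn(f"skipping genes on unknown chromosome(s): {bad}")
            genes = genes[genes["chrom"].isin(known)]
    out = regions.copy()
    gene_lists: list[str] = []
    n_genes: list[int] = []
    for _, r in out.iterrows():
        sub = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] <= r["end"])
            & (genes["end"] >= r["start"])
        ]
        ids = list(sub["gene_id"])
        gene_lists.append(",".join(ids))
        n_genes.append(len(ids))
    out["genes"] = gene_lists
    out["n_genes"] = n_genes
    return out


def regions_to_bed(regions: pd.DataFrame, path: str) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = r["genes"] if "genes" in regions.columns and r.get("genes") else "."
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{name}\n")
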