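"""Windowed diversity statistics: theta_pi, theta_w, Tajima's D, SNP density.

Per-bp values divide by the full window length, implicitly treating unlisted
positions as invariant (no accessibility mask). Missing genotypes enter
through a per-site effective allele count n_i; the variance constants for
Tajima's D use a single rounded mean n over the segregating sites of each
window.
"""

from __future__ import annotations

import dataclasses
import functools
from typing import Iterable

import numpy as np
import pandas as pd

from popscan.genotype_io import DataError, GenotypeMatrix, PopulationMap, group_allele_freq

__all__ = [
    "WindowSpec",
    "TajimaConstants",
    "tajima_constants",
    "site_pi",
    "windows_for",
    "window_diversity",
    "group_summary",
]


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: windows start at 1, 1+step, ... per chromosome;
    the last window may be truncated at the chromosome end."""

    size: int
    step: int

    def __post_init__(self) -> None:
        if self.size <= 0 or not 0 < self.step <= self.size:
            raise DataError("require size > 0 and 0 < step <= size")


def windows_for(chrom_length: int, spec: WindowSpec) -> np.ndarray:
    """(n, 2) array of 1-based inclusive [start, end] windows."""
    starts = np.arange(1, chrom_length + 1, spec.step, dtype=np.int64)
    ends = np.minimum(starts + spec.size - 1, chrom_length)
    return np.stack([starts, ends], axis=1)


@dataclasses.dataclass(frozen=True)
class TajimaConstants:
    """Normalizing constants for Tajima's D at haplotype count n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@functools.lru_cache(maxsize=4096)
def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise DataError("Tajima constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@functools.lru_cache(maxsize=4096)
def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def site_pi(freq: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """Unbiased per-site heterozygosity: (n/(n-1)) * 2*p*(1-p).

    Equals the mean pairwise difference over the n observed alleles at the
    site. NaN where n < 2 (undefined).
    """
    freq = np.asarray(freq, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n >= 2, n / (n - 1.0) * 2.0 * freq * (1.0 - freq), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _site_arrays(
    gm: GenotypeMatrix, pm: PopulationMap, group: str | Iterable[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (pi, seg_flag, n, 1/a1(n_i) for segregating sites)."""
    freq, n = group_allele_freq(gm, pm, group)
    pi = np.asarray(site_pi(freq, n), dtype=float)
    pi = np.where(np.isnan(pi), 0.0, pi)
    seg = (n >= 2) & (freq > 0) & (freq < 1)
    inv_a1 = np.zeros(gm.n_sites)
    for v in np.unique(n[seg]):  # few distinct allele counts in practice
        inv_a1[seg & (n == v)] = 1.0 / _a1(int(v))
    return pi, seg, n, inv_a1


def window_diversity(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str | Iterable[str],
    spec: WindowSpec = WindowSpec(10_000, 5_000),
) -> pd.DataFrame:
    """Windowed theta_pi, theta_w, Tajima's D, and SNP density for a group.

    Returns a DataFrame with one row per window and columns
    chrom, start, end, n_snps, snp_per_kb, theta_pi, theta_w, tajimas_d,
    n_eff, n_unstable. A position belongs to every window whose [start, end]
    contains it. Tajima's D is NaN (undefined) when S < 2 or the rounded mean
    allele count is < 4; ``n_unstable`` flags windows whose segregating-site
    allele counts vary more than 2-fold.
    """
    pi, seg, n, inv_a1 = _site_arrays(gm, pm, group)
    pi_seg = np.where(seg, pi, 0.0)
    n_seg = np.where(seg, n, 0)

    rows: list[dict] = []
    for chrom in gm.chromosomes():
        cmask = gm.chrom == chrom
        cpos = gm.pos[cmask]
        c_pi = np.concatenate(([0.0], np.cumsum(pi_seg[cmask])))
        c_s = np.concatenate(([0], np.cumsum(seg[cmask].astype(np.int64))))
        c_inv = np.concatenate(([0.0], np.cumsum(inv_a1[cmask])))
        c_n = np.concatenate(([0.0], np.cumsum(n_seg[cmask].astype(float))))
        nvals = n_seg[cmask]
        for start, end in windows_for(gm.chrom_length(chrom), spec):
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            length = end - start + 1
            s = int(c_s[hi] - c_s[lo])
            sum_pi = float(c_pi[hi] - c_pi[lo])
            sum_inv = float(c_inv[hi] - c_inv[lo])
            n_eff = (c_n[hi] - c_n[lo]) / s if s else np.nan
            d = np.nan
            unstable = False
            if s:
                wn = nvals[lo:hi]
                wn = wn[wn > 0]
                unstable = bool(wn.size and wn.max() > 2 * wn.min())
            if s >= 2:
                n_round = int(round(n_eff))
                if n_round >= 4:
                    k = tajima_constants(n_round)
                    var = k.e1 * s + k.e2 * s * (s - 1)
                    if var > 0:
                        d = (sum_pi - s / k.a1) / np.sqrt(var)
            rows.append(
                dict(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_snps=s,
                    snp_per_kb=1000.0 * s / length,
                    theta_pi=sum_pi / length,
                    theta_w=sum_inv / length,
                    tajimas_d=d,
                    n_eff=n_eff,
                    n_unstable=unstable,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_snps",
            "snp_per_kb",
            "theta_pi",
            "theta_w",
            "tajimas_d",
            "n_eff",
            "n_unstable",
        ],
    )


def group_summary(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str | Iterable[str],
    spec: WindowSpec = WindowSpec(10_000, 5_000),
) -> dict:
    """Genome-wide summary for a group.

    ``theta_pi`` / ``tajimas_d`` are window means weighted by window length;
    the unweighted counterparts are reported alongside. SNP count and SNP/kb
    are computed directly from segregating sites, not from windows (sites
    would otherwise be double-counted by overlapping windows).
    """
    _, seg, _, _ = _site_arrays(gm, pm, group)
    total_len = sum(gm.chrom_length(c) for c in gm.chromosomes())
    wt = window_diversity(gm, pm, group, spec)
    lengths = (wt["end"] - wt["start"] + 1).to_numpy(dtype=float)

    def wmean(col: str) -> float:
        v = wt[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if not ok.any():
            return float("nan")
        return float(np.average(v[ok], weights=lengths[ok]))

    return {
        "group": group if isinstance(group, str) else "+".join(group),
        "n_samples": len(pm.samples_in(group)),
        "n_snps": int(seg.sum()),
        "snp_per_kb": 1000.0 * float(seg.sum()) / total_len if total_len else float("nan"),
        "theta_pi": wmean("theta_pi"),
        "theta_w": wmean("theta_w"),
        "tajimas_d": wmean("tajimas_d"),
        "theta_pi_unweighted": float(np.nanmean(wt["theta_pi"])) if len(wt) else float("nan"),
        "tajimas_d_unweighted": float(np.nanmean(wt["tajimas_d"])) if len(wt) else float("nan"),
        "n_windows": int(len(wt)),
    }
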