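"""Pairwise genotype r^2, distance-binned decay curves, half-decay distance.

r^2 is the squared Pearson correlation of dosage vectors over the samples
non-missing at both sites. The half-decay distance is measured from the
maximum bin mean (r^2 at distance zero being unobservable) and located by
linear interpolation between the last bin above half-maximum and the first
bin at or below it.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from popscan.genotype_io import MISSING, DataError, GenotypeMatrix, PopulationMap

__all__ = [
    "LDDecayCurve",
    "pair_r2",
    "decay_curve",
    "group_mean_r2",
    "half_decay_distance",
]

_PAIR_CHUNK = 250_000


@dataclasses.dataclass
class LDDecayCurve:
    """Distance-binned LD decay summary.

    ``bin_edges`` has length n_bins + 1; ``mean_r2`` is NaN for empty bins.
    ``half_distance`` is the bp distance at which the (optionally smoothed)
    bin means first fall to half of ``max_r2``; NaN when the curve never
    crosses half-maximum.
    """

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    max_r2: float
    half_distance: float
    overall_mean_r2: float
    n_pairs_total: int
    subsampled: bool = False
    seed: int | None = None

    @property
    def bin_mid(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid_bp": self.bin_mid, "mean_r2": self.mean_r2, "n_pairs": self.n_pairs}
        )

    def summary(self) -> dict:
        return {
            "mean_r2": self.overall_mean_r2,
            "max_r2": self.max_r2,
            "half_distance_bp": self.half_distance,
            "n_pairs": int(self.n_pairs_total),
            "subsampled": self.subsampled,
            "seed": self.seed,
        }


def pair_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing at both sites; NaN (pair skipped) when
    fewer than 2 shared samples remain or either vector is constant on them.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        return float("nan")
    va = a - a.mean()
    vb = b - b.mean()
    den = (va**2).sum() * (vb**2).sum()
    if den == 0:
        return float("nan")
    return float((va * vb).sum() ** 2 / den)


def _pair_indices(
    pos: np.ndarray, max_dist: int
) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs (i < j) on one chromosome with pos[j]-pos[i] <= max_dist."""
    hi = np.searchsorted(pos, pos + max_dist, side="right")
    counts = hi - np.arange(pos.size) - 1
    i_idx = np.repeat(np.arange(pos.size), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    j_idx = np.arange(offsets[-1]) - offsets[i_idx] + i_idx + 1
    return i_idx, j_idx


def _chunked_r2(sub: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Vectorized r^2 for index-pair arrays over a (sites x samples) block."""
    sub = sub.T  # samples x sites below
    out = np.empty(i_idx.size)
    has_missing = bool((sub == MISSING).any())
    X = sub.astype(float)
    if not has_missing:
        Xc = X - X.mean(axis=0)
        ss = (Xc**2).sum(axis=0)
        for s in range(0, i_idx.size, _PAIR_CHUNK):
            ii = i_idx[s : s + _PAIR_CHUNK]
            jj = j_idx[s : s + _PAIR_CHUNK]
            num = np.einsum("si,si->i", Xc[:, ii], Xc[:, jj]) ** 2
            den = ss[ii] * ss[jj]
            with np.errstate(divide="ignore", invalid="ignore"):
                out[s : s + _PAIR_CHUNK] = np.where(den > 0, num / den, np.nan)
        return out
    M = (sub != MISSING).astype(float)
    Xz = np.where(sub == MISSING, 0.0, X)
    for s in range(0, i_idx.size, _PAIR_CHUNK):
        ii = i_idx[s : s + _PAIR_CHUNK]
        jj = j_idx[s : s + _PAIR_CHUNK]
        m = M[:, ii] * M[:, jj]
        n = m.sum(axis=0)
        xa = Xz[:, ii] * m
        xb = Xz[:, jj] * m
        sa, sb = xa.sum(axis=0), xb.sum(axis=0)
        saa = (xa**2).sum(axis=0)
        sbb = (xb**2).sum(axis=0)
        sab = (xa * xb).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sab - sa * sb / n
            va = saa - sa**2 / n
            vb = sbb - sb**2 / n
            r2 = np.where((n >= 2) & (va > 0) & (vb > 0), cov**2 / (va * vb), np.nan)
        out[s : s + _PAIR_CHUNK] = r2
    return out


def _collect_pairs(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str | Iterable[str],
    max_dist: int,
    max_pairs: int | None,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """(distances, r2 values, subsampled?) over all intra-chromosomal pairs."""
    idx = gm.sample_indices(pm.samples_in(group))
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    rng = np.random.Generator(np.random.PCG64(seed))
    subsampled = False
    chrom_data = []
    total = 0
    for chrom in gm.chromosomes():
        cmask = gm.chrom == chrom
        cpos = gm.pos[cmask]
        sub = gm.dosages[np.ix_(cmask, idx)]
        i_idx, j_idx = _pair_indices(cpos, max_dist)
        chrom_data.append((cpos, sub, i_idx, j_idx))
        total += i_idx.size
    frac = 1.0
    if max_pairs is not None and total > max_pairs:
        frac = max_pairs / total
        subsampled = True
    for cpos, sub, i_idx, j_idx in chrom_data:
        if frac < 1.0 and i_idx.size:
            keep = rng.random(i_idx.size) < frac
            i_idx, j_idx = i_idx[keep], j_idx[keep]
        if i_idx.size == 0:
            continue
        dists.append(cpos[j_idx] - cpos[i_idx])
        r2s.append(_chunked_r2(sub, i_idx, j_idx))
    if not dists:
        return np.empty(0, dtype=np.int64), np.empty(0), subsampled
    return np.concatenate(dists), np.concatenate(r2s), subsampled


def half_decay_distance(
    bin_mid: np.ndarray, mean_r2: np.ndarray, smooth_bins: int = 1
) -> tuple[float, float]:
    """(max_r2, half_distance) from binned means.

    Bins with NaN means are ignored. An odd ``smooth_bins`` > 1 applies a
    centred moving average before locating the crossing. Half-maximum is
    exactly 50% of the maximum (smoothed) bin mean; the crossing is linearly
    interpolated between bin midpoints.
    """
    ok = ~np.isnan(mean_r2)
    x = np.asarray(bin_mid, dtype=float)[ok]
    y = np.asarray(mean_r2, dtype=float)[ok]
    if x.size == 0:
        return float("nan"), float("nan")
    if smooth_bins > 1 and y.size >= smooth_bins:
        kernel = np.ones(smooth_bins) / smooth_bins
        y = np.convolve(y, kernel, mode="same")
    i_max = int(np.argmax(y))
    max_r2 = float(y[i_max])
    half = max_r2 / 2.0
    for k in range(i_max, y.size):
        if y[k] <= half:
            if k == i_max:
                return max_r2, float(x[k])
            x0, x1 = x[k - 1], x[k]
            y0, y1 = y[k - 1], y[k]
            t = (y0 - half) / (y0 - y1) if y0 != y1 else 0.0
            return max_r2, float(x0 + t * (x1 - x0))
    return max_r2, float("nan")


def decay_curve(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str | Iterable[str],
    max_dist: int = 200_000,
    bin_width: int = 100,
    max_pairs: int | None = 5_000_000,
    smooth_bins: int = 1,
    seed: int = 0,
) -> LDDecayCurve:
    """Distance-binned LD decay curve for a group.

    Every intra-chromosomal site pair with separation <= ``max_dist``
    contributes its r^2 to the bin of its distance. When the pair count
    exceeds ``max_pairs`` the pairs are subsampled uniformly (seeded) and the
    fact is recorded on the result.
    """
    dists, r2, subsampled = _collect_pairs(gm, pm, group, max_dist, max_pairs, seed)
    ok = ~np.isnan(r2)
    dists, r2 = dists[ok], r2[ok]
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=np.int64)
    n_bins = edges.size - 1
    which = np.minimum((dists - 1) // bin_width, n_bins - 1).astype(np.int64)
    n_pairs = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2.0
    max_r2, half = half_decay_distance(mids, means, smooth_bins=smooth_bins)
    return LDDecayCurve(
        bin_edges=edges,
        mean_r2=means,
        n_pairs=n_pairs,
        max_r2=max_r2,
        half_distance=half,
        overall_mean_r2=float(r2.mean()) if r2.size else float("nan"),
        n_pairs_total=int(r2.size),
        subsampled=subsampled,
        seed=seed,
    )


def group_mean_r2(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    group: str | Iterable[str],
    max_dist: int = 200_000,
    max_pairs: int | None = 5_000_000,
    seed: int = 0,
) -> float:
    """Unweighted mean r^2 over all counted pairs (NaN-skipping)."""
    _, r2, _ = _collect_pairs(gm, pm, group, max_dist, max_pairs, seed)
    r2 = r2[~np.isnan(r2)]
    return float(r2.mean()) if r2.size else float("nan")
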