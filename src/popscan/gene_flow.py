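"""Four-population D statistic with block-jackknife Z-scores, and Wright's Nm.

The D statistic is frequency-based (population samples, not single genomes):

    D = sum_sites (w - x)(y - z) / sum_sites (w + x - 2wx)(y + z - 2yz)

over informative sites (all four frequencies defined, near-fixed outgroup,
positive denominator term). For haploid single-sequence populations this
reduces to the familiar site-pattern count ratio. Standard errors come from a
delete-one block jackknife over contiguous genomic spans; a signal is called
significant when |Z| > 3.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from popscan.genotype_io import DataError, GenotypeMatrix, PopulationMap, group_allele_freq

__all__ = [
    "DStatResult",
    "NmEstimate",
    "d_statistic",
    "jackknife_z",
    "d_test",
    "nm_from_fst",
    "interpret_sign",
]

Z_SIGNIFICANT = 3.0

_POSITIVE_DIRECTION = "gene flow between W and Y or between X and Z; significant"
_NEGATIVE_DIRECTION = "gene flow between W and Z or X and Y; significant"
_NOT_SIGNIFICANT = "not significant"


@dataclasses.dataclass
class DStatResult:
    """Result of one four-population test; Z the outgroup (last label)."""

    pops: tuple[str, str, str, str]
    d: float
    z_score: float
    n_blocks: int
    n_sites: int
    se: float

    @property
    def significant(self) -> bool:
        return abs(self.z_score) > Z_SIGNIFICANT

    @property
    def direction(self) -> str:
        return interpret_sign(self.d, self.z_score, self.pops)

    def to_row(self) -> dict:
        w, x, y, z = self.pops
        return dict(
            W=w,
            X=x,
            Y=y,
            Z=z,
            D=self.d,
            z_score=self.z_score,
            se=self.se,
            n_sites=self.n_sites,
            n_blocks=self.n_blocks,
            significant=self.significant,
            direction=self.direction,
        )


@dataclasses.dataclass(frozen=True)
class NmEstimate:
    """Wright's island-model migrant number from an FST value."""

    fst_input: float
    nm: float


def d_statistic(
    freq_w: np.ndarray,
    freq_x: np.ndarray,
    freq_y: np.ndarray,
    freq_z: np.ndarray,
    outgroup_tol: float = 0.01,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """D statistic from per-site alternate-allele frequencies.

    Returns ``(d, num, den, informative)`` where ``num``/``den`` are the
    per-site numerator and denominator terms (zero outside informative sites)
    and ``informative`` marks sites used: all four frequencies defined, the
    outgroup within ``outgroup_tol`` of fixation, and a positive denominator
    term. ``d`` is NaN when the summed denominator is zero.
    """
    w = np.asarray(freq_w, dtype=float)
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    z = np.asarray(freq_z, dtype=float)
    defined = ~(np.isnan(w) | np.isnan(x) | np.isnan(y) | np.isnan(z))
    z_fixed = (z <= outgroup_tol) | (z >= 1.0 - outgroup_tol)
    num = (w - x) * (y - z)
    den = (w + x - 2.0 * w * x) * (y + z - 2.0 * y * z)
    informative = defined & z_fixed & (den > 0)
    num = np.where(informative, num, 0.0)
    den = np.where(informative, den, 0.0)
    total_den = den.sum()
    d = float(num.sum() / total_den) if total_den > 0 else float("nan")
    return d, num, den, informative


def jackknife_z(
    num: np.ndarray,
    den: np.ndarray,
    block_ids: np.ndarray,
) -> tuple[float, float, int]:
    """Delete-one-block jackknife Z for a ratio-of-sums statistic.

    ``block_ids`` assigns each site to a contiguous genomic block; blocks with
    zero total denominator are dropped. Returns ``(z, se, n_blocks)``; when
    the jackknife SE is zero (all leave-one-out values identical) z is
    +/- inf rather than an error.

    Raises :class:`DataError` when fewer than 10 non-empty blocks remain.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    blocks = pd.unique(np.asarray(block_ids))
    n_tot = num.sum()
    d_tot = den.sum()
    if d_tot <= 0:
        raise DataError("total denominator is zero; D undefined")
    bn = np.array([num[block_ids == b].sum() for b in blocks])
    bd = np.array([den[block_ids == b].sum() for b in blocks])
    keep = bd > 0
    bn, bd = bn[keep], bd[keep]
    n_blocks = int(keep.sum())
    if n_blocks < 10:
        raise DataError(
            f"only {n_blocks} non-empty jackknife blocks; use a smaller block size"
        )
    d_hat = n_tot / d_tot
    loo = (n_tot - bn) / (d_tot - bd)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    if se == 0.0:
        z = float("inf") if d_hat > 0 else (float("-inf") if d_hat < 0 else 0.0)
    else:
        z = float(d_hat / se)
    return z, se, n_blocks


def _block_ids(
    chrom: np.ndarray, pos: np.ndarray, block_size: int
) -> np.ndarray:
    codes = pd.factorize(chrom)[0].astype(np.int64)
    return codes * 10_000_000 + pos // block_size


def d_test(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    quartet: Sequence[str],
    block_size: int | None = None,
    outgroup_tol: float = 0.01,
) -> DStatResult:
    """Run the four-population test for ``quartet = (W, X, Y, Z)``, Z outgroup.

    ``block_size`` defaults to 5 Mb, falling back to 1/20 of the total
    genomic span whenever 5 Mb yields fewer than 10 non-empty blocks (short
    simulated chromosomes).
    """
    if len(quartet) != 4:
        raise DataError("quartet must name exactly four groups (W, X, Y, Z)")
    freqs = [group_allele_freq(gm, pm, g)[0] for g in quartet]
    d, num, den, informative = d_statistic(*freqs, outgroup_tol=outgroup_tol)
    if np.isnan(d):
        raise DataError("no informative sites; D undefined")

    candidates: list[int] = []
    if block_size is not None:
        candidates.append(int(block_size))
    else:
        candidates.append(5_000_000)
        span = sum(gm.chrom_length(c) for c in gm.chromosomes())
        candidates.append(max(1, span // 20))
    last_err: DataError | None = None
    for bs in candidates:
        try:
            ids = _block_ids(gm.chrom, gm.pos, bs)
            z, se, n_blocks = jackknife_z(num, den, ids)
            return DStatResult(
                pops=tuple(quartet),
                d=d,
                z_score=z,
                n_blocks=n_blocks,
                n_sites=int(informative.sum()),
                se=se,
            )
        except DataError as exc:
            last_err = exc
    raise last_err  # type: ignore[misc]


def nm_from_fst(fst: float) -> NmEstimate:
    """Wright's Nm = (1 - FST) / (4 * FST); NaN (flagged) for fst <= 0."""
    if not 0 < fst <= 1:
        return NmEstimate(fst_input=float(fst), nm=float("nan"))
    return NmEstimate(fst_input=float(fst), nm=(1.0 - fst) / (4.0 * fst))


def interpret_sign(
    d: float, z: float, pops: Sequence[str] | None = None
) -> str:
    """Verbal reading of a D test: direction by the sign of Z, significance
    when |Z| > 3."""
    if abs(z) <= Z_SIGNIFICANT:
        return _NOT_SIGNIFICANT
    return _POSITIVE_DIRECTION if z > 0 else _NEGATIVE_DIRECTION
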