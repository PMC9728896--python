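"""Independent brute-force reference implementations.

Each function here recomputes a statistic by direct enumeration, staying
deliberately naive and structurally unrelated to the optimized code paths in
the analysis modules. They exist solely to validate those paths (unit tests
and the acceptance report); never use them in the pipeline.
"""

from __future__ import annotations

import itertools

import numpy as np

from popscan.genotype_io import MISSING

__all__ = [
    "ref_site_pi",
    "ref_window_pi",
    "ref_fst_wc",
    "ref_r2",
    "ref_d_haploid_counts",
    "ref_p_distance",
]


def ref_site_pi(dosages: np.ndarray) -> float:
    """Mean pairwise allele difference at one site by explicit enumeration.

    Expands each non-missing diploid into two alleles and averages the 0/1
    difference over all unordered allele pairs. NaN with < 2 alleles.
    """
    alleles: list[int] = []
    for d in dosages:
        if d == MISSING:
            continue
        alleles.extend([1] * int(d) + [0] * (2 - int(d)))
    if len(alleles) < 2:
        return float("nan")
    diffs = [abs(a - b) for a, b in itertools.combinations(alleles, 2)]
    return sum(diffs) / len(diffs)


def ref_window_pi(dosages: np.ndarray, length: int) -> float:
    """Per-bp pi of a window: sum of per-site pairwise differences / length."""
    total = 0.0
    for row in dosages:
        v = ref_site_pi(row)
        if not np.isnan(v):
            total += v
    return total / length


def ref_fst_wc(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """WC84 components (a, a+b) for one biallelic site, coded from the
    general r-population textbook formulas with explicit loops."""
    r = 2
    ns = [n1, n2]
    ps = [p1, p2]
    n_bar = sum(ns) / r
    s1 = sum(ns)
    nc = (s1 - sum(n**2 for n in ns) / s1) / (r - 1)
    p_bar = sum(n * p for n, p in zip(ns, ps)) / s1
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
    a = (n_bar / nc) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2
    )
    return a, a + b


def ref_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared correlation via the textbook covariance formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        return float("nan")
    cov = (a * b).mean() - a.mean() * b.mean()
    var_a = (a**2).mean() - a.mean() ** 2
    var_b = (b**2).mean() - b.mean() ** 2
    if var_a == 0 or var_b == 0:
        return float("nan")
    return float(cov**2 / (var_a * var_b))


def ref_d_haploid_counts(
    w: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> float:
    """D from explicit ABBA/BABA site-pattern counts for single haploid
    sequences coded 0/1, with z the (ancestral) outgroup.

    The sign convention matches the frequency formula
    sum (w-x)(y-z) / sum (...): a site with (w,x,y,z) = (1,0,1,0) counts +1.
    """
    n_pos = n_neg = 0
    for sw, sx, sy, sz in zip(w, x, y, z):
        if sz == 1:  # orient on the outgroup: ancestral allele is z's
            sw, sx, sy = 1 - sw, 1 - sx, 1 - sy
        if sw == 1 and sx == 0 and sy == 1:
            n_pos += 1
        elif sw == 0 and sx == 1 and sy == 1:
            n_neg += 1
    if n_pos + n_neg == 0:
        return float("nan")
    return (n_pos - n_neg) / (n_pos + n_neg)


def ref_p_distance(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Allele-difference fraction between two diploids by explicit pairing.

    At each shared site the two genotypes are compared as unordered allele
    multisets under the pairing that minimizes mismatches, which for
    biallelic dosages is |da - db| allele differences out of 2.
    """
    total = 0.0
    n = 0
    for da, db in zip(dos_a, dos_b):
        if da == MISSING or db == MISSING:
            continue
        set_a = sorted([1] * int(da) + [0] * (2 - int(da)))
        set_b = sorted([1] * int(db) + [0] * (2 - int(db)))
        best = min(
            sum(a != b for a, b in zip(set_a, perm))
            for perm in itertools.permutations(set_b)
        )
        total += best / 2.0
        n += 1
    return total / n if n else float("nan")
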