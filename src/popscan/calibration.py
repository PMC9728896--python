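"""Simulation experiments that validate every estimator against known truth.

Each function runs a seeded, self-contained experiment and returns a dict of
plain numbers. They are shared by the acceptance test suite and the
acceptance report script; parameter defaults are chosen so each experiment
fits in minutes on one CPU while leaving the statistical targets comfortable
margins.
"""

from __future__ import annotations

import numpy as np

from popscan.diversity import WindowSpec, site_pi, window_diversity
from popscan.gene_flow import d_test, nm_from_fst
from popscan.genotype_io import GenotypeMatrix, PopulationMap
from popscan.ld_decay import decay_curve
from popscan.selection_scan import call_sweeps, window_scan
from popscan.simulate import Event, SimConfig, inject_sweep, simulate_four_pop, simulate_wf

__all__ = [
    "two_deme_island_config",
    "equilibrium_calibration",
    "oracle_equivalence",
    "fst_vs_migration",
    "sweep_recovery",
    "dstat_calibration",
    "ld_monotonicity",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _sim_popmap(gm: GenotypeMatrix) -> PopulationMap:
    """Population map recovering the deme from simulator sample IDs."""
    return PopulationMap({s: s.rsplit("_", 1)[0] for s in gm.samples})


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def two_deme_island_config(
    nm: float,
    deme_size: int = 50,
    mu: float = 1e-5,
    seq_length: int = 100_000,
    n_chrom: int = 20,
    sample_size: int = 30,
    seed: int = 0,
    burn_in: int | None = None,
    rec: float = 4e-6,
) -> SimConfig:
    """Symmetric two-deme config calibrated to Wright's island-model FST.

    Wright's FST = 1/(1 + 4Nm) assumes migrants drawn from an infinite pool
    of unrelated genes. With only two demes of size N exchanging migrants at
    per-gene rate m, coalescent times are T_within = 4N and
    T_between = 4N + 1/(2m), and the Weir-Cockerham ratio-of-sums estimator
    converges to (T_between - T_within)/T_between = 1/(1 + 8Nm)
    (verified empirically). Setting the simulated rate to m = nm / (2N)
    therefore makes the realized equilibrium FST match Wright's 1/(1 + 4 nm)
    for the configured migrant number ``nm``.
    """
    m = nm / (2.0 * deme_size)
    return SimConfig(
        seq_length=seq_length,
        n_chrom=n_chrom,
        mu=mu,
        rec=rec,
        demes=[("A", deme_size), ("B", deme_size)],
        migration={"A": {"B": m}, "B": {"A": m}},
        sample_sizes={"A": sample_size, "B": sample_size},
        seed=seed,
        burn_in=burn_in,
    )


# ---------------------------------------------------------------------------
# criterion 1: estimator calibration at neutral equilibrium
# ---------------------------------------------------------------------------


def equilibrium_calibration(
    seed: int,
    deme_size: int = 100,
    mu: float = 5e-6,
    chrom_length: int = 110_000,
    n_chrom: int = 20,
    rec: float = 2e-6,
) -> dict:
    """Single-deme equilibrium: windowed theta_pi / theta_w vs 4*N*mu.

    Defaults give 4*N*mu = 2e-3 per bp (thousands of expected SNPs over
    2.2 Mb) and 440 10kb/5kb windows. Recombination is set high enough that
    windows are quasi-independent, which tames the deep-genealogy variance of
    the window means.
    """
    cfg = SimConfig(
        seq_length=chrom_length,
        n_chrom=n_chrom,
        mu=mu,
        rec=rec,
        demes=[("A", deme_size)],
        sample_sizes={"A": deme_size},
        seed=seed,
    )
    gm, truth = simulate_wf(cfg)
    pm = _sim_popmap(gm)
    wt = window_diversity(gm, pm, "A", WindowSpec(10_000, 5_000))
    theta = truth.theta_per_site
    pi_mean = float(np.nanmean(wt["theta_pi"]))
    w_mean = float(np.nanmean(wt["theta_w"]))
    return {
        "theta_true": theta,
        "n_windows": int(len(wt)),
        "n_snps": int(gm.n_sites),
        "theta_pi_mean": pi_mean,
        "theta_w_mean": w_mean,
        "theta_pi_rel_bias": pi_mean / theta - 1.0,
        "theta_w_rel_bias": w_mean / theta - 1.0,
        "tajimas_d_mean": float(np.nanmean(wt["tajimas_d"])),
    }


# ---------------------------------------------------------------------------
# criterion 2: oracle equivalence on random small matrices
# ---------------------------------------------------------------------------


def oracle_equivalence(seed: int, n_matrices: int = 100) -> dict:
    """Optimized statistics vs brute-force references on random matrices.

    Returns the maximum absolute deviation per statistic over ``n_matrices``
    random dosage matrices of <= 10 samples x <= 50 sites.
    """
    from popscan.gene_flow import d_statistic
    from popscan.ld_decay import pair_r2
    from popscan.phylo import p_distance
    from popscan.reference import (
        ref_d_haploid_counts,
        ref_fst_wc,
        ref_p_distance,
        ref_r2,
        ref_site_pi,
    )
    from popscan.selection_scan import site_fst_wc

    rng = np.random.Generator(np.random.PCG64(seed))
    errs = {k: 0.0 for k in ("site_pi", "fst", "r2", "d_stat", "p_distance")}
    for _ in range(n_matrices):
        n_samp = int(rng.integers(4, 11))
        n_sites = int(rng.integers(10, 51))
        dos = rng.integers(0, 3, size=(n_sites, n_samp)).astype(np.int8)

        # theta_pi per site
        for row in dos[: min(10, n_sites)]:
            p = row.sum() / (2.0 * n_samp)
            mine = site_pi(p, 2 * n_samp)
            ref = ref_site_pi(row)
            errs["site_pi"] = max(errs["site_pi"], abs(float(mine) - ref))

        # WC84 FST components on a random split of the samples
        half = n_samp // 2
        p1 = dos[:, :half].sum(axis=1) / (2.0 * half)
        p2 = dos[:, half:].sum(axis=1) / (2.0 * (n_samp - half))
        n1 = np.full(n_sites, 2 * half)
        n2 = np.full(n_sites, 2 * (n_samp - half))
        a, d = site_fst_wc(p1, n1, p2, n2)
        for i in range(n_sites):
            ra, rd = ref_fst_wc(float(p1[i]), int(n1[i]), float(p2[i]), int(n2[i]))
            errs["fst"] = max(errs["fst"], abs(a[i] - ra), abs(d[i] - rd))

        # r^2 on random site pairs
        for _ in range(5):
            i, j = rng.integers(0, n_sites, 2)
            mine = pair_r2(dos[i], dos[j])
            ref = ref_r2(dos[i], dos[j])
            if np.isnan(mine) and np.isnan(ref):
                continue
            errs["r2"] = max(errs["r2"], abs(mine - ref))

        # D statistic with haploid single-sequence populations (0/2 coded)
        hap = (rng.integers(0, 2, size=(n_sites, 4)) * 2).astype(np.int8)
        freqs = [hap[:, k] / 2.0 for k in range(4)]
        mine, _, _, _ = d_statistic(*freqs, outgroup_tol=0.0)
        ref = ref_d_haploid_counts(*(hap[:, k] // 2 for k in range(4)))
        if not (np.isnan(mine) and np.isnan(ref)):
            errs["d_stat"] = max(errs["d_stat"], abs(mine - ref))

        # p-distance on the first two samples
        gm = GenotypeMatrix(
            samples=[f"s{k}" for k in range(n_samp)],
            chrom=np.array(["chr1"] * n_sites, dtype=object),
            pos=np.arange(1, n_sites + 1),
            ref=["A"] * n_sites,
            alts=[("T",)] * n_sites,
            qual=np.full(n_sites, 60.0),
            dosages=dos,
            chrom_lengths={"chr1": n_sites},
        )
        dm = p_distance(gm)
        ref = ref_p_distance(dos[:, 0], dos[:, 1])
        errs["p_distance"] = max(errs["p_distance"], abs(dm.d[0, 1] - ref))
    errs["max_abs_error"] = max(errs.values())
    return errs


# ---------------------------------------------------------------------------
# criterion 3: FST vs migration in the island model
# ---------------------------------------------------------------------------


def fst_vs_migration(seed: int, nm_values: tuple[float, ...] = (0.5, 2.0)) -> dict:
    """Two-deme island model: realized windowed FST vs 1/(1+4Nm)."""
    out: dict = {}
    seeds = _spawn_seeds(seed, len(nm_values))
    for nm, s in zip(nm_values, seeds):
        cfg = two_deme_island_config(nm, seed=s)
        gm, _ = simulate_wf(cfg)
        pm = _sim_popmap(gm)
        wt = window_scan(gm, pm, "A", "B", WindowSpec(100_000, 10_000))
        fst = float(np.nanmean(wt["fst"]))
        expected = 1.0 / (1.0 + 4.0 * nm)
        nm_hat = nm_from_fst(fst).nm
        key = str(nm).rstrip("0").rstrip(".")
        out[f"fst_nm_{key}"] = fst
        out[f"fst_expected_nm_{key}"] = expected
        out[f"fst_rel_err_nm_{key}"] = fst / expected - 1.0
        out[f"nm_recovered_nm_{key}"] = nm_hat
        out[f"nm_ratio_nm_{key}"] = nm_hat / nm
    return out


# ---------------------------------------------------------------------------
# criterion 4: sweep recovery
# ---------------------------------------------------------------------------


def sweep_recovery(
    seed: int,
    n_reps: int = 50,
    chrom_length: int = 600_000,
    interval: tuple[int, int] = (200_001, 400_000),
    wild_size: int = 60,
    dom_size: int = 60,
    divergence: int = 10,
    mu: float = 8.3e-6,
    rec: float = 1e-6,
) -> dict:
    """Injected-sweep recovery with the three-criterion caller.

    Per replicate: a domesticated deme splits from the wild deme and drifts
    for ``divergence`` generations; a founder_count=2 sweep is injected into
    the domesticated deme over ``interval``; the caller runs with the exact
    thresholds (FST > 0.15, top decile, ROD > 0.2). Reports the fraction of
    replicates whose called regions overlap the true interval and the mean
    fraction of the non-sweep genome covered by calls not overlapping it.
    """
    seeds = _spawn_seeds(seed, n_reps)
    hits = 0
    fp_fracs: list[float] = []
    start, end = interval
    nonsweep_len = chrom_length - (end - start + 1)
    for s in seeds:
        cfg = SimConfig(
            seq_length=chrom_length,
            n_chrom=1,
            mu=mu,
            rec=rec,
            demes=[("wild", wild_size)],
            events=[Event(0, "split", ("wild", "dom", dom_size))],
            generations=divergence,
            sample_sizes={"wild": 20, "dom": 20},
            seed=s,
        )
        gm, _ = simulate_wf(cfg)
        pm = _sim_popmap(gm)
        dom_samples = pm.samples_in("dom")
        gm = inject_sweep(gm, dom_samples, ("chr1", start, end), founder_count=2, seed=s)
        wt = window_scan(gm, pm, "wild", "dom", WindowSpec(100_000, 10_000))
        regions, _ = call_sweeps(wt)
        hit = False
        fp_bp = 0
        for _, r in regions.iterrows():
            if r["start"] <= end and r["end"] >= start:
                hit = True
            else:
                fp_bp += int(r["end"]) - int(r["start"]) + 1
        hits += hit
        fp_fracs.append(fp_bp / nonsweep_len)
    return {
        "n_reps": n_reps,
        "overlap_rate": hits / n_reps,
        "false_positive_fraction": float(np.mean(fp_fracs)),
    }


# ---------------------------------------------------------------------------
# criterion 5: D-statistic calibration and power
# ---------------------------------------------------------------------------


def _dstat_reps(seed: int, n_reps: int, f: float) -> tuple[np.ndarray, np.ndarray]:
    seeds = _spawn_seeds(seed, n_reps)
    ds = np.empty(n_reps)
    zs = np.empty(n_reps)
    for k, s in enumerate(seeds):
        gm, _ = simulate_four_pop(
            deme_size=20,
            seq_length=120_000,
            n_chrom=3,
            mu=2.5e-5,
            rec=1e-5,
            f=f,
            sample_size=12,
            seed=s,
            split_times=(0, 100, 140),
            admix_time=160,
            total_generations=170,
            burn_in=200,
        )
        pm = _sim_popmap(gm)
        res = d_test(gm, pm, ("W", "X", "Y", "Z"))
        ds[k] = res.d
        zs[k] = res.z_score
    return ds, zs


def dstat_calibration(seed: int, n_reps: int = 100) -> dict:
    """Null (f=0) false-positive rate and admixed (f=0.3) power of |Z| > 3.

    Admixture flows from Y into X, so for the quartet order (W, X, Y, Z) the
    expected sign of D (and Z) under admixture is negative.
    """
    s_null, s_adm = _spawn_seeds(seed, 2)
    d0, z0 = _dstat_reps(s_null, n_reps, f=0.0)
    d3, z3 = _dstat_reps(s_adm, n_reps, f=0.3)
    return {
        "n_reps": n_reps,
        "null_fpr": float(np.mean(np.abs(z0) > 3)),
        "null_z_mean": float(np.mean(z0)),
        "null_z_sd": float(np.std(z0)),
        "power_f03": float(np.mean(np.abs(z3) > 3)),
        "sign_match_f03": float(np.mean(z3 < 0)),
        "d_mean_f03": float(np.mean(d3)),
        "d_mean_null": float(np.mean(d0)),
    }


# ---------------------------------------------------------------------------
# criterion 6: LD decay monotonicity and the bottleneck contrast
# ---------------------------------------------------------------------------


def ld_monotonicity(
    seed: int,
    rec_values: tuple[float, ...] = (1e-8, 5e-8, 1e-7),
    n_reps: int = 10,
) -> dict:
    """Half-decay distance ordering across recombination rates, plus the
    bottleneck-vs-ancestral LD contrast."""
    seeds = _spawn_seeds(seed, n_reps * (len(rec_values) + 1))
    it = iter(seeds)
    strict = 0
    halves = {r: [] for r in rec_values}
    for _ in range(n_reps):
        vals = []
        for rec in rec_values:
            # N = 200 keeps all three half-decay scales resolvable inside one
            # 400 kb chromosome; 5 kb bins resolve the fastest decay so the
            # half-maximum target stays above the finite-sample r^2 floor
            cfg = SimConfig(
                seq_length=400_000,
                n_chrom=3,
                mu=1.25e-6,
                rec=rec,
                demes=[("A", 200)],
                sample_sizes={"A": 60},
                seed=next(it),
                burn_in=800,
            )
            gm, _ = simulate_wf(cfg)
            pm = _sim_popmap(gm)
            curve = decay_curve(
                gm, pm, "A", max_dist=390_000, bin_width=5_000,
                max_pairs=300_000, smooth_bins=3, seed=1,
            )
            vals.append(curve.half_distance)
            halves[rec].append(curve.half_distance)
        # a curve still above half-maximum at max_dist has half-distance
        # > max_dist: a censored value, ordered above any measured one.
        # Two censored arms cannot be ordered strictly -> not counted.
        v = [np.inf if np.isnan(x) else x for x in vals]
        if sum(np.isinf(x) for x in v) <= 1 and v[0] > v[1] > v[2]:
            strict += 1

    bottleneck_longer = 0
    for _ in range(n_reps):
        # 8 short chromosomes average away the genealogical noise of the
        # heavily drifted bottleneck deme
        cfg = SimConfig(
            seq_length=250_000,
            n_chrom=8,
            mu=2.5e-6,
            rec=3e-7,
            demes=[("wild", 100)],
            events=[Event(0, "split", ("wild", "dom", 15))],
            generations=150,
            sample_sizes={"wild": 30, "dom": 15},
            seed=next(it),
        )
        gm, _ = simulate_wf(cfg)
        pm = _sim_popmap(gm)
        kw = dict(max_dist=240_000, bin_width=5_000, max_pairs=300_000,
                  smooth_bins=5, seed=1)
        h_wild = decay_curve(gm, pm, "wild", **kw).half_distance
        h_dom = decay_curve(gm, pm, "dom", **kw).half_distance
        # a bottlenecked curve that never falls to half-max within range is
        # the extreme of the expected long-LD pattern (censored above)
        if (np.isnan(h_dom) and not np.isnan(h_wild)) or (
            not np.isnan(h_dom) and not np.isnan(h_wild) and h_dom > h_wild
        ):
            bottleneck_longer += 1
    return {
        "n_reps": n_reps,
        "strict_ordering_rate": strict / n_reps,
        "bottleneck_longer_rate": bottleneck_longer / n_reps,
        "half_distance_means": {
            str(r): float(np.nanmean(v)) for r, v in halves.items()
        },
    }
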