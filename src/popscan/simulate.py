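"""Forward-in-time Wright-Fisher simulator with known truth.

Multi-deme diploid Wright-Fisher reproduction with per-gamete migration,
Poisson recombination (uniform breakpoints), infinite-sites mutation on
integer base-pair positions (collisions re-drawn), demographic events
(deme splits, bottlenecks, admixture pulses), and post-hoc sweep injection.

Chromosomes are simulated independently (free recombination between
chromosomes); all randomness flows from a single seed through spawned
child generators, so a fixed seed yields byte-identical output.

The simulator exists so that every downstream estimator in this package has a
recovery test against configured truth; it is not in the analysis path.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from popscan.genotype_io import MISSING, DataError, GenotypeMatrix

__all__ = [
    "Event",
    "SimConfig",
    "SimTruth",
    "simulate_wf",
    "inject_sweep",
    "simulate_four_pop",
]


@dataclasses.dataclass(frozen=True)
class Event:
    """A demographic event scheduled ``time`` generations after burn-in.

    Kinds
    -----
    split:        params ``(parent, name, size)`` — found a new deme of
                  ``size`` diploids by copying individuals from ``parent``.
    bottleneck:   params ``(deme, size)`` — instantaneous resize.
    admixture:    params ``(dest, source, fraction)`` — one-generation pulse:
                  each gene copy born into ``dest`` draws its parent from
                  ``source`` with probability ``fraction``.
    """

    time: int
    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("split", "bottleneck", "admixture"):
            raise DataError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise DataError("event time must be >= 0 (generations after burn-in)")


@dataclasses.dataclass
class SimConfig:
    """Parameters of a Wright-Fisher run.

    Attributes
    ----------
    seq_length:
        Chromosome length in bp (all chromosomes equal length).
    n_chrom:
        Number of independently simulated chromosomes.
    mu, rec:
        Mutation / recombination probability per bp per generation.
    demes:
        Initial demes as ``(name, diploid size)`` pairs.
    migration:
        ``{dest: {source: rate}}`` — probability that a gene copy born in
        ``dest`` has its parent in ``source``. Off-diagonal row sums must be
        <= 1; the remainder is the within-deme probability.
    events:
        Demographic events, ordered by non-decreasing time.
    burn_in:
        Generations before the event clock starts; default 10 x max deme size.
    generations:
        Generations simulated after burn-in, i.e. the sampling time on the
        event clock.
    sample_sizes:
        Diploids sampled per deme at the end.
    seed:
        Master seed; fixed seed implies identical output.
    """

    seq_length: int
    mu: float
    rec: float
    demes: list[tuple[str, int]]
    sample_sizes: dict[str, int]
    seed: int
    n_chrom: int = 1
    migration: dict[str, dict[str, float]] | None = None
    events: list[Event] = dataclasses.field(default_factory=list)
    burn_in: int | None = None
    generations: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1 or self.n_chrom < 1:
            raise DataError("seq_length and n_chrom must be positive")
        if self.mu < 0 or self.rec < 0:
            raise DataError("mu and rec must be >= 0")
        names = [n for n, _ in self.demes]
        if len(set(names)) != len(names):
            raise DataError("duplicate deme names")
        if any(n < 1 for _, n in self.demes):
            raise DataError("deme sizes must be >= 1")
        if self.migration:
            for dest, row in self.migration.items():
                if any(r < 0 for r in row.values()):
                    raise DataError("migration rates must be >= 0")
                if sum(r for s, r in row.items() if s != dest) > 1 + 1e-12:
                    raise DataError(f"migration row for {dest!r} sums to > 1")
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise DataError("events must be ordered by non-decreasing time")
        if times and times[-1] > self.generations:
            raise DataError("event scheduled after the sampling generation")

    @property
    def effective_burn_in(self) -> int:
        if self.burn_in is not None:
            return int(self.burn_in)
        return 10 * max(n for _, n in self.demes)


@dataclasses.dataclass
class SimTruth:
    """Ground-truth parameters recorded alongside a simulated matrix."""

    theta_per_site: float  # 4*N*mu for the first (focal) deme
    migration: dict[str, dict[str, float]] | None
    sweep_interval: tuple[str, int, int] | None = None
    admixture_fraction: float | None = None
    founder_count: int | None = None
    seed: int | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# core engine (single chromosome)
# ---------------------------------------------------------------------------


class _Chrom:
    """Haplotype state of one chromosome: per-deme boolean matrices over a
    shared column set.

    Columns are NOT kept position-sorted during evolution (sorting every
    generation is the dominant cost); they are sorted once at sampling time.
    ``pos_set`` mirrors ``pos`` for O(1) collision checks.
    """

    def __init__(self, deme_sizes: dict[str, int]):
        self.sizes = dict(deme_sizes)
        self.pos = np.empty(0, dtype=np.int64)
        self.pos_set: set[int] = set()
        self.haps: dict[str, np.ndarray] = {
            d: np.zeros((2 * n, 0), dtype=bool) for d, n in deme_sizes.items()
        }

    @property
    def total_haps(self) -> int:
        return sum(2 * n for n in self.sizes.values())

    def prune_fixed(self) -> None:
        if self.pos.size == 0:
            return
        count = np.zeros(self.pos.size, dtype=np.int64)
        for h in self.haps.values():
            count += h.sum(axis=0)
        keep = (count > 0) & (count < self.total_haps)
        if not keep.all():
            self.pos = self.pos[keep]
            self.pos_set = set(int(p) for p in self.pos)
            for d in self.haps:
                self.haps[d] = self.haps[d][:, keep]


def _mig_row(
    dest: str,
    names: list[str],
    migration: dict[str, dict[str, float]] | None,
    override: tuple[str, str, float] | None,
) -> np.ndarray:
    """Parent-deme probability vector for children born in ``dest``."""
    probs = np.zeros(len(names))
    if migration and dest in migration:
        for j, s in enumerate(names):
            if s != dest:
                probs[j] = migration[dest].get(s, 0.0)
    probs[names.index(dest)] = 1.0 - probs.sum()
    if override is not None and override[0] == dest:
        _, source, f = override
        probs *= 1.0 - f
        probs[names.index(source)] += f
    return probs


def _apply_crossovers(
    gamete: np.ndarray,
    other: np.ndarray,
    pos: np.ndarray,
    breakpoints: np.ndarray,
) -> None:
    """Overwrite alternating segments of ``gamete`` with ``other`` in place.

    A breakpoint at coordinate b means the gamete switches template for all
    sites with position > b. ``pos`` need not be sorted; ``breakpoints`` must
    be sorted ascending.
    """
    segment = np.searchsorted(breakpoints, pos, side="left")
    odd = (segment % 2).astype(bool)
    gamete[odd] = other[odd]


def _step(
    st: _Chrom,
    cfg: SimConfig,
    rng: np.random.Generator,
    override: tuple[str, str, float] | None = None,
) -> None:
    """One non-overlapping Wright-Fisher generation for every live deme."""
    names = list(st.haps)
    L = cfg.seq_length
    new_haps: dict[str, np.ndarray] = {}
    for dest in names:
        n_gam = 2 * st.sizes[dest]
        probs = _mig_row(dest, names, cfg.migration, override)
        self_idx = names.index(dest)
        if probs[self_idx] >= 1.0:
            src = np.full(n_gam, self_idx, dtype=np.int64)
        else:
            src = rng.choice(len(names), size=n_gam, p=probs)
        child = np.empty((n_gam, st.pos.size), dtype=bool)
        for k, sname in enumerate(names):
            sel = np.flatnonzero(src == k)
            if sel.size == 0:
                continue
            H = st.haps[sname]
            n_src = H.shape[0] // 2
            par = rng.integers(0, n_src, sel.size)
            start = rng.integers(0, 2, sel.size)
            child[sel] = H[2 * par + start]
            n_x = rng.poisson(cfg.rec * L, sel.size)
            single = np.flatnonzero(n_x == 1)
            if single.size:  # vectorized fast path for 1-crossover meioses
                bps = rng.integers(1, L, single.size)
                other = H[2 * par[single] + 1 - start[single]]
                swap = st.pos[None, :] > bps[:, None]
                rows = child[sel[single]]
                child[sel[single]] = np.where(swap, other, rows)
            for t in np.flatnonzero(n_x > 1):
                bps = np.sort(rng.integers(1, L, n_x[t]))
                _apply_crossovers(
                    child[sel[t]], H[2 * par[t] + 1 - start[t]], st.pos, bps
                )
        new_haps[dest] = child
    st.haps = new_haps

    # infinite-sites mutation: one new biallelic column per mutation event
    tot = st.total_haps
    n_mut = rng.poisson(cfg.mu * L * tot)
    if n_mut > 0:
        new_pos: list[int] = []
        while len(new_pos) < n_mut:
            cand = np.unique(rng.integers(1, L + 1, n_mut - len(new_pos)))
            fresh = [int(c) for c in cand if int(c) not in st.pos_set]
            take = fresh[: n_mut - len(new_pos)]
            new_pos.extend(take)  # collisions re-drawn next round
            st.pos_set.update(take)
        carriers = rng.integers(0, tot, n_mut)
        offsets = {}
        off = 0
        for d in st.haps:
            offsets[d] = off
            off += st.haps[d].shape[0]
        for d in st.haps:
            block = np.zeros((st.haps[d].shape[0], n_mut), dtype=bool)
            local = carriers - offsets[d]
            in_deme = (local >= 0) & (local < st.haps[d].shape[0])
            block[local[in_deme], np.flatnonzero(in_deme)] = True
            st.haps[d] = np.concatenate((st.haps[d], block), axis=1)
        st.pos = np.concatenate((st.pos, np.array(new_pos, dtype=np.int64)))


def _apply_event(st: _Chrom, ev: Event, rng: np.random.Generator) -> None:
    if ev.kind == "split":
        parent, name, size = ev.params
        if parent not in st.haps:
            raise DataError(f"split from unknown deme {parent!r}")
        if name in st.haps:
            raise DataError(f"split creates existing deme {name!r}")
        n_par = st.haps[parent].shape[0] // 2
        founders = rng.choice(n_par, size=size, replace=size > n_par)
        rows = np.stack([2 * founders, 2 * founders + 1], axis=1).ravel()
        st.haps[name] = st.haps[parent][rows].copy()
        st.sizes[name] = size
    elif ev.kind == "bottleneck":
        deme, size = ev.params
        if deme not in st.haps:
            raise DataError(f"bottleneck of unknown deme {deme!r}")
        n_cur = st.haps[deme].shape[0] // 2
        kept = rng.choice(n_cur, size=size, replace=size > n_cur)
        rows = np.stack([2 * kept, 2 * kept + 1], axis=1).ravel()
        st.haps[deme] = st.haps[deme][rows].copy()
        st.sizes[deme] = size
    # admixture is handled as a transient migration override in the main loop


def _run_chromosome(
    cfg: SimConfig, rng: np.random.Generator, prune_every: int = 25
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Evolve one chromosome; return (positions, per-deme haplotype matrices)."""
    st = _Chrom({d: n for d, n in cfg.demes})
    for g in range(cfg.effective_burn_in):
        _step(st, cfg, rng)
        if g % prune_every == prune_every - 1:
            st.prune_fixed()
    events = list(cfg.events)
    for g in range(cfg.generations + 1):
        override = None
        while events and events[0].time == g:
            ev = events.pop(0)
            if ev.kind == "admixture":
                dest, source, f = ev.params
                if dest not in st.haps or source not in st.haps:
                    raise DataError("admixture between unknown demes")
                override = (dest, source, float(f))
            else:
                _apply_event(st, ev, rng)
        if g == cfg.generations:
            break
        _step(st, cfg, rng, override=override)
        if g % prune_every == prune_every - 1:
            st.prune_fixed()
    st.prune_fixed()
    order = np.argsort(st.pos, kind="stable")
    return st.pos[order], {d: h[:, order] for d, h in st.haps.items()}


def simulate_wf(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run the Wright-Fisher simulation described by ``cfg``.

    Returns a :class:`GenotypeMatrix` over the sampled diploids (sites
    monomorphic across the whole sample are dropped, mirroring real variant
    calls against a reference) and a :class:`SimTruth` with the configured
    parameters. The focal deme for ``theta_per_site`` is the first configured
    deme.
    """
    truth = SimTruth(
        theta_per_site=4.0 * cfg.demes[0][1] * cfg.mu,
        migration=cfg.migration,
        seed=cfg.seed,
    )
    min_burn = 10 * max(n for _, n in cfg.demes)
    if cfg.effective_burn_in < min_burn:
        truth.warnings.append(
            f"burn_in {cfg.effective_burn_in} < 10 x max deme size ({min_burn}); "
            "equilibrium not guaranteed"
        )

    ss = np.random.SeedSequence(cfg.seed)
    chrom_seeds = ss.spawn(cfg.n_chrom)

    sample_ids: list[str] | None = None
    chroms_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    dos_out: list[np.ndarray] = []
    chrom_lengths: dict[str, int] = {}

    for c in range(cfg.n_chrom):
        rng = np.random.Generator(np.random.PCG64(chrom_seeds[c]))
        pos, haps = _run_chromosome(cfg, rng)
        cols: list[np.ndarray] = []
        ids: list[str] = []
        for deme, k in cfg.sample_sizes.items():
            if deme not in haps:
                raise DataError(f"sample requested from unknown/extinct deme {deme!r}")
            n_d = haps[deme].shape[0] // 2
            if k > n_d:
                raise DataError(f"sample size {k} exceeds deme {deme!r} size {n_d}")
            chosen = rng.choice(n_d, size=k, replace=False)
            for i in chosen:
                cols.append(
                    haps[deme][2 * i].astype(np.int8) + haps[deme][2 * i + 1].astype(np.int8)
                )
            ids.extend(f"{deme}_{j}" for j in range(k))
        if sample_ids is None:
            sample_ids = ids
        dosages = (
            np.stack(cols, axis=1)
            if cols and pos.size
            else np.empty((pos.size, len(ids)), dtype=np.int8)
        )
        # drop sites monomorphic within the sample
        if pos.size:
            tot = dosages.sum(axis=1)
            seg = (tot > 0) & (tot < 2 * len(ids))
            pos, dosages = pos[seg], dosages[seg]
        name = f"chr{c + 1}"
        chrom_lengths[name] = cfg.seq_length
        chroms_out.append(np.full(pos.size, name, dtype=object))
        pos_out.append(pos)
        dos_out.append(dosages)

    assert sample_ids is not None
    n_sites = sum(p.size for p in pos_out)
    gm = GenotypeMatrix(
        samples=sample_ids,
        chrom=np.concatenate(chroms_out) if n_sites else np.empty(0, dtype=object),
        pos=np.concatenate(pos_out) if n_sites else np.empty(0, dtype=np.int64),
        ref=["A"] * n_sites,
        alts=[("T",)] * n_sites,
        qual=np.full(n_sites, 60.0),
        dosages=(
            np.concatenate(dos_out, axis=0)
            if n_sites
            else np.empty((0, len(sample_ids)), dtype=np.int8)
        ),
        chrom_lengths=chrom_lengths,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# sweep injection
# ---------------------------------------------------------------------------


def inject_sweep(
    gm: GenotypeMatrix,
    deme_samples: Sequence[str],
    interval: tuple[str, int, int],
    founder_count: int,
    seed: int = 0,
    assignment: str = "random",
) -> GenotypeMatrix:
    """Collapse haplotype diversity of ``deme_samples`` inside ``interval``.

    Within the interval each target pseudo-haplotype (derived from dosages by
    a deterministic split: dosage 1 -> alleles (1, 0)) is replaced by one of
    ``founder_count`` founder haplotypes drawn from the same deme. Genotypes
    outside the interval are untouched, so diversity inside the interval can
    only decrease.

    ``assignment='identity'`` requires ``founder_count == 2 * len(deme_samples)``
    and maps every haplotype to itself (a no-op, useful for testing).
    """
    chrom, start, end = interval
    if chrom not in gm.chrom_lengths and chrom not in set(gm.chrom):
        raise DataError(f"interval chromosome {chrom!r} not in matrix")
    length = gm.chrom_length(chrom)
    if start < 1 or end > length or start > end:
        raise DataError(f"interval {interval} outside chromosome bounds (1..{length})")
    idx = gm.sample_indices(deme_samples)
    n_haps = 2 * len(idx)
    if not 1 <= founder_count <= n_haps:
        raise DataError(f"founder_count must be in [1, {n_haps}]")
    if assignment == "identity":
        if founder_count != n_haps:
            raise DataError("identity assignment requires founder_count == 2 x samples")
        return gm.take_sites(np.arange(gm.n_sites))
    if assignment != "random":
        raise DataError(f"unknown assignment mode {assignment!r}")

    in_iv = (gm.chrom == chrom) & (gm.pos >= start) & (gm.pos <= end)
    sub = gm.dosages[np.ix_(in_iv, idx)].astype(np.int16)
    sub = np.where(sub == MISSING, 0, sub)  # simulated data carries no missing
    hap_a = (sub + 1) // 2  # het -> (1, 0)
    hap_b = sub // 2
    haps = np.empty((sub.shape[0], n_haps), dtype=np.int16)
    haps[:, 0::2] = hap_a
    haps[:, 1::2] = hap_b

    rng = np.random.Generator(np.random.PCG64(seed))
    founders = rng.choice(n_haps, size=founder_count, replace=False)
    choice = rng.integers(0, founder_count, n_haps)
    new_haps = haps[:, founders[choice]]
    new_dos = (new_haps[:, 0::2] + new_haps[:, 1::2]).astype(np.int8)

    out = gm.take_sites(np.arange(gm.n_sites))
    out.dosages[np.ix_(np.flatnonzero(in_iv), idx)] = new_dos
    return out


# ---------------------------------------------------------------------------
# four-population scenario for D-statistic testing
# ---------------------------------------------------------------------------


def simulate_four_pop(
    deme_size: int = 40,
    seq_length: int = 300_000,
    n_chrom: int = 1,
    mu: float = 1.25e-5,
    rec: float = 2.5e-7,
    f: float = 0.0,
    sample_size: int = 10,
    seed: int = 0,
    split_times: tuple[int, int, int] = (0, 200, 280),
    admix_time: int = 320,
    total_generations: int = 360,
    burn_in: int | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate four demes with topology ((W,X),Y) plus outgroup Z.

    The ancestral deme is labelled X so the final deme names are W, X, Y, Z.
    On the post-burn-in clock, Z splits off at ``split_times[0]``, Y at
    ``split_times[1]``, and W at ``split_times[2]``; an optional single-pulse
    admixture of fraction ``f`` flows from Y into X at ``admix_time``. With
    ``f == 0`` the W/X pair is exchangeable with respect to Y (the D-statistic
    null).
    """
    if not 0 <= f < 1:
        raise DataError("admixture fraction must be in [0, 1)")
    t_z, t_y, t_w = split_times
    events = [
        Event(t_z, "split", ("X", "Z", deme_size)),
        Event(t_y, "split", ("X", "Y", deme_size)),
        Event(t_w, "split", ("X", "W", deme_size)),
    ]
    if f > 0:
        events.append(Event(admix_time, "admixture", ("X", "Y", f)))
    cfg = SimConfig(
        seq_length=seq_length,
        n_chrom=n_chrom,
        mu=mu,
        rec=rec,
        demes=[("X", deme_size)],
        migration=None,
        events=events,
        burn_in=burn_in,
        generations=total_generations,
        sample_sizes={d: sample_size for d in ("W", "X", "Y", "Z")},
        seed=seed,
    )
    gm, truth = simulate_wf(cfg)
    truth.admixture_fraction = f if f > 0 else None
    return gm, truth
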