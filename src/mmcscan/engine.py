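"""Forward-in-time diploid Wright-Fisher engine.

Implements neutral reproduction with recombination and infinite-sites
mutation, fitness-weighted reproduction for fixation-conditioned selective
sweeps, instantaneous bottlenecks with recovery, and ψ-sweepstakes episodes
in which one carrier of a focal neutral marker (m2) contributes round(2Nψ)
haplotype slots per generation until m2 fixes.

The population state is a dense 2N x S derived-allele matrix (uint8) managed
by the compiled kernels in :mod:`mmcscan._kernels`; this module owns buffer
capacity, epoch sequencing, fixation conditioning, and sampling.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels as K
from .params import DemographyModel, PsiModel, SelectionModel, SimulationParams

__all__ = [
    "Population",
    "HaplotypeMatrix",
    "burn_in",
    "wf_generation",
    "psi_generation",
    "run_psi_phase",
    "run_sweep",
    "apply_bottleneck",
    "sample_haplotypes",
    "simulate_observed",
    "simulate_training_replicate",
    "RestartLimitError",
]

_COMPACT_EVERY = 32
_EV_CAP = 4096


class RestartLimitError(RuntimeError):
    """Fixation conditioning exceeded the restart cap."""


@dataclasses.dataclass(frozen=True)
class HaplotypeMatrix:
    """A sampled binary haplotype alignment.

    ``matrix`` is n_sample x S (1 = derived), ``positions`` are strictly
    increasing 0-based bp coordinates inside the half-open ``span``.
    Sites monomorphic within the sample are never present.
    """

    matrix: np.ndarray
    positions: np.ndarray
    span: tuple[int, int]

    def __post_init__(self):
        if self.matrix.shape[1] != self.positions.shape[0]:
            raise ValueError("matrix/positions shape mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


def _pow2_at_least(x: int) -> int:
    n = 256
    while n < x:
        n *= 2
    return n


class Population:
    """2N haplotypes evolving forward in time.

    All stochasticity flows from ``seed``: the compiled kernel draws from an
    xorshift128+ stream and python-level choices (sampling times, sampled
    rows, ψ draws) from a numpy Generator, both derived from the same
    SeedSequence, so runs are bit-reproducible.
    """

    def __init__(self, params: SimulationParams, seed: int | None = None,
                 cap: int | None = None):
        if params.lam != 1.0:
            raise ValueError("scale params with scale_params() before simulating")
        self.params = params
        self.N = params.N
        self.n_hap = 2 * params.N
        self.L = params.L
        self.generation = 0
        self.tracked = -1
        ss = np.random.SeedSequence(params.seed if seed is None else seed)
        kseed, gseed = ss.spawn(2)
        self.state = K.seed_state(int(kseed.generate_state(1)[0]))
        self.rng = np.random.default_rng(gseed)
        if cap is None:
            theta = 4.0 * params.N * params.mu * params.L
            live = theta * (np.log(2 * params.N) + 1.0)
            growth = _COMPACT_EVERY * 2 * params.N * params.mu * params.L
            cap = _pow2_at_least(int(3 * live + 2 * growth + 128))
        self._alloc(cap)
        self.n_sites = 0

    # ---- storage ----------------------------------------------------------

    def _alloc(self, cap: int) -> None:
        self.cap = cap
        self.W = cap // 8
        max_hap = self.n_hap
        self._a = np.zeros(max_hap * cap, dtype=np.uint8)
        self._b = np.zeros(max_hap * cap, dtype=np.uint8)
        self._a64 = self._a.view(np.uint64)
        self._b64 = self._b.view(np.uint64)
        self.pos = np.zeros(cap, dtype=np.int64)
        self._parent = np.zeros(max_hap, dtype=np.int64)
        self._strand = np.zeros(max_hap, dtype=np.int64)
        self._counts = np.zeros(cap, dtype=np.int64)
        self._dest = np.zeros(cap, dtype=np.int64)
        self._cum_fit = np.zeros(max_hap // 2 + 1, dtype=np.float64)
        self._carriers = np.zeros(max_hap // 2 + 1, dtype=np.int64)
        self._ev_child = np.zeros(_EV_CAP, dtype=np.int64)
        self._ev_bp = np.zeros(_EV_CAP, dtype=np.int64)

    def _grow(self) -> None:
        old = self.matrix_view().copy()
        oldpos = self.pos[: self.n_sites].copy()
        self._alloc(self.cap * 2)
        self._view2d()[: old.shape[0], : old.shape[1]] = old
        self.pos[: oldpos.shape[0]] = oldpos
        self.n_sites = old.shape[1]

    def _view2d(self) -> np.ndarray:
        return self._a.reshape(-1, self.cap)

    def matrix_view(self) -> np.ndarray:
        """Current n_hap x n_sites view (no copy)."""
        return self._view2d()[: self.n_hap, : self.n_sites]

    @property
    def positions(self) -> np.ndarray:
        return self.pos[: self.n_sites]

    def tracked_count(self) -> int:
        if self.tracked < 0:
            raise ValueError("no tracked allele")
        return int(K.column_count(self._a, self.cap, self.tracked, self.n_hap))

    def tracked_frequency(self) -> float:
        return self.tracked_count() / self.n_hap

    # ---- state surgery (always re-establishes the zero-tail invariant) ----

    def _zero_tails(self) -> None:
        a2 = self._a.reshape(-1, self.cap)
        b2 = self._b.reshape(-1, self.cap)
        a2[:, self.n_sites:] = 0
        b2[:, :] = 0

    def compact(self) -> None:
        """Drop columns fixed or lost in the population (tracked kept)."""
        view = self.matrix_view()
        counts = view.sum(axis=0, dtype=np.int64)
        keep = (counts > 0) & (counts < self.n_hap)
        if self.tracked >= 0:
            keep[self.tracked] = True
        idx = np.flatnonzero(keep)
        new = view[:, idx].copy()
        newpos = self.pos[idx].copy()
        if self.tracked >= 0:
            self.tracked = int(np.searchsorted(idx, self.tracked))
        a2 = self._a.reshape(-1, self.cap)
        a2[: self.n_hap, : new.shape[1]] = new
        self.n_sites = new.shape[1]
        self.pos[: self.n_sites] = newpos
        self._zero_tails()

    def snapshot(self) -> dict:
        return {
            "geno": self.matrix_view().copy(),
            "pos": self.positions.copy(),
            "generation": self.generation,
            "tracked": self.tracked,
            "n_hap": self.n_hap,
        }

    def restore(self, snap: dict) -> None:
        self.n_hap = snap["n_hap"]
        g = snap["geno"]
        self.n_sites = g.shape[1]
        a2 = self._a.reshape(-1, self.cap)
        a2[: self.n_hap, : self.n_sites] = g
        self.pos[: self.n_sites] = snap["pos"]
        self.generation = snap["generation"]
        self.tracked = snap["tracked"]
        self._zero_tails()

    def add_mutation(self, position: int | None = None,
                     haplotype: int | None = None, track: bool = True) -> int:
        """Place a new derived allele on one haplotype; returns its column."""
        if self.n_sites >= self.cap - 8:
            self.compact()
            while self.n_sites >= self.cap - 8:
                self._grow()
        if position is None:
            active = set(self.positions.tolist())
            while True:
                position = int(self.rng.integers(0, self.L))
                if position not in active:
                    break
        elif position in set(self.positions.tolist()):
            raise ValueError(f"position {position} already segregating")
        if haplotype is None:
            haplotype = int(self.rng.integers(0, self.n_hap))
        col = self.n_sites
        a2 = self._a.reshape(-1, self.cap)
        a2[: self.n_hap, col] = 0
        a2[haplotype, col] = 1
        self.pos[col] = position
        self.n_sites += 1
        self._b.reshape(-1, self.cap)[:, col] = 0
        if track:
            self.tracked = col
        return col

    # ---- epochs ------------------------------------------------------------

    def _epoch(self, gens: int, mode: int = K.NEUTRAL,
               s: float = 0.0, h: float = 0.5, psi_slots: int = 0,
               n_child_hap: int | None = None,
               stop_on_absorb: bool = False) -> tuple[int, int]:
        """Run up to ``gens`` generations; returns (gens_done, status)."""
        n_child = self.n_hap if n_child_hap is None else n_child_hap
        done = 0
        status = K.DONE
        while done < gens:
            (self.n_sites, g, status, self.tracked) = K.run_epoch(
                self._a, self._b, self._a64, self._b64, self.W,
                self.pos, self.n_sites, self.n_hap, n_child,
                self.L, self.params.rho, self.params.mu,
                mode, self.tracked, s, h, psi_slots,
                gens - done, _COMPACT_EVERY, stop_on_absorb, self.state,
                self._parent, self._strand, self._counts, self._dest,
                self._cum_fit, self._carriers, self._ev_child, self._ev_bp)
            done += g
            if g > 0:
                self.n_hap = n_child
            if status == K.CAPACITY:
                self.compact()
                if self.n_sites >= self.cap - 64:
                    self._grow()
                continue
            if status in (K.FIXED, K.LOST):
                break
            # status DONE with done == gens falls out of the loop
        self.generation += done
        return done, status

    def last_parents(self) -> np.ndarray:
        """Diploid parent index of each haplotype slot of the last generation."""
        return self._parent[: self.n_hap].copy()


# ---------------------------------------------------------------------------
# population-genetic operations
# ---------------------------------------------------------------------------

def burn_in(pop: Population, params: SimulationParams | None = None) -> Population:
    """10·N generations of neutral WF reproduction from the current state."""
    pop._epoch(10 * pop.N)
    return pop


def wf_generation(pop: Population, params: SimulationParams | None = None,
                  selection: SelectionModel | None = None) -> Population:
    """Advance one Wright-Fisher generation (fitness-weighted if selection)."""
    if selection is None:
        pop._epoch(1)
    else:
        if pop.tracked < 0:
            raise ValueError("selection requires a tracked beneficial allele")
        pop._epoch(1, mode=K.SELECTION, s=selection.s, h=selection.dominance)
    return pop


def psi_generation(pop: Population, params: SimulationParams | None = None,
                   psi: float = 0.0) -> Population:
    """One sweepstakes generation: a carrier of m2 fills round(2Nψ) slots."""
    if pop.tracked < 0:
        raise ValueError("psi_generation requires the tracked marker m2")
    c = pop.tracked_count()
    if c == 0 or c == pop.n_hap:
        raise ValueError("m2 must be segregating (caller detects loss/fixation)")
    slots = int(round(2 * pop.N * psi))
    pop._epoch(1, mode=K.PSI, psi_slots=slots)
    return pop


def run_psi_phase(pop: Population, params: SimulationParams | None = None,
                  psi: float = 0.0, max_restarts: int = 10_000
                  ) -> tuple[Population, str, int]:
    """ψ episode conditioned on fixation of the focal marker m2.

    Introduces m2 on one random haplotype and iterates sweepstakes
    generations until fixation; episodes losing m2 are restarted from the
    pre-episode state.  Returns ``(pop, "fixed", phase_length)``.
    """
    snap = pop.snapshot()
    slots = int(round(2 * pop.N * psi))
    for _ in range(max_restarts):
        pop.restore(snap)
        pop.add_mutation(track=True)
        done, status = pop._epoch(10_000_000, mode=K.PSI, psi_slots=slots,
                                  stop_on_absorb=True)
        if status == K.FIXED:
            pop.tracked = -1
            pop.compact()
            return pop, "fixed", done
    raise RestartLimitError(f"m2 failed to fix in {max_restarts} episodes")


def run_sweep(pop: Population, params: SimulationParams | None = None,
              selection: SelectionModel | None = None,
              max_restarts: int = 10_000) -> tuple[Population, int]:
    """Deterministically conditioned sweep: iterate until the beneficial
    mutation (introduced at selection.position on one haplotype) fixes;
    losses restart from the pre-sweep state.  Returns (pop, fixation_generation).
    """
    if selection is None:
        raise ValueError("selection model required")
    site = selection.site(pop.L)
    snap = pop.snapshot()
    for _ in range(max_restarts):
        pop.restore(snap)
        # infinite sites: in the rare case a neutral variant occupies the
        # sweep site, nudge the beneficial mutation to the next free base
        active = set(pop.positions.tolist())
        bsite = site
        while bsite in active:
            bsite = (bsite + 1) % pop.L
        pop.add_mutation(position=bsite, track=True)
        done, status = pop._epoch(10_000_000, mode=K.SELECTION,
                                  s=selection.s, h=selection.dominance,
                                  stop_on_absorb=True)
        if status == K.FIXED:
            pop.tracked = -1
            pop.compact()
            return pop, pop.generation
    raise RestartLimitError(
        f"beneficial allele failed to fix in {max_restarts} attempts")


def apply_bottleneck(pop: Population, params: SimulationParams | None = None,
                     demog: DemographyModel | None = None) -> Population:
    """Instantaneous contraction to round(βN) diploids for the bottleneck
    duration, then instantaneous recovery to N by offspring sampling from
    the bottlenecked pool."""
    if demog is None or demog.kind != "bottleneck":
        raise ValueError("bottleneck demography required")
    if demog.beta == 1.0:
        return pop
    k = demog.bottleneck_size(pop.N)
    dur = demog.duration_generations(pop.N)
    n_full_hap = 2 * pop.N
    chosen = pop.rng.choice(pop.N, size=k, replace=False)
    rows = np.empty(2 * k, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    view = pop.matrix_view()[rows].copy()
    a2 = pop._a.reshape(-1, pop.cap)
    a2[: 2 * k, : pop.n_sites] = view
    pop.n_hap = 2 * k
    pop._zero_tails()
    pop.compact()
    pop._epoch(dur)
    # instantaneous recovery: one reproduction event back to 2N haplotypes
    pop._epoch(1, n_child_hap=n_full_hap)
    return pop


def sample_haplotypes(pop: Population, n_sample: int,
                      span: tuple[int, int] | None = None) -> HaplotypeMatrix:
    """Draw n_sample haplotypes uniformly without replacement; drop sites
    monomorphic within the sample; restrict and sort positions to span."""
    if n_sample > pop.n_hap:
        raise ValueError(f"n_sample {n_sample} > 2N {pop.n_hap}")
    if span is None:
        span = (0, pop.L)
    rows = pop.rng.choice(pop.n_hap, size=n_sample, replace=False)
    sub = pop.matrix_view()[rows]
    posv = pop.positions
    counts = sub.sum(axis=0, dtype=np.int64)
    keep = ((counts > 0) & (counts < n_sample)
            & (posv >= span[0]) & (posv < span[1]))
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(posv[idx], kind="stable")]
    return HaplotypeMatrix(matrix=np.ascontiguousarray(sub[:, order]),
                           positions=posv[order].astype(np.int64),
                           span=span)


# ---------------------------------------------------------------------------
# scenario drivers
# ---------------------------------------------------------------------------

def _run_demography(pop: Population, demog: DemographyModel) -> None:
    if demog.kind == "bottleneck":
        apply_bottleneck(pop, pop.params, demog)


def simulate_observed(params: SimulationParams, demog: DemographyModel,
                      selection: SelectionModel | None = None,
                      seed: int | None = None) -> HaplotypeMatrix:
    """One observed chromosome: burn-in, demography, then either a
    fixation-conditioned sweep (sampled at fixation) or neutral continuation
    sampled at τ ~ U[0, tau_max] generations after the demographic event."""
    pop = Population(params, seed=seed)
    burn_in(pop)
    _run_demography(pop, demog)
    if selection is not None:
        run_sweep(pop, params, selection)
    else:
        tau_max = demog.tau_max_generations(pop.N)
        tau = int(pop.rng.integers(0, tau_max + 1))
        if tau:
            pop._epoch(tau)
    return sample_haplotypes(pop, params.n_sample)


def simulate_training_replicate(model: str, demog: DemographyModel,
                                params: SimulationParams,
                                psi_prior: PsiModel | None = None,
                                seed: int | None = None,
                                stats_fn=None) -> tuple[np.ndarray, float | None]:
    """One training-region replicate for the Kingman or MMC model.

    The region length is ``params.L`` (by convention, the scan window size).
    Kingman: neutral continuation sampled at τ ~ U[0, tau_max].  MMC: one ψ
    episode (ψ ~ prior) starting where a sweep would start, sampled either at
    m2 fixation or at one of 20 random post-fixation time points — i.e. a
    uniformly chosen one of the 21 sampling epochs per emitted vector.

    Returns ``(summary_vector, psi_draw_or_None)``.
    """
    from .sumstats import compute_summary
    if stats_fn is None:
        stats_fn = compute_summary
    model = model.lower()
    if model not in ("kingman", "mmc"):
        raise ValueError(f"unknown model {model!r}")
    pop = Population(params, seed=seed)
    burn_in(pop)
    _run_demography(pop, demog)
    tau_max = demog.tau_max_generations(pop.N)
    psi_draw: float | None = None
    if model == "kingman":
        tau = int(pop.rng.integers(0, tau_max + 1))
        if tau:
            pop._epoch(tau)
    else:
        if psi_prior is None:
            psi_prior = PsiModel()
        psi_draw = psi_prior.draw(pop.rng)
        run_psi_phase(pop, params, psi_draw)
        # 1 of 21 sampling epochs: fixation itself, else a random later time
        if int(pop.rng.integers(0, 21)) != 0:
            tau = int(pop.rng.integers(0, tau_max + 1))
            if tau:
                pop._epoch(tau)
    m = sample_haplotypes(pop, params.n_sample)
    return stats_fn(m), psi_draw
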