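"""Scenario parameter types and the λ-rescaling rule.

Every simulation in :mod:`mmcscan` is described by four small descriptors:

* :class:`SimulationParams` — population-genetic parameters (N, μ, ρ, L, λ,
  sample size, seed),
* :class:`DemographyModel` — equilibrium or an instantaneous bottleneck of
  severity β lasting ``duration`` generations, followed by instantaneous
  recovery,
* :class:`SelectionModel` — a fixation-conditioned hard sweep from a de novo
  beneficial mutation,
* :class:`PsiModel` — a sweepstakes-reproduction (ψ) episode in which a
  single diploid parent contributes a fraction ψ of the next generation.

All coordinates are 0-based with half-open spans; times are in generations
unless stated otherwise.
"""

from __future__ import annotations

import dataclasses

__all__ = [
    "SimulationParams",
    "DemographyModel",
    "SelectionModel",
    "PsiModel",
    "WindowSpec",
    "scale_params",
    "desk_profile",
]


class InvalidScalingError(ValueError):
    """λ-rescaling would reduce the population below 2 diploids."""


class InvalidDemographyError(ValueError):
    """Bottleneck parameters describe an impossible population."""


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Core population parameters.

    Parameters
    ----------
    N : int
        Diploid population size.
    mu : float
        Mutation rate per site per generation.
    rho : float
        Recombination rate per site per generation.
    L : int
        Chromosome (or training-region) length in base pairs.
    lam : float
        Rescaling factor λ ≥ 1.  ``scale_params`` maps N→N/λ, μ→μλ, ρ→ρλ,
        leaving the population-scaled rates θ=4NμL and 4NρL invariant.
    n_sample : int
        Number of haplotypes drawn when the population is sampled.
    seed : int
        Seed for all random draws of a simulation built from these params.
    """

    N: int
    mu: float
    rho: float
    L: int
    lam: float = 1.0
    n_sample: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.mu < 0 or self.rho < 0:
            raise ValueError("mu and rho must be non-negative")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if not (2 <= self.n_sample <= 2 * self.N):
            raise ValueError(
                f"n_sample must be in [2, 2N]={2 * self.N}, got {self.n_sample}"
            )

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate 4NμL of the whole region."""
        return 4.0 * self.N * self.mu * self.L


def scale_params(params: SimulationParams) -> SimulationParams:
    """Apply the λ-rescaling: N→round(N/λ), μ→μλ, ρ→ρλ.

    θ=4NμL and 4NρL are preserved up to the integer rounding of N.  All
    downstream time quantities are interpreted against the scaled N.
    """
    if params.lam == 1.0:
        return params
    n_scaled = round(params.N / params.lam)
    if n_scaled < 2:
        raise InvalidScalingError(
            f"N/lam = {params.N}/{params.lam} rounds below 2 diploids"
        )
    return dataclasses.replace(
        params,
        N=n_scaled,
        mu=params.mu * params.lam,
        rho=params.rho * params.lam,
        lam=1.0,
        n_sample=min(params.n_sample, 2 * n_scaled),
    )


@dataclasses.dataclass(frozen=True)
class DemographyModel:
    """Equilibrium or a single instantaneous bottleneck.

    A bottleneck reduces the population to ``round(beta*N)`` diploids
    (floored at 2; see docs/methods.md) for ``duration`` generations and then
    recovers instantaneously to N.  Neutral replicates are sampled at
    τ ~ U[0, tau_max] generations after recovery; sweep and ψ replicates
    start their focal mutation at the instant of recovery.

    ``duration=None`` selects the default 0.005×4N generations; ``tau_max``
    of ``None`` selects N generations (an estimate of the fixation time of
    the weakest sweep considered — see docs/methods.md).
    """

    kind: str = "equilibrium"
    beta: float = 1.0
    t_b: float = 0.0
    duration: float | None = None
    tau_max: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("equilibrium", "bottleneck"):
            raise ValueError(f"unknown demography kind {self.kind!r}")
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.kind == "equilibrium":
            if self.beta != 1.0:
                raise ValueError("equilibrium demography requires beta=1")
        if self.duration is not None and self.duration < 1 and self.kind == "bottleneck":
            raise ValueError("bottleneck duration must be >= 1 generation")
        if self.tau_max is not None and self.tau_max < 0:
            raise ValueError("tau_max must be >= 0")

    def bottleneck_size(self, N: int) -> int:
        """Diploid size during the bottleneck, floored at 2."""
        k = round(self.beta * N)
        if k < 1:
            raise InvalidDemographyError(
                f"round(beta*N) = round({self.beta}*{N}) < 1"
            )
        return max(2, k)

    def duration_generations(self, N: int) -> int:
        if self.kind == "equilibrium":
            return 0
        if self.duration is not None:
            return int(round(self.duration))
        return max(1, int(round(0.005 * 4 * N)))

    def tau_max_generations(self, N: int) -> int:
        if self.tau_max is not None:
            return int(round(self.tau_max))
        return N


@dataclasses.dataclass(frozen=True)
class SelectionModel:
    """A hard selective sweep from a de novo beneficial mutation.

    ``s`` is the homozygote selection coefficient (fitnesses 1 : 1+hs : 1+s);
    2Ns at the working N sets the sweep strength.  ``position=None`` places
    the beneficial mutation at floor(L/2).  Replicates in which the allele is
    lost are restarted, so retained replicates are conditioned on fixation.
    """

    s: float
    position: int | None = None
    dominance: float = 0.5
    condition_on_fixation: bool = True

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if self.position is not None and self.position < 0:
            raise ValueError("position must be >= 0")

    def site(self, L: int) -> int:
        pos = L // 2 if self.position is None else self.position
        if not (0 <= pos < L):
            raise ValueError(f"sweep position {pos} outside [0, {L})")
        return pos

    @staticmethod
    def from_2ns(two_ns: float, N: int, **kw) -> "SelectionModel":
        """Build from the population-scaled strength 2Ns at diploid size N."""
        return SelectionModel(s=two_ns / (2 * N), **kw)


@dataclasses.dataclass(frozen=True)
class PsiModel:
    """Sweepstakes-reproduction episode parameters.

    During a ψ episode one carrier of a focal neutral marker m2 contributes
    ``round(2Nψ)`` of the next generation's haplotype slots each generation;
    the episode ends when m2 fixes.  ``psi`` may be fixed, or drawn from
    U[prior_low, prior_high] when building training data.
    """

    psi: float | None = None
    prior_low: float = 0.004
    prior_high: float = 0.08

    def __post_init__(self) -> None:
        if not (0 < self.prior_low < self.prior_high < 1):
            raise ValueError("prior bounds must satisfy 0 < low < high < 1")
        if self.psi is not None and not (0 < self.psi < 1):
            raise ValueError(f"psi must be in (0, 1), got {self.psi}")

    def draw(self, rng) -> float:
        if self.psi is not None:
            return self.psi
        return float(rng.uniform(self.prior_low, self.prior_high))


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """A genomic window: [start, end) in bp."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad window [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start


# Reference full-scale (human-like) parameters: N=1e4, mu=1.2e-8, rho=1e-8,
# lam=2 -> N_scaled=5000. The desk profile below shrinks N and L while
# preserving 2Ns, beta, the rho/mu ratio, the psi prior (which is kept fixed
# under rescaling, as under the lambda-scaling convention) and the training
# regions' segregating-site distribution (see docs/methods.md).


def desk_profile(seed: int = 0) -> dict:
    """Desk-scale study conditions used by the test-suite and examples.

    Returns a dict with keys ``params`` (training-region sized),
    ``obs_params`` (observed-chromosome sized), ``psi`` (prior),
    ``window``/``step`` (scan geometry) and ``tolerance``/``level``
    (ABC settings).
    """
    N = 500
    window = 10_000
    mu = 1e-7
    return {
        "params": SimulationParams(
            N=N, mu=mu, rho=mu / 1.2, L=window, n_sample=20, seed=seed
        ),
        "obs_params": SimulationParams(
            N=N, mu=mu, rho=mu / 1.2, L=100_000, n_sample=20, seed=seed
        ),
        "psi": PsiModel(prior_low=0.004, prior_high=0.08),
        "window": window,
        "step": window // 2,
        "tolerance": 0.10,
        "level": 0.99,
    }
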