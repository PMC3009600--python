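"""Wright-Fisher model of selection on G+C content and its analytic limit.

A haploid population of N short "genomes" (binary sequences of length L over
an effective {A, G} alphabet, where G stands for either strong nucleotide)
evolves by fitness-proportional multinomial resampling and per-site mutation:
G -> A at rate mu_to_AT per site per generation and A -> G at rate mu_to_GC.
Fitness depends only on the number of G/C sites n through a landscape:

* goal landscape      f(n) = exp(-eta * (n - n_opt)^2)   (log-quadratic,
  symmetric around the optimum, strictly positive),
* threshold landscape f(n) = 1 for n <= n_opt, exp(-eta * (n - n_opt)) above
  (moves toward fewer G/C are never deleterious).

Substitutions are counted against a reference genome R: whenever a site's
major-allele frequency exceeds ``fix_thr`` (default 0.95) and differs from R,
the event is recorded and R updated. Exposure is tallied from R once per
generation (site-generations), so under neutrality the substitution-rate
estimators N_{G->A}/N_G and N_{A->G}/N_A equal the mutation rates.

In the drift-dominated regime (theta = 2 N mu << 1) the population is
summarised by the G/C count n of a single resident genome performing a
birth-death walk on {0..L}: new mutants arise at rate N mu (L - n) upward and
N mu n downward and fix with Kimura's haploid diffusion probability
u(s) = (1 - e^{-2s}) / (1 - e^{-2Ns}), s the marginal fitness change. The
stationary distribution follows from detailed balance and yields closed-form
mean G+C and per-site substitution rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

THETA_BOUND = 0.04


@dataclass
class WFParams:
    """Population and mutation parameters.

    Defaults give a neutral stationary G+C content of
    mu_to_GC / (mu_to_AT + mu_to_GC) = 0.30 and theta = 2*N*max(mu) = 0.014,
    comfortably inside the drift-dominated regime (theta < 0.04).
    """

    N: int = 10_000
    L: int = 20
    mu_to_AT: float = 7e-7  # G/C -> A/T, the faster direction
    mu_to_GC: float = 3e-7  # A/T -> G/C

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.L < 1:
            raise ValueError("genome size must be >= 1")
        for mu in (self.mu_to_AT, self.mu_to_GC):
            if not (0.0 < mu < 1.0):
                raise ValueError("mutation rates must lie in (0, 1)")

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate 2*N*max(mu)."""
        return 2.0 * self.N * max(self.mu_to_AT, self.mu_to_GC)

    @property
    def neutral_gc(self) -> float:
        return self.mu_to_GC / (self.mu_to_AT + self.mu_to_GC)

    def rescaled(self, k: float) -> "WFParams":
        """Desk-scale rescaling (N/k, mu*k): preserves N*mu (and N*s when
        eta is scaled by k alongside)."""
        return WFParams(N=int(round(self.N / k)), L=self.L,
                        mu_to_AT=self.mu_to_AT * k, mu_to_GC=self.mu_to_GC * k)


@dataclass
class FitnessLandscape:
    """Selection regime on the G/C count n of an L-site genome."""

    kind: str = "goal"  # "goal" | "threshold"
    n_opt: int = 4
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("goal", "threshold"):
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        if self.eta < 0:
            raise ValueError("selection intensity eta must be >= 0")

    def table(self, L: int) -> np.ndarray:
        """Fitness f(n) for n = 0..L (strictly positive)."""
        n = np.arange(L + 1, dtype=float)
        if self.kind == "goal":
            return np.exp(-self.eta * (n - self.n_opt) ** 2)
        excess = np.maximum(n - self.n_opt, 0.0)
        return np.exp(-self.eta * excess)

    def log_table(self, L: int) -> np.ndarray:
        n = np.arange(L + 1, dtype=float)
        if self.kind == "goal":
            return -self.eta * (n - self.n_opt) ** 2
        return -self.eta * np.maximum(n - self.n_opt, 0.0)


def fitness(landscape: FitnessLandscape, n: int, L: int = 20) -> float:
    """Fitness of a genome with n G/C sites out of L."""
    if not 0 <= n <= L:
        raise ValueError(f"G/C count {n} outside [0, {L}]")
    return float(landscape.table(L)[n])


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

@dataclass
class WFResult:
    r_gain: float            # A/T gain: G->A fixations per G site-generation
    r_loss: float            # A/T loss: A->G fixations per A site-generation
    n_gain_events: int
    n_loss_events: int
    exposure_gc: float       # N_G, site-generations of the reference in G
    exposure_at: float       # N_A
    mean_gc: float           # population mean G+C after burn-in
    gc_trajectory: np.ndarray = field(repr=False, default=None)


def run_wf(params: WFParams, landscape: FitnessLandscape, generations: int,
           burn_in_coalescents: float = 4.0, fix_thr: float = 0.95,
           seed: int | np.random.Generator = 0,
           traj_stride: int = 100) -> WFResult:
    """Forward Wright-Fisher simulation; returns substitution-rate estimates.

    ``generations`` counts post-burn-in generations; the burn-in adds
    ``burn_in_coalescents * N`` generations up front. Deterministic given the
    seed.
    """
    if fix_thr <= 0.5:
        raise ValueError("fixation threshold must exceed 0.5")
    burn_in = int(round(burn_in_coalescents * params.N))
    if generations <= 0:
        raise ValueError("need generations > 0 after burn-in")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    N, L = params.N, params.L
    ftab = landscape.table(L)
    if np.any(ftab <= 0):
        raise ValueError("non-positive fitness encountered")

    # initial population: neutral-composition reference
    n0 = int(round(params.neutral_gc * L))
    ref = np.zeros(L, dtype=np.uint8)
    ref[:n0] = 1
    pop = np.tile(ref, (N, 1))

    n_gain = n_loss = 0
    exp_gc = exp_at = 0.0
    gc_sum = 0.0
    gc_count = 0
    traj: list[float] = []

    total = burn_in + generations
    for gen in range(total):
        counting = gen >= burn_in
        # fitness-proportional multinomial resampling
        n_per = pop.sum(axis=1)
        w = ftab[n_per]
        w = w / w.sum()
        offspring = rng.multinomial(N, w)
        pop = np.repeat(pop, offspring, axis=0)

        # sparse mutation: draw event counts first, locate sites only if needed
        s1 = int(n_per @ offspring)  # G/C sites after resampling
        s0 = N * L - s1
        k_down = rng.binomial(s1, params.mu_to_AT) if s1 else 0
        k_up = rng.binomial(s0, params.mu_to_GC) if s0 else 0
        flat = pop.reshape(-1)
        if k_down:
            ones = np.flatnonzero(flat)
            flat[rng.choice(ones, size=k_down, replace=False)] = 0
        if k_up:
            zeros = np.flatnonzero(flat == 0)
            flat[rng.choice(zeros, size=k_up, replace=False)] = 1

        freq1 = pop.mean(axis=0)
        if counting:
            exp_gc += float(ref.sum())
            exp_at += float(L - ref.sum())
            gc_sum += float(freq1.mean())
            gc_count += 1
            if gc_count % traj_stride == 0:
                traj.append(float(freq1.mean()))
        # reference update: major allele above threshold and != R
        fixed_up = (freq1 > fix_thr) & (ref == 0)
        fixed_down = (freq1 < 1.0 - fix_thr) & (ref == 1)
        if counting:
            n_loss += int(fixed_up.sum())   # A -> G : A/T loss
            n_gain += int(fixed_down.sum())  # G -> A : A/T gain
        ref[fixed_up] = 1
        ref[fixed_down] = 0

    r_gain = n_gain / exp_gc if exp_gc > 0 else np.nan
    r_loss = n_loss / exp_at if exp_at > 0 else np.nan
    return WFResult(r_gain=r_gain, r_loss=r_loss,
                    n_gain_events=n_gain, n_loss_events=n_loss,
                    exposure_gc=exp_gc, exposure_at=exp_at,
                    mean_gc=gc_sum / max(gc_count, 1),
                    gc_trajectory=np.asarray(traj))


# ---------------------------------------------------------------------------
# analytic birth-death approximation
# ---------------------------------------------------------------------------

@dataclass
class StationaryResult:
    pi: np.ndarray           # stationary distribution over n = 0..L
    mean_gc: float           # mean G+C fraction
    r_gain: float            # per-site G/C -> A/T substitution rate
    r_loss: float            # per-site A/T -> G/C substitution rate
    lam_up: np.ndarray = field(repr=False, default=None)
    lam_down: np.ndarray = field(repr=False, default=None)


def _log_fixation_prob(s: np.ndarray, N: int) -> np.ndarray:
    """log u(s) with u(s) = (1 - e^{-2s})/(1 - e^{-2Ns}), u(0) = 1/N.

    Stable for strongly deleterious mutations (2N|s| large), where the naive
    denominator overflows.
    """
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    small = np.abs(s) < 1e-12
    out[small] = -np.log(N)
    sb = s[~small]
    # numerator / denominator share sign; work with |expm1| in log space
    with np.errstate(over="ignore"):
        log_num = np.log(np.abs(np.expm1(-2.0 * sb)))
    with np.errstate(over="ignore"):
        x = -2.0 * N * sb
        log_den = np.where(x > 50.0, x,
                           np.log(np.abs(np.expm1(np.minimum(x, 700.0)))))
    out[~small] = log_num - log_den
    return out


def analytic_stationary(params: WFParams,
                        landscape: FitnessLandscape) -> StationaryResult:
    """Stationary distribution of the birth-death G/C-count chain.

    Up-rate   lam+(n) = N * mu_to_GC * (L - n) * u(s+(n)),
    down-rate lam-(n) = N * mu_to_AT * n       * u(s-(n)),
    with s the marginal fitness change f(n') / f(n) - 1 of the mutant.
    pi follows from detailed balance; per-site substitution rates are
    exposure-weighted expected fixations per site-generation, matching the
    simulator's N_{x->y} / N_x estimators.
    """
    if params.theta > 0.1:
        import warnings
        warnings.warn(f"theta = {params.theta:.3g} > 0.1: drift-dominance "
                      "approximation may be poor", stacklevel=2)
    L, N = params.L, params.N
    logf = landscape.log_table(L)
    n = np.arange(L + 1, dtype=float)

    # selection coefficients for up (n -> n+1) and down (n -> n-1) moves;
    # clip exponents so extreme intensities saturate instead of overflowing
    s_up = np.expm1(np.clip(np.diff(logf), -700.0, 700.0))
    s_down = np.expm1(np.clip(logf[:-1] - logf[1:], -700.0, 700.0))

    log_u_up = _log_fixation_prob(s_up, N)
    log_u_down = _log_fixation_prob(s_down, N)

    with np.errstate(divide="ignore"):
        log_lam_up = np.log(N * params.mu_to_GC * (L - n[:-1])) + log_u_up
        log_lam_down = np.log(N * params.mu_to_AT * n[1:]) + log_u_down
    if not (np.any(np.isfinite(log_lam_up)) or np.any(np.isfinite(log_lam_down))):
        raise ValueError("degenerate chain: all transition rates are zero")

    # detailed balance: log pi(n+1) = log pi(n) + log lam+(n) - log lam-(n+1)
    log_pi = np.concatenate(([0.0], np.cumsum(log_lam_up - log_lam_down)))
    log_pi -= logsumexp(log_pi)
    pi = np.exp(log_pi)

    lam_up = np.exp(np.concatenate((log_lam_up, [-np.inf])))   # lam+(L) = 0
    lam_down = np.exp(np.concatenate(([-np.inf], log_lam_down)))  # lam-(0) = 0

    exposure_gc = float(pi @ n)           # expected G/C sites
    exposure_at = float(pi @ (L - n))
    r_gain = float(pi @ lam_down) / exposure_gc if exposure_gc > 0 else np.nan
    r_loss = float(pi @ lam_up) / exposure_at if exposure_at > 0 else np.nan
    return StationaryResult(pi=pi, mean_gc=float(pi @ n) / L,
                            r_gain=r_gain, r_loss=r_loss,
                            lam_up=lam_up, lam_down=lam_down)


def sweep_intensities(params: WFParams, landscape_kind: str,
                      eta_grid: np.ndarray, n_opt: int = 4,
                      simulate: bool = False, generations: int = 40_000,
                      seed: int = 0) -> pd.DataFrame:
    """Analytic (and optionally simulated) rates across selection intensities.

    Returns a table of (eta, r_gain, r_loss, mean_gc) from the analytic
    birth-death chain, plus simulated columns when ``simulate`` is set.
    """
    eta_grid = np.asarray(eta_grid, dtype=float)
    if np.any(np.diff(eta_grid) < 0) or np.any(eta_grid < 0):
        raise ValueError("eta_grid must be sorted and non-negative")
    rows = []
    for i, eta in enumerate(eta_grid):
        ls = FitnessLandscape(kind=landscape_kind, n_opt=n_opt, eta=float(eta))
        st = analytic_stationary(params, ls)
        row = {"eta": eta, "r_gain": st.r_gain, "r_loss": st.r_loss,
               "mean_gc": st.mean_gc}
        if simulate:
            sim = run_wf(params, ls, generations=generations,
                         seed=np.random.default_rng([seed, i]))
            row.update(sim_r_gain=sim.r_gain, sim_r_loss=sim.r_loss,
                       sim_mean_gc=sim.mean_gc,
                       sim_n_gain=sim.n_gain_events, sim_n_loss=sim.n_loss_events,
                       sim_exposure_gc=sim.exposure_gc,
                       sim_exposure_at=sim.exposure_at)
        rows.append(row)
    return pd.DataFrame(rows)
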