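"""Spatial coupling between A/T-gaining and A/T-losing substitutions.

From per-position branch posteriors over (ancestor, descendant) nucleotide
pairs, each position j gets expected A/T-gain and A/T-loss event masses
g(j), l(j) (a gain is any C/G -> A/T fixation, a loss any A/T -> C/G one).
A *horizon* window over the h positions preceding j (default 5 bp, never
including j) yields windowed sums Gain_h(j), Loss_h(j) and the net A/T
divergence D(j) = Gain_h(j) - Loss_h(j). Positions are labelled A/T-gaining
context (D > 0.9), A/T-losing context (D < -0.9), or background (conserved
window: Gain_h + Loss_h < 1 - 0.9).

Compensation shows up as elevated gain rates in losing contexts (and vice
versa). Because each position's own substitution mass is conditioned on the
*preceding* window only, every unit of posterior mass enters exactly one
conditional-rate numerator. Significance: the event-to-context assignment is
randomised under the null by drawing, without replacement, the total gain
count from the pooled C/G opportunity sites of the two divergence contexts
(and losses likewise from pooled A/T sites), preserving total event counts
and context sizes while removing the context-direction association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GAIN_PARENTS = (1, 2)  # C, G
LOSS_PARENTS = (0, 3)  # A, T

CTX_BACKGROUND, CTX_GAINING, CTX_LOSING, CTX_NONE = 0, 1, 2, -1

DEFAULT_HORIZON = 5
DEFAULT_THRESHOLD = 0.9
DEFAULT_RESAMPLES = 100_000


@dataclass
class SubstitutionExpectation:
    """Per-position expected substitution masses on one focal lineage."""

    gain: np.ndarray    # expected C/G -> A/T mass in [0, 1]
    loss: np.ndarray    # expected A/T -> C/G mass
    anc_gc: np.ndarray  # posterior P(ancestral nucleotide in {C, G})
    mask: np.ndarray    # True where the position carries posterior mass

    def __post_init__(self) -> None:
        if np.any(self.gain[self.mask] + self.loss[self.mask] > 1 + 1e-8):
            raise ValueError("gain + loss exceeds 1 at some position")


@dataclass
class DivergenceContext:
    gain_h: np.ndarray       # windowed expected gains over preceding h bp
    loss_h: np.ndarray
    divergence: np.ndarray   # D = Gain_h - Loss_h
    short_window: np.ndarray  # True where fewer than h positions precede j
    horizon: int


@dataclass
class CouplingCounts:
    """Expected event counts and opportunity-site counts by context."""

    n_gain_in_gainctx: float
    n_loss_in_gainctx: float
    n_gain_in_lossctx: float
    n_loss_in_lossctx: float
    n_at_in_gainctx: float
    n_at_in_lossctx: float
    n_cg_in_gainctx: float
    n_cg_in_lossctx: float

    def __post_init__(self) -> None:
        vals = [self.n_gain_in_gainctx, self.n_loss_in_gainctx,
                self.n_gain_in_lossctx, self.n_loss_in_lossctx,
                self.n_at_in_gainctx, self.n_at_in_lossctx,
                self.n_cg_in_gainctx, self.n_cg_in_lossctx]
        if any(v < 0 for v in vals):
            raise ValueError("counts must be non-negative")
        eps = 1e-6
        if (self.n_gain_in_gainctx > self.n_cg_in_gainctx + eps
                or self.n_gain_in_lossctx > self.n_cg_in_lossctx + eps
                or self.n_loss_in_gainctx > self.n_at_in_gainctx + eps
                or self.n_loss_in_lossctx > self.n_at_in_lossctx + eps):
            raise ValueError("event counts exceed opportunity counts")


@dataclass
class CouplingTestResult:
    observed: float
    B: int
    p_value: float
    seed: int
    null_mean: float = np.nan
    null_sd: float = np.nan


def expected_events(pair_posteriors: np.ndarray,
                    mask: np.ndarray | None = None) -> SubstitutionExpectation:
    """Expected gain/loss masses from (L, 4, 4) branch pair posteriors.

    ``pair_posteriors[j, p, c]`` is the posterior probability that the
    ancestor carried nucleotide p and the descendant c at position j
    (A, C, G, T = 0..3). Conserved and within-class pairs contribute no
    event mass. Masked positions get zero mass and zero opportunity.
    """
    post = np.asarray(pair_posteriors, dtype=float)
    if post.ndim != 3 or post.shape[1:] != (4, 4):
        raise ValueError("pair posteriors must have shape (L, 4, 4)")
    L = post.shape[0]
    if mask is None:
        mask = np.ones(L, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    gain = np.zeros(L)
    loss = np.zeros(L)
    for p in GAIN_PARENTS:
        for c in LOSS_PARENTS:
            gain += post[:, p, c]
    for p in LOSS_PARENTS:
        for c in GAIN_PARENTS:
            loss += post[:, p, c]
    anc_gc = post[:, GAIN_PARENTS, :].sum(axis=(1, 2))
    gain[~mask] = 0.0
    loss[~mask] = 0.0
    anc_gc[~mask] = 0.0
    return SubstitutionExpectation(gain=gain, loss=loss, anc_gc=anc_gc,
                                   mask=mask)


def window_divergence(expectations: SubstitutionExpectation,
                      horizon: int = DEFAULT_HORIZON) -> DivergenceContext:
    """Windowed gain/loss sums over the h positions preceding each site.

    The window is [j-h, j-1]; position j itself is never included. Masked
    positions contribute zero. Positions with an incomplete window (j < h)
    are flagged as short-window.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    L = expectations.gain.size

    def preceding_sum(x: np.ndarray) -> np.ndarray:
        cs = np.concatenate(([0.0], np.cumsum(x)))
        j = np.arange(L)
        lo = np.maximum(j - horizon, 0)
        return cs[j] - cs[lo]

    gain_h = preceding_sum(expectations.gain)
    loss_h = preceding_sum(expectations.loss)
    short = np.arange(L) < horizon
    return DivergenceContext(gain_h=gain_h, loss_h=loss_h,
                             divergence=gain_h - loss_h,
                             short_window=short, horizon=horizon)


def label_contexts(divergence: DivergenceContext,
                   thr: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Label positions as gaining / losing / background divergence contexts.

    D > thr -> gaining; D < -thr -> losing; background requires a conserved
    window, Gain_h + Loss_h < (1 - thr). Everything else is unlabelled
    (CTX_NONE) and drops out of the conditional rates.
    """
    if thr <= 0:
        raise ValueError("thr must be positive")
    D = divergence.divergence
    total = divergence.gain_h + divergence.loss_h
    labels = np.full(D.size, CTX_NONE, dtype=np.int8)
    labels[total < (1.0 - thr)] = CTX_BACKGROUND
    labels[D > thr] = CTX_GAINING
    labels[D < -thr] = CTX_LOSING
    return labels


def coupling_counts(labels: np.ndarray,
                    expectations: SubstitutionExpectation) -> CouplingCounts:
    """Tally events and opportunity sites in gaining vs losing contexts.

    Opportunity counts are posterior-weighted by the inferred ancestral
    nucleotide class (C/G opportunities for gains, A/T for losses).
    """
    m = expectations.mask
    anc_at = np.where(m, 1.0 - expectations.anc_gc, 0.0)
    out = {}
    for name, sel in (("gainctx", labels == CTX_GAINING),
                      ("lossctx", labels == CTX_LOSING)):
        sel = sel & m
        out[f"n_gain_in_{name}"] = float(expectations.gain[sel].sum())
        out[f"n_loss_in_{name}"] = float(expectations.loss[sel].sum())
        out[f"n_cg_in_{name}"] = float(expectations.anc_gc[sel].sum())
        out[f"n_at_in_{name}"] = float(anc_at[sel].sum())
    return CouplingCounts(**out)


def conditional_rates(labels: np.ndarray,
                      expectations: SubstitutionExpectation,
                      bin_index: np.ndarray | None = None) -> pd.DataFrame:
    """Gain/loss rates conditional on divergence context, per occupancy bin.

    rate(gain | ctx) = sum_j g(j) / n_CG_in_ctx and analogously for losses,
    within each occupancy bin (``bin_index``; a single pseudo-bin when None).
    Empty context classes yield NaN rates. Each position's event mass enters
    exactly one numerator (that of its own context label and bin).
    """
    L = expectations.gain.size
    if bin_index is None:
        bin_index = np.zeros(L, dtype=np.int64)
    bin_index = np.asarray(bin_index)
    m = expectations.mask
    anc_at = np.where(m, 1.0 - expectations.anc_gc, 0.0)
    names = {CTX_BACKGROUND: "background", CTX_GAINING: "gaining",
             CTX_LOSING: "losing"}
    rows = []
    for b in np.unique(bin_index):
        inb = (bin_index == b) & m
        for code, name in names.items():
            sel = inb & (labels == code)
            n_cg = float(expectations.anc_gc[sel].sum())
            n_at = float(anc_at[sel].sum())
            sum_g = float(expectations.gain[sel].sum())
            sum_l = float(expectations.loss[sel].sum())
            rows.append({
                "bin": b, "context": name, "n_positions": int(sel.sum()),
                "n_cg": n_cg, "n_at": n_at,
                "sum_gain": sum_g, "sum_loss": sum_l,
                "rate_gain": sum_g / n_cg if n_cg > 0 else np.nan,
                "rate_loss": sum_l / n_at if n_at > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def bootstrap_coupling_test(counts: CouplingCounts,
                            B: int = DEFAULT_RESAMPLES,
                            seed: int = 0) -> CouplingTestResult:
    """Bootstrap test of compensatory coupling against the clustering null.

    Observed statistic: expected gains in losing contexts plus expected
    losses in gaining contexts (the compensatory events). Null resamples
    reassign the total gain count to contexts by sampling without
    replacement from the pooled C/G opportunity sites of the two contexts,
    and the total loss count likewise from pooled A/T sites; this preserves
    total event counts and context site availabilities while removing the
    context-direction association. Expected (fractional) counts are rounded
    to the nearest integer for resampling. p = (1 + #{null >= observed}) /
    (B + 1), so p >= 1/(B+1).
    """
    r = lambda x: int(round(x))
    n_cg_g, n_cg_l = r(counts.n_cg_in_gainctx), r(counts.n_cg_in_lossctx)
    n_at_g, n_at_l = r(counts.n_at_in_gainctx), r(counts.n_at_in_lossctx)
    gains_tot = r(counts.n_gain_in_gainctx) + r(counts.n_gain_in_lossctx)
    losses_tot = r(counts.n_loss_in_gainctx) + r(counts.n_loss_in_lossctx)
    if min(n_cg_g, n_cg_l, n_at_g, n_at_l) <= 0:
        raise ValueError("all opportunity counts must be positive")
    if gains_tot + losses_tot == 0:
        raise ValueError("no events to test")
    observed = r(counts.n_gain_in_lossctx) + r(counts.n_loss_in_gainctx)

    rng = np.random.default_rng(seed)
    # gains falling into losing contexts under the null
    x = rng.hypergeometric(n_cg_l, n_cg_g, gains_tot, size=B) if gains_tot else 0
    # losses falling into gaining contexts
    y = rng.hypergeometric(n_at_g, n_at_l, losses_tot, size=B) if losses_tot else 0
    null = np.asarray(x) + np.asarray(y)
    if null.ndim == 0:
        null = np.full(B, null)
    p = (1 + int(np.sum(null >= observed))) / (B + 1)
    return CouplingTestResult(observed=float(observed), B=B, p_value=p,
                              seed=seed, null_mean=float(null.mean()),
                              null_sd=float(null.std()))
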