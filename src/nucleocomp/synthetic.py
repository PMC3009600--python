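"""Synthetic genomes, alignments, occupancy tracks and SNP panels.

The generator realises the statistical structure the downstream analyses
assume, with known ground truth: a root sequence drawn from a 2nd-order
Markov model evolves down a fixed tree, each branch applying its
context-dependent conditional P(child | parent, parent flanks) — so the
planted :class:`~nucleocomp.substitution.ContextRateSet` is exactly the
quantity the EM estimator targets. Occupancy tracks are an affine function
of windowed G+C plus Gaussian noise (anti-correlated with A+T content by
construction); compensatory (A/T-loss, A/T-gain) event pairs can be planted
within a distance horizon as a positive control for the coupling test; and
SNP panels draw minor-allele frequencies from a folded site-frequency
spectrum tilted by a class-specific scaled selection coefficient.

Defaults emulate the yeast intergenic setting: ~35% G+C root composition,
five-taxon tree, per-branch divergence of a few percent with up to ~4-fold
context modulation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .substitution import (NT, AlignmentBlock, ContextRateSet,
                           SecondOrderMarkov, Tree, SENSU_STRICTO_NEWICK)

AT_CODES = (0, 3)
GC_CODES = (1, 2)


# ---------------------------------------------------------------------------
# world specification
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorldSpec:
    """Everything needed to generate one synthetic genome and its history."""

    genome_length: int
    tree: Tree
    root_model: SecondOrderMarkov
    true_rates: ContextRateSet
    occupancy_coupling: float = 1.0
    noise_sd: float = 0.3
    tss_positions: list[int] = field(default_factory=list)
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 3:
            raise ValueError("genome_length must be >= 3")
        if isinstance(self.tree, str):
            self.tree = Tree.from_newick(self.tree)
        missing = [ln for ln in self.tree.lineages
                   if ln not in self.true_rates.rates]
        if missing:
            raise ValueError(f"no rate set for branch(es): {missing}")
        for t in self.tss_positions:
            if not 0 <= t < self.genome_length:
                raise ValueError(f"TSS {t} outside genome")
        for s, e in self.exon_intervals:
            if not 0 <= s <= e <= self.genome_length:
                raise ValueError(f"exon ({s},{e}) outside genome")


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests."""

    true_rates: ContextRateSet
    planted_pairs: pd.DataFrame  # position_loss, position_gain, lineage
    snp_selection: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.snp_selection.values():
            if not np.isfinite(v):
                raise ValueError("selection coefficients must be finite")


@dataclass
class AlignmentTruth:
    """A simulated phylogenetic history: all node sequences plus events."""

    spec: SyntheticWorldSpec
    node_seqs: dict[str, np.ndarray]   # name -> (L,) int8 codes
    events: pd.DataFrame               # pos, lineage, parent, child (codes)

    @property
    def block(self) -> AlignmentBlock:
        tree = self.spec.tree
        return AlignmentBlock(tree.leaf_names,
                              np.stack([self.node_seqs[n]
                                        for n in tree.leaf_names]))


def default_rates(lineages: list[str], seed: int = 1234,
                  divergence: float = 0.12,
                  context_spread: float = 0.35,
                  stationary_gc: float = 0.35,
                  rate_floor: float = 0.03) -> ContextRateSet:
    """Reverse-complement-symmetric context-dependent rates.

    The base conditional is reversible with stationary G+C content
    ``stationary_gc`` (the A/T-ward mutational bias of yeast intergenic DNA)
    and transition-biased (2:1) around a total per-site divergence of
    ``divergence``. Each flanking context scales the whole conditional by a
    log-normal factor of spread ``context_spread`` (up to roughly four-fold
    across contexts, as seen for yeast C->T rates); the context-scaling
    preserves the stationary composition.
    """
    rng = np.random.default_rng(seed)
    pi = np.array([(1 - stationary_gc) / 2, stationary_gc / 2,
                   stationary_gc / 2, (1 - stationary_gc) / 2])
    base = np.tile(pi, (4, 1))  # reversible: rate[p, c] = s[p, c] * pi[c]
    for p in range(4):
        base[p, (p + 2) % 4] *= 2.0  # transitions A<->G (0,2), C<->T (1,3)
    np.fill_diagonal(base, 0.0)
    base *= divergence / base.sum(axis=1).mean()

    out = {}
    for ln in lineages:
        mod = np.exp(rng.normal(0.0, context_spread, size=(4, 4)))
        r = mod[:, :, None, None] * base[None, None, :, :]
        r = 0.5 * (r + r[::-1, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3))
        # keep every substitution estimable at the scales the tests use
        r = np.clip(r, rate_floor, 0.2)
        for a in range(4):
            for b in range(4):
                np.fill_diagonal(r[a, b], 0.0)
                np.fill_diagonal(r[a, b], 1.0 - r[a, b].sum(axis=1))
        out[ln] = r
    return ContextRateSet(out)


def stationary_profile(rates: ContextRateSet) -> np.ndarray:
    """Stationary nucleotide distribution of the context-averaged chain."""
    m = np.mean([r.mean(axis=(0, 1)) for r in rates.rates.values()], axis=0)
    w, v = np.linalg.eig(m.T)
    p = np.real(v[:, np.argmax(np.real(w))])
    p = np.abs(p)
    return p / p.sum()


def default_world(genome_length: int = 100_000, seed: int = 0,
                  newick: str = SENSU_STRICTO_NEWICK,
                  n_tss: int | None = None,
                  **kwargs) -> SyntheticWorldSpec:
    """Study-condition defaults: yeast-like composition and divergence."""
    tree = Tree.from_newick(newick)
    rates = kwargs.pop("true_rates", None) or default_rates(tree.lineages)
    root_model = kwargs.pop("root_model", None) or \
        SecondOrderMarkov.iid(stationary_profile(rates))
    rng = np.random.default_rng([seed, 99])
    if n_tss is None:
        n_tss = max(genome_length // 2000, 1)  # ~1 TSS per 2 kb intergenic
    tss = sorted(rng.choice(genome_length, size=n_tss, replace=False).tolist())
    return SyntheticWorldSpec(genome_length=genome_length, tree=tree,
                              root_model=root_model, true_rates=rates,
                              tss_positions=tss, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------

def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cdf[:, -1]
    return (cdf < u[:, None]).sum(axis=1).astype(np.int8)


def _branch_conditionals(table: np.ndarray, seq: np.ndarray) -> np.ndarray:
    """Per-site conditional rows given the current sequence's own flanks."""
    L = seq.size
    a = np.empty(L, dtype=np.int64)
    b = np.empty(L, dtype=np.int64)
    a[1:] = seq[:-1]
    b[:-1] = seq[1:]
    a[0] = 0
    b[-1] = 0
    probs = table[a, b, seq]
    probs[0] = table.mean(axis=0)[b[0], seq[0]]    # missing 5' flank
    probs[-1] = table.mean(axis=1)[a[-1], seq[-1]]  # missing 3' flank
    return probs


def simulate_branch(parent: np.ndarray, table: np.ndarray,
                    rng: np.random.Generator, n_steps: int = 1) -> np.ndarray:
    """Evolve one branch under P(child | parent, parent flanks).

    With ``n_steps == 1`` (default) the conditional is applied in a single
    draw per site, with flanking context read from the parent sequence —
    exactly the generative model the inference assumes. With ``n_steps > 1``
    the off-diagonal mass is spread over sub-steps (each <= 0.01 per site
    when ``n_steps`` is chosen by :func:`required_steps`) and contexts are
    re-read from the evolving sequence, approximating a gradual process.
    """
    if n_steps == 1:
        return _sample_rows(_branch_conditionals(table, parent), rng)
    step = table / n_steps
    for a in range(4):
        for b in range(4):
            np.fill_diagonal(step[a, b], 0.0)
            np.fill_diagonal(step[a, b], 1.0 - step[a, b].sum(axis=1))
    seq = parent.copy()
    for _ in range(n_steps):
        seq = _sample_rows(_branch_conditionals(step, seq), rng)
    return seq


def required_steps(table: np.ndarray, per_step: float = 0.01) -> int:
    """Sub-step count so each step's off-diagonal mass is <= per_step."""
    off = 1.0 - np.einsum("abpp->abp", table)
    return max(int(np.ceil(off.max() / per_step)), 1)


def gen_alignment(spec: SyntheticWorldSpec, n_steps: int = 1) -> AlignmentTruth:
    """Simulate the root and every descendant; record realized events.

    Returns one gapless sequence per tree node; the leaf sequences form the
    alignment. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    root = spec.root_model.sample(spec.genome_length, rng)
    node_seqs = {tree.names[0]: root}
    rows = []
    for v in range(1, tree.n_nodes):  # preorder: parent always done first
        name = tree.names[v]
        parent_seq = node_seqs[tree.names[tree.parent[v]]]
        child_seq = simulate_branch(parent_seq, spec.true_rates[name], rng,
                                    n_steps=n_steps)
        node_seqs[name] = child_seq
        changed = np.flatnonzero(child_seq != parent_seq)
        for j in changed:
            rows.append((int(j), name, int(parent_seq[j]), int(child_seq[j])))
    events = pd.DataFrame(rows, columns=["pos", "lineage", "parent", "child"])
    return AlignmentTruth(spec=spec, node_seqs=node_seqs, events=events)


# ---------------------------------------------------------------------------
# occupancy track
# ---------------------------------------------------------------------------

def windowed_gc(codes: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-average G+C fraction (window clipped at the edges)."""
    gc = np.isin(codes, GC_CODES).astype(float)
    cs = np.concatenate(([0.0], np.cumsum(gc)))
    j = np.arange(codes.size)
    lo = np.clip(j - window // 2, 0, codes.size)
    hi = np.clip(lo + window, 0, codes.size)
    lo = np.minimum(lo, hi - 1)
    return (cs[hi] - cs[lo]) / (hi - lo)


def gen_occupancy_track(sequence: np.ndarray, window: int,
                        spec: SyntheticWorldSpec) -> np.ndarray:
    """Occupancy scores anti-correlated with windowed A+T content.

    score = coupling * zscore(windowed G+C) + N(0, noise_sd); with zero
    noise the track is a deterministic affine function of windowed G+C, so
    higher G+C always scores higher. The continuous scores support exact
    quantile partitions (e.g. top 21% / bottom 14%).
    """
    codes = np.asarray(sequence, dtype=np.int8)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > codes.size:
        raise ValueError("window longer than sequence")
    gcw = windowed_gc(codes, window)
    sd = gcw.std()
    z = (gcw - gcw.mean()) / (sd if sd > 0 else 1.0)
    track = spec.occupancy_coupling * z
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 7])
        track = track + rng.normal(0.0, spec.noise_sd, size=codes.size)
    return track


# ---------------------------------------------------------------------------
# planted compensatory events
# ---------------------------------------------------------------------------

def plant_compensatory_events(truth: AlignmentTruth, horizon: int,
                              excess: float, seed: int = 0,
                              lineage: str | None = None,
                              ) -> tuple[AlignmentTruth, PlantedTruth]:
    """Insert paired (A/T-loss, A/T-gain) events on one terminal branch.

    Pairs are planted at a rate proportional to ``excess`` (about
    ``excess`` pairs per kb), each pair on the same branch with
    |position_gain - position_loss| <= horizon. Only terminal branches are
    eligible so descendant sequences stay consistent. The input truth is
    not modified.
    """
    if excess < 0:
        raise ValueError("excess must be >= 0")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    tree = truth.spec.tree
    lineage = lineage or tree.leaf_names[0]
    if tree.children[tree.index[lineage]]:
        raise ValueError("compensatory events can only be planted on a "
                         "terminal branch")
    out = copy.deepcopy(truth)
    empty = pd.DataFrame(columns=["position_loss", "position_gain", "lineage"])
    planted = PlantedTruth(true_rates=truth.spec.true_rates,
                           planted_pairs=empty)
    n_pairs = int(round(excess * truth.spec.genome_length / 1000.0))
    if n_pairs == 0:
        return out, planted

    rng = np.random.default_rng(seed)
    parent_seq = out.node_seqs[tree.names[tree.parent[tree.index[lineage]]]]
    child_seq = out.node_seqs[lineage]
    conserved = child_seq == parent_seq
    loss_ok = np.isin(parent_seq, AT_CODES) & conserved   # can lose an A/T
    gain_ok = np.isin(parent_seq, GC_CODES) & conserved   # can gain an A/T
    if not (loss_ok.any() and gain_ok.any()):
        raise ValueError("no eligible sites to plant compensatory pairs")

    pairs = []
    new_rows = []
    candidates = np.flatnonzero(loss_ok)
    rng.shuffle(candidates)
    for i in candidates:
        if len(pairs) >= n_pairs:
            break
        lo, hi = max(i - horizon, 0), min(i + horizon + 1, child_seq.size)
        near = [j for j in range(lo, hi) if j != i and gain_ok[j]]
        if not near:
            continue
        j = int(rng.choice(near))
        new_loss = int(rng.choice(GC_CODES))   # A/T -> C/G at i
        new_gain = int(rng.choice(AT_CODES))   # C/G -> A/T at j
        child_seq[i] = new_loss
        child_seq[j] = new_gain
        loss_ok[i] = gain_ok[j] = False
        pairs.append((i, j, lineage))
        new_rows.append((i, lineage, int(parent_seq[i]), new_loss))
        new_rows.append((j, lineage, int(parent_seq[j]), new_gain))
    if not pairs:
        raise ValueError("no eligible (loss, gain) pairs within the horizon")

    out.events = pd.concat(
        [out.events, pd.DataFrame(new_rows, columns=out.events.columns)],
        ignore_index=True).sort_values(["lineage", "pos"], ignore_index=True)
    planted.planted_pairs = pd.DataFrame(
        pairs, columns=["position_loss", "position_gain", "lineage"])
    return out, planted


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

def _folded_sfs_weights(n: int, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Folded site-frequency weights over minor counts 1..n//2.

    Unfolded density g(x) = (1 - e^{-2*gamma*(1-x)}) / (x(1-x)) with
    gamma = N*s the scaled selection coefficient of the minor variant
    (diffusion form; the neutral gamma -> 0 limit is 1/x), folded at 0.5.
    """
    ks = np.arange(1, n // 2 + 1)

    def g(x: np.ndarray) -> np.ndarray:
        if abs(gamma) < 1e-9:
            num = 1.0 - x
        else:
            # the (1 - e^{-2 gamma}) normaliser carries the sign for
            # deleterious variants (gamma < 0)
            num = np.expm1(-2.0 * gamma * (1.0 - x)) / np.expm1(-2.0 * gamma)
        return num / (x * (1.0 - x))

    x = ks / n
    w = g(x) + np.where(ks * 2 == n, 0.0, g(1.0 - x))
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise ValueError(f"degenerate frequency spectrum for gamma={gamma}")
    return ks, w / w.sum()


def gen_snp_panel(n_strains: int, n_snps: int,
                  class_selection: dict[str, float], seed: int = 0,
                  gc_flank_prob: float = 0.35,
                  occupancy_classes: tuple[str, ...] = ("low", "high"),
                  ) -> pd.DataFrame:
    """Biallelic SNP panel with class-specific selection on allele frequency.

    Each SNP is assigned a direction class from ``class_selection`` (keys
    AT_gain / AT_loss / AT_conserving, values are scaled selection
    coefficients N*s of the minor variant); its minor-allele count is drawn
    from the correspondingly tilted folded spectrum. Allele identities match
    the class (AT_gain: major C/G, minor A/T; AT_loss reciprocal;
    AT_conserving within-class). Flanks and occupancy classes are assigned
    at random. All sites are intergenic and called in all strains.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if not class_selection:
        raise ValueError("class map must not be empty")
    rng = np.random.default_rng(seed)
    classes = sorted(class_selection)
    spectra = {c: _folded_sfs_weights(n_strains, class_selection[c])
               for c in classes}

    a_codes = list("AT")
    g_codes = list("GC")
    rows = []
    positions = rng.choice(max(20 * n_snps, n_snps + 1), size=n_snps,
                           replace=False)
    for i in range(n_snps):
        cls = classes[rng.integers(len(classes))]
        ks, w = spectra[cls]
        minor_count = int(rng.choice(ks, p=w))
        if cls == "AT_gain":
            major, minor = rng.choice(g_codes), rng.choice(a_codes)
        elif cls == "AT_loss":
            major, minor = rng.choice(a_codes), rng.choice(g_codes)
        elif cls == "AT_conserving":
            pool = a_codes if rng.random() < 0.5 else g_codes
            major, minor = rng.permutation(pool)
        else:
            raise ValueError(f"unknown SNP class {cls!r}")
        flanks = np.where(rng.random(2) < gc_flank_prob,
                          rng.choice(g_codes, 2), rng.choice(a_codes, 2))
        rows.append({
            "pos": int(positions[i]), "allele1": major, "allele2": minor,
            "count1": n_strains - minor_count, "count2": minor_count,
            "n_called": n_strains,
            "flank5": str(flanks[0]), "flank3": str(flanks[1]),
            "occupancy": occupancy_classes[rng.integers(len(occupancy_classes))],
            "intergenic": True, "true_class": cls,
        })
    return pd.DataFrame(rows)
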