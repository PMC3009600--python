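"""Context-dependent substitution model on a fixed phylogeny.

Each lineage (branch of a rooted tree, identified by its child node) carries
an independent set of conditional substitution probabilities
P(child | parent, 5' flank, 3' flank): 16 flanking contexts x a 4x4 table.
No branch lengths or global rate matrix are assumed; the per-lineage
conditionals are the free parameters. The root sequence follows a 2nd-order
Markov model.

Ancestral inference uses loopy belief propagation on a factor graph with one
variable per (node, site). Per branch and site there is a factor over
(parent site-1, parent site, parent site+1, child site) implementing the
context conditional, with the flanking context read from the *parent*
(ancestral) sequence; the root chain contributes triplet factors. With
context-free rates the graph decouples per site and BP is exact, matching
Felsenstein pruning.

Parameter estimation is a generalized EM: the E-step runs BP and accumulates
expected (5', 3', parent, child) transition counts per lineage from the
branch-factor beliefs; the M-step row-normalizes them. Rates are
reverse-complement averaged for reporting, and key results can be
cross-checked with Fitch parsimony (ambiguous columns excluded).

Nucleotides are encoded A, C, G, T = 0..3; reverse complement is 3 - x.
Coordinates are 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

NT = "ACGT"
GC_CODES = (1, 2)
_UNIF = 0.25


class BPNonConvergence(RuntimeError):
    """Loopy BP failed to converge; carries the per-iteration delta trace."""

    def __init__(self, trace: list[float]):
        super().__init__(f"belief propagation did not converge "
                         f"(last delta {trace[-1]:.3g} after {len(trace)} iterations)")
        self.trace = trace


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

class Tree:
    """Rooted phylogeny with named nodes; lineages are child-node names."""

    def __init__(self, names: list[str], parent: list[int]):
        self.names = list(names)
        self.parent = np.asarray(parent, dtype=np.int64)
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("nodes must be in preorder with root first")
        n = len(names)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(1, n):
            self.children[self.parent[v]].append(v)
        self.leaves = [v for v in range(n) if not self.children[v]]
        self.leaf_names = [self.names[v] for v in self.leaves]
        self.index = {nm: i for i, nm in enumerate(self.names)}
        if len(self.index) != n:
            raise ValueError("node names must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def lineages(self) -> list[str]:
        """Branch identifiers: every non-root node names the branch above it."""
        return [self.names[v] for v in range(1, self.n_nodes)]

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        from Bio import Phylo
        clades = Phylo.read(StringIO(newick), "newick")
        names: list[str] = []
        parent: list[int] = []

        def walk(clade, par: int) -> None:
            idx = len(names)
            names.append(clade.name or f"node{idx}")
            parent.append(par)
            for ch in clade.clades:
                walk(ch, idx)

        walk(clades.root, -1)
        return cls(names, parent)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                return self.names[v]
            inner = ",".join(rec(c) for c in self.children[v])
            return f"({inner}){self.names[v]}"
        return rec(0) + ";"


#: topology of the five sensu stricto yeasts used throughout the examples
SENSU_STRICTO_NEWICK = "((((Scer,Spar)cp,Smik)cpm,Skud)cpmk,Sbay)root;"


# ---------------------------------------------------------------------------
# rate sets and root model
# ---------------------------------------------------------------------------

@dataclass
class ContextRateSet:
    """Per-lineage conditional substitution probabilities.

    ``rates[lineage][a, b, p, c]`` = P(child = c | parent = p, 5' = a, 3' = b),
    contexts read from the parent sequence. Rows sum to one.
    """

    rates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, r in self.rates.items():
            r = np.asarray(r, dtype=float)
            if r.shape != (4, 4, 4, 4):
                raise ValueError(f"{name}: rate table must be (4,4,4,4)")
            if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
                raise ValueError(f"{name}: probabilities outside [0, 1]")
            if np.max(np.abs(r.sum(axis=3) - 1.0)) > 1e-10:
                raise ValueError(f"{name}: rows must sum to 1")
            self.rates[name] = r

    def __getitem__(self, lineage: str) -> np.ndarray:
        return self.rates[lineage]

    def copy(self) -> "ContextRateSet":
        return ContextRateSet({k: v.copy() for k, v in self.rates.items()})

    @classmethod
    def context_free(cls, lineages: list[str],
                     matrix: np.ndarray) -> "ContextRateSet":
        """Same 4x4 conditional in every context and lineage."""
        matrix = np.asarray(matrix, dtype=float)
        table = np.broadcast_to(matrix, (4, 4, 4, 4)).copy()
        return cls({ln: table.copy() for ln in lineages})

    @classmethod
    def jukes_cantor(cls, lineages: list[str], p: float = 0.05) -> "ContextRateSet":
        """Context-uniform init: equal off-diagonals p/3, diagonal 1 - p."""
        m = np.full((4, 4), p / 3.0)
        np.fill_diagonal(m, 1.0 - p)
        return cls.context_free(lineages, m)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ln, r in self.rates.items():
            for a, b, p, c in itertools.product(range(4), repeat=4):
                rows.append({"lineage": ln, "five": NT[a], "three": NT[b],
                             "parent": NT[p], "child": NT[c],
                             "rate": r[a, b, p, c]})
        return pd.DataFrame(rows)


def rc_average(rates: ContextRateSet) -> ContextRateSet:
    """Average each context rate with its reverse complement; idempotent.

    Pairing: rate(p->c | a, b) with rate(rc(p)->rc(c) | rc(b), rc(a)); e.g.
    the middle substitution of CAT->CCT pairs with that of ATG->AGG.
    """
    out = {}
    for ln, r in rates.rates.items():
        flipped = r[::-1, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3)
        out[ln] = 0.5 * (r + flipped)
    return ContextRateSet(out)


GAIN_PAIRS = [(1, 0), (1, 3), (2, 0), (2, 3)]  # C->A, C->T, G->A, G->T
LOSS_PAIRS = [(0, 1), (0, 2), (3, 1), (3, 2)]  # A->C, A->G, T->C, T->G


def aggregate_gain_loss(rates: ContextRateSet) -> dict[str, dict]:
    """Per-lineage A/T gain and loss rates, context-resolved and averaged.

    Gain is the average of the four A/T-gaining substitution rates
    (C->A, C->T, G->A, G->T); loss averages the reciprocal four. Expects
    reverse-complement-averaged rates.
    """
    out = {}
    for ln, r in rates.rates.items():
        gain_ctx = np.mean([r[:, :, p, c] for p, c in GAIN_PAIRS], axis=0)
        loss_ctx = np.mean([r[:, :, p, c] for p, c in LOSS_PAIRS], axis=0)
        per_ctx = pd.DataFrame(
            [{"five": NT[a], "three": NT[b],
              "gain": gain_ctx[a, b], "loss": loss_ctx[a, b]}
             for a in range(4) for b in range(4)])
        out[ln] = {"gain": float(gain_ctx.mean()),
                   "loss": float(loss_ctx.mean()),
                   "per_context": per_ctx}
    return out


@dataclass
class SecondOrderMarkov:
    """2nd-order Markov model over a nucleotide sequence.

    ``trans[a, b, c]`` = P(next = c | previous two = a, b); ``pair`` is the
    joint distribution of the first two symbols.
    """

    trans: np.ndarray
    pair: np.ndarray

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.pair = np.asarray(self.pair, dtype=float)
        if self.trans.shape != (4, 4, 4) or self.pair.shape != (4, 4):
            raise ValueError("trans must be (4,4,4) and pair (4,4)")
        if np.max(np.abs(self.trans.sum(axis=2) - 1.0)) > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if abs(self.pair.sum() - 1.0) > 1e-12:
            raise ValueError("pair distribution must sum to 1")

    @classmethod
    def iid(cls, p: np.ndarray) -> "SecondOrderMarkov":
        p = np.asarray(p, dtype=float)
        p = p / p.sum()
        return cls(np.broadcast_to(p, (4, 4, 4)).copy(), np.outer(p, p))

    @classmethod
    def uniform(cls) -> "SecondOrderMarkov":
        return cls.iid(np.full(4, 0.25))

    @classmethod
    def from_codes(cls, codes: np.ndarray,
                   pseudocount: float = 1.0) -> "SecondOrderMarkov":
        codes = np.asarray(codes)
        ok = codes >= 0
        tri_ok = ok[:-2] & ok[1:-1] & ok[2:]
        counts = np.full((4, 4, 4), pseudocount)
        idx = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
        counts += np.bincount(idx[tri_ok], minlength=64).reshape(4, 4, 4)
        trans = counts / counts.sum(axis=2, keepdims=True)
        pair = counts.sum(axis=2) / counts.sum()
        return cls(trans, pair)

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        if length < 3:
            raise ValueError("sequence length must be >= 3")
        seq = np.empty(length, dtype=np.int8)
        first = rng.choice(16, p=self.pair.reshape(-1))
        seq[0], seq[1] = divmod(first, 4)
        cum = np.cumsum(self.trans, axis=2)
        u = rng.random(length)
        for j in range(2, length):
            seq[j] = np.searchsorted(cum[seq[j - 2], seq[j - 1]], u[j],
                                     side="right")
        return seq


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """Gapless aligned leaf sequences with a per-column validity mask."""

    leaf_names: list[str]
    seqs: np.ndarray  # (n_leaves, L) int8, -1 for non-ACGT
    mask: np.ndarray = None  # (L,) bool, True = column carries likelihood

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype=np.int8)
        if self.seqs.ndim != 2:
            raise ValueError("sequences must be a 2-D array")
        auto = np.all(self.seqs >= 0, axis=0)
        self.mask = auto if self.mask is None else np.asarray(self.mask, bool) & auto

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @classmethod
    def from_strings(cls, sequences: dict[str, str],
                     mask: np.ndarray | None = None) -> "AlignmentBlock":
        names = list(sequences)
        lens = {len(s) for s in sequences.values()}
        if len(lens) != 1:
            raise ValueError("aligned sequences must have equal length")
        lut = np.full(256, -1, dtype=np.int8)
        for i, c in enumerate(NT):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        seqs = np.stack([lut[np.frombuffer(sequences[n].encode(), np.uint8)]
                         for n in names])
        return cls(names, seqs, mask)


# ---------------------------------------------------------------------------
# loopy belief propagation
# ---------------------------------------------------------------------------

@dataclass
class BPOptions:
    tol: float = 1e-6
    max_iter: int = 200
    damping: float = 0.25
    block_size: int = 10_000
    overlap: int = 2


@dataclass
class AncestralPosterior:
    """Node marginals and per-branch (parent, child) pair posteriors."""

    node_marginal: dict[str, np.ndarray]       # name -> (L, 4)
    branch_pair: dict[str, np.ndarray]         # child name -> (L, 4, 4)
    mask: np.ndarray
    n_iterations: int
    loglik: float                              # Bethe approximation


def _shift_up(x: np.ndarray) -> np.ndarray:
    """out[j] = x[j+1]; last row ones."""
    out = np.empty_like(x)
    out[:-1] = x[1:]
    out[-1] = 1.0
    return out


def _shift_down(x: np.ndarray, k: int = 1) -> np.ndarray:
    """out[j] = x[j-k]; first k rows ones."""
    out = np.empty_like(x)
    out[k:] = x[:-k]
    out[:k] = 1.0
    return out


def _norm_rows(x: np.ndarray) -> np.ndarray:
    s = x.sum(axis=-1, keepdims=True)
    return x / np.where(s > 0, s, 1.0)


class _BranchState:
    __slots__ = ("psi", "psi64", "in_A", "in_P", "in_B", "in_C",
                 "out_A", "out_P", "out_B", "out_C")

    def __init__(self, rate_table: np.ndarray, L: int):
        # rate tables are (5', 3', parent, child); the factor is laid out as
        # (5'-flank, parent, 3'-flank, child) to follow the site order
        self.psi = np.ascontiguousarray(rate_table.transpose(0, 2, 1, 3))
        self.psi64 = self.psi.reshape(64, 4)
        for slot in ("in_A", "in_P", "in_B", "in_C",
                     "out_A", "out_P", "out_B", "out_C"):
            setattr(self, slot, np.full((L, 4), _UNIF))


class _FactorGraphBP:
    """One BP run over a (sub-)block of columns."""

    def __init__(self, block: AlignmentBlock, tree: Tree,
                 rates: ContextRateSet, root_model: SecondOrderMarkov,
                 opts: BPOptions):
        self.tree = tree
        self.opts = opts
        self.L = L = block.length
        if L < 3:
            raise ValueError("block too short for flanking contexts (< 3)")
        self.root_model = root_model
        missing = [ln for ln in tree.lineages if ln not in rates.rates]
        if missing:
            raise ValueError(f"no rate set for lineage(s): {missing}")

        # evidence per node: ones for internal / masked, one-hot for leaves
        self.ev = [np.ones((L, 4)) for _ in range(tree.n_nodes)]
        leaf_row = {nm: i for i, nm in enumerate(block.leaf_names)}
        for v in tree.leaves:
            nm = tree.names[v]
            if nm not in leaf_row:
                raise ValueError(f"leaf {nm!r} missing from alignment")
            codes = block.seqs[leaf_row[nm]]
            e = np.ones((L, 4))
            obs = block.mask & (codes >= 0)
            e[obs] = 0.0
            e[np.flatnonzero(obs), codes[obs]] = 1.0
            self.ev[v] = e

        self.branches = {v: _BranchState(rates[tree.names[v]], L)
                         for v in range(1, tree.n_nodes)}
        # root chain messages (triplet factors at sites 2..L-1)
        self.rin = {k: np.full((L, 4), _UNIF) for k in "ABC"}
        self.rout = {k: np.full((L, 4), _UNIF) for k in "ABC"}
        self.pin0 = np.full(4, _UNIF)
        self.pin1 = np.full(4, _UNIF)
        self.pout0 = np.full(4, _UNIF)
        self.pout1 = np.full(4, _UNIF)
        self.beliefs = [np.full((L, 4), _UNIF) for _ in range(tree.n_nodes)]
        self.trace: list[float] = []

    # -- factor side -------------------------------------------------------
    def _update_factors(self) -> float:
        damp = self.opts.damping
        delta = 0.0

        def absorb(old: np.ndarray, raw: np.ndarray,
                   dead: slice | int | None = None) -> float:
            raw = _norm_rows(raw)
            if dead is not None:
                raw[dead] = _UNIF  # rows with no corresponding variable
            new = damp * old + (1.0 - damp) * raw
            d = float(np.max(np.abs(new - old)))
            old[:] = new
            return d

        L = self.L
        for st in self.branches.values():
            fA, fP, fB, fC = st.in_A, st.in_P, st.in_B, st.in_C
            # U[j, (a,p,b)] = sum_c psi[a,p,b,c] fC[j,c]
            U = (fC @ st.psi64.T).reshape(L, 4, 4, 4)
            W = np.matmul(fA[:, None, :], U.reshape(L, 4, 16))  # sum over a
            W = W.reshape(L, 4, 4)                              # (j, p, b)
            to_P = (W * fB[:, None, :]).sum(axis=2)
            to_B = (W * fP[:, :, None]).sum(axis=1)
            PB = (fP[:, :, None] * fB[:, None, :]).reshape(L, 16, 1)
            to_A = np.matmul(U.reshape(L, 4, 16), PB)[:, :, 0]
            AP = (fA[:, :, None] * fP[:, None, :]).reshape(L, 16)
            APB = (AP[:, :, None] * fB[:, None, :]).reshape(L, 64)
            to_C = APB @ st.psi64
            delta = max(delta, absorb(st.out_A, to_A, dead=0),
                        absorb(st.out_P, to_P),
                        absorb(st.out_B, to_B, dead=-1),
                        absorb(st.out_C, to_C))

        rho = self.root_model.trans
        rA, rB, rC = self.rin["A"], self.rin["B"], self.rin["C"]
        Wr = (rA @ rho.reshape(4, 16)).reshape(L, 4, 4)  # (j, b, c)
        to_C = (Wr * rB[:, :, None]).sum(axis=1)
        to_B = (Wr * rC[:, None, :]).sum(axis=2)
        BC = (rB[:, :, None] * rC[:, None, :]).reshape(L, 16)
        to_A = BC @ rho.reshape(4, 16).T
        # triplet factors exist for j >= 2 only
        for key, raw in (("A", to_A), ("B", to_B), ("C", to_C)):
            delta = max(delta, absorb(self.rout[key], raw, dead=slice(0, 2)))

        pairpot = self.root_model.pair
        new0 = _norm_rows(pairpot @ self.pin1)
        new1 = _norm_rows(self.pin0 @ pairpot)
        for old, new in ((self.pout0, new0), (self.pout1, new1)):
            mixed = damp * old + (1.0 - damp) * new
            delta = max(delta, float(np.max(np.abs(mixed - old))))
            old[:] = mixed
        return delta

    # -- variable side -----------------------------------------------------
    def _update_variables(self) -> None:
        tree = self.tree
        for v in range(tree.n_nodes):
            ports: list[tuple[str, object, np.ndarray]] = []
            if v != 0:
                ports.append(("parC", v, self.branches[v].out_C))
            for w in tree.children[v]:
                st = self.branches[w]
                ports.append(("chP", w, st.out_P))
                ports.append(("chA", w, _shift_up(st.out_A)))
                ports.append(("chB", w, _shift_down(st.out_B)))
            if v == 0:
                rc = self.rout["C"].copy()
                rc[:2] = 1.0
                ports.append(("rC", None, rc))
                ports.append(("rB", None, _shift_up(self.rout["B"])))
                ports.append(("rA", None, _shift_up(_shift_up(self.rout["A"]))))
                p0 = np.ones((self.L, 4))
                p0[0] = self.pout0
                p1 = np.ones((self.L, 4))
                p1[1] = self.pout1
                ports.append(("pair0", None, p0))
                ports.append(("pair1", None, p1))

            arrays = [self.ev[v]] + [a for _, _, a in ports]
            m = len(arrays)
            prefix = [np.ones((self.L, 4))]
            for a in arrays:
                prefix.append(prefix[-1] * a)
            suffix: list = [None] * (m + 1)
            suffix[m] = np.ones((self.L, 4))
            for i in range(m - 1, -1, -1):
                suffix[i] = suffix[i + 1] * arrays[i]
            self.beliefs[v] = _norm_rows(prefix[m])

            for i, (kind, w, _) in enumerate(ports, start=1):
                loo = _norm_rows(prefix[i] * suffix[i + 1])
                if kind == "parC":
                    self.branches[w].in_C[:] = loo
                elif kind == "chP":
                    self.branches[w].in_P[:] = loo
                elif kind == "chA":
                    self.branches[w].in_A[:] = _shift_down(loo)
                    self.branches[w].in_A[0] = _UNIF
                elif kind == "chB":
                    self.branches[w].in_B[:] = _shift_up(loo)
                    self.branches[w].in_B[-1] = _UNIF
                elif kind == "rC":
                    self.rin["C"][:] = loo
                    self.rin["C"][:2] = _UNIF
                elif kind == "rB":
                    self.rin["B"][:] = _shift_down(loo)
                    self.rin["B"][:2] = _UNIF
                elif kind == "rA":
                    self.rin["A"][:] = _shift_down(loo, 2)
                    self.rin["A"][:2] = _UNIF
                elif kind == "pair0":
                    self.pin0[:] = loo[0]
                elif kind == "pair1":
                    self.pin1[:] = loo[1]

    def run(self) -> None:
        for _ in range(self.opts.max_iter):
            # variables first so evidence reaches the factors before the
            # convergence check sees their outputs
            self._update_variables()
            delta = self._update_factors()
            self.trace.append(delta)
            if delta < self.opts.tol:
                self._update_variables()  # refresh beliefs / in-messages
                return
        raise BPNonConvergence(self.trace)

    # -- read-outs ---------------------------------------------------------
    def pair_posterior(self, v: int) -> np.ndarray:
        st = self.branches[v]
        V = np.einsum("apbc,ja,jb->jpc", st.psi, st.in_A, st.in_B)
        pair = V * st.in_P[:, :, None] * st.in_C[:, None, :]
        s = pair.sum(axis=(1, 2), keepdims=True)
        return pair / np.where(s > 0, s, 1.0)

    def branch_expected_counts(self, v: int, chunk: int = 4096) -> np.ndarray:
        """Sum over sites of branch-factor beliefs, as (5', 3', parent, child)."""
        st = self.branches[v]
        total = np.zeros((4, 4, 4, 4))
        for s in range(0, self.L, chunk):
            e = slice(s, min(s + chunk, self.L))
            b = np.einsum("apbc,ja,jp,jb,jc->japbc", st.psi, st.in_A[e],
                          st.in_P[e], st.in_B[e], st.in_C[e])
            z = b.sum(axis=(1, 2, 3, 4), keepdims=True)
            total += (b / np.where(z > 0, z, 1.0)).sum(axis=0)
        return total.transpose(0, 2, 1, 3)  # (a, p, b, c) -> (a, b, p, c)

    def root_expected_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Expected triplet counts (and first-pair belief) of the root chain."""
        rho = self.root_model.trans
        b = np.einsum("abc,ja,jb,jc->jabc", rho, self.rin["A"][2:],
                      self.rin["B"][2:], self.rin["C"][2:])
        z = b.sum(axis=(1, 2, 3), keepdims=True)
        tri = (b / np.where(z > 0, z, 1.0)).sum(axis=0)
        bp = self.root_model.pair * np.outer(self.pin0, self.pin1)
        bp = bp / max(bp.sum(), 1e-300)
        return tri, bp

    def bethe_loglik(self) -> float:
        """Bethe approximation of the log-likelihood of the block."""
        from scipy.special import xlogy

        def H(b: np.ndarray, axis) -> np.ndarray:
            return -xlogy(b, b).sum(axis=axis)

        L = self.L
        total = 0.0
        with np.errstate(divide="ignore"):
            for st in self.branches.values():
                logpsi = np.where(st.psi > 0, np.log(st.psi), 0.0)
                for s in range(0, L, 4096):
                    e = slice(s, min(s + 4096, L))
                    b = np.einsum("apbc,ja,jp,jb,jc->japbc", st.psi,
                                  st.in_A[e], st.in_P[e], st.in_B[e], st.in_C[e])
                    z = b.sum(axis=(1, 2, 3, 4), keepdims=True)
                    b = b / np.where(z > 0, z, 1.0)
                    total += float(np.einsum("japbc,apbc->", b, logpsi))
                    total += float(H(b, axis=(1, 2, 3, 4)).sum())
                # boundary factors carry a latent uniform flank (prior 1/4)
                total -= 2.0 * np.log(4.0)
            rho = self.root_model.trans
            logrho = np.where(rho > 0, np.log(rho), 0.0)
            b = np.einsum("abc,ja,jb,jc->jabc", rho, self.rin["A"][2:],
                          self.rin["B"][2:], self.rin["C"][2:])
            z = b.sum(axis=(1, 2, 3), keepdims=True)
            b = b / np.where(z > 0, z, 1.0)
            total += float(np.einsum("jabc,abc->", b, logrho))
            total += float(H(b, axis=(1, 2, 3)).sum())
            bp = self.root_model.pair * np.outer(self.pin0, self.pin1)
            bp = bp / max(bp.sum(), 1e-300)
            logpair = np.where(self.root_model.pair > 0,
                               np.log(self.root_model.pair), 0.0)
            total += float((bp * logpair).sum()) + float(H(bp, axis=None))

        # variable entropies weighted by (degree - 1); evidence unary factors
        # cancel exactly and are omitted from the degree count
        j = np.arange(L)
        for v in range(self.tree.n_nodes):
            d = np.zeros(L)
            if v != 0:
                d += 1.0
            n_ch = len(self.tree.children[v])
            if n_ch:
                per_child = np.full(L, 3.0)
                per_child[0] = 2.0
                per_child[-1] = 2.0
                d += n_ch * per_child
            if v == 0:
                d += (j >= 2).astype(float)               # C-port of triplet j
                d += ((j >= 1) & (j <= L - 2)).astype(float)  # B of triplet j+1
                d += (j <= L - 3).astype(float)           # A of triplet j+2
                d += (j <= 1).astype(float)               # pair factor
            with np.errstate(divide="ignore", invalid="ignore"):
                hv = -np.where(self.beliefs[v] > 0,
                               self.beliefs[v] * np.log(self.beliefs[v]),
                               0.0).sum(axis=1)
            total -= float(((d - 1.0) * hv).sum())
        return total


def _iter_blocks(L: int, size: int, overlap: int):
    """Yield (keep_start, keep_end, ext_start, ext_end) sub-block windows."""
    if L <= size:
        yield 0, L, 0, L
        return
    start = 0
    while start < L:
        end = min(start + size, L)
        yield start, end, max(start - overlap, 0), min(end + overlap, L)
        start = end


def infer_posteriors(block: AlignmentBlock, tree: Tree, rates: ContextRateSet,
                     root_model: SecondOrderMarkov | None = None,
                     bp_opts: BPOptions | None = None) -> AncestralPosterior:
    """Posterior node marginals and branch pair posteriors via loopy BP.

    Long alignments are processed in sub-blocks (default 10 kb) overlapping by
    two sites so every kept column retains its full flanking context.
    Raises :class:`BPNonConvergence` when message passing stalls.
    """
    bp_opts = bp_opts or BPOptions()
    root_model = root_model or SecondOrderMarkov.uniform()
    L = block.length
    marg = {nm: np.empty((L, 4)) for nm in tree.names}
    pair = {tree.names[v]: np.empty((L, 4, 4)) for v in range(1, tree.n_nodes)}
    iters = 0
    loglik = 0.0
    for ks, ke, es, ee in _iter_blocks(L, bp_opts.block_size, bp_opts.overlap):
        sub = AlignmentBlock(block.leaf_names, block.seqs[:, es:ee],
                             block.mask[es:ee])
        bp = _FactorGraphBP(sub, tree, rates, root_model, bp_opts)
        bp.run()
        iters = max(iters, len(bp.trace))
        loglik += bp.bethe_loglik()
        sl = slice(ks - es, ks - es + (ke - ks))
        for v, nm in enumerate(tree.names):
            marg[nm][ks:ke] = bp.beliefs[v][sl]
        for v in range(1, tree.n_nodes):
            pair[tree.names[v]][ks:ke] = bp.pair_posterior(v)[sl]
    return AncestralPosterior(node_marginal=marg, branch_pair=pair,
                              mask=block.mask.copy(), n_iterations=iters,
                              loglik=loglik)


# ---------------------------------------------------------------------------
# generalized EM
# ---------------------------------------------------------------------------

@dataclass
class EMOptions:
    tol: float = 1e-4          # max absolute rate change between iterations
    max_iter: int = 20
    min_columns: int = 200     # expected opportunities per context per lineage


@dataclass
class EMResult:
    rates: ContextRateSet
    root_model: SecondOrderMarkov
    loglik_trace: list[float]
    n_iter: int
    flagged: list[tuple[str, str, str]]  # (lineage, 5', 3') with sparse data


def estimate_rates(block: AlignmentBlock, tree: Tree,
                   init: ContextRateSet | None = None,
                   em_opts: EMOptions | None = None,
                   bp_opts: BPOptions | None = None,
                   root_model: SecondOrderMarkov | None = None) -> EMResult:
    """Generalized EM for per-lineage context-dependent rates.

    E-step: loopy BP posteriors; expected (5', 3', parent, child) counts per
    lineage accumulate from branch-factor beliefs. M-step: row-normalized
    count updates; the root 2nd-order Markov model is re-estimated from the
    chain-factor beliefs. Contexts whose expected opportunity count falls
    below ``min_columns`` are flagged and held at the initial rates.
    Deterministic given the same data and initialisation.
    """
    em_opts = em_opts or EMOptions()
    bp_opts = bp_opts or BPOptions()
    rates = (init or ContextRateSet.jukes_cantor(tree.lineages)).copy()
    init_rates = rates.copy()
    if root_model is None:
        # leaf-average composition at initialisation
        pooled = block.seqs[:, block.mask].reshape(-1)
        root_model = SecondOrderMarkov.from_codes(pooled) if pooled.size >= 3 \
            else SecondOrderMarkov.uniform()

    trace: list[float] = []
    flagged: list[tuple[str, str, str]] = []
    n_iter = 0
    for n_iter in range(1, em_opts.max_iter + 1):
        counts = {ln: np.zeros((4, 4, 4, 4)) for ln in tree.lineages}
        tri_counts = np.zeros((4, 4, 4))
        pair_counts = np.zeros((4, 4))
        loglik = 0.0
        for ks, ke, es, ee in _iter_blocks(block.length, bp_opts.block_size,
                                           bp_opts.overlap):
            sub = AlignmentBlock(block.leaf_names, block.seqs[:, es:ee],
                                 block.mask[es:ee])
            bp = _FactorGraphBP(sub, tree, rates, root_model, bp_opts)
            bp.run()
            loglik += bp.bethe_loglik()
            for v in range(1, tree.n_nodes):
                counts[tree.names[v]] += bp.branch_expected_counts(v)
            tri, bp_pair = bp.root_expected_counts()
            tri_counts += tri
            pair_counts += bp_pair
        trace.append(loglik)

        new_rates = {}
        flagged = []
        max_change = 0.0
        for ln in tree.lineages:
            c = counts[ln]
            opp = c.sum(axis=(2, 3))  # expected opportunities per (a, b)
            r = np.empty((4, 4, 4, 4))
            for a in range(4):
                for b in range(4):
                    if opp[a, b] < em_opts.min_columns:
                        flagged.append((ln, NT[a], NT[b]))
                        r[a, b] = init_rates[ln][a, b]
                        continue
                    rows = c[a, b]
                    rows = rows / np.where(rows.sum(axis=1, keepdims=True) > 0,
                                           rows.sum(axis=1, keepdims=True), 1.0)
                    zero = rows.sum(axis=1) == 0
                    rows[zero] = init_rates[ln][a, b][zero]
                    r[a, b] = rows
            max_change = max(max_change,
                             float(np.max(np.abs(r - rates[ln]))))
            new_rates[ln] = r
        rates = ContextRateSet(new_rates)
        tri_sum = tri_counts.sum(axis=2, keepdims=True)
        root_model = SecondOrderMarkov(
            tri_counts / np.where(tri_sum > 0, tri_sum, 1.0),
            pair_counts / max(pair_counts.sum(), 1e-300))
        if max_change < em_opts.tol:
            break
    return EMResult(rates=rates, root_model=root_model, loglik_trace=trace,
                    n_iter=n_iter, flagged=sorted(set(flagged)))


# ---------------------------------------------------------------------------
# parsimony validation
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyResult:
    counts: dict[str, np.ndarray]         # lineage -> (4, 4) substitutions
    opportunities: dict[str, np.ndarray]  # lineage -> (4,) parent exposures
    rates: dict[str, np.ndarray]          # counts / opportunities
    events: pd.DataFrame                  # pos, lineage, parent, child
    n_ambiguous: int
    ambiguous: np.ndarray                 # per-position flag


def parsimony_substitutions(block: AlignmentBlock, tree: Tree) -> ParsimonyResult:
    """Fitch small parsimony with ambiguity-excluded substitution counts.

    Columns admitting more than one minimum-substitution labelling of the
    internal nodes (differing in any branch assignment) are excluded from the
    rate counts and tallied as ambiguous. Rates are substitutions divided by
    parent-nucleotide opportunity counts over the unambiguous columns.
    """
    if len(tree.leaves) < 3:
        raise ValueError("parsimony needs at least 3 leaves")
    leaf_row = {nm: i for i, nm in enumerate(block.leaf_names)}
    leaf_of_node = {v: leaf_row[tree.names[v]] for v in tree.leaves}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    edges = [(tree.parent[v], v) for v in range(1, tree.n_nodes)]

    # map column patterns to unique parsimony profiles (memoised: at most
    # 4^n_leaves distinct patterns)
    L = block.length
    counts = {ln: np.zeros((4, 4)) for ln in tree.lineages}
    opps = {ln: np.zeros(4) for ln in tree.lineages}
    ambiguous = np.zeros(L, dtype=bool)
    ev_rows = []
    cache: dict[tuple[int, ...], object] = {}
    cols = block.seqs[[leaf_of_node[v] for v in tree.leaves], :]
    for j in range(L):
        if not block.mask[j]:
            continue
        pat = tuple(int(x) for x in cols[:, j])
        if pat not in cache:
            cache[pat] = _solve_column(pat, tree, internal, edges)
        sol = cache[pat]
        if sol is None:
            ambiguous[j] = True
            continue
        profile, parent_state = sol
        for v, p, c in profile:
            ln = tree.names[v]
            counts[ln][p, c] += 1
            ev_rows.append({"pos": j, "lineage": ln,
                            "parent": NT[p], "child": NT[c]})
        for (u, v), pstate in zip(edges, parent_state):
            opps[tree.names[v]][pstate] += 1

    rates = {}
    for ln in tree.lineages:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = counts[ln] / opps[ln][:, None]
        rates[ln] = np.where(opps[ln][:, None] > 0, r, np.nan)
    events = pd.DataFrame(ev_rows, columns=["pos", "lineage", "parent", "child"])
    return ParsimonyResult(counts=counts, opportunities=opps, rates=rates,
                           events=events, n_ambiguous=int(ambiguous.sum()),
                           ambiguous=ambiguous)


def _solve_column(pattern: tuple[int, ...], tree: Tree,
                  internal: list[int], edges: list[tuple[int, int]]):
    """Unique minimum-substitution labelling of one column, or None."""
    state = {v: pattern[i] for i, v in enumerate(tree.leaves)}
    best = None
    profiles: set = set()
    parent_states: set = set()
    for assign in itertools.product(range(4), repeat=len(internal)):
        for v, s in zip(internal, assign):
            state[v] = s
        cost = sum(state[u] != state[v] for u, v in edges)
        if best is None or cost < best:
            best = cost
            profiles = set()
            parent_states = set()
        if cost == best:
            profiles.add(tuple((v, state[u], state[v])
                               for u, v in edges if state[u] != state[v]))
            parent_states.add(tuple(state[u] for u, _ in edges))
    if len(profiles) != 1 or len(parent_states) != 1:
        return None
    return next(iter(profiles)), next(iter(parent_states))


# ---------------------------------------------------------------------------
# ancestral vs extant G+C
# ---------------------------------------------------------------------------

def ancestral_gc_by_bin(posteriors: AncestralPosterior, bin_index: np.ndarray,
                        focal_codes: np.ndarray, ancestor: str) -> pd.DataFrame:
    """Extant vs posterior-mean ancestral G+C per occupancy bin.

    Ancestral G+C at a position is the marginal posterior probability of
    {G, C} at the designated ancestor node; extant G+C comes from the focal
    leaf. Only unmasked positions contribute; empty bins are flagged with
    NaN means.
    """
    marg = posteriors.node_marginal[ancestor]
    anc_gc = marg[:, GC_CODES[0]] + marg[:, GC_CODES[1]]
    ext_gc = np.isin(focal_codes, GC_CODES).astype(float)
    m = posteriors.mask & (focal_codes >= 0)
    rows = []
    for b in np.unique(bin_index):
        sel = (bin_index == b) & m
        n = int(sel.sum())
        rows.append({"bin": b, "n": n,
                     "extant_gc": float(ext_gc[sel].mean()) if n else np.nan,
                     "ancestral_gc": float(anc_gc[sel].mean()) if n else np.nan,
                     "empty": n == 0})
    return pd.DataFrame(rows)
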