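"""Partition genomic positions by nucleosome occupancy and TSS proximity.

Positions carry a per-base occupancy score (log scale, genome-mean centered,
as in MNase-seq derived tracks). Classification uses fixed thresholds
(low < -2.5, high > 0.4, boundary values fall in ``mid``) or occupancy-rank
quantile bins. Proximity splits non-exonic positions into TSS-proximal
(within ``d`` bp of an annotated TSS, inclusive) and TSS-distal; exonic
positions are excluded from both. Composition statistics (windowed G+C,
reverse-complement-averaged trinucleotide frequencies) support comparing
the sequence makeup of the resulting classes.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# occupancy class codes
OCC_LOW, OCC_MID, OCC_HIGH = 0, 1, 2
# proximity class codes
PROX_PROXIMAL, PROX_DISTAL, PROX_EXCLUDED = 0, 1, 2

LOW_THRESHOLD = -2.5
HIGH_THRESHOLD = 0.4
TSS_WINDOW = 200

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class LocusClassMap:
    """Per-position occupancy and proximity classes.

    ``occupancy`` holds codes {OCC_LOW, OCC_MID, OCC_HIGH} or quantile bin
    indices 0..k-1 (see ``bins``); ``proximity`` holds
    {PROX_PROXIMAL, PROX_DISTAL, PROX_EXCLUDED}.
    """

    occupancy: np.ndarray | None = None
    proximity: np.ndarray | None = None
    bins: np.ndarray | None = None

    def __len__(self) -> int:
        for a in (self.occupancy, self.proximity, self.bins):
            if a is not None:
                return len(a)
        return 0


def classify_occupancy(track: np.ndarray,
                       low_thr: float = LOW_THRESHOLD,
                       high_thr: float = HIGH_THRESHOLD) -> np.ndarray:
    """Classify per-position occupancy scores into low/mid/high.

    Comparisons are strict: score < low_thr -> low, score > high_thr -> high,
    everything else (including exact boundary values) -> mid.
    """
    track = np.asarray(track, dtype=float)
    if low_thr >= high_thr:
        raise ValueError("low_thr must be < high_thr")
    if not np.all(np.isfinite(track)):
        raise ValueError("occupancy track contains non-finite scores")
    out = np.full(track.shape, OCC_MID, dtype=np.int8)
    out[track < low_thr] = OCC_LOW
    out[track > high_thr] = OCC_HIGH
    return out


def bin_occupancy(track: np.ndarray, k: int) -> np.ndarray:
    """Assign each position to one of ``k`` equal-sized occupancy-rank bins.

    Bin sizes differ by at most one position. Ties in score are broken by
    genomic coordinate (stable sort) for reproducibility.
    """
    track = np.asarray(track, dtype=float)
    n = track.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more bins than positions")
    order = np.argsort(track, kind="stable")
    bins = np.empty(n, dtype=np.int64)
    # first (n % k) bins get one extra position
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    bins[order] = np.repeat(np.arange(k), sizes)
    return bins


def classify_proximity(tss_positions: np.ndarray,
                       exon_intervals: list[tuple[int, int]],
                       genome_length: int,
                       d: int = TSS_WINDOW) -> np.ndarray:
    """Label positions TSS-proximal / TSS-distal / excluded(exonic).

    A non-exonic position is proximal iff its distance to the nearest TSS
    coordinate is <= d ("within d bp", inclusive, strand-agnostic). Exonic
    positions are excluded from both proximity classes.
    """
    tss = np.sort(np.asarray(tss_positions, dtype=np.int64))
    if tss.size and (tss.min() < 0 or tss.max() >= genome_length):
        raise ValueError("TSS coordinate outside genome")
    pos = np.arange(genome_length, dtype=np.int64)
    if tss.size == 0:
        dist = np.full(genome_length, np.iinfo(np.int64).max)
    else:
        idx = np.searchsorted(tss, pos)
        left = tss[np.clip(idx - 1, 0, tss.size - 1)]
        right = tss[np.clip(idx, 0, tss.size - 1)]
        dist = np.minimum(np.abs(pos - left), np.abs(pos - right))
    out = np.where(dist <= d, PROX_PROXIMAL, PROX_DISTAL).astype(np.int8)
    for start, end in exon_intervals:
        if start < 0 or end > genome_length or start > end:
            raise ValueError(f"exon interval ({start},{end}) outside genome")
        out[start:end] = PROX_EXCLUDED
    return out


def _seq_to_codes(sequence) -> np.ndarray:
    if isinstance(sequence, str):
        raw = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
        codes = np.full(raw.size, -1, dtype=np.int8)
        for i, c in enumerate(_NT):
            codes[raw == c] = i
        return codes
    return np.asarray(sequence, dtype=np.int8)


def gc_windows(sequence, w: int = 20) -> np.ndarray:
    """G+C fraction in consecutive non-overlapping windows of w bp.

    Only complete windows are used (a trailing partial window is dropped).
    Non-ACGT symbols count toward window length but not toward G+C.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    codes = _seq_to_codes(sequence)
    if codes.size == 0:
        raise ValueError("empty sequence")
    if w > codes.size:
        raise ValueError("window longer than sequence")
    nwin = codes.size // w
    gc = ((codes == 1) | (codes == 2)).astype(float)
    return gc[: nwin * w].reshape(nwin, w).mean(axis=1)


def gc_distribution_logratio(observed_windows: np.ndarray,
                             reference_windows: np.ndarray,
                             n_bins: int = 21) -> pd.DataFrame:
    """Binned log-ratio of the observed vs reference G+C density.

    Both inputs are samples of window G+C fractions in [0, 1]; the densities
    are histograms over ``n_bins`` equal bins of [0, 1]. Bins where the
    reference density is zero are flagged (log-ratio set to NaN there).
    """
    obs = np.asarray(observed_windows, dtype=float)
    ref = np.asarray(reference_windows, dtype=float)
    if obs.size == 0 or ref.size == 0:
        raise ValueError("both samples must be non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    dens_obs, _ = np.histogram(obs, bins=edges, density=True)
    dens_ref, _ = np.histogram(ref, bins=edges, density=True)
    if not np.any((dens_obs > 0) & (dens_ref > 0)):
        raise ValueError("observed and reference densities do not overlap")
    flagged = dens_ref == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log(dens_obs / dens_ref)
    lr[flagged] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"gc_level": centers, "log_ratio": lr,
                         "zero_reference": flagged})


def _rc_code(codes: np.ndarray) -> np.ndarray:
    return 3 - codes


def trinuc_classes() -> tuple[np.ndarray, list[str]]:
    """Map from trinucleotide index (16*a+4*b+c) to one of 32 RC classes."""
    class_of = np.full(64, -1, dtype=np.int64)
    names: list[str] = []
    alphabet = "ACGT"
    nxt = 0
    for idx in range(64):
        if class_of[idx] >= 0:
            continue
        a, b, c = idx // 16, (idx // 4) % 4, idx % 4
        rc = 16 * (3 - c) + 4 * (3 - b) + (3 - a)
        class_of[idx] = nxt
        class_of[rc] = nxt
        tri = alphabet[a] + alphabet[b] + alphabet[c]
        tri_rc = alphabet[3 - c] + alphabet[3 - b] + alphabet[3 - a]
        names.append(tri if idx <= rc else tri_rc)
        nxt += 1
    return class_of, names


_TRI_CLASS, TRINUC_CLASS_NAMES = trinuc_classes()


def trinuc_freqs(sequence, mask: np.ndarray | None = None) -> pd.Series:
    """Frequencies of the 32 reverse-complement trinucleotide classes.

    Counts every overlapping trinucleotide whose three positions all lie in
    the mask (and are all ACGT); frequencies sum to 1.
    """
    codes = _seq_to_codes(sequence)
    if mask is None:
        mask = np.ones(codes.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & (codes >= 0)
    valid = mask[:-2] & mask[1:-1] & mask[2:] if codes.size >= 3 else np.array([], bool)
    if codes.size < 3 or not np.any(valid):
        raise ValueError("masked region shorter than 3")
    tri = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
    counts = np.bincount(_TRI_CLASS[tri[valid]], minlength=32).astype(float)
    return pd.Series(counts / counts.sum(), index=TRINUC_CLASS_NAMES)
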