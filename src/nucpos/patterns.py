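"""Positional dinucleotide (and k-mer) patterns from 5'-anchored reads.

Nucleosome windows of length L (147 by default, dyad at base 73) are cut from
the genome starting at each read's 5' end, strand-wise: minus-strand windows
are reverse complemented so every window runs 5'->3' along the read. The
per-step frequency of each of the 16 dinucleotides over such a window set is
the positional pattern everything downstream consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import (
    DINUC_INDEX,
    DINUCLEOTIDES,
    N_CODE,
    RC_PERMUTATION,
    dinucleotide_codes,
    encode,
    expand_iupac_dinucleotide,
)
from .io import GenomeSequence

__all__ = [
    "DinucleotideProfile",
    "KmerProfile",
    "extract_aligned_windows",
    "dinucleotide_profile",
    "kmer_positional_profile",
    "estimate_dyad_offset",
    "fragment_length_stats",
]


@dataclass
class DinucleotideProfile:
    """16 x (L-1) per-step relative dinucleotide frequencies.

    Rows follow the lexicographic order AA, AC, ..., TT. Steps containing an
    N in any window are excluded from both numerator and denominator at that
    column, so every column with coverage sums to exactly 1; a column with no
    valid observation is flagged undefined (NaN).
    """

    freq: np.ndarray
    n_sequences: int
    L: int = 147
    anchor: str = "five_prime"
    dyad_step: int = 73
    n_valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.freq.shape != (16, self.L - 1):
            raise ValueError(f"freq must be 16 x {self.L - 1}")

    def track(self, members) -> np.ndarray:
        """Summed per-step frequency of a dinucleotide class.

        ``members`` may be explicit 2-mers ({'AA','TT'}) or a 2-letter IUPAC
        pattern string such as 'WW'.
        """
        if isinstance(members, str):
            members = expand_iupac_dinucleotide(members)
        idx = [DINUC_INDEX[m.upper()] for m in members]
        return self.freq[idx].sum(axis=0)

    def reverse_complement(self) -> "DinucleotideProfile":
        """Profile of the reverse-complemented window set: rows permuted
        (AA<->TT, AC<->GT, ...) and columns reversed."""
        rc = self.freq[RC_PERMUTATION][:, ::-1].copy()
        nv = None if self.n_valid is None else self.n_valid[::-1].copy()
        return DinucleotideProfile(rc, self.n_sequences, self.L, self.anchor,
                                   self.L - 1 - self.dyad_step - 1, nv)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# L={self.L} n={self.n_sequences} "
                     f"anchor={self.anchor} dyad_step={self.dyad_step}\n")
            pd.DataFrame(self.freq, index=list(DINUCLEOTIDES)).to_csv(
                fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DinucleotideProfile":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            table = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(table.loc[list(DINUCLEOTIDES)].to_numpy(),
                   int(meta["n"]), int(meta["L"]), meta["anchor"],
                   int(meta["dyad_step"]))


@dataclass
class KmerProfile:
    """Per-position relative frequency track for a requested k-mer set."""

    tracks: dict[str, np.ndarray]
    n_sequences: int
    L: int

    def peak_position(self, kmer: str) -> int:
        return int(np.nanargmax(self.tracks[kmer.upper()]))


def extract_aligned_windows(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    L: int = 147,
) -> np.ndarray:
    """Cut one window of length L per read from its 5' end, strand-wise.

    Plus-strand: ``genome[start : start+L]``. Minus-strand: the reverse
    complement of ``genome[end-L : end]`` (5' end at ``end-1``). Windows
    running off a chromosome are dropped and counted in
    ``result.attrs['n_dropped']`` (ndarray has no attrs; the count is
    attached to the returned array via a small wrapper attribute on the
    function call, see below). Returns an (n, L) int8 code matrix.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if len(reads) == 0:
        raise ValueError("empty read set")
    chunks = []
    n_dropped = 0
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in genome:
            n_dropped += len(grp)
            continue
        codes = encode(genome.sequences[chrom])
        size = codes.size
        minus = (grp["strand"] == "-").to_numpy()
        starts = np.where(minus, grp["end"].to_numpy() - L,
                          grp["start"].to_numpy())
        ok = (starts >= 0) & (starts + L <= size)
        n_dropped += int((~ok).sum())
        starts, minus = starts[ok], minus[ok]
        if starts.size == 0:
            continue
        win = codes[starts[:, None] + np.arange(L)[None, :]]
        if minus.any():
            m = win[minus]
            rc = np.where(m < N_CODE, 3 - m, N_CODE)[:, ::-1]
            win[minus] = rc
        chunks.append(win)
    if not chunks:
        raise ValueError("no read windows fall inside the genome")
    out = np.concatenate(chunks, axis=0)
    extract_aligned_windows.last_n_dropped = n_dropped
    return out


def dinucleotide_profile(windows: np.ndarray, L: int | None = None,
                         dyad_step: int = 73) -> DinucleotideProfile:
    """Per-step dinucleotide frequencies over an aligned window set."""
    windows = np.asarray(windows)
    if windows.ndim != 2 or windows.shape[0] == 0:
        raise ValueError("need a non-empty (n, L) window matrix")
    n, L_eff = windows.shape
    steps = dinucleotide_codes(windows)  # (n, L-1), -1 where N
    freq = np.full((16, L_eff - 1), np.nan)
    n_valid = np.zeros(L_eff - 1, dtype=np.int64)
    for j in range(L_eff - 1):
        col = steps[:, j]
        col = col[col >= 0]
        n_valid[j] = col.size
        if col.size:
            freq[:, j] = np.bincount(col, minlength=16) / col.size
    return DinucleotideProfile(freq, n, L_eff, "five_prime",
                               min(dyad_step, L_eff - 2), n_valid)


def kmer_positional_profile(windows: np.ndarray, kmers) -> KmerProfile:
    """Per-position frequency track for each requested k-mer, k in {2, 3, 4}."""
    windows = np.asarray(windows)
    n, L = windows.shape
    tracks: dict[str, np.ndarray] = {}
    for kmer in kmers:
        km = kmer.upper()
        if not (2 <= len(km) <= 4) or any(c not in "ACGT" for c in km):
            raise ValueError(f"invalid k-mer {kmer!r} (k must be 2-4, ACGT)")
        k = len(km)
        target = encode(km)
        match = np.ones((n, L - k + 1), dtype=bool)
        valid = np.ones((n, L - k + 1), dtype=bool)
        for o, t in enumerate(target):
            sl = windows[:, o:o + L - k + 1]
            match &= sl == t
            valid &= sl < N_CODE
        nv = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            tracks[km] = np.where(nv > 0, match.sum(axis=0) / np.maximum(nv, 1),
                                  np.nan)
    return KmerProfile(tracks, n, L)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return np.nan
    return float((x * y).sum() / denom)


def estimate_dyad_offset(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    search_range: range = range(50, 111),
    L: int = 147,
) -> tuple[int, pd.DataFrame]:
    """Dyad distance from the 5' read anchor, from two-strand pattern symmetry.

    Builds the positional dinucleotide profile separately from plus-anchored
    windows (``genome[start:start+L]``) and minus-anchored windows
    (``genome[end-L:end]``, kept in the forward genome frame — NOT reverse
    complemented). If the dyad lies ``d`` bases from every 5' end, the same
    footprint pattern sits at step ``d`` of the plus profile and at step
    ``L-1-d`` of the minus profile, so their cross-correlation over steps
    peaks at lag ``s = (L-1) - 2d``. For each candidate offset ``c`` the
    Pearson correlation of the two concatenated 16-row profiles (each row
    centered over the overlap, so positional structure rather than overall
    base composition drives the statistic) is evaluated at lag
    ``(L-1) - 2c``; the argmax is the recovered offset (ties toward the
    smaller offset).

    Returns ``(offset, curve)`` where curve has columns offset/correlation.
    """
    plus = reads[reads["strand"] == "+"]
    minus = reads[reads["strand"] == "-"]
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("reads from both strands are required")
    wp = extract_aligned_windows(plus, genome, L)
    # forward-frame minus windows: pretend they are plus reads ending at e
    fake = minus.copy()
    fake["start"] = fake["end"] - L
    fake["end"] = fake["start"] + L
    fake["strand"] = "+"
    wm = extract_aligned_windows(fake, genome, L)
    A = dinucleotide_profile(wp).freq
    B = dinucleotide_profile(wm).freq
    n_steps = L - 1
    rows = []
    for c in search_range:
        s = n_steps - 2 * c
        lo, hi = max(0, -s), min(n_steps, n_steps - s)
        if hi - lo < 10:
            continue
        a = A[:, lo:hi]
        b = B[:, lo + s:hi + s]
        a = (a - np.nanmean(a, axis=1, keepdims=True)).ravel()
        b = (b - np.nanmean(b, axis=1, keepdims=True)).ravel()
        m = ~(np.isnan(a) | np.isnan(b))
        rows.append((c, _pearson(a[m], b[m])))
    curve = pd.DataFrame(rows, columns=["offset", "correlation"])
    best = curve["correlation"].to_numpy()
    offset = int(curve["offset"].iloc[int(np.nanargmax(best))])
    return offset, curve


def recenter_reads(reads: pd.DataFrame, dyad_offset: int,
                   L: int = 147) -> pd.DataFrame:
    """Shift read anchors so an L-window covers the footprint symmetrically.

    With the dyad ``dyad_offset`` bases from each 5' end, shifting every
    anchor 3'-ward by ``dyad_offset - L//2`` puts the dyad at the window
    center — the frame in which dyad-symmetry profiles are drawn.
    """
    shift = dyad_offset - L // 2
    out = reads.copy()
    plus = (out["strand"] == "+").to_numpy()
    out.loc[plus, "start"] = out.loc[plus, "start"] + shift
    out.loc[plus, "end"] = out.loc[plus, "start"] + L
    out.loc[~plus, "end"] = out.loc[~plus, "end"] - shift
    out.loc[~plus, "start"] = out.loc[~plus, "end"] - L
    return out


def fragment_length_stats(
    reads: pd.DataFrame,
    genome: GenomeSequence | None = None,
    length_bins: dict[str, tuple[int, int]] | None = None,
    L: int = 147,
) -> dict:
    """Fragment-length histogram + mean/SD, optionally length-stratified
    dinucleotide profiles.

    ``fragment_len`` is taken from the read table (actual length for paired
    protocols, the protocol's nominal mean for unpaired ones).
    ``length_bins`` maps a stratum name to a half-open [lo, hi) length range;
    when given (requires ``genome``), one DinucleotideProfile per stratum is
    returned under ``"profiles"`` so flank-proximal peak shifts with fragment
    length can be read off.
    """
    lengths = reads["fragment_len"].to_numpy()
    values, counts = np.unique(lengths, return_counts=True)
    out = {
        "mean": float(lengths.mean()),
        "sd": float(lengths.std(ddof=0)),
        "histogram": pd.DataFrame({"length": values, "count": counts}),
    }
    if length_bins:
        if genome is None:
            raise ValueError("stratified profiles require the genome")
        profiles = {}
        for name, (lo, hi) in length_bins.items():
            sub = reads[(lengths >= lo) & (lengths < hi)]
            if len(sub) == 0:
                continue
            profiles[name] = dinucleotide_profile(
                extract_aligned_windows(sub, genome, L))
        out["profiles"] = profiles
    return out
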