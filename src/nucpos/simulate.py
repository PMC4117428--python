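"""Synthetic genomes, nucleosome maps, and protocol-specific reads.

The generator plants every statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any sequencing download:

* a helically phased dinucleotide signal inside each 147 bp nucleosome
  footprint — AA/TT emission is favored at steps whose distance from the dyad
  is within +/-1 bp of an integer multiple of the period (10.2 bp by
  default), GG/CC at steps offset by half the rounded period (5 bp), so the
  two tracks come out counter-phased;
* two promoter classes with distinct base composition (AT-rich ~40% G+C,
  GC-rich ~60%) and distinct nucleosome densities around the TSS;
* GC-dependent nucleosome loss in the apoptotic condition (GC-rich footprints
  retained with probability ``retention_gc_rich``, 0.2 by default);
* two read protocols: unpaired 24-25 bp reads from ~150 bp MNase-like
  fragments, and paired 120 bp reads from ~170 bp apoptotic-nuclease-like
  fragments. Fragments are centered on the dyad with a small jitter, so the
  dyad sits near fragment_length/2 from either 5' end.

The dinucleotide bias is position-dependent first-order emission: at a phased
step whose previous base can extend the favored class (A/T for AA/TT, G/C for
GG/CC), the probability of repeating that base is raised by
``enrichment_strength`` and the distribution renormalized. This is the
simplest mechanism that reproduces phased positional profiles and is easy to
invert in tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alphabet import decode, encode
from .config import (
    DEFAULT_CLASSES,
    PromoterClassConfig,
    ProtocolConfig,
    SignalConfig,
)
from .io import GenomeSequence

__all__ = [
    "phased_steps",
    "build_synthetic_genome",
    "apply_apoptotic_depletion",
    "simulate_protocol_reads",
    "simulate_dataset",
]

TRUTH_COLUMNS = [
    "chrom", "dyad_pos", "promoter_id", "class_label", "retained_in_apoptosis",
]

_A, _C, _G, _T = 0, 1, 2, 3


def _class_probs(gc_fraction: float) -> np.ndarray:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return np.array([at, gc, gc, at])  # A C G T


def phased_steps(signal: SignalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (length footprint-1) of WW- and SS-phased steps.

    Step ``s`` covers footprint bases (s, s+1); its distance from the dyad is
    ``s - footprint//2``. A step is phased when that distance lies within
    +/-1 bp of an integer multiple of the period (plus the class phase
    offset). Multiples of both signs are used, so the mask is symmetric
    about the dyad.
    """
    L = signal.footprint_bp
    dyad = signal.dyad_index
    dist = np.arange(L - 1) - dyad

    def near_multiple(x: np.ndarray) -> np.ndarray:
        k = np.round(x / signal.period_bp)
        return np.abs(x - k * signal.period_bp) <= 1.0

    ww = near_multiple(dist - signal.ww_phase)
    ss = near_multiple(dist - signal.ww_phase - signal.ss_phase_offset_bp)
    return ww, ss


def signal_envelopes(signal: SignalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-step amplitude envelopes of the WW and SS enrichment.

    GG/CC enrichment is maximal at the dyad and decays linearly by
    ``gradient`` toward the footprint edges; AA/TT enrichment runs the other
    way. This plants the convex/concave gradient seen in whole-set
    nucleosome patterns and gives the footprint an absolute position signal.
    """
    L = signal.footprint_bp
    dyad = signal.dyad_index
    rel = np.abs(np.arange(L - 1) - dyad) / dyad  # 0 at dyad -> ~1 at edges
    ss_env = 1.0 - signal.gradient * rel
    ww_env = 1.0 - signal.gradient * (1.0 - rel)
    return ww_env, ss_env


def _emit_footprints(n: int, signal: SignalConfig, probs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Emit ``n`` footprint sequences (codes, shape (n, footprint_bp))."""
    L = signal.footprint_bp
    ww, ss = phased_steps(signal)
    ww_env, ss_env = signal_envelopes(signal)
    bg = rng.choice(4, size=(n, L), p=probs).astype(np.int8)
    if signal.enrichment_strength == 0.0 or n == 0:
        return bg
    out = bg.copy()
    for s in range(L - 1):
        prev = out[:, s]
        if ww[s]:
            boosted = (prev == _A) | (prev == _T)
            boost = signal.enrichment_strength * ww_env[s]
        elif ss[s]:
            boosted = (prev == _C) | (prev == _G)
            boost = signal.enrichment_strength * ss_env[s]
        else:
            continue
        # With boost b, P(next == prev) = (p_bg[prev] + b)/(1 + b): emit
        # prev with probability b/(1+b), else fall back to the background.
        take = boosted & (rng.random(n) < boost / (1.0 + boost))
        out[:, s + 1] = np.where(take, prev, bg[:, s + 1])
    return out


def _place_dyads(n_promoters: int, flank: int, density: float,
                 footprint: int, min_gap: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Dyad offsets (relative to each promoter window start), non-overlapping.

    Each promoter receives exactly round(window * density) nucleosomes
    (capped at the packing limit) at uniform random non-overlapping
    positions; footprints are spaced by at least ``min_gap``. The count is
    deterministic so the class density is realized exactly — promoter-to-
    promoter variability comes from placement and read sampling.
    """
    window = 2 * flank
    m = footprint + min_gap
    k_max = window // m
    counts = np.full(n_promoters,
                     min(int(round(window * density)), k_max))
    offsets = []
    half = footprint // 2
    for k in counts:
        if k == 0:
            offsets.append(np.empty(0, dtype=np.int64))
            continue
        u = np.sort(rng.uniform(0, window - k * m, size=k))
        starts = np.floor(u).astype(np.int64) + np.arange(k) * m
        offsets.append(starts + half)
    return offsets


def build_synthetic_genome(
    classes: PromoterClassConfig | tuple[PromoterClassConfig, ...] = DEFAULT_CLASSES,
    signal: SignalConfig = SignalConfig(),
    seed: int = 0,
    flank: int = 1000,
    spacer: int = 400,
    min_gap: int = 20,
    margin: int = 200,
) -> tuple[GenomeSequence, pd.DataFrame, pd.DataFrame]:
    """Generate a promoter-structured genome with planted nucleosomes.

    One chromosome per promoter class; each promoter occupies a
    ``2*flank + spacer`` slot with its TSS at ``slot_start + flank``.
    Nucleosomes are placed at the class density within +/-flank of the TSS
    and their footprints emitted with the phased dinucleotide bias; the rest
    of the chromosome is i.i.d. background at the class G+C fraction.

    Returns (genome, tss_table, truth_map); the truth map records every
    planted dyad with ``retained_in_apoptosis=True``.
    """
    if isinstance(classes, PromoterClassConfig):
        classes = (classes,)
    if margin < signal.footprint_bp:
        raise ValueError(
            "margin must be at least one footprint so no promoter region "
            "overlaps a chromosome end")
    rng = np.random.default_rng(seed)
    slot = 2 * flank + spacer
    sequences: dict[str, str] = {}
    tss_rows = []
    truth_rows = []
    for cls in classes:
        chrom = f"chr_{cls.name}"
        if chrom in sequences:
            raise ValueError(f"duplicate class name {cls.name!r}")
        length = 2 * margin + cls.n_promoters * slot
        probs = _class_probs(cls.gc_fraction)
        chrom_codes = rng.choice(4, size=length, p=probs).astype(np.int8)
        dyad_offsets = _place_dyads(
            cls.n_promoters, flank, cls.nucleosome_density,
            signal.footprint_bp, min_gap, rng)
        all_dyads = []
        for i, offs in enumerate(dyad_offsets):
            win_start = margin + i * slot
            tss = win_start + flank
            strand = "+" if rng.random() < 0.5 else "-"
            pid = f"{cls.name}_p{i}"
            tss_rows.append((chrom, tss, strand, pid, cls.name))
            for d in offs:
                dyad = win_start + int(d)
                all_dyads.append(dyad)
                truth_rows.append((chrom, dyad, pid, cls.name, True))
        fps = _emit_footprints(len(all_dyads), signal, probs, rng)
        half = signal.dyad_index
        for dyad, fp in zip(all_dyads, fps):
            chrom_codes[dyad - half: dyad - half + signal.footprint_bp] = fp
        sequences[chrom] = decode(chrom_codes)
    genome = GenomeSequence(sequences)
    tss = pd.DataFrame(
        tss_rows, columns=["chrom", "tss_pos", "strand", "promoter_id",
                           "class_label"])
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "dyad_pos"]).reset_index(drop=True)
    return genome, tss, truth


def footprint_gc(truth: pd.DataFrame, genome: GenomeSequence,
                 footprint: int = 147) -> np.ndarray:
    """G+C fraction of each dyad's footprint."""
    half = footprint // 2
    gc = np.empty(len(truth), dtype=float)
    for chrom, grp in truth.groupby("chrom", sort=False):
        codes = encode(genome.sequences[chrom])
        is_gc = ((codes == _C) | (codes == _G)).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        start = grp["dyad_pos"].to_numpy() - half
        end = start + footprint
        gc[grp.index] = (cum[end] - cum[start]) / footprint
    return gc


def apply_apoptotic_depletion(
    truth: pd.DataFrame,
    genome: GenomeSequence,
    retention_gc_rich: float = 0.2,
    gc_threshold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """GC-dependent nucleosome loss of the apoptotic condition.

    Nucleosomes whose footprint G+C fraction exceeds ``gc_threshold`` are
    retained independently with probability ``retention_gc_rich``; all others
    are retained with probability 1. Returns a copy with the
    ``retained_in_apoptosis`` flags (and a ``footprint_gc`` column) updated.
    """
    if not 0.0 <= retention_gc_rich <= 1.0:
        raise ValueError("retention_gc_rich must lie in [0, 1]")
    truth = truth.copy()
    if truth.empty:
        return truth
    rng = np.random.default_rng(seed)
    gc = footprint_gc(truth, genome)
    gc_rich = gc > gc_threshold
    lost = gc_rich & (rng.random(len(truth)) >= retention_gc_rich)
    truth["footprint_gc"] = gc
    truth["retained_in_apoptosis"] = (
        truth["retained_in_apoptosis"].to_numpy() & ~lost
    )
    return truth


def simulate_protocol_reads(
    genome: GenomeSequence,
    truth: pd.DataFrame,
    protocol: ProtocolConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate nuclease-protected fragments and emit BED-compatible reads.

    Each retained dyad yields Poisson(``reads_per_nucleosome_mean``)
    fragments. Fragment length is a rounded Normal(mean, sd); the fragment
    center jitters around the dyad with SD ``center_jitter_sd_bp``. The
    unpaired protocol emits one stranded 5'-anchored read per fragment
    (random strand, fragment_len recorded as the protocol's nominal mean,
    which is what gel fractionation tells the experimenter); the paired
    protocol emits both ends (``/1`` forward, ``/2`` reverse, actual fragment
    length recorded). Fragments extending past a chromosome end are dropped;
    ``reads.attrs`` carries the drawn/emitted/dropped accounting.
    """
    rng = np.random.default_rng(seed)
    retained = truth[truth["retained_in_apoptosis"]]
    rows_per_chrom = []
    n_drawn = 0
    n_dropped = 0
    frag_id = 0
    sizes = genome.chrom_sizes
    for chrom, grp in retained.groupby("chrom", sort=False):
        dyads = grp["dyad_pos"].to_numpy()
        counts = rng.poisson(protocol.reads_per_nucleosome_mean, len(dyads))
        n_drawn += int(counts.sum())
        centers = np.repeat(dyads, counts)
        if centers.size == 0:
            continue
        jitter = np.rint(rng.normal(0.0, protocol.center_jitter_sd_bp,
                                    centers.size)).astype(np.int64)
        lengths = np.rint(rng.normal(protocol.fragment_mean_bp,
                                     protocol.fragment_sd_bp,
                                     centers.size)).astype(np.int64)
        lengths = np.maximum(lengths, protocol.read_len_bp)
        starts = centers + jitter - lengths // 2
        ends = starts + lengths
        ok = (starts >= 0) & (ends <= sizes[chrom])
        n_dropped += int((~ok).sum())
        starts, ends, lengths = starts[ok], ends[ok], lengths[ok]
        n = starts.size
        ids = np.arange(frag_id, frag_id + n)
        frag_id += n
        if protocol.paired:
            r = protocol.read_len_bp
            fwd = pd.DataFrame({
                "chrom": chrom, "start": starts, "end": starts + r,
                "name": [f"f{i}/1" for i in ids],
                "fragment_len": lengths, "strand": "+",
            })
            rev = pd.DataFrame({
                "chrom": chrom, "start": ends - r, "end": ends,
                "name": [f"f{i}/2" for i in ids],
                "fragment_len": lengths, "strand": "-",
            })
            rows_per_chrom.append(pd.concat([fwd, rev], ignore_index=True))
        else:
            minus = rng.random(n) < 0.5
            r = protocol.read_len_bp
            nominal = int(round(protocol.fragment_mean_bp))
            rows_per_chrom.append(pd.DataFrame({
                "chrom": chrom,
                "start": np.where(minus, ends - r, starts),
                "end": np.where(minus, ends, starts + r),
                "name": [f"f{i}" for i in ids],
                "fragment_len": nominal,
                "strand": np.where(minus, "-", "+"),
            }))
    if rows_per_chrom:
        reads = pd.concat(rows_per_chrom, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=[
            "chrom", "start", "end", "name", "fragment_len", "strand"])
    reads.attrs["n_fragments_drawn"] = n_drawn
    reads.attrs["n_fragments_dropped"] = n_dropped
    reads.attrs["n_fragments_emitted"] = n_drawn - n_dropped
    reads.attrs["protocol"] = protocol.name
    return reads


def simulate_dataset(
    classes=DEFAULT_CLASSES,
    signal: SignalConfig = SignalConfig(),
    protocol: ProtocolConfig | None = None,
    seed: int = 0,
    flank: int = 1000,
    apoptotic_depletion: bool = False,
    retention_gc_rich: float = 0.2,
    **genome_kwargs,
) -> dict:
    """One-call simulation: genome + TSS + truth (+ optional depletion) + reads.

    Returns a dict with keys ``genome``, ``tss``, ``truth``, ``reads``.
    Sub-seeds for the three stochastic stages are derived from ``seed``.
    """
    from .config import MNASE_PROTOCOL
    protocol = protocol or MNASE_PROTOCOL
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    genome, tss, truth = build_synthetic_genome(
        classes, signal, seed=seeds[0], flank=flank, **genome_kwargs)
    if apoptotic_depletion:
        truth = apply_apoptotic_depletion(
            truth, genome, retention_gc_rich, seed=seeds[1])
    reads = simulate_protocol_reads(genome, truth, protocol, seed=seeds[2])
    return {"genome": genome, "tss": tss, "truth": truth, "reads": reads}
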