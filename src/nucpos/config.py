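"""Configuration objects for the simulator and the pipeline.

All coordinates in the package are 0-based, half-open. Defaults encode the
study conditions the package is designed around: a ~10.2 bp helical repeat of
counter-phased AA/TT vs GG/CC enrichment inside 147 bp nucleosome footprints,
an MNase-like protocol (150 bp fragments, 24-25 bp unpaired reads) and an
apoptotic-nuclease-like protocol (170 bp fragments, 120 bp paired reads), and
two promoter classes (AT-rich at one nucleosome per 250 bp, GC-rich at one per
1000 bp in the apoptotic state).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SignalConfig",
    "ProtocolConfig",
    "PromoterClassConfig",
    "RunConfig",
    "MNASE_PROTOCOL",
    "APOPTOTIC_PROTOCOL",
    "DEFAULT_CLASSES",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SignalConfig:
    """Planted positional dinucleotide signal inside a nucleosome footprint.

    Parameters
    ----------
    period_bp
        Helical repeat of the planted enrichment, in bp.
    ww_phase
        Offset (bp) of the AA/TT enrichment maxima relative to the dyad.
    ss_phase_offset_bp
        Offset (bp) of GG/CC maxima relative to AA/TT maxima. The default,
        half the rounded period, makes the two tracks counter-phased by 5 bp.
    enrichment_strength
        Excess probability, in [0, 1], of emitting the favored dinucleotide
        class at helically phased steps (position-dependent first-order
        emission, renormalized).
    gradient
        Depth, in [0, 1], of the counter-running amplitude envelopes across
        the footprint: GG/CC enrichment is strongest at the dyad and decays
        toward the edges by this fraction, AA/TT enrichment the reverse.
        This reproduces the convex/concave gradient of whole-set nucleosome
        patterns and gives the footprint an absolute positional signature on
        top of the 10 bp phase signal.
    footprint_bp
        Footprint length; odd, so a central dyad base exists.
    """

    period_bp: float = 10.2
    ww_phase: int = 0
    ss_phase_offset_bp: int = 5
    enrichment_strength: float = 0.6
    gradient: float = 0.5
    footprint_bp: int = 147

    def __post_init__(self) -> None:
        if self.period_bp <= 2:
            raise ValueError("period_bp must exceed 2 bp")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ValueError("enrichment_strength must lie in [0, 1]")
        if not 0.0 <= self.gradient <= 1.0:
            raise ValueError("gradient must lie in [0, 1]")
        if self.footprint_bp % 2 != 1:
            raise ValueError("footprint_bp must be odd so a central dyad exists")

    @property
    def dyad_index(self) -> int:
        return self.footprint_bp // 2


@dataclass(frozen=True)
class ProtocolConfig:
    """Read-generation protocol (nuclease digestion + sequencing geometry)."""

    name: str = "mnase"
    fragment_mean_bp: float = 150.0
    fragment_sd_bp: float = 4.0
    read_len_bp: int = 25
    paired: bool = False
    reads_per_nucleosome_mean: float = 4.0
    center_jitter_sd_bp: float = 2.0

    def __post_init__(self) -> None:
        if self.read_len_bp > self.fragment_mean_bp:
            raise ValueError("read_len_bp must not exceed fragment_mean_bp")
        if self.reads_per_nucleosome_mean < 0:
            raise ValueError("reads_per_nucleosome_mean must be non-negative")


#: 24-25 bp unpaired reads from ~150 bp MNase-protected fragments.
MNASE_PROTOCOL = ProtocolConfig(
    name="mnase", fragment_mean_bp=150.0, fragment_sd_bp=4.0,
    read_len_bp=25, paired=False,
)

#: 120 bp paired reads from ~170 bp apoptotic-nuclease fragments.
APOPTOTIC_PROTOCOL = ProtocolConfig(
    name="apoptotic", fragment_mean_bp=170.0, fragment_sd_bp=6.0,
    read_len_bp=120, paired=True,
)


@dataclass(frozen=True)
class PromoterClassConfig:
    """One promoter class of the synthetic genome.

    ``nucleosome_density`` is nucleosomes per bp over the +/- flank window
    around each TSS of the class.
    """

    name: str = "AT_rich"
    n_promoters: int = 400
    gc_fraction: float = 0.40
    nucleosome_density: float = 1 / 250

    def __post_init__(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")
        if self.nucleosome_density <= 0:
            raise ValueError("nucleosome_density must be > 0")


#: The two promoter classes of the apoptotic condition: AT-rich promoters
#: retain nucleosomes (one per 250 bp); GC-rich promoters are depleted
#: (one per 1000 bp).
DEFAULT_CLASSES = (
    PromoterClassConfig("AT_rich", 400, 0.40, 1 / 250),
    PromoterClassConfig("GC_rich", 400, 0.60, 1 / 1000),
)


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration (see pipeline module)."""

    seed: int = 1
    outdir: str = "nucpos_out"
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "patterns", "periodicity", "occupancy", "predict",
        "curvature",
    ])
    # simulate stage
    signal: SignalConfig = field(default_factory=SignalConfig)
    protocol: ProtocolConfig = field(default_factory=lambda: MNASE_PROTOCOL)
    classes: tuple[PromoterClassConfig, ...] = DEFAULT_CLASSES
    flank_bp: int = 1000
    retention_gc_rich: float = 0.2
    # externally supplied inputs (used when the simulate stage is off)
    genome_fasta: str | None = None
    reads_bed: str | None = None
    tss_tsv: str | None = None
    gene_sets_tsv: str | None = None
    # analysis parameters
    smooth_bp: int = 30
    kmeans_k: int = 2
    max_lag: int = 20
    n_eval_windows: int = 500
    tolerances: tuple[int, ...] = (15, 36)
    strict: bool = False
    make_figures: bool = True


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; keys mirror the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "signal" in kwargs:
        kwargs["signal"] = SignalConfig(**kwargs["signal"])
    if "protocol" in kwargs:
        kwargs["protocol"] = ProtocolConfig(**kwargs["protocol"])
    if "classes" in kwargs:
        kwargs["classes"] = tuple(
            PromoterClassConfig(**c) for c in kwargs["classes"]
        )
    if "stages" in kwargs:
        kwargs["stages"] = list(kwargs["stages"])
    if "tolerances" in kwargs:
        kwargs["tolerances"] = tuple(kwargs["tolerances"])
    return RunConfig(**kwargs)
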