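"""Shared synthetic datasets, generated once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nucpos.config import (
    APOPTOTIC_PROTOCOL,
    MNASE_PROTOCOL,
    PromoterClassConfig,
    SignalConfig,
)
from nucpos.patterns import dinucleotide_profile, extract_aligned_windows
from nucpos.simulate import build_synthetic_genome, simulate_protocol_reads

TWO_CLASSES = (
    PromoterClassConfig("AT_rich", 600, 0.40, 1 / 250),
    PromoterClassConfig("GC_rich", 600, 0.60, 1 / 1000),
)


@pytest.fixture(scope="session")
def default_genome():
    """Default-signal genome with planted nucleosomes (seed 1)."""
    genome, tss, truth = build_synthetic_genome(
        TWO_CLASSES, SignalConfig(), seed=1)
    return {"genome": genome, "tss": tss, "truth": truth}


@pytest.fixture(scope="session")
def mnase_reads(default_genome):
    """~50k unpaired MNase-like reads over the default genome."""
    proto = dataclasses.replace(MNASE_PROTOCOL, reads_per_nucleosome_mean=9.0)
    return simulate_protocol_reads(
        default_genome["genome"], default_genome["truth"], proto, seed=2)


@pytest.fixture(scope="session")
def apoptotic_reads(default_genome):
    """Paired 120 bp apoptotic-protocol reads over the default genome."""
    proto = dataclasses.replace(APOPTOTIC_PROTOCOL,
                                reads_per_nucleosome_mean=5.0)
    return simulate_protocol_reads(
        default_genome["genome"], default_genome["truth"], proto, seed=2)


@pytest.fixture(scope="session")
def mnase_profile(default_genome, mnase_reads):
    """16-dinucleotide positional profile of the MNase read windows."""
    windows = extract_aligned_windows(mnase_reads, default_genome["genome"])
    return dinucleotide_profile(windows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
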