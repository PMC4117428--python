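"""Intrinsic DNA curvature by the wedge model.

Each dinucleotide step deflects the helix axis by fixed roll and tilt angles
while rotating by its twist; composing these rotations along a sequence
traces the 3-D helix-axis path. Curvature at a position is the angle (in
degrees) between the chords entering and leaving an 11 bp window centered
there — i.e. the net axis deflection over one helical turn. Only relative
comparisons are meaningful at this level of modeling: phased A-tracts come
out curved, shuffled controls flat, and nucleosomal window sets can be
averaged into dyad-centered curvature tracks.

The bundled wedge-angle table is a versioned data file and is injectable, so
alternative parameter sets can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import DINUCLEOTIDES, dinucleotide_codes, encode

__all__ = ["WedgeTable", "CurvatureProfile", "curvature_profile",
           "mean_curvature_track"]


@dataclass(frozen=True)
class WedgeTable:
    """Per-dinucleotide roll, tilt and twist angles in degrees."""

    roll: np.ndarray   # (16,) indexed by dinucleotide code
    tilt: np.ndarray
    twist: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        for arr in (self.roll, self.tilt, self.twist):
            if np.asarray(arr).shape != (16,):
                raise ValueError("wedge table needs 16 entries per angle")
        if not (np.asarray(self.twist) > 0).all():
            raise ValueError("twist angles must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WedgeTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index("dinucleotide").loc[list(DINUCLEOTIDES)]
        direction = np.deg2rad(df["direction"].to_numpy())
        wedge = df["wedge"].to_numpy()
        return cls(
            roll=wedge * np.cos(direction),
            tilt=wedge * np.sin(direction),
            twist=df["twist"].to_numpy(),
            provenance=str(path),
        )

    @classmethod
    def default(cls) -> "WedgeTable":
        with resources.as_file(
            resources.files("nucpos.data") / "wedge_angles.tsv"
        ) as p:
            table = cls.from_tsv(p)
        object.__setattr__(table, "provenance", "bundled wedge_angles.tsv v1")
        return table

    @classmethod
    def zero(cls) -> "WedgeTable":
        """All-zero deflections (straight helix), for controls."""
        return cls(np.zeros(16), np.zeros(16), np.full(16, 36.0), "zero table")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "dinucleotide": list(DINUCLEOTIDES),
            "roll": self.roll, "tilt": self.tilt, "twist": self.twist,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class CurvatureProfile:
    """Per-position curvature magnitude, degrees of axis deflection per
    window; NaN within window/2 of the ends and around Ns."""

    values: np.ndarray
    window: int = 11

    def __len__(self) -> int:
        return self.values.size


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _step_matrices(table: WedgeTable) -> np.ndarray:
    """Per-dinucleotide step rotation.

    The wedge (magnitude w = hypot(roll, tilt), direction phi = atan2(tilt,
    roll)) is one rotation about the in-plane axis at angle phi, flanked by
    half the twist on either side:

        M = Rz(t/2) [Rz(phi) Rx(w) Rz(-phi)] Rz(t/2)

    With complementary steps carrying equal w and opposite phi, this makes
    the composed path strand-symmetric: the curvature profile of the reverse
    complement is the original profile reversed.
    """
    mats = np.empty((2, 16, 3, 3))
    for d in range(16):
        t = np.deg2rad(table.twist[d])
        w = float(np.deg2rad(np.hypot(table.roll[d], table.tilt[d])))
        phi = float(np.arctan2(table.tilt[d], table.roll[d]))
        mats[0, d] = (_rot_z(t / 2.0 + phi) @ _rot_x(w)
                      @ _rot_z(t / 2.0 - phi))
        # half-step: frame at the middle of the wedge; using its z as the
        # axis segment direction is what makes the path strand-symmetric
        mats[1, d] = _rot_z(t / 2.0 + phi) @ _rot_x(w / 2.0)
    return mats


def helix_axis_path(seq: str | np.ndarray,
                    table: WedgeTable | None = None) -> np.ndarray:
    """3-D helix-axis points, one per base; steps with N propagate NaN.

    Each step advances one unit along the mid-step axis direction (the z of
    the frame halfway through the step's wedge rotation).
    """
    table = table or WedgeTable.default()
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    steps = dinucleotide_codes(codes)
    full, half = _step_matrices(table)
    n = codes.size
    points = np.full((n, 3), np.nan)
    points[0] = 0.0
    R = np.eye(3)
    ez = np.array([0.0, 0.0, 1.0])
    for i, d in enumerate(steps):
        if d < 0:
            # N breaks the chain: restart the path at the next defined base
            points[i + 1] = np.nan
            continue
        direction = R @ half[d] @ ez
        R = R @ full[d]
        prev = points[i]
        if np.isnan(prev).any():
            prev = np.zeros(3)
            points[i] = prev
        points[i + 1] = prev + direction
    return points


def curvature_profile(seq: str | np.ndarray, window: int = 11,
                      table: WedgeTable | None = None) -> CurvatureProfile:
    """Wedge-model curvature of a sequence.

    Curvature at base ``p`` is the angle in degrees between the axis chords
    ``P[p] - P[p - h]`` and ``P[p + h] - P[p]`` with ``h = window // 2``;
    undefined (NaN) within ``h`` of the ends and wherever an N falls inside
    the window.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if codes.size < window + 1:
        raise ValueError("sequence shorter than window + 1")
    points = helix_axis_path(codes, table)
    h = window // 2
    n = codes.size
    values = np.full(n, np.nan)
    bad = np.isnan(points).any(axis=1)
    for p in range(h, n - h):
        if bad[p - h:p + h + 1].any():
            continue
        a = points[p] - points[p - h]
        b = points[p + h] - points[p]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            continue
        cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
        values[p] = np.degrees(np.arccos(cosang))
    return CurvatureProfile(values, window)


def mean_curvature_track(windows: np.ndarray, window: int = 11,
                         table: WedgeTable | None = None) -> np.ndarray:
    """Mean curvature profile over an aligned (n, L) nucleosome window set,
    e.g. dyad-centered curvature tracks; NaN-aware."""
    windows = np.atleast_2d(windows)
    table = table or WedgeTable.default()
    profiles = np.vstack([
        curvature_profile(w, window, table).values for w in windows
    ])
    finite = np.isfinite(profiles)
    n = finite.sum(axis=0)
    total = np.where(finite, profiles, 0.0).sum(axis=0)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)
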