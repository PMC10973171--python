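"""Synthetic sequences and measurements with known ground truth.

Every generator is a pure function of its spec (including the seed), so
simulation-based tests are reproducible offline.  Measurement noise is
multiplicative (coefficient-of-variation style): photometric replicate
error scales with signal in practice, so each simulated reading is the
exact Beer-Lambert value times ``1 + N(0, cv)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .photometry import MacResult
from .quantify import DilutionSeries

__all__ = ["SyntheticSpec", "SeriesSpec", "random_sequence", "simulate_series"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a random sequence: length, base fractions, seed."""

    length: int
    fractions: dict[str, float]
    seed: int
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValidationError(f"length must be non-negative, got {self.length}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValidationError("base fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"base fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a simulated dilution series with known stock truth.

    ``concentration`` is the true stock molar concentration (M); ``cv`` the
    replicate coefficient of variation; ``dilutions`` the fold-dilution
    ladder.
    """

    concentration: float
    dilutions: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    cv: float = 0.0
    replicates: int = 3
    path_length: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError("true concentration must be positive")
        if self.cv < 0:
            raise ValidationError(f"noise CV must be non-negative, got {self.cv}")
        if self.replicates < 1:
            raise ValidationError("at least one replicate per point")
        if any(d < 1 for d in self.dilutions):
            raise ValidationError("dilution factors must be >= 1")


def random_sequence(spec: SyntheticSpec) -> tuple[str, str]:
    """Draw a sequence of ``spec.length`` residues at the given base fractions.

    Returns a ``(id, sequence)`` record; the id embeds the seed so every
    generated artifact records how to regenerate it.
    """
    rng = np.random.default_rng(spec.seed)
    codes = sorted(spec.fractions)
    probs = np.array([spec.fractions[c] for c in codes])
    if spec.length == 0:
        seq = ""
    else:
        seq = "".join(rng.choice(codes, size=spec.length, p=probs / probs.sum()))
    return f"{spec.record_id}_seed{spec.seed}", seq


def simulate_series(spec: SeriesSpec, mac: MacResult) -> DilutionSeries:
    """Simulate replicate A260 readings of a serial dilution of a known stock.

    Each reading is ``MAC260 * l * c / dilution`` times ``1 + N(0, cv)``.
    Negative draws (possible only at unrealistically large CV) are clipped
    to zero to keep readings physical.
    """
    if mac.mac_260 <= 0:
        raise ValidationError("MAC260 must be positive to simulate absorbances")
    rng = np.random.default_rng(spec.seed)
    points = []
    for d in spec.dilutions:
        ideal = mac.mac_260 * spec.path_length * spec.concentration / d
        noise = 1.0 + rng.normal(0.0, spec.cv, size=spec.replicates)
        reps = tuple(float(max(a, 0.0)) for a in ideal * noise)
        points.append((d, reps))
    return DilutionSeries(tuple(points), path_length=spec.path_length)
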