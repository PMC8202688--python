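"""Emulated fixed-point arithmetic and the 16-bit synaptic weight codec.

State variables on the neuromorphic target are held in the ISO ``accum``
format: a signed fixed-point number with 16 integer and 15 fractional bits
(s16.15).  Synaptic weights are stored in 16 bits with a per-projection
power-of-two scale chosen so that the largest per-timestep summed input — the
*peak conductance* — is still representable.  This module emulates both:
quantization to an arbitrary format (round to nearest, ties to even,
saturating with a diagnostic counter) and the cover-the-peak weight codec,
including the representability analysis (bits required, relative encoding
error).

Bit-for-bit agreement with any particular hardware rounding pipeline is not
promised; quantization is applied at well-defined points of the state update
and saturation is always counted, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixedFormat",
    "S16_15",
    "WEIGHT16",
    "WeightCodec",
    "SaturationCounter",
    "quantize",
    "bits_required",
    "build_codec",
    "normalize_weight",
]


@dataclass(frozen=True)
class FixedFormat:
    """A fixed-point number format: sign bit, integer bits, fractional bits."""

    total_bits: int = 32
    frac_bits: int = 15
    signed: bool = True

    def __post_init__(self) -> None:
        if self.total_bits <= self.frac_bits + int(self.signed):
            raise ValueError("format must have at least one integer bit")

    @property
    def quantum(self) -> float:
        return 2.0 ** (-self.frac_bits)

    @property
    def max_value(self) -> float:
        return (2 ** (self.total_bits - int(self.signed)) - 1) * self.quantum

    @property
    def min_value(self) -> float:
        if not self.signed:
            return 0.0
        return -(2 ** (self.total_bits - 1)) * self.quantum


#: The ``accum`` state format: signed, 16 integer + 15 fractional bits.
S16_15 = FixedFormat(total_bits=32, frac_bits=15, signed=True)

#: The raw 16-bit unsigned weight word (before power-of-two scaling).
WEIGHT16 = FixedFormat(total_bits=16, frac_bits=15, signed=False)


class SaturationCounter:
    """Counts values clipped during quantization; saturation is never silent."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)


def quantize(x, fmt: FixedFormat = S16_15,
             saturation: SaturationCounter | None = None):
    """Round ``x`` to the nearest representable value of ``fmt``.

    Ties go to even (matching IEEE default rounding of the integer grid).
    Out-of-range values saturate to the format limits; each saturated element
    increments ``saturation`` when a counter is supplied.
    """
    arr = np.asarray(x, dtype=np.float64)
    q = fmt.quantum
    scaled = np.rint(arr / q)
    lo = fmt.min_value / q
    hi = fmt.max_value / q
    clipped = np.clip(scaled, lo, hi)
    if saturation is not None:
        saturation.add(np.count_nonzero(clipped != scaled))
    out = clipped * q
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def bits_required(peak: float, smallest_weight: float) -> float:
    """Bits of precision needed to span ``smallest_weight`` up to ``peak``.

    If the smallest weight occupies a single bit, representing the peak
    per-timestep summed conductance alongside it needs log2(peak / smallest)
    bits.
    """
    if peak <= 0 or smallest_weight <= 0:
        raise ValueError("peak and smallest_weight must be positive")
    if peak < smallest_weight:
        raise ValueError("peak must be >= smallest_weight")
    return math.log2(peak / smallest_weight)


@dataclass(frozen=True)
class WeightCodec:
    """16-bit weight representation with a power-of-two cover-the-peak scale.

    The quantum is the smallest power of two q such that 65,535 * q covers
    ``peak_conductance``; a prescribed weight is encoded as round(w / q)
    quanta (minimum one).
    """

    format: FixedFormat
    scale_exponent: int            # quantum = 2 ** scale_exponent
    peak_conductance: float        # uS

    @property
    def quantum(self) -> float:
        return 2.0 ** self.scale_exponent

    @property
    def max_representable(self) -> float:
        return (2 ** self.format.total_bits - 1) * self.quantum

    def encode(self, weight: float) -> int:
        """Integer word for a (positive-magnitude) weight, >= 1 quantum."""
        if weight <= 0:
            raise ValueError("encode expects a positive weight magnitude")
        word = int(round(weight / self.quantum))
        word = max(word, 1)
        return min(word, 2 ** self.format.total_bits - 1)

    def decode(self, word: int) -> float:
        return word * self.quantum


def build_codec(weight: float, peak: float,
                fmt: FixedFormat = WEIGHT16) -> tuple[WeightCodec, dict]:
    """Build the 16-bit codec for one projection and report its fidelity.

    ``weight`` is the prescribed synaptic weight magnitude (uS) and ``peak``
    the largest per-timestep summed conductance the format must also cover
    (uS).  The report carries the encoded value, the signed relative error
    (encoded - prescribed) / prescribed and the number of bits the encoded
    word occupies.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if peak < weight:
        raise ValueError("peak must be >= weight")
    n_codes = 2 ** fmt.total_bits - 1
    # smallest k with n_codes * 2**k >= peak
    k = math.ceil(math.log2(peak / n_codes))
    codec = WeightCodec(format=fmt, scale_exponent=k, peak_conductance=peak)
    word = codec.encode(weight)
    encoded = codec.decode(word)
    report = {
        "prescribed": weight,
        "peak": peak,
        "quantum": codec.quantum,
        "word": word,
        "encoded": encoded,
        "relative_error": (encoded - weight) / weight,
        "bits_used": word.bit_length(),
    }
    return codec, report


class Float64Backend:
    """Double-precision reference arithmetic (the baseline role)."""

    name = "float64"
    saturation: SaturationCounter | None = None

    def q(self, x):
        return x


class FixedBackend:
    """Emulated s16.15 state arithmetic with a saturation diagnostic.

    ``q`` rounds to the nearest accum-representable value; every clipped
    element is counted on ``saturation``.
    """

    name = "fixed"

    def __init__(self, fmt: FixedFormat = S16_15) -> None:
        self.format = fmt
        self.saturation = SaturationCounter()

    def q(self, x):
        return quantize(x, self.format, self.saturation)


def get_backend(name: str):
    """Backend factory: ``float64`` (reference) or ``fixed`` (s16.15)."""
    if name == "float64":
        return Float64Backend()
    if name == "fixed":
        return FixedBackend()
    raise ValueError(f"unknown arithmetic backend {name!r}")


def normalize_weight(weight: float, params) -> float:
    """Scale a weight (uS) by tau_m / cm, making the conductance dimensionless.

    Normalizing synaptic input by the leak conductance cm / tau_m keeps the
    decayed quantities well inside the fixed-point range and removes a
    multiplication from the neuron state update.
    """
    return weight * params.tau_m / params.cm
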