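"""Domain parameter types shared across the package.

The two-state (random telegraph) gene switches between an inactive and an
active promoter state. Rates, all first order:

* ``a`` — activation (off -> on), 1/min; the burst frequency.
* ``b`` — inactivation (on -> off), 1/min; sets the burst duration 1/b.
* ``c`` — transcript initiation while active, 1/min.
* ``d`` — mRNA degradation, 1/min.

Snapshot (fixed-cell) data only identify the decay-normalized ratios
``alpha = a/d``, ``beta = b/d``, ``gamma = c/d``; live-cell traces work in
absolute minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TelegraphParams",
    "NormalizedParams",
    "DoseMap",
    "TraceSimConfig",
    "TRACE_MODES",
]


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic rates of the two-state gene, in 1/min."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"rate {name} must be >= 0, got {v!r}")

    def normalized(self) -> "NormalizedParams":
        """Decay-normalized ratios (a/d, b/d, c/d); requires d > 0."""
        if self.d <= 0:
            raise ValueError("d must be > 0 to form decay-normalized ratios")
        return NormalizedParams(self.a / self.d, self.b / self.d, self.c / self.d)


@dataclass(frozen=True)
class NormalizedParams:
    """Dimensionless telegraph parameters (alpha, beta, gamma) = (a, b, c)/d."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha!r}")
        if not (self.beta >= 0):
            raise ValueError(f"beta must be >= 0, got {self.beta!r}")
        if not (self.gamma >= 0):
            raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")

    def with_alpha(self, alpha: float) -> "NormalizedParams":
        return NormalizedParams(alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class DoseMap:
    """Frequency-modulated dose response: a(dose) = activation_scale * dose.

    Only the activation rate varies with ligand concentration; b, c, d are
    dose independent. ``activation_scale`` has units 1/(min*uM) (or
    dimensionless-per-uM when working in decay-normalized units).
    """

    doses: tuple[float, ...]
    activation_scale: float

    def __init__(self, doses, activation_scale: float):
        doses = tuple(float(x) for x in doses)
        if len(doses) == 0:
            raise ValueError("dose list must be non-empty")
        if any(x <= 0 for x in doses):
            raise ValueError("doses must be strictly positive")
        if any(y <= x for x, y in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if not (activation_scale > 0):
            raise ValueError("activation_scale must be > 0")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "activation_scale", float(activation_scale))

    def activation_rate(self, dose: float) -> float:
        return self.activation_scale * dose


TRACE_MODES = ("steady", "induction", "pulse", "always_on")


@dataclass(frozen=True)
class TraceSimConfig:
    """Acquisition/emission settings for transcription-site trace simulation.

    ``nascent_dwell`` is the deterministic residence time (min) of one nascent
    transcript's signal at the site after its initiation event — the time to
    finish elongation and release. The site intensity at a frame is the number
    of initiation events in the trailing ``nascent_dwell`` window plus
    Gaussian measurement noise of SD ``noise_sd``.
    """

    frame_interval: float = 15.0
    duration: float = 900.0
    nascent_dwell: float = 5.0
    noise_sd: float = 0.0
    mode: str = "steady"

    def __post_init__(self) -> None:
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if not (self.duration >= self.frame_interval):
            raise ValueError("duration must be >= frame_interval")
        if not (self.nascent_dwell > 0):
            raise ValueError("nascent_dwell must be > 0")
        if not (self.noise_sd >= 0):
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in TRACE_MODES:
            raise ValueError(f"mode must be one of {TRACE_MODES}, got {self.mode!r}")

    @property
    def n_frames(self) -> int:
        return int(self.duration // self.frame_interval) + 1
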