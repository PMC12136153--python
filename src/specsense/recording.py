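"""In-memory containers for intracellular recordings.

A :class:`Trace` is one stimulus presentation: a uniformly sampled
time-voltage series plus the stimulus metadata needed downstream
(wavelength, intensity, LED phase, repeat index, and whether the
presentation belongs to the spectral series or the intensity series).
A :class:`CellRecording` collects all presentations from one photoreceptor
together with the identity labels used for group-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "CellRecording"]

LED_PHASES = ("off", "before", "during", "after")
TRACE_KINDS = ("spectral", "vlogi")


@dataclass
class Trace:
    """One presentation's voltage record with stimulus metadata.

    ``voltage`` is in mV, sampled uniformly at ``sample_rate`` Hz.
    ``stimulus_onset`` is in ms from the start of the record; at least
    500 ms of pre-onset baseline is expected by the feature extractors.
    """

    voltage: np.ndarray
    sample_rate: float  # Hz
    stimulus_onset: float  # ms
    wavelength: float  # nm
    intensity: float  # photons/cm^2/s
    led: str = "off"
    repeat: int = 0
    kind: str = "spectral"

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 1:
            raise ValueError("voltage must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.led not in LED_PHASES:
            raise ValueError(f"unknown led phase {self.led!r}")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        """Time axis in ms."""
        return np.arange(self.voltage.size) * self.dt

    @property
    def duration(self) -> float:
        return self.voltage.size * self.dt


@dataclass
class CellRecording:
    """All presentations recorded from a single photoreceptor."""

    cell_id: str
    individual_id: str
    group: str
    traces: list = field(default_factory=list)

    def select(self, kind=None, led=None, wavelength=None) -> list:
        out = []
        for tr in self.traces:
            if kind is not None and tr.kind != kind:
                continue
            if led is not None and tr.led != led:
                continue
            if wavelength is not None and abs(tr.wavelength - wavelength) > 1e-9:
                continue
            out.append(tr)
        return out

    @property
    def wavelengths(self) -> np.ndarray:
        """Distinct spectral-series wavelengths, sorted."""
        wls = sorted({tr.wavelength for tr in self.traces if tr.kind == "spectral"})
        return np.asarray(wls)

    @property
    def led_phases(self) -> set:
        return {tr.led for tr in self.traces}
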