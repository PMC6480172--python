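"""Capacitive-coupling circuit model of the cloth electrode interface.

A capacitive ECG electrode senses the body potential through cloth, which
acts as a lossy capacitor in series with a contact resistance.  The
equivalent circuit is the contact resistance ``R_cont`` in series with the
parallel combination of the cloth resistance ``R_cloth`` and the cloth
capacitance ``C_cloth``.  Its impedance magnitude falls monotonically with
frequency, from ``R_cont + R_cloth`` at DC to ``R_cont`` at high frequency:

    |Z(f)| = R_cont + R_cloth / sqrt((2*pi*f*R_cloth*C_cloth)**2 + 1)

The default component values (150 MOhm cloth resistance, 70 pF cloth
capacitance) are typical of a conductive-fabric bed electrode sensing
through bedclothes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["CouplingCircuit", "coupling_magnitude", "apply_coupling_filter"]


@dataclass(frozen=True)
class CouplingCircuit:
    """Series contact resistance plus parallel RC cloth coupling.

    Parameters
    ----------
    r_cont : float
        Contact resistance between cloth and electrode, Ohm (>= 0).
    r_cloth : float
        Cloth resistance, Ohm (> 0). Default 150 MOhm.
    c_cloth : float
        Cloth capacitance, F (> 0). Default 70 pF.
    """

    r_cont: float = 0.0
    r_cloth: float = 1.5e8
    c_cloth: float = 7e-11

    def __post_init__(self) -> None:
        if self.r_cont < 0:
            raise InvalidParameterError(f"r_cont must be >= 0, got {self.r_cont}")
        if self.r_cloth <= 0 or self.c_cloth <= 0:
            raise InvalidParameterError(
                f"r_cloth and c_cloth must be > 0, got {self.r_cloth}, {self.c_cloth}"
            )


def coupling_magnitude(circuit: CouplingCircuit, freq) -> np.ndarray | float:
    """Impedance magnitude |Z(f)| of the coupling circuit, in Ohm.

    ``freq`` may be a scalar or array of non-negative frequencies in Hz.
    Strictly decreasing in frequency; the limits are ``r_cont + r_cloth``
    at f=0 and ``r_cont`` as f -> inf.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0):
        raise InvalidParameterError("freq must be >= 0")
    omega_tau = 2.0 * np.pi * f * circuit.r_cloth * circuit.c_cloth
    out = circuit.r_cont + circuit.r_cloth / np.sqrt(omega_tau**2 + 1.0)
    return float(out) if np.isscalar(freq) else out


def apply_coupling_filter(x: np.ndarray, fs: float, circuit: CouplingCircuit) -> np.ndarray:
    """Shape a signal by the normalized coupling magnitude response.

    Optional modelling stage (off by default in the generator): the signal
    spectrum is multiplied by |Z(f)| / |Z(0)| via a zero-phase FFT filter,
    emulating the passive attenuation of high-frequency content by the
    cloth interface.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    gain = coupling_magnitude(circuit, freqs) / coupling_magnitude(circuit, 0.0)
    return np.fft.irfft(np.fft.rfft(x) * gain, n=x.size)
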