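"""Contrast transfer function (CTF) evaluation.

The CTF multiplies the Fourier transform of an ideal projection and encodes
the microscope's defocus-dependent phase contrast:

    CTF(f, theta) = -sqrt(1 - A^2) * sin(chi) - A * cos(chi)
    chi(f, theta) = pi * lambda * dz(theta) * f^2
                    - (pi / 2) * Cs * lambda^3 * f^4 + phase_shift

with ``A`` the amplitude-contrast fraction, ``dz(theta)`` the astigmatic
defocus at azimuth ``theta`` (underfocus positive) and ``lambda`` the
relativistic electron wavelength. The sign convention makes the CTF negative
at low frequency for underfocus (white-on-black particle contrast), the
convention shared by RELION and CryoSPARC; the cross term in the sieving
score depends on it, so it is pinned by tests.

No envelope is folded into the CTF: amplitude decay (radiation damage,
detector falloff) is modeled separately as B-factor envelopes in the
synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CTFParams", "electron_wavelength", "ctf_value", "ctf_image"]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom.

    lambda = 12.2639 / sqrt(V + 0.97845e-6 * V^2), V in volts.
    300 kV -> 0.01969 A, 200 kV -> 0.02508 A.
    """
    if not voltage_kv > 0:
        raise ValueError("voltage must be positive")
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass
class CTFParams:
    """Per-particle optics parameters defining the CTF.

    defocus_u/defocus_v are in Angstrom (underfocus positive); astig_angle
    and phase_shift in degrees. ``defocus_u >= defocus_v`` is canonicalized
    on construction by swapping and rotating the astigmatism axis 90 deg.
    """

    voltage: float = 300.0  # kV
    cs: float = 2.7  # mm
    amplitude_contrast: float = 0.1
    defocus_u: float = 10000.0  # A
    defocus_v: float = 10000.0  # A
    astig_angle: float = 0.0  # deg
    phase_shift: float = 0.0  # deg

    def __post_init__(self) -> None:
        if not self.voltage > 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast < 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1)")
        if self.defocus_v > self.defocus_u:
            self.defocus_u, self.defocus_v = self.defocus_v, self.defocus_u
            self.astig_angle += 90.0

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)


def _chi(params: CTFParams, f2: np.ndarray, theta: np.ndarray) -> np.ndarray:
    lam = params.wavelength
    cs_A = params.cs * 1e7  # mm -> A
    dz_mean = 0.5 * (params.defocus_u + params.defocus_v)
    dz_diff = 0.5 * (params.defocus_u - params.defocus_v)
    ang = np.deg2rad(params.astig_angle)
    dz = dz_mean + dz_diff * np.cos(2.0 * (theta - ang))
    return (
        np.pi * lam * dz * f2
        - 0.5 * np.pi * cs_A * lam**3 * f2 * f2
        + np.deg2rad(params.phase_shift)
    )


def ctf_value(params: CTFParams, fx, fy):
    """CTF at spatial frequency (fx, fy) in 1/Angstrom; scalar or array."""
    fx = np.asarray(fx, dtype=np.float64)
    fy = np.asarray(fy, dtype=np.float64)
    f2 = fx * fx + fy * fy
    theta = np.arctan2(fy, fx)
    a = params.amplitude_contrast
    chi = _chi(params, f2, theta)
    out = -np.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)
    return out if out.ndim else float(out)


def ctf_image(params: CTFParams, L: int, pixel_size: float) -> np.ndarray:
    """CTF on the L x L discrete FFT grid, DC at element (0, 0) (unshifted).

    Real and Friedel-symmetric by construction (chi depends on f^2 and on
    theta only through cos(2 theta)).
    """
    if L % 2 != 0:
        raise ValueError("L must be even")
    f = np.fft.fftfreq(L, d=pixel_size)  # 1/A
    fy = f[:, None]
    fx = f[None, :]
    return ctf_value(params, fx + 0.0 * fy, fy + 0.0 * fx)
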