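"""Physical constants and unit helpers.

Wavenumbers are cm^-1 throughout; times are fs for pulse delays and
trajectory timesteps, ps for waiting times and lifetimes; distances are
Angstrom.
"""

# speed of light in cm/fs (2.99792458e10 cm/s * 1e-15 s/fs)
C_CM_PER_FS = 2.99792458e-5

PS_PER_FS = 1e-3


def nyquist_wavenumber(dt_fs: float) -> float:
    """Maximum wavenumber offset (cm^-1) representable at sampling step ``dt_fs``."""
    return 1.0 / (2.0 * dt_fs * C_CM_PER_FS)


def fft_bin_wavenumber(n_points: int, dt_fs: float) -> float:
    """DFT bin width in cm^-1 for ``n_points`` samples spaced ``dt_fs`` apart."""
    return 1.0 / (n_points * dt_fs * C_CM_PER_FS)
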