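"""Physical constants and unit conversions.

Internal unit system: length μm, time ms, concentration mM, conductance nS,
voltage mV, current pA, volume μm³. All conversion factors between these and
SI live here so the rest of the package never carries stray powers of ten.
"""

import numpy as np

#: Faraday constant, C/mol.
FARADAY = 96485.33212

#: Molar gas constant, J/(mol·K).
GAS_CONSTANT = 8.314462618

#: 35 °C in kelvin, the physiological temperature used throughout.
BODY_TEMPERATURE_K = 308.15


def nernst(z: int, c_in: float, c_out: float, temperature: float = BODY_TEMPERATURE_K) -> float:
    """Nernst equilibrium potential in mV.

    Parameters
    ----------
    z : ionic valence (e.g. -1 for Cl⁻ and HCO3⁻).
    c_in, c_out : intra-/extracellular concentrations, mM (any common unit;
        only the ratio enters).
    temperature : absolute temperature, K.
    """
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    if np.any(c_in <= 0) or np.any(c_out <= 0):
        raise ValueError("Nernst potential requires strictly positive concentrations")
    if z == 0:
        raise ValueError("valence must be nonzero")
    # RT/zF in volts -> mV
    out = 1e3 * GAS_CONSTANT * temperature / (z * FARADAY) * np.log(c_out / c_in)
    return float(out) if out.ndim == 0 else out


def delta_conc_from_current(i_pA, volume_um3, dt_ms):
    """Concentration change (mM) produced by a transmembrane ionic current.

    Δ[X] = I·dt/(F·V) with I in pA, dt in ms, V in μm³. The pA·ms charge is
    1e-15 C and the μm³ volume is 1e-15 L, so the only surviving factor is
    the mol→mmol conversion (1e3). A 20 pA current into 1 μm³ for 1 ms
    raises the concentration by ≈0.207 mM.
    """
    volume_um3 = np.asarray(volume_um3, dtype=float)
    if np.any(volume_um3 <= 0):
        raise ValueError("compartment volume must be positive")
    return np.asarray(i_pA, dtype=float) * np.asarray(dt_ms, dtype=float) * 1e3 / (
        FARADAY * volume_um3
    )


#: Particles per (mM·μm³) at true molarity (Avogadro scale). Stochastic runs
#: normally use a much smaller, configurable factor.
AVOGADRO_PARTICLES_PER_MM_UM3 = 6.02214076e23 * 1e-3 * 1e-15
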