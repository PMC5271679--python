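"""Photon dose unit conversions.

All cross sections in this package are carried in Å² quanta⁻¹ and photon
doses in quanta Å⁻², so products of the two are directly photons PSII⁻¹.
Light intensities are µmol photons m⁻² s⁻¹, the unit instruments report.
"""

#: photons per µmol of photons (Avogadro constant / 1e6, at the precision
#: conventional in aquatic photophysiology)
PHOTONS_PER_UMOL = 6.022e17

#: Å² per m² (exact)
A2_PER_M2 = 1.0e20

#: quanta Å⁻² s⁻¹ delivered by 1 µmol photons m⁻² s⁻¹
QUANTA_A2_PER_UMOL = PHOTONS_PER_UMOL / A2_PER_M2  # = 6.022e-3


def umol_to_photons_m2(intensity_umol: float, duration_s: float) -> float:
    """Photon dose (photons m⁻²) from intensity (µmol m⁻² s⁻¹) and time (s)."""
    return intensity_umol * duration_s * PHOTONS_PER_UMOL


def photons_m2_to_quanta_A2(dose_m2: float) -> float:
    return dose_m2 / A2_PER_M2


def quanta_A2_to_photons_m2(dose_A2: float) -> float:
    return dose_A2 * A2_PER_M2
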