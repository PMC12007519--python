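"""Embedded constants tables: sampling ranges, concentration / relaxation /
macromolecule / residual-water parameterizations.

All tables here are editable configuration with representative literature
values; the engine treats them as inputs, not ground truth.  Concentrations
are institutional units on the scale of mM; T2 values are the Lorentzian
component referenced to 1.5 T.
"""

from __future__ import annotations

import json
from importlib import resources

#: Proton gyromagnetic ratio over 2*pi, MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.5774

#: Default acquisition-grid enumeration: 18 field strengths x 15 echo times.
DEFAULT_B0_TESLA = tuple(round(1.4 + 0.1 * k, 1) for k in range(18))
DEFAULT_TE_SECONDS = tuple(round(0.010 + 0.005 * k, 3) for k in range(15))

#: Examples generated per (B0, TE) cell in the full dataset configuration.
DEFAULT_EXAMPLES_PER_CELL = 960

#: NAA singlet target linewidth range, Hz (uniform).
NAA_FWHM_RANGE_HZ = (3.0, 18.0)
#: Per-metabolite Gaussian decay-rate jitter, s^-2 (uniform).
GAUSSIAN_JITTER_RANGE = (20.0, 100.0)
#: NAA-singlet SNR range (uniform).
SNR_RANGE = (5.0, 80.0)
#: Residual-water scaling relative to the metabolite spectrum maximum.
WATER_SCALE_RANGE = (1.0, 20.0)
#: Frequency shift (ppm), zero-order phase (deg), first-order phase (deg/ppm).
FREQ_SHIFT_RANGE_PPM = (-0.313, 0.313)
PHASE0_RANGE_DEG = (-180.0, 180.0)
PHASE1_RANGE_DEG_PER_PPM = (-19.5, 19.5)

#: OOV echo parameter sampling ranges.
OOV_TAU_RANGE_S = (0.010, 0.400)
OOV_W_RANGE = (500.0, 8000.0)
OOV_PPM_RANGE = (1.0, 4.0)
OOV_AMP_RANGE = (0.001, 0.20)
OOV_PHI_RANGE_DEG = (0.0, 360.0)
#: Fraction of examples receiving an OOV echo.
OOV_INJECTION_PROBABILITY = 0.85
#: Ground-truth mask level: fraction of the Gaussian envelope maximum.
OOV_MASK_LEVEL = 0.05
#: Minimum run length kept by the cluster-threshold post-processing step.
OOV_CLUSTER_MIN_RUN = 5


def load_spin_systems() -> dict:
    """Load the packaged spin-system table (shifts in ppm, J in Hz)."""
    text = resources.files("mrsynth.data").joinpath("spin_systems.json").read_text()
    raw = json.loads(text)
    raw.pop("_comment", None)
    return raw


#: Metabolites combined into the metabolite component, with mean/SD
#: concentrations per cohort.  Keys with a list value name basis variants
#: chosen with equal probability per example (GABA spin-system enumerations,
#: glucose anomers).
BASIS_VARIANTS = {
    "GABA": ("GABA_1", "GABA_2"),
    "Glc": ("Glc_A", "Glc_B"),
}

CONCENTRATION_TABLE = {
    "healthy": {
        "Ala": (0.60, 0.22),
        "Asc": (1.20, 0.40),
        "Asp": (1.80, 0.60),
        "Cr": (4.80, 0.90),
        "GABA": (1.42, 0.40),
        "Glc": (1.50, 0.60),
        "Gln": (3.00, 0.80),
        "Glu": (8.60, 1.40),
        "GPC": (1.00, 0.30),
        "GSH": (2.00, 0.50),
        "Gly": (0.80, 0.30),
        "Lac": (0.95, 0.35),
        "mI": (6.00, 1.20),
        "NAA": (11.2, 1.50),
        "NAAG": (1.50, 0.50),
        "PCho": (0.60, 0.20),
        "PCr": (3.90, 0.90),
        "PE": (1.80, 0.50),
        "Ser": (1.00, 0.40),
        "sI": (0.40, 0.15),
        "Tau": (1.50, 0.50),
        "Thr": (0.60, 0.25),
    },
    "clinical": {
        "Ala": (0.70, 0.35),
        "Asc": (1.20, 0.55),
        "Asp": (1.80, 0.80),
        "Cr": (4.60, 1.20),
        "GABA": (1.30, 0.55),
        "Glc": (1.70, 0.80),
        "Gln": (3.40, 1.20),
        "Glu": (8.00, 2.00),
        "GPC": (1.20, 0.45),
        "GSH": (1.90, 0.70),
        "Gly": (0.90, 0.40),
        "Lac": (1.40, 0.70),
        "mI": (6.40, 1.80),
        "NAA": (10.2, 2.20),
        "NAAG": (1.50, 0.70),
        "PCho": (0.70, 0.30),
        "PCr": (3.80, 1.20),
        "PE": (1.80, 0.70),
        "Ser": (1.10, 0.55),
        "sI": (0.45, 0.22),
        "Tau": (1.60, 0.70),
        "Thr": (0.65, 0.35),
    },
}

#: Lorentzian T2 (seconds, at 1.5 T) low/high per metabolite.
T2_TABLE = {
    "Ala": (0.25, 0.45),
    "Asc": (0.20, 0.40),
    "Asp": (0.20, 0.40),
    "Cr": (0.28, 0.42),
    "GABA": (0.22, 0.40),
    "Glc": (0.20, 0.40),
    "Gln": (0.22, 0.40),
    "Glu": (0.22, 0.40),
    "GPC": (0.30, 0.45),
    "GSH": (0.20, 0.38),
    "Gly": (0.25, 0.45),
    "Lac": (0.30, 0.55),
    "mI": (0.22, 0.38),
    "NAA": (0.35, 0.50),
    "NAAG": (0.28, 0.45),
    "PCho": (0.30, 0.45),
    "PCr": (0.28, 0.42),
    "PE": (0.22, 0.40),
    "Ser": (0.22, 0.40),
    "sI": (0.25, 0.42),
    "Tau": (0.22, 0.40),
    "Thr": (0.25, 0.45),
}

#: Macromolecule singlet template: 14 entries of
#: (ppm, amplitude low/high, T2 low/high seconds, target FWHM low/high Hz).
#: Chemical shifts are jittered by +-MM_JITTER_PPM at sampling time.
MM_TEMPLATE = [
    {"ppm": 0.92, "amp": (0.45, 1.80), "t2": (0.025, 0.050), "fwhm": (16.0, 38.0)},
    {"ppm": 1.21, "amp": (0.40, 1.60), "t2": (0.025, 0.050), "fwhm": (16.0, 38.0)},
    {"ppm": 1.39, "amp": (0.30, 1.20), "t2": (0.025, 0.050), "fwhm": (16.0, 38.0)},
    {"ppm": 1.67, "amp": (0.20, 0.80), "t2": (0.025, 0.050), "fwhm": (16.0, 38.0)},
    {"ppm": 2.04, "amp": (0.50, 2.00), "t2": (0.025, 0.050), "fwhm": (16.0, 40.0)},
    {"ppm": 2.26, "amp": (0.22, 0.90), "t2": (0.025, 0.050), "fwhm": (16.0, 40.0)},
    {"ppm": 2.56, "amp": (0.15, 0.60), "t2": (0.025, 0.050), "fwhm": (16.0, 40.0)},
    {"ppm": 2.70, "amp": (0.15, 0.60), "t2": (0.025, 0.050), "fwhm": (16.0, 40.0)},
    {"ppm": 2.99, "amp": (0.25, 1.00), "t2": (0.025, 0.050), "fwhm": (16.0, 40.0)},
    {"ppm": 3.21, "amp": (0.30, 1.20), "t2": (0.025, 0.050), "fwhm": (16.0, 40.0)},
    {"ppm": 3.62, "amp": (0.35, 1.40), "t2": (0.025, 0.050), "fwhm": (16.0, 42.0)},
    {"ppm": 3.75, "amp": (0.25, 1.00), "t2": (0.025, 0.050), "fwhm": (16.0, 42.0)},
    {"ppm": 3.86, "amp": (0.30, 1.20), "t2": (0.025, 0.050), "fwhm": (16.0, 42.0)},
    {"ppm": 4.03, "amp": (0.18, 0.70), "t2": (0.025, 0.050), "fwhm": (16.0, 42.0)},
]
MM_JITTER_PPM = 0.03

#: Residual-water composite template: up to five Voigt components, each row
#: (ppm low/high, phase low/high deg, relative amplitude low/high).
WATER_TEMPLATE = [
    {"ppm": (4.679, 4.711), "phase": (-10.0, 10.0), "amp": (1.00, 1.00)},
    {"ppm": (4.599, 4.641), "phase": (15.0, 45.0), "amp": (0.35, 0.55)},
    {"ppm": (4.759, 4.801), "phase": (-60.0, -30.0), "amp": (0.35, 0.55)},
    {"ppm": (4.449, 4.541), "phase": (-70.0, 45.0), "amp": (0.10, 0.25)},
    {"ppm": (4.859, 4.901), "phase": (105.0, 135.0), "amp": (0.10, 0.25)},
]
#: Water Voigt decay-rate sampling: Lorentzian T2 (s) and Gaussian rate
#: (s^-2) ranges, chosen to produce water linewidths of roughly 10-60 Hz.
WATER_T2_RANGE_S = (0.020, 0.100)
WATER_GAUSS_RANGE = (100.0, 2000.0)
#: Number of water components is uniform over {0, ..., 5}.
WATER_MAX_COMPONENTS = 5
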