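"""Bundled worked-example records for falling-head permeametry and CFD
permeability of decellularized human nerve fascicles.

These are the published measurement records that the experimental-permeability
equations are exercised against: falling-head permeameter geometries, head
drops, elapsed times and the hydraulic conductivities / permeabilities as
originally reported, plus the three image-based (CFD) permeability values
with their reported mean and SD.  They serve as worked examples and as
consistency checks of the implementation — every derivable number can be
recomputed from the recorded inputs.

Known quirks of the source records, kept as printed and handled downstream:

* The single-trial table (``FALLING_HEAD_SINGLE``) prints a sample height of
  H = 1.00e-1 m, but its printed conductivities are only consistent with
  H = 1.00e-2 m (a factor-10 slip).  The printed H is stored unchanged;
  :func:`eecm.pipeline.audit_falling_head_height` demonstrates the
  inconsistency numerically rather than silently correcting it.
* In the triplicate table (``FALLING_HEAD_TRIPLICATE``), sample 3 trial #3
  prints k = 7.33e-12 m^2, but its printed K = 7.18e-6 m/s converts to
  7.33e-13 m^2; the stored reference value is 7.33e-13 (exponent typo).
* Sample 3 trial #2 prints K = 8.23e-6 m/s, but its own recorded time
  (t = 4460 s) gives K = 8.82e-6 m/s — which is also the value consistent
  with its printed k = 9.09e-13 m^2.  The printed K looks like a digit
  transposition; it is stored as printed and the record carries
  ``"discrepant": True`` so consistency checks can exclude it.
"""

from __future__ import annotations

# single-trial falling-head records: geometry (m, m^2), heads (m), time (s),
# with the reported hydraulic conductivity K (m/s) and permeability k (m^2)
FALLING_HEAD_SINGLE = [
    {
        "sample": 1,
        "H_printed": 1.00e-1,
        "a": 2.16e-4,
        "A": 2.74e-6,
        "L1": 1.46,
        "L2": 1.44,
        "t": 350.0,
        "K_reported": 3.11e-5,
        "k_reported": 3.17e-12,
    },
    {
        "sample": 2,
        "H_printed": 1.00e-1,
        "a": 2.16e-4,
        "A": 2.52e-6,
        "L1": 1.46,
        "L2": 1.44,
        "t": 1196.0,
        "K_reported": 9.89e-6,
        "k_reported": 1.01e-12,
    },
    {
        "sample": 3,
        "H_printed": 1.00e-1,
        "a": 2.16e-4,
        "A": 2.37e-6,
        "L1": 1.46,
        "L2": 1.44,
        "t": 532.0,
        "K_reported": 2.36e-5,
        "k_reported": 2.41e-12,
    },
]

#: the sample height consistent with the printed K values of
#: FALLING_HEAD_SINGLE (see the height audit)
FALLING_HEAD_SINGLE_H_CONSISTENT = 1.00e-2

# triplicate falling-head records (three samples, three trials each)
FALLING_HEAD_TRIPLICATE = [
    {
        "sample": 1,
        "H": 1.00e-2,
        "a": 3.58e-3,
        "A": 1.42e-5,
        "L1": 0.45,
        "L2": 0.425,
        "trials": [
            {"t": 950.0, "K_reported": 1.51e-4, "k_reported": 1.55e-11},
            {"t": 890.0, "K_reported": 1.61e-4, "k_reported": 1.65e-11},
            {"t": 520.0, "K_reported": 2.77e-4, "k_reported": 2.83e-11},
        ],
    },
    {
        "sample": 2,
        "H": 8.00e-3,
        "a": 3.58e-3,
        "A": 1.24e-5,
        "L1": 0.45,
        "L2": 0.425,
        "trials": [
            {"t": 1440.0, "K_reported": 9.17e-5, "k_reported": 9.35e-12},
            {"t": 1540.0, "K_reported": 8.57e-5, "k_reported": 8.75e-12},
            {"t": 2130.0, "K_reported": 6.20e-5, "k_reported": 6.32e-12},
        ],
    },
    {
        "sample": 3,
        "H": 1.00e-2,
        "a": 3.58e-3,
        "A": 5.20e-5,
        "L1": 0.45,
        "L2": 0.425,
        "trials": [
            {"t": 5400.0, "K_reported": 7.29e-6, "k_reported": 7.44e-13},
            # printed K is not consistent with its own t or k; see docstring
            {"t": 4460.0, "K_reported": 8.23e-6, "k_reported": 9.09e-13,
             "discrepant": True},
            # printed as 7.33e-12; exponent typo, see module docstring
            {"t": 5480.0, "K_reported": 7.18e-6, "k_reported": 7.33e-13},
        ],
    },
]

# image-based (CFD) permeabilities of the three reconstructed RVEs, m^2,
# with the reported average and population SD
CFD_PERMEABILITIES = [3.29e-12, 2.84e-12, 3.18e-12]
CFD_PERMEABILITY_MEAN_REPORTED = 3.10e-12
CFD_PERMEABILITY_SD_REPORTED = 1.91e-13

# reference microstructural parameters of endoneurium ECM (mean, SD)
MICROSTRUCTURE_REFERENCE = {
    "pore_size_um": (11.8, 2.8),
    "solid_thickness_um": (11.4, 3.1),
    "porosity": (0.355, 0.017),
    "tortuosity_solid_x": (1.26, 0.028),
    "tortuosity_solid_y": (1.26, 0.020),
    "tortuosity_solid_z": (1.17, 0.03),
    "tortuosity_pore_x": (1.50, 0.09),
    "tortuosity_pore_y": (1.44, 0.06),
    "tortuosity_pore_z": (1.13, 0.04),
    "savr_um^-1": (0.165, 0.007),
}

#: linear-region Young's modulus of fascicles from tensile tests, MPa
TENSILE_LINEAR_MODULUS = 38.5
#: toe-region extent of the J-shaped tensile curve, engineering strain
TENSILE_TOE_STRAIN = 0.13
#: reference histological solid-area rate used for threshold calibration
HISTOLOGY_AREA_RATE = 0.5186
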