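"""Published deconvolution statistics for adult and pediatric cohorts.

Each table row holds the class-conditional average amplitude (AMP, sensor
units), mean (retention units), SD (retention units) and FWHM (retention
units) of one Gaussian "order" of the composite VOC profile.  The printed
FWHM is stored verbatim alongside the SD so that consistency with the
Gaussian relation FWHM = 2*sqrt(2*ln 2)*SD can be audited rather than
assumed.
"""

from __future__ import annotations

# (amplitude, mean, sd, printed_fwhm) per order 0..2, per class.
ADULT_TABLE: dict[str, list[tuple[float, float, float, float]]] = {
    "asthmatic": [
        (0.00258, 0.026, 1.022, 2.41),
        (327.86, 17.04, 4.51, 10.61),
        (343.15, 27.61, 8.97, 21.12),
    ],
    "control": [
        (0.00084, 0.0085, 1.0075, 2.37),
        (0.0027, 0.088, 1.34, 3.15),
        (173.91, 24.18, 7.82, 18.42),
    ],
}

PEDIATRIC_TABLE: dict[str, list[tuple[float, float, float, float]]] = {
    "asthmatic": [
        (643.18, 15.52, 3.51, 8.26),
        (6.02e-10, 5.08e-9, 4.96, 11.68),
        (612.02, 27.85, 42.11, 21.81),
    ],
    "control": [
        (0.000774, 0.13, 1.31, 3.17),
        (150.33, 21.56, 0.99, 2.35),
        (497.99, 16.56, 9.26, 19.18),
    ],
}

TABLES_BY_AGE_GROUP = {"adult": ADULT_TABLE, "pediatric": PEDIATRIC_TABLE}
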