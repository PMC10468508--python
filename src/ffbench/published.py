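"""Published benchmark values for the thirteen force fields.

These are the printed score tables of the R2-FUS-LC force-field
benchmarking study that this package's scoring layer reproduces: the raw
and normalised intra-peptide contact-map MCC scores, four published
confusion matrices, the normalised Rg and SSP component columns with their
combined scores, and the final three-measure ranking.  They serve as a
regression oracle for the arithmetic linking the tables (see
:func:`ffbench.pipeline.verify_printed_tables`); nothing in the analysis
pipeline reads them.

All confusion-matrix entries are percentages of (snapshot × peptide ×
pair) instances; all other values are dimensionless scores.
"""

from __future__ import annotations

#: Final ranking table: normalized Rg / SSP / contact-map components,
#: published final score (bare product) and rank.
FINAL_TABLE = {
    # label: (rg_norm, ssp_norm, cmap_norm, final, rank)
    "c36m2021s3p": (1.0, 0.65613, 0.77657, 5.10e-01, 1),
    "a99sb4pew": (0.39845, 1.0, 0.64988, 2.59e-01, 2),
    "c36ms3p": (0.86920, 0.31996, 0.85621, 2.38e-01, 3),
    "a19sbopc": (0.30691, 0.61874, 0.71610, 1.36e-01, 4),
    "a99disp": (0.21986, 0.51499, 0.54300, 6.15e-02, 5),
    "a99sbildn4pd": (0.19783, 0.45716, 0.47616, 4.31e-02, 6),
    "a99sbCufix3p": (0.07391, 0.73450, 0.34292, 1.86e-02, 7),
    "c22s3p": (0.05156, 0.40010, 0.53323, 1.10e-02, 8),
    "a03ws": (0.02029, 0.10312, 0.10120, 2.12e-04, 9),
    "a14sb3p": (0.00001, 0.76161, 0.40067, 3.05e-06, 10),
    "c36m3pm": (0.00029, 0.00320, 0.99460, 9.23e-07, 11),
    "c36m2021s3pm": (0.04438, 0.00001, 1.0, 4.44e-07, 12),
    "c27s3p": (0.03130, 0.00001, 0.00001, 3.13e-12, 13),
}

#: Rg component table: normalized U-shaped, L-shaped and Unfolded scores
#: and the published combined (renormalized product) Rg score.
RG_TABLE = {
    # label: (u_norm, l_norm, unfolded_norm, final_rg)
    "c36m2021s3p": (0.05654, 0.26227, 0.04817, 1.00000),
    "c36ms3p": (0.02194, 1.00000, 0.02830, 0.86920),
    "a99sb4pew": (1.00000, 0.43082, 0.00066, 0.39845),
    "a19sbopc": (0.11252, 0.17544, 0.01111, 0.30691),
    "a99disp": (0.09730, 0.16614, 0.00972, 0.21986),
    "a99sbildn4pd": (0.06440, 0.20090, 0.01092, 0.19783),
    "a99sbCufix3p": (0.14855, 0.21916, 0.00162, 0.07391),
    "c22s3p": (0.04650, 0.11735, 0.00675, 0.05156),
    "c36m2021s3pm": (0.00035, 0.08977, 1.00000, 0.04438),
    "c27s3p": (0.07513, 0.13992, 0.00213, 0.03130),
    "a03ws": (0.03703, 0.10192, 0.00384, 0.02029),
    "c36m3pm": (0.00001, 0.08983, 0.22404, 0.00029),
    "a14sb3p": (0.91433, 0.00001, 0.00001, 0.00001),
}

#: Contact-map table: raw MCC against the U-shaped reference and the
#: published normalized contact-map score.
MCC_TABLE = {
    # label: (raw_mcc, normalized)
    "c36m2021s3pm": (0.70418, 1.00000),
    "c36m3pm": (0.70323, 0.99460),
    "c36ms3p": (0.67892, 0.85621),
    "c36m2021s3p": (0.66494, 0.77657),
    "a19sbopc": (0.65431, 0.71610),
    "a99sb4pew": (0.64268, 0.64988),
    "a99disp": (0.62391, 0.54300),
    "c22s3p": (0.62219, 0.53323),
    "a99sbildn4pd": (0.61217, 0.47616),
    "a14sb3p": (0.59891, 0.40067),
    "a99sbCufix3p": (0.58877, 0.34292),
    "a03ws": (0.54631, 0.10120),
    "c27s3p": (0.52854, 0.00001),
}

#: Published confusion matrices (percent of instances) for four force
#: fields, as (TP, FP, FN, TN).
CONFUSION_TABLE = {
    "c36m2021s3p": (13.86, 5.13, 5.18, 75.82),
    "a99sbCufix3p": (14.17, 8.99, 4.88, 71.96),
    "c36m2021s3pm": (13.75, 3.52, 5.30, 77.43),
    "c36m3pm": (13.75, 3.57, 5.29, 77.38),
}

#: SSP table: normalized U-shaped and L-shaped log-likelihood scores and
#: the published combined (renormalized product) SSP score.
SSP_TABLE = {
    # label: (u_norm, l_norm, final_ssp)
    "a99sb4pew": (1.0, 1.0, 1.0),
    "a14sb3p": (0.852963, 0.892893, 0.761607),
    "a99sbCufix3p": (0.823343, 0.892089, 0.734498),
    "c36m2021s3p": (0.787453, 0.833228, 0.656131),
    "a19sbopc": (0.725248, 0.853141, 0.618743),
    "a99disp": (0.708013, 0.727370, 0.514992),
    "a99sbildn4pd": (0.677607, 0.674657, 0.457158),
    "c22s3p": (0.630039, 0.635035, 0.400103),
    "c36ms3p": (0.564177, 0.567119, 0.319962),
    "a03ws": (0.330989, 0.311533, 0.103123),
    "c36m3pm": (0.044558, 0.071552, 0.003198),
    "c36m2021s3pm": (0.00001, 0.057822, 0.00001),
    "c27s3p": (0.011461, 0.00001, 0.00001),
}

#: Reference radii of gyration (Å): U-shaped fibril (mean over 20 NMR
#: models), L-shaped fibril, and the Flory coil prediction for N=16.
REFERENCE_RG = {"U": 10.0, "L": 14.4, "FL": 10.8}

#: Intra-peptide contact counts of the reference conformations at 5 Å.
REFERENCE_CONTACT_COUNTS = {"U": 20, "L": 15}
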