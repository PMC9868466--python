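"""Published plasma validation panel for the progesterone immunoassay.

Per-level within-run CV%, spiking-recovery bias %, range-based bias %,
average-based bias %, and the published observed-total-error columns, as
printed in the assay's validation report.  Used as input data for
arithmetic-reproduction tests.
"""

# level_id: (spiked, within_cv_pct, srb_pct, rb_pct, ab_pct, teo_sr, teo_rb, teo_ab)
PLASMA_PANEL = {
    "L1": (0.4, 12.0, -40.9, 19.1, 9.9, 64.9, 43.1, 33.9),
    "L2": (0.7, 7.7, -22.5, 19.1, 9.9, 37.8, 34.5, 15.4),
    "L3": (1.0, 9.8, -7.2, 19.1, 9.9, 26.8, 38.7, 19.6),
    "L4": (2.0, 4.5, -9.0, 7.3, 9.9, 18.0, 16.3, 9.0),
    "L5": (5.0, 5.2, -7.6, 5.0, 9.9, 18.0, 15.4, 10.4),
    "L6": (7.0, 3.7, -10.3, 9.2, 9.9, 17.6, 16.6, 7.4),
    "L7": (10.0, 3.2, -14.8, 8.3, 9.9, 21.1, 14.7, 6.4),
    "L8": (15.0, 7.4, -15.8, 8.3, 9.9, 30.7, 23.1, 14.8),
    "L9": (20.0, 4.3, -13.2, 8.3, 9.9, 21.8, 16.9, 8.6),
    "L10": (30.0, 4.7, -16.9, 8.3, 9.9, 26.3, 17.7, 9.4),
}

# QC materials: level -> (nominal ng/mL, between-run CV%, bias %, published TEo %)
QC_SUMMARY = {
    "QC1": (0.64, 6.3, 7.7, 20.4),
    "QC2": (7.5, 1.1, 2.6, 4.7),
    "QC3": (20.9, 3.0, 6.6, 12.6),
}

# Bland-Altman percentage-difference agreement between the two laboratories
BA_PERCENT = {"mean_bias": 9.9, "loa_lower": -12.6, "loa_upper": 32.3}
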