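"""Reference eicosanoid panel: the 67 targeted analytes with their pathway
assignments and published plasma summary statistics (mean +- SD, ng/ml) for
healthy controls and asthmatics; ``None`` marks analytes not detected in
plasma. 41 of the 67 analytes are detected. Used by
:func:`eicostats.simulate.reference_config` to anchor the simulator's
concentration scale; the LOD values shipped with the reference panel are
synthetic (the assay's true per-analyte LODs are not published).
"""

# (metabolite, pathway, ctrl_mean, ctrl_sd, asthma_mean, asthma_sd)
REFERENCE_PANEL = [
    ("12-HETE", "12-LOX", 0.503, 0.524, 0.458, 0.653),
    ("Tetranor-12-HETE", "12-LOX", 0.029, 0.014, 0.033, 0.021),
    ("12-oxoETE", "12-LOX", None, None, None, None),
    ("14-HDoHE", "12-LOX", 0.151, 0.207, 0.146, 0.282),
    ("Maresin 1", "12-LOX", None, None, None, None),
    ("12-HEPE", "12-LOX", 0.108, 0.154, 0.092, 0.181),
    ("15-HETE", "15-LOX", 0.277, 0.162, 0.298, 0.252),
    ("15-oxoETE", "15-LOX", 0.005, 0.012, 0.026, 0.059),
    ("8-HETE", "15-LOX", 0.045, 0.031, 0.054, 0.035),
    ("14,15-LTC4", "15-LOX", None, None, None, None),
    ("8,15-diHETE", "15-LOX", None, None, None, None),
    ("LXA4", "15-LOX", None, None, None, None),
    ("17-HDoHE", "15-LOX", 0.214, 0.164, 0.217, 0.325),
    ("10,17-DiHoHE", "15-LOX", None, None, None, None),
    ("7,17-dihydroxy-DPA", "15-LOX", None, None, None, None),
    ("15-HEPE", "15-LOX", 0.032, 0.030, 0.045, 0.053),
    ("13-HODE", "15-LOX", 4.394, 4.625, 4.331, 3.978),
    ("5-HETE", "5-LOX", 0.141, 0.058, 0.143, 0.080),
    ("5-oxoETE", "5-LOX", 0.011, 0.010, 0.013, 0.011),
    ("LTE4", "5-LOX", 0.001, 0.001, 0.002, 0.003),
    ("20-carboxy-LTB4", "5-LOX", None, None, None, None),
    ("20-hydroxy-LTB4", "5-LOX", None, None, None, None),
    ("LTB4", "5-LOX", None, None, None, None),
    ("LTC4", "5-LOX", None, None, None, None),
    ("LTD4", "5-LOX", None, None, None, None),
    ("5,15-diHETE", "5-LOX/15-LOX", None, None, None, None),
    ("4-HDoHE", "5-LOX", 0.102, 0.104, 0.073, 0.073),
    ("7-HDoHE", "5-LOX", 0.015, 0.018, 0.021, 0.025),
    ("RvD2", "5-LOX/15-LOX", None, None, None, None),
    ("5-HEPE", "5-LOX", 0.032, 0.023, 0.037, 0.028),
    ("RvE1", "5-LOX", None, None, None, None),
    ("11-HETE", "COX", 0.042, 0.039, 0.030, 0.024),
    ("12-HHT", "COX", 0.259, 0.348, 0.247, 0.423),
    ("6-keto-PGF1a", "COX", 0.014, 0.013, 0.019, 0.011),
    ("PGA2", "COX", 0.005, 0.005, 0.006, 0.006),
    ("PGE2", "COX", 0.082, 0.402, 0.091, 0.512),
    ("PGF2a", "COX", 0.032, 0.013, 0.036, 0.013),
    ("Tetranor-PGEM", "COX", 0.075, 0.102, 0.048, 0.094),
    ("TXB2", "COX", 0.096, 0.177, 0.122, 0.238),
    ("11-dhTXB2", "COX", None, None, None, None),
    ("15-deoxy-PGJ2", "COX", None, None, None, None),
    ("6,15-diketo-13,14-dihydro-PGF1a", "COX", None, None, None, None),
    ("PGD2", "COX", None, None, None, None),
    ("PGF1a", "COX", 0.013, 0.011, 0.017, 0.010),
    ("17-keto-DPA", "COX", 0.021, 0.043, 0.014, 0.035),
    ("PGF3a", "COX", 0.008, 0.010, 0.009, 0.010),
    ("11-HEPE", "COX", None, None, None, None),
    ("PGD3", "COX", None, None, None, None),
    ("PGE3", "COX", None, None, None, None),
    ("TXB3", "COX", None, None, None, None),
    ("9-HODE", "COX", 2.179, 1.822, 2.273, 1.991),
    ("9-HpODE", "COX", None, None, None, None),
    ("11,12-DHET", "CYP", 0.283, 0.121, 0.252, 0.119),
    ("11,12-EET", "CYP", 0.003, 0.004, 0.003, 0.003),
    ("14,15-DHET", "CYP", 0.351, 0.285, 0.354, 0.307),
    ("18-HETE", "CYP", 0.148, 0.116, 0.177, 0.144),
    ("20-HETE", "CYP", None, None, None, None),
    ("14,15-diHETE", "CYP", 0.103, 0.047, 0.109, 0.060),
    ("12,13-diHOME", "CYP", 4.328, 4.238, 3.162, 2.838),
    ("12,13-EpOME", "CYP", 0.414, 0.478, 0.550, 0.653),
    ("9,10-diHOME", "CYP", 1.548, 2.013, 1.235, 1.297),
    ("18-HEPE", "CYP/COX", 0.027, 0.030, 0.024, 0.026),
    ("5-iso-PGF2a", "AUTOX", 0.051, 0.021, 0.140, 0.840),
    ("9-HETE", "AUTOX", 0.031, 0.018, 0.027, 0.020),
    ("10-HDoHE", "AUTOX", 0.029, 0.036, 0.018, 0.020),
    ("9-HEPE", "AUTOX", 0.004, 0.009, 0.003, 0.013),
    ("8-HEPE", "AUTOX", None, None, None, None),
]
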