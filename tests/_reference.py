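"""Fixed published detection-count inputs used for metric-arithmetic checks.

Object-wise rows are (tp, fp, fn); pixel-wise rows are (tn, fn, tp, fp).
The expected metric values are the published 3-decimal figures these counts
must reproduce.
"""

# object-wise detection counts per model (tp, fp, fn); 2660 manual foci total
OBJECT_COUNTS = {
    "MLP": (2551, 372, 109),
    "RF": (2163, 98, 497),
    "MLP+RF": (2154, 91, 506),
    "MLP+RF+SVM": (2530, 321, 130),
    "cNB+MLP+RF+SVM": (2480, 253, 180),
}

# published object-wise metrics (sensitivity, ppv, fnr, f1) at 3 decimals
OBJECT_METRICS = {
    "MLP": (0.959, 0.873, 0.041, 0.914),
    "RF": (0.813, 0.957, 0.187, 0.879),
    "MLP+RF": (0.810, 0.959, 0.190, 0.878),
    "MLP+RF+SVM": (0.951, 0.887, 0.049, 0.918),
    "cNB+MLP+RF+SVM": (0.932, 0.907, 0.068, 0.920),
}

TOTAL_MANUAL_FOCI = 2660

# pixel-wise confusion counts per model (tn, fn, tp, fp), 15 rows
PIXEL_COUNTS = {
    "SVM": (3475866, 3680, 154816, 172406),
    "MLP": (3621996, 36440, 122056, 26276),
    "cNB": (3532468, 46102, 112394, 115804),
    "RF": (3625892, 37815, 120681, 22380),
    "MLP+SVM": (3622023, 37566, 120930, 26249),
    "RF+SVM": (3625967, 37761, 120735, 22305),
    "cNB+SVM": (3577436, 46534, 111962, 70836),
    "MLP+RF": (3630833, 42863, 115633, 17439),
    "cNB+MLP": (3633011, 59455, 99041, 15261),
    "cNB+RF": (3634212, 60311, 98185, 14060),
    "MLP+RF+SVM": (3620910, 33093, 125403, 27362),
    "cNB+MLP+SVM": (3564959, 26191, 132305, 83313),
    "cNB+RF+SVM": (3567063, 24060, 134436, 81209),
    "cNB+MLP+RF": (3624782, 38493, 120003, 23490),
    "cNB+MLP+RF+SVM": (3625631, 38500, 119996, 22641),
}
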