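"""Frozen reference values for the packaged [18F]FE-PE2I PD dataset.

INDIVIDUAL_BPND holds the published individual binding-potential values
(region -> ten (test, retest) pairs, subjects "1".."10") transcribed at
printed precision; PUBLISHED_N9 holds the published per-region summary
metrics of the main analysis (subject "8" excluded, n = 9). These are the
ground truth the fixture and the pipeline are checked against.
"""

INDIVIDUAL_BPND = {
    "striatum": [
        (1.763, 1.827), (1.051, 1.065), (1.892, 1.91), (1.835, 1.789),
        (1.306, 1.372), (1.273, 1.497), (1.339, 1.217), (2.801, 2.256),
        (1.537, 1.426), (1.978, 1.948),
    ],
    "caudate": [
        (2.428, 2.562), (0.914, 0.91), (2.339, 2.388), (1.697, 1.872),
        (1.43, 1.496), (1.876, 2.125), (1.356, 1.245), (3.268, 2.588),
        (1.928, 1.744), (2.564, 2.582),
    ],
    "putamen": [
        (1.264, 1.275), (1.095, 1.121), (1.516, 1.513), (1.824, 1.607),
        (1.15, 1.21), (0.672, 0.898), (1.203, 1.104), (2.332, 1.888),
        (1.166, 1.112), (1.423, 1.37),
    ],
    "ventral striatum": [
        (1.736, 1.722), (1.623, 1.687), (2.317, 2.319), (3.131, 2.717),
        (1.848, 2.021), (1.758, 1.838), (2.441, 2.011), (3.054, 2.714),
        (2.211, 2.191), (2.855, 2.686),
    ],
    "substantia nigra": [
        (0.73, 0.849), (0.635, 0.602), (0.813, 0.798), (1.016, 0.854),
        (0.668, 0.666), (0.397, 0.602), (0.752, 0.754), (0.894, 0.716),
        (0.653, 0.603), (0.796, 0.75),
    ],
}

# region -> (mean_test, sd_test, cov_test, mean_retest, sd_retest,
#            cov_retest, absvar %, icc, (ci_low, ci_high), mdd,
#            detectable %) at published display precision
PUBLISHED_N9 = {
    "striatum": (1.55, 0.33, 21.1, 1.56, 0.32, 20.5, 5.3, 0.95,
                 (0.82, 0.989), 0.195, -8.3),
    "caudate": (1.84, 0.55, 29.9, 1.88, 0.59, 31.4, 6.0, 0.97,
                (0.89, 0.99), 0.264, -8.9),
    "putamen": (1.26, 0.32, 25.3, 1.25, 0.22, 17.8, 7.5, 0.91,
                (0.68, 0.98), 0.225, -11.9),
    "ventral striatum": (2.21, 0.53, 23.9, 2.13, 0.38, 17.9, 6.5, 0.89,
                         (0.61, 0.97), 0.426, -12.1),
    "substantia nigra": (0.72, 0.17, 23.2, 0.72, 0.1, 14.5, 10.6, 0.74,
                         (0.24, 0.93), 0.194, -17.9),
}

#: SHA-256 of the fixture's canonical serialisation; guards against any
#: accidental edit of the packaged data file.
FIXTURE_CHECKSUM = "7f20339eeddf1b13617ae3660d88651158fec1ee541fe814ab3aaa81fb5cdcf0"
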