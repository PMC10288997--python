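"""Published cohort summary statistics used as simulator presets.

Each preset encodes, per study arm, the per-eye sample size and the
mean/SD of every biomarker on every plexus, plus demographic covariates.
The cohort simulator draws independent Gaussians from these, so synthetic
cohorts have the marginal structure of the reported groups.  Metric
columns are named ``{plexus}_{metric}``.

``FA`` here is in the reporting unit of the source cohort (percent of the
analyzed field); ``direction_area`` is in rose units squared.
"""

from __future__ import annotations

# demographic preset: age / BMI / BCVA for the two arms, eye-level n
DEMOGRAPHICS = {
    "HC": {"n_eyes": 50, "age": (47.36, 13.21), "bcva": (1.15, 0.18), "bmi": (22.80, 2.51)},
    "NMOSD": {"n_eyes": 44, "age": (47.68, 12.48), "bcva": (0.66, 0.47), "bmi": (22.34, 2.38)},
}

_HC_METRICS = {
    "SVC": {
        "FA": (3.07, 1.06), "FC": (0.71, 0.14), "FAR": (1.81, 0.63),
        "FR": (36.06, 9.80), "FS": (0.85, 0.06),
        "direction_ratio": (0.83, 0.06), "direction_area": (126975.41, 35612.57),
        "tortuosity": (1.75, 0.28), "VAD": (15.50, 2.37), "VLD": (5.71, 0.94),
        "FD": (1.48, 0.04), "B_num": (142.18, 33.76),
    },
    "DVC": {
        "FA": (1.42, 0.52), "FC": (0.99, 0.12), "FAR": (1.09, 0.13),
        "FR": (37.67, 4.64), "FS": (0.94, 0.04),
        "direction_ratio": (0.80, 0.04), "direction_area": (253055.16, 60396.85),
        "tortuosity": (1.56, 0.18), "VAD": (24.71, 5.16), "VLD": (9.72, 1.92),
        "FD": (1.59, 0.05), "B_num": (240.26, 63.31),
    },
    "IVC": {
        "FA": (1.54, 0.59), "FC": (0.92, 0.15), "FAR": (1.13, 0.14),
        "FR": (36.15, 4.35), "FS": (0.92, 0.05),
        "direction_ratio": (0.83, 0.05), "direction_area": (137133.29, 35682.46),
        "tortuosity": (1.76, 0.30), "VAD": (16.58, 1.16), "VLD": (6.22, 1.16),
        "FD": (1.50, 0.04), "B_num": (146.06, 37.23),
    },
}

_NMOSD_METRICS = {
    "SVC": {
        "FA": (3.84, 1.74), "FC": (0.70, 0.20), "FAR": (1.32, 0.80),
        "FR": (44.16, 32.36), "FS": (0.86, 0.06),
        "direction_ratio": (0.84, 0.07), "direction_area": (95386.17, 35612.57),
        "tortuosity": (1.94, 0.36), "VAD": (13.17, 2.74), "VLD": (4.71, 1.11),
        "FD": (1.44, 0.05), "B_num": (114.76, 38.36),
    },
    "DVC": {
        "FA": (1.69, 0.49), "FC": (0.94, 0.13), "FAR": (1.03, 0.20),
        "FR": (41.69, 11.84), "FS": (0.93, 0.03),
        "direction_ratio": (0.81, 0.04), "direction_area": (194469.51, 65790.78),
        "tortuosity": (1.60, 0.20), "VAD": (20.33, 5.18), "VLD": (7.94, 2.04),
        "FD": (1.55, 0.06), "B_num": (191.81, 10.11),
    },
    "IVC": {
        "FA": (1.73, 0.55), "FC": (0.92, 0.13), "FAR": (1.09, 0.18),
        "FR": (38.46, 7.66), "FS": (0.91, 0.04),
        "direction_ratio": (0.83, 0.07), "direction_area": (130898.89, 37292.13),
        "tortuosity": (1.82, 0.29), "VAD": (15.97, 1.19), "VLD": (5.97, 1.19),
        "FD": (1.49, 0.04), "B_num": (138.07, 35.60),
    },
}

_NON_ON_METRICS = {
    "SVC": {
        "FA": (3.59, 1.31), "FC": (0.69, 0.22), "FAR": (1.55, 1.10),
        "FR": (32.32, 8.22), "FS": (0.84, 0.07),
        "direction_ratio": (0.85, 0.08), "direction_area": (112396.77, 38514.02),
        "tortuosity": (1.89, 0.27), "VAD": (14.41, 2.82), "VLD": (5.23, 1.15),
        "FD": (1.47, 0.04), "B_num": (127.11, 38.81),
    },
    "DVC": {
        "FA": (1.50, 0.55), "FC": (0.94, 0.16), "FAR": (0.95, 0.18),
        "FR": (45.76, 14.57), "FS": (0.93, 0.04),
        "direction_ratio": (0.81, 0.04), "direction_area": (230685.61, 67930.71),
        "tortuosity": (1.58, 0.11), "VAD": (23.08, 5.35), "VLD": (9.07, 2.07),
        "FD": (1.58, 0.04), "B_num": (218.36, 50.47),
    },
    "IVC": {
        "FA": (1.65, 0.55), "FC": (0.91, 0.14), "FAR": (1.13, 0.17),
        "FR": (36.75, 5.96), "FS": (0.91, 0.04),
        "direction_ratio": (0.84, 0.05), "direction_area": (129787.94, 39670.54),
        "tortuosity": (1.85, 0.21), "VAD": (15.96, 3.15), "VLD": (5.94, 1.25),
        "FD": (1.49, 0.05), "B_num": (132.28, 29.76),
    },
}

_ON_METRICS = {
    "SVC": {
        "FA": (3.97, 1.97), "FC": (0.69, 0.19), "FAR": (1.19, 0.57),
        "FR": (50.83, 38.83), "FS": (0.87, 0.05),
        "direction_ratio": (0.82, 0.07), "direction_area": (85817.71, 31093.79),
        "tortuosity": (1.98, 0.41), "VAD": (12.47, 2.52), "VLD": (4.41, 1.00),
        "FD": (1.42, 0.05), "B_num": (107.81, 37.37),
    },
    "DVC": {
        "FA": (1.82, 0.44), "FC": (0.93, 0.11), "FAR": (1.09, 0.19),
        "FR": (38.34, 8.00), "FS": (0.93, 0.04),
        "direction_ratio": (0.81, 0.05), "direction_area": (164644.48, 47683.01),
        "tortuosity": (1.62, 0.26), "VAD": (18.07, 3.88), "VLD": (7.01, 1.52),
        "FD": (1.52, 0.05), "B_num": (169.94, 52.37),
    },
    "IVC": {
        "FA": (1.79, 0.55), "FC": (0.92, 0.13), "FAR": (1.06, 0.19),
        "FR": (39.87, 8.74), "FS": (0.92, 0.05),
        "direction_ratio": (0.82, 0.08), "direction_area": (131813.79, 36427.00),
        "tortuosity": (1.79, 0.35), "VAD": (15.99, 2.88), "VLD": (6.00, 1.18),
        "FD": (1.49, 0.04), "B_num": (142.82, 40.04),
    },
}


def _flatten(per_plexus: dict) -> dict:
    out = {}
    for plexus, metrics in per_plexus.items():
        for metric, ms in metrics.items():
            out[f"{plexus}_{metric}"] = ms
    return out


#: Case-control presets keyed by the cohort contrast they emulate.
COHORT_PRESETS = {
    # full NMOSD arm vs healthy controls
    "nmosd_vs_hc": {
        "HC": {"n_eyes": 50, "covariates": DEMOGRAPHICS["HC"], "metrics": _flatten(_HC_METRICS)},
        "NMOSD": {"n_eyes": 44, "covariates": DEMOGRAPHICS["NMOSD"], "metrics": _flatten(_NMOSD_METRICS)},
    },
    # eyes without an optic-neuritis history vs healthy controls
    "non_on_vs_hc": {
        "HC": {"n_eyes": 50, "covariates": DEMOGRAPHICS["HC"], "metrics": _flatten(_HC_METRICS)},
        "NON_ON": {"n_eyes": 19, "covariates": DEMOGRAPHICS["NMOSD"], "metrics": _flatten(_NON_ON_METRICS)},
    },
    # eyes with an optic-neuritis history vs healthy controls
    "on_vs_hc": {
        "HC": {"n_eyes": 50, "covariates": DEMOGRAPHICS["HC"], "metrics": _flatten(_HC_METRICS)},
        "ON": {"n_eyes": 25, "covariates": DEMOGRAPHICS["NMOSD"], "metrics": _flatten(_ON_METRICS)},
    },
    # demographics only (age / BMI / BCVA)
    "demographics": {
        "HC": {"n_eyes": 50, "covariates": DEMOGRAPHICS["HC"], "metrics": {}},
        "NMOSD": {"n_eyes": 44, "covariates": DEMOGRAPHICS["NMOSD"], "metrics": {}},
    },
}
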