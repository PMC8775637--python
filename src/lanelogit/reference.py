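"""Published estimates from the motivating field study of lane occupancy.

A large observational study in Pingdingshan, China (34,631 riders filmed at
eight sites covering five bicycle-facility configurations) fitted exactly the
models this package implements: a fixed-parameter ("standard") Bayesian logit
and a random-parameter logit over all facilities, plus one random-parameter
refit per dividing-strip type.  The raw data were never deposited, so those
coefficient tables are the only quantitative anchor available.  This module
transcribes them — posterior mean, posterior SD, equal-tailed 2.5%/97.5%
bounds, printed odds ratio, and (for random coefficients) the posterior
summary of the coefficient-distribution SD — together with the descriptive
category counts and the heterogeneity-share percentages quoted in the study's
narrative.

The tables serve two purposes here:

* regression tests: every printed OR must equal ``exp(mean)`` and every
  checkable share must equal ``100 * Phi(mean / sd)`` (or its complement),
  which validates this package's summary arithmetic against independently
  published numbers;
* realistic defaults: the synthetic-data generator draws covariates with the
  study's marginal frequencies, and example "truth" vectors reuse the
  published coefficient means.

A handful of printed shares are internally inconsistent in the source tables
(duplicated or not matching the printed mean/SD at all); those rows carry
``checkable=False`` and are excluded from regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EstimateRow",
    "ShareClaim",
    "MODELS",
    "MODEL_DIC",
    "SHARE_CLAIMS",
    "CATEGORY_COUNTS",
    "N_TOTAL",
    "N_OCCUPYING",
    "OCCUPANCY_RATE_PCT",
]


@dataclass(frozen=True)
class EstimateRow:
    """One coefficient row of a published posterior-summary table.

    ``random_sd`` is the (mean, sd, 2.5%, 97.5%) summary of the coefficient
    distribution's standard deviation when the coefficient was modelled as
    random, else ``None``.  ``odds_ratio`` is the printed OR (absent for the
    intercept and for the fixed-logit table, which printed none).
    """

    label: str
    mean: float
    sd: float
    lo: float
    hi: float
    odds_ratio: float | None = None
    random_sd: tuple[float, float, float, float] | None = None


@dataclass(frozen=True)
class ShareClaim:
    """A quoted heterogeneity-share percentage for a random coefficient.

    ``side`` selects the arithmetic the quote corresponds to: ``"pos"`` means
    the printed percentage equals ``100 * Phi(mean/sd)``, ``"neg"`` the
    complement.  (The narrative's "more/less likely" wording occasionally
    contradicts the printed coefficient sign; ``side`` follows the printed
    numbers, and magnitude is what regression tests compare.)
    """

    model: str
    label: str
    printed_pct: float
    side: str
    checkable: bool = True


N_TOTAL = 34_631
N_OCCUPYING = 9_917
#: Share of observed riders occupying the motor lane, as printed (percent).
OCCUPANCY_RATE_PCT = 28.64

#: Observed category counts per variable (each sums to ``N_TOTAL``).
CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"female": 18_014, "male": 16_617},
    "age": {"young": 6_362, "middle_aged": 24_363, "old": 3_906},
    "bike_type": {"c_bike": 1_944, "e_bike": 10_656, "e_scooter": 19_348, "tricycle": 2_683},
    "bike_lane_width": {"4.5": 5_052, "2.5": 22_518, "3.5": 5_650, "1.5": 1_411},
    "vehicle_lanes": {"2": 16_925, "3": 7_788, "4": 5_052, "1": 4_866},
    "dividing_strip": {
        "greenbelt": 10_702,
        "barriers": 9_433,
        "marking": 9_630,
        "pedestrian_bicycle": 3_455,
        "mixed": 1_411,
    },
    "bike_volume": {"low": 7_826, "medium": 10_689, "high": 16_116},
    "vehicle_volume": {"low": 5_239, "medium": 26_818, "high": 2_574},
    "on_street_parking": {"no": 23_158, "yes": 11_473},
    "temporary_parking": {"no": 31_878, "yes": 2_753},
    "weather": {"sunny": 17_409, "cloudy": 16_195, "rainy": 1_027},
    "time_interval": {"morning": 12_352, "noon": 10_561, "evening": 11_718},
    "manned_riding": {"no": 28_438, "yes": 6_193},
    "workday": {"no": 10_701, "yes": 23_930},
}

_R = EstimateRow

#: Published posterior-summary tables, keyed by model.  ``all_fixed`` is the
#: fixed-parameter logit over all facilities, ``all_random`` its
#: random-parameter counterpart; the remaining keys are per-facility
#: random-parameter refits stratified by dividing-strip type.
MODELS: dict[str, list[EstimateRow]] = {
    "all_fixed": [
        _R("intercept", -4.675, 0.748, -6.250, -3.594),
        _R("gender:male vs female", 0.621, 0.031, 0.560, 0.681),
        _R("age:middle_aged vs young", -0.088, 0.038, -0.163, -0.013),
        _R("age:old vs young", -0.334, 0.059, -0.451, -0.218),
        _R("bike_type:e_bike vs c_bike", 1.189, 0.082, 1.031, 1.352),
        _R("bike_type:e_scooter vs c_bike", 1.822, 0.080, 1.670, 1.982),
        _R("bike_type:tricycle vs c_bike", 2.161, 0.091, 1.985, 2.341),
        _R("dividing_strip:barriers vs greenbelt", 0.211, 1.538, 0.314, 0.109),
        _R("dividing_strip:marking vs greenbelt", 2.250, 3.604, -2.988, 8.519),
        _R("dividing_strip:pedestrian_bicycle vs greenbelt", 1.724, 6.997, -11.41, 10.52),
        _R("dividing_strip:mixed vs greenbelt", 1.937, 1.536, -0.749, 4.462),
        _R("bike_lane_width:2.5 vs 4.5", 1.115, 0.740, -0.008, 2.673),
        _R("bike_lane_width:3.5 vs 4.5", -0.416, 1.616, -3.677, 2.660),
        _R("bike_lane_width:1.5 vs 4.5", 4.142, 8.362, -7.172, 18.09),
        _R("vehicle_lanes:2 vs 1", 0.127, 0.080, -0.029, 0.286),
        _R("vehicle_lanes:3 vs 1", 1.065, 1.582, -2.578, 3.948),
        _R("vehicle_lanes:4 vs 1", -1.851, 4.769, -9.742, 5.271),
        _R("bike_volume:medium vs low", 0.052, 0.054, -0.053, 0.157),
        _R("bike_volume:high vs low", 0.322, 0.066, 0.196, 0.452),
        _R("vehicle_volume:medium vs low", 0.014, 0.004, -0.021, 0.053),
        _R("vehicle_volume:high vs low", -0.213, 0.097, -0.405, -0.023),
        _R("on_street_parking:yes vs no", -1.022, 0.098, -1.209, -0.826),
        _R("temporary_parking:yes vs no", 1.147, 0.055, 1.039, 1.253),
        _R("weather:cloudy vs sunny", -0.231, 0.073, -0.374, -0.089),
        _R("weather:rainy vs sunny", -0.712, 0.152, -1.010, -0.418),
        _R("time_interval:noon vs morning", 0.299, 0.038, 0.224, 0.372),
        _R("time_interval:evening vs morning", 0.053, 0.037, -0.020, 0.124),
        _R("manned_riding:yes vs no", -0.197, 0.040, -0.276, -0.197),
        _R("workday:yes vs no", 1.141, 1.321, -1.668, 3.475),
    ],
    "all_random": [
        _R("intercept", -4.680, 0.034, 0.017, 0.084),
        _R("gender:male vs female", 0.621, 0.026, 0.569, 0.674, 1.860),
        _R("age:middle_aged vs young", -0.088, 0.029, -0.145, -0.030, 0.916,
           random_sd=(0.079, 0.113, 0.020, 0.292)),
        _R("age:old vs young", -0.333, 0.040, -0.414, -0.252, 0.716),
        _R("bike_type:e_bike vs c_bike", 1.188, 0.035, 1.117, 1.261, 3.281),
        _R("bike_type:e_scooter vs c_bike", 1.822, 0.034, 1.751, 1.892, 6.184),
        _R("bike_type:tricycle vs c_bike", 2.161, 0.040, 2.078, 2.243, 8.680),
        _R("dividing_strip:barriers vs greenbelt", 0.212, 0.050, 0.315, 0.110, 1.236,
           random_sd=(0.165, 0.052, 0.020, 0.196)),
        _R("dividing_strip:marking vs greenbelt", 2.251, 0.055, 2.140, 2.362, 9.497),
        _R("dividing_strip:pedestrian_bicycle vs greenbelt", 1.726, 0.063, 1.602, 1.858, 5.618),
        _R("dividing_strip:mixed vs greenbelt", 1.936, 0.048, 1.834, 2.032, 6.931),
        _R("bike_lane_width:2.5 vs 4.5", 1.116, 0.069, 0.987, 1.252, 3.053),
        _R("bike_lane_width:3.5 vs 4.5", -0.415, 0.070, -0.553, -0.274, 0.660),
        _R("bike_lane_width:1.5 vs 4.5", 4.140, 0.068, 3.999, 4.279, 62.803),
        _R("vehicle_lanes:2 vs 1", 0.128, 0.035, 0.058, 0.198, 1.136,
           random_sd=(0.069, 0.061, 0.020, 0.217)),
        _R("vehicle_lanes:3 vs 1", 1.065, 0.057, 0.948, 1.181, 2.901),
        _R("vehicle_lanes:4 vs 1", -1.852, 0.051, -1.954, -1.749, 0.157),
        _R("bike_volume:medium vs low", 0.053, 0.033, -0.013, 0.120, 1.055,
           random_sd=(0.077, 0.107, 0.020, 0.287)),
        _R("bike_volume:high vs low", 0.324, 0.035, 0.253, 0.394, 1.383),
        _R("vehicle_volume:medium vs low", 0.015, 0.004, -0.027, 0.058, 1.015,
           random_sd=(0.088, 0.138, 0.021, 0.333)),
        _R("vehicle_volume:high vs low", -0.212, 0.050, -0.316, -0.106, 0.809),
        _R("on_street_parking:yes vs no", -1.021, 0.041, -1.103, -0.938, 0.360),
        _R("temporary_parking:yes vs no", 1.147, 0.044, 1.058, 1.238, 3.149),
        _R("weather:cloudy vs sunny", -0.230, 0.039, -0.309, -0.149, 0.795),
        _R("weather:rainy vs sunny", -0.711, 0.072, -0.862, -0.556, 0.491),
        _R("time_interval:noon vs morning", 0.299, 0.028, 0.244, 0.356, 1.348),
        _R("time_interval:evening vs morning", 0.053, 0.028, -0.003, 0.110, 1.055,
           random_sd=(0.073, 0.111, 0.019, 0.275)),
        _R("manned_riding:yes vs no", -0.197, 0.034, -0.265, -0.129, 0.821),
        _R("workday:yes vs no", 1.143, 0.073, 1.004, 1.288, 3.136),
    ],
    "greenbelt": [
        _R("intercept", -3.148, 0.101, -3.354, -2.933),
        _R("gender:male vs female", 0.906, 0.056, 0.792, 1.021, 2.475),
        _R("age:middle_aged vs young", -0.095, 0.054, -0.204, -0.095, 0.909,
           random_sd=(0.109, 0.166, 0.022, 0.436)),
        _R("age:old vs young", -0.271, 0.070, -0.418, -0.122, 0.762),
        _R("bike_type:e_bike vs c_bike", 0.450, 0.064, 0.316, 0.581, 1.568),
        _R("bike_type:e_scooter vs c_bike", 1.067, 0.059, 0.944, 1.188, 2.907),
        _R("bike_type:tricycle vs c_bike", 1.200, 0.073, 1.041, 1.352, 3.320),
        _R("bike_volume:medium vs low", 0.057, 0.055, -0.057, 0.170, 1.059,
           random_sd=(0.113, 0.461, 0.022, 0.428)),
        _R("bike_volume:high vs low", 0.414, 0.068, 0.269, 0.554, 1.513),
        _R("vehicle_volume:medium vs low", -0.239, 0.085, -0.416, -0.066, 0.787,
           random_sd=(0.143, 0.277, 0.024, 0.613)),
        _R("vehicle_volume:high vs low", -0.340, 0.100, -0.553, -0.126, 0.712),
        _R("on_street_parking:yes vs no", -0.477, 0.061, -0.602, -0.350, 0.620),
        _R("weather:cloudy vs sunny", -0.304, 0.054, -0.416, -0.194, 0.738),
        _R("weather:rainy vs sunny", -1.813, 0.114, -2.065, -1.565, 0.163),
        _R("time_interval:noon vs morning", 0.331, 0.053, 0.221, 0.441, 1.392),
        _R("time_interval:evening vs morning", 0.336, 0.060, 0.211, 0.460, 1.399),
        _R("manned_riding:yes vs no", -0.539, 0.068, -0.681, -0.399, 0.583),
    ],
    "barriers": [
        _R("intercept", -4.536, 0.082, -4.698, -4.359),
        _R("gender:male vs female", 1.029, 0.049, 0.931, 1.129, 2.798),
        _R("age:middle_aged vs young", 0.067, 0.049, -0.035, 0.166, 1.069,
           random_sd=(0.107, 0.163, 0.022, 0.419)),
        _R("age:old vs young", -0.140, 0.070, -0.290, 0.005, 0.870),
        _R("bike_type:e_bike vs c_bike", 1.043, 0.057, 0.920, 1.158, 2.838),
        _R("bike_type:e_scooter vs c_bike", 1.717, 0.053, 1.603, 1.821, 5.568),
        _R("bike_type:tricycle vs c_bike", 2.147, 0.063, 2.014, 2.274, 8.559),
        _R("vehicle_lanes:3 vs 2", 0.065, 0.065, -0.070, 0.198, 1.067,
           random_sd=(0.627, 0.119, 0.024, 2.129)),
        _R("bike_volume:medium vs low", 0.422, 0.061, 0.295, 0.550, 1.525,
           random_sd=(0.145, 0.234, 0.022, 0.429)),
        _R("bike_volume:high vs low", 0.345, 0.061, 0.219, 0.472, 1.412),
        _R("time_interval:noon vs morning", 0.438, 0.046, 0.345, 0.531, 1.549),
        _R("time_interval:evening vs morning", -0.629, 0.049, -0.730, -0.530, 0.533),
        _R("manned_riding:yes vs no", -0.368, 0.066, -0.503, -0.234, 0.692),
    ],
    "marking": [
        _R("intercept", -0.887, 0.073, -1.035, -0.736),
        _R("gender:male vs female", 0.435, 0.039, 0.356, 0.514, 1.546),
        _R("age:middle_aged vs young", -0.100, 0.041, -0.183, -0.016, 0.905,
           random_sd=(0.095, 0.166, 0.021, 0.378)),
        _R("age:old vs young", -0.532, 0.054, -0.644, -0.420, 0.588),
        _R("bike_type:e_bike vs c_bike", 1.262, 0.045, 1.170, 1.354, 3.532),
        _R("bike_type:e_scooter vs c_bike", 1.970, 0.043, 1.881, 2.057, 7.171),
        _R("bike_type:tricycle vs c_bike", 2.005, 0.053, 1.894, 2.115, 7.426),
        _R("bike_volume:medium vs low", 0.095, 0.060, -0.031, 0.224, 1.100,
           random_sd=(0.105, 0.253, 0.022, 0.415)),
        _R("bike_volume:high vs low", 0.137, 0.061, 0.264, 0.005, 1.146),
        _R("vehicle_volume:medium vs low", -0.271, 0.048, -0.368, -0.174, 0.763),
        _R("on_street_parking:yes vs no", -1.092, 0.040, -1.174, -1.011, 0.336),
        _R("temporary_parking:yes vs no", 1.111, 0.045, 1.018, 1.203, 3.037),
        _R("time_interval:noon vs morning", 0.182, 0.042, 0.266, 0.097, 1.199,
           random_sd=(0.090, 0.197, 0.021, 0.335)),
        _R("time_interval:evening vs morning", 0.198, 0.042, 0.113, 0.284, 1.219),
        _R("manned_riding:yes vs no", -0.114, 0.051, -0.217, -0.010, 0.892,
           random_sd=(0.574, 0.142, 0.024, 2.132)),
    ],
    "pedestrian_bicycle": [
        _R("intercept", -3.885, 0.086, -4.06, -3.706),
        _R("gender:male vs female", 0.205, 0.064, 0.071, 0.335, 1.228,
           random_sd=(0.716, 0.261, 0.024, 2.267)),
        _R("age:middle_aged vs young", -0.321, 0.061, -0.451, -0.195, 0.726),
        _R("age:old vs young", -0.340, 0.075, -0.499, -0.179, 0.711,
           random_sd=(0.116, 0.193, 0.023, 0.475)),
        _R("bike_type:e_bike vs c_bike", 1.654, 0.072, 1.504, 1.8, 5.228),
        _R("bike_type:e_scooter vs c_bike", 2.241, 0.068, 2.100, 2.378, 9.403),
        _R("bike_type:tricycle vs c_bike", 3.658, 0.078, 3.492, 3.913, 38.784),
        _R("bike_volume:medium vs low", 0.165, 0.065, 0.030, 0.301, 1.180,
           random_sd=(0.120, 0.215, 0.023, 0.470)),
        _R("bike_volume:high vs low", 0.186, 0.076, 0.027, 0.186, 1.204),
        _R("vehicle_volume:high vs medium", -0.105, 0.067, -0.244, 0.035, 0.900,
           random_sd=(0.824, 0.343, 0.024, 2.257)),
        _R("time_interval:noon vs morning", 1.168, 0.062, 1.039, 1.297, 3.216),
        _R("time_interval:evening vs morning", 0.557, 0.064, 0.424, 0.691, 1.745),
        _R("manned_riding:yes vs no", 0.077, 0.085, -0.105, 0.254, 1.080,
           random_sd=(0.531, 0.426, 0.026, 2.596)),
    ],
    "mixed": [
        _R("intercept", -1.458, 0.010, -1.662, -1.243),
        _R("gender:male vs female", 0.263, 0.086, 0.084, 0.443, 1.301,
           random_sd=(1.051, 0.384, 0.025, 2.557)),
        _R("age:middle_aged vs young", -0.075, 0.086, -0.259, 0.101, 0.928,
           random_sd=(0.145, 0.257, 0.024, 0.615)),
        _R("age:old vs young", -0.442, 0.104, -0.666, -0.226, 0.643),
        _R("bike_type:e_bike vs c_bike", 1.428, 0.077, 1.261, 1.587, 4.170),
        _R("bike_type:e_scooter vs c_bike", 1.856, 0.077, 1.689, 2.017, 6.398),
        _R("bike_type:tricycle vs c_bike", 1.674, 0.091, 1.478, 1.864, 5.333),
        _R("bike_volume:medium vs low", 0.002, 0.096, -0.210, 0.205, 1.002,
           random_sd=(0.682, 0.895, 0.025, 2.674)),
        _R("temporary_parking:yes vs no", 3.493, 0.423, 2.585, 4.465, 32.884),
        _R("weather:rainy vs sunny", 0.564, 0.138, 0.269, 0.859, 1.758,
           random_sd=(0.923, 0.134, 0.027, 3.583)),
        _R("time_interval:noon vs morning", 0.876, 0.084, 0.697, 1.054, 2.401),
        _R("time_interval:evening vs morning", 0.865, 0.087, 0.680, 1.048, 2.374),
        _R("manned_riding:yes vs no", 0.253, 0.108, 0.025, 0.484, 1.288,
           random_sd=(0.920, 0.231, 0.026, 3.123)),
    ],
}

#: Published deviance information criteria of the two all-facility models.
MODEL_DIC: dict[str, float] = {"all_fixed": 33_230.0, "all_random": 33_210.0}

_S = ShareClaim

#: Heterogeneity-share percentages quoted in the study narrative.  Rows with
#: ``checkable=False`` do not reproduce from the printed mean/SD (duplicated
#: figures or arithmetic inconsistencies in the source) and are documented
#: rather than asserted.
SHARE_CLAIMS: list[ShareClaim] = [
    _S("all_random", "age:middle_aged vs young", 86.74, "neg"),
    _S("all_random", "dividing_strip:barriers vs greenbelt", 90.57, "pos", checkable=False),
    _S("all_random", "vehicle_lanes:2 vs 1", 96.79, "pos"),
    _S("all_random", "bike_volume:medium vs low", 90.06, "pos", checkable=False),
    _S("all_random", "vehicle_volume:medium vs low", 43.24, "neg"),
    _S("all_random", "time_interval:evening vs morning", 76.57, "pos"),
    _S("greenbelt", "age:middle_aged vs young", 80.83, "neg"),
    _S("greenbelt", "bike_volume:medium vs low", 69.30, "pos"),
    _S("greenbelt", "vehicle_volume:medium vs low", 95.27, "neg"),
    _S("barriers", "age:middle_aged vs young", 73.42, "pos"),
    _S("barriers", "bike_volume:medium vs low", 99.81, "pos"),
    _S("barriers", "vehicle_lanes:3 vs 2", 54.13, "pos"),
    _S("marking", "age:middle_aged vs young", 85.38, "neg"),
    _S("marking", "bike_volume:medium vs low", 81.72, "pos"),
    _S("marking", "time_interval:noon vs morning", 97.85, "pos"),
    _S("marking", "manned_riding:yes vs no", 57.88, "neg"),
    _S("pedestrian_bicycle", "gender:male vs female", 61.26, "pos"),
    _S("pedestrian_bicycle", "age:old vs young", 99.83, "neg"),
    _S("pedestrian_bicycle", "bike_volume:medium vs low", 81.72, "pos", checkable=False),
    _S("pedestrian_bicycle", "vehicle_volume:high vs medium", 55.07, "neg"),
    _S("pedestrian_bicycle", "manned_riding:yes vs no", 58.09, "pos", checkable=False),
    _S("mixed", "gender:male vs female", 59.87, "pos"),
    _S("mixed", "age:middle_aged vs young", 30.25, "pos"),
    _S("mixed", "bike_volume:medium vs low", 50.12, "pos"),
    _S("mixed", "weather:rainy vs sunny", 72.94, "pos"),
    _S("mixed", "manned_riding:yes vs no", 57.88, "pos", checkable=False),
]
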