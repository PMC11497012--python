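"""Bundled reference tables: published regional prevalence projections.

Published pancreatic-cancer ASPR projections (per 100,000, 2020-2040 on a
5-year grid, with 95% uncertainty bounds) and the two period percentage
changes (1990-2019, 2019-2040), globally and for the 21 GBD regions,
stratified by sex, from a global illness-death modelling study of GBD
1990-2019 data. These tables serve as worked-example inputs for the trend
analytics: rankings, threshold counts, sex contrasts and fold-changes are
recomputed from these cells rather than hard-coded.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_regional_projections", "GBD_REGIONS"]

_HEADER = (
    "region,aspr_2020,lower_2020,upper_2020,aspr_2025,lower_2025,upper_2025,"
    "aspr_2030,lower_2030,upper_2030,aspr_2035,lower_2035,upper_2035,"
    "aspr_2040,lower_2040,upper_2040,pct_1990_2019,pct_2019_2040"
)

_BOTH = """\
Global,5.448,5.386,5.51,5.602,5.409,5.802,5.761,5.43,6.113,5.925,5.45,6.441,6.093,5.47,6.786,31.45631768,12.29155567
Central Asia,4.407,4.296,4.521,4.32,3.992,4.675,4.235,3.706,4.84,4.151,3.439,5.011,4.07,3.192,5.188,129.4552361,-7.916674391
Central Europe,8.278,8.116,8.442,8.569,8.065,9.105,8.871,8.006,9.829,9.183,7.948,10.611,9.507,7.889,11.456,27.27798082,15.61054981
Eastern Europe,6.101,5.603,6.643,5.603,4.307,7.288,5.145,3.299,8.025,4.725,2.526,8.84,4.34,1.934,9.739,21.05956254,-31.08054446
Australasia,8.334,8.108,8.566,8.53,7.837,9.284,8.73,7.565,10.075,8.935,7.302,10.934,9.145,7.047,11.867,24.05433629,9.831235837
High-income Asia Pacific,10.5,10.305,10.699,10.017,9.454,10.613,9.556,8.666,10.537,9.116,7.943,10.462,8.697,7.28,10.388,24.07071737,-18.19689508
High-income North America,9.331,9.176,9.489,9.284,8.817,9.776,9.237,8.466,10.08,9.191,8.128,10.393,9.145,7.803,10.717,21.57127113,-2.300349259
Southern Latin America,8.274,8.024,8.531,8.737,7.947,9.604,9.225,7.861,10.826,9.742,7.775,12.206,10.287,7.689,13.762,26.53554757,26.16080513
Western Europe,9.162,9.001,9.326,8.919,8.444,9.421,8.682,7.915,9.524,8.452,7.419,9.628,8.227,6.954,9.735,32.53797176,-10.94565609
Andean Latin America,4.012,3.872,4.157,4.331,3.882,4.832,4.675,3.886,5.626,5.048,3.889,6.552,5.449,3.892,7.63,168.3107445,38.43488258
Caribbean,4.01,3.89,4.134,4.104,3.738,4.507,4.201,3.586,4.921,4.3,3.44,5.374,4.401,3.3,5.869,223.7059783,10.90478112
Central Latin America,4.242,4.131,4.356,4.785,4.408,5.195,5.398,4.698,6.202,6.089,5.007,7.405,6.868,5.335,8.842,27.42925662,65.72212431
Tropical Latin America,4.689,4.592,4.788,4.707,4.412,5.021,4.724,4.235,5.27,4.742,4.065,5.531,4.76,3.902,5.806,24.12891613,1.253435529
North Africa and Middle East,4.236,4.195,4.278,4.715,4.575,4.86,5.249,4.988,5.524,5.843,5.437,6.279,6.504,5.927,7.137,104.3317885,56.57407372
South Asia,2.163,2.102,2.225,2.447,2.242,2.671,2.769,2.389,3.21,3.133,2.544,3.859,3.545,2.71,4.639,104.1977898,67.64412555
East Asia,4.686,4.623,4.751,5.705,5.469,5.951,6.945,6.467,7.458,8.454,7.646,9.348,10.292,9.039,11.718,85.45130511,129.340114
Oceania,1.862,1.845,1.879,1.983,1.928,2.039,2.112,2.014,2.214,2.249,2.104,2.404,2.395,2.197,2.61,41.56778211,30.37931129
Southeast Asia,3.335,3.299,3.371,3.734,3.612,3.861,4.181,3.952,4.424,4.682,4.324,5.069,5.242,4.731,5.809,84.4994384,60.84487205
Central Sub-Saharan Africa,2.087,2.062,2.112,2.417,2.329,2.508,2.799,2.629,2.98,3.242,2.969,3.541,3.756,3.352,4.208,27.86489339,85.92026432
Eastern Sub-Saharan Africa,2.162,2.146,2.179,2.478,2.419,2.539,2.84,2.727,2.958,3.255,3.073,3.447,3.73,3.464,4.017,51.57360041,77.71598805
Southern Sub-Saharan Africa,4.362,3.894,4.886,4.185,2.949,5.939,4.015,2.222,7.255,3.853,1.674,8.868,3.696,1.26,10.841,-0.695935808,-15.5488894
Western Sub-Saharan Africa,3.37,3.325,3.416,3.76,3.605,3.921,4.195,3.907,4.504,4.68,4.234,5.173,5.221,4.588,5.941,101.8327318,58.9078446
"""

_MALE = """\
Global,6.172,6.096,6.249,6.33,6.092,6.577,6.492,6.084,6.926,6.657,6.077,7.294,6.828,6.069,7.681,29.89103324,11.04291545
Central Asia,5.37,5.233,5.509,5.168,4.774,5.595,4.974,4.351,5.687,4.788,3.964,5.783,4.608,3.612,5.88,126.1904846,-14.6548582
Central Europe,10.3,10.069,10.535,10.557,9.845,11.32,10.821,9.617,12.175,11.091,9.392,13.097,11.368,9.173,14.089,23.17136354,10.92618448
Eastern Europe,8.186,7.413,9.04,7.173,5.281,9.744,6.285,3.746,10.546,5.508,2.656,11.421,4.826,1.883,12.371,17.00282452,-43.58754075
Australasia,9.298,8.993,9.614,9.477,8.548,10.507,9.659,8.114,11.498,9.845,7.701,12.586,10.034,7.308,13.778,19.48247418,7.863465327
High-income Asia Pacific,12.218,11.954,12.487,11.422,10.678,12.218,10.678,9.53,11.965,9.983,8.504,11.719,9.332,7.588,11.478,13.14483352,-24.92169873
High-income North America,10.446,10.259,10.636,10.545,9.973,11.15,10.645,9.688,11.697,10.746,9.41,12.272,10.848,9.139,12.876,18.02164247,4.168370618
Southern Latin America,8.996,8.679,9.324,9.557,8.555,10.676,10.152,8.42,12.242,10.785,8.285,14.04,11.458,8.152,16.104,21.76538083,29.49008242
Western Europe,9.756,9.576,9.939,9.395,8.872,9.95,9.048,8.213,9.969,8.714,7.602,9.99,8.392,7.036,10.01,20.70028125,-14.89184188
Andean Latin America,3.761,3.652,3.874,3.99,3.641,4.371,4.232,3.627,4.938,4.489,3.611,5.58,4.761,3.596,6.305,140.5693771,28.46308462
Caribbean,4.433,4.282,4.59,4.471,4.016,4.977,4.509,3.762,5.405,4.548,3.522,5.871,4.586,3.298,6.378,229.3857932,4.235745956
Central Latin America,4.392,4.238,4.552,5.162,4.624,5.763,6.067,5.037,7.309,7.131,5.486,9.271,8.382,5.974,11.76,33.56468621,97.37604016
Tropical Latin America,5.142,5.021,5.266,5.114,4.751,5.504,5.086,4.492,5.759,5.058,4.246,6.027,5.031,4.013,6.307,23.71252904,-2.739946978
North Africa and Middle East,4.96,4.903,5.017,5.468,5.278,5.665,6.029,5.678,6.4,6.647,6.109,7.232,7.328,6.572,8.171,95.08240941,50.26962746
South Asia,2.232,2.172,2.293,2.518,2.314,2.739,2.841,2.464,3.276,3.205,2.622,3.918,3.617,2.791,4.687,79.26705056,65.90415186
East Asia,5.995,5.911,6.081,7.139,6.834,7.458,8.501,7.897,9.152,10.123,9.123,11.233,12.055,10.541,13.787,94.76210057,108.8537441
Oceania,2.146,2.12,2.171,2.267,2.185,2.352,2.395,2.25,2.549,2.531,2.318,2.763,2.674,2.387,2.995,37.0576473,26.15644765
Southeast Asia,3.494,3.438,3.55,3.89,3.703,4.087,4.332,3.986,4.708,4.823,4.289,5.424,5.371,4.616,6.249,71.21988534,57.06851254
Central Sub-Saharan Africa,2.637,2.606,2.668,2.999,2.892,3.11,3.41,3.208,3.626,3.878,3.557,4.228,4.41,3.945,4.931,20.3817037,72.06636496
Eastern Sub-Saharan Africa,2.403,2.384,2.422,2.69,2.623,2.757,3.01,2.886,3.14,3.369,3.176,3.575,3.771,3.494,4.071,36.95528989,60.92474385
Southern Sub-Saharan Africa,5.211,4.667,5.819,4.822,3.432,6.777,4.463,2.511,7.93,4.13,1.836,9.286,3.821,1.343,10.875,0.63798293,-28.29685185
Western Sub-Saharan Africa,3.192,3.149,3.237,3.476,3.332,3.627,3.785,3.523,4.067,4.122,3.725,4.561,4.489,3.939,5.115,74.18520182,43.56823533
"""

_FEMALE = """\
Global,4.765,4.715,4.817,4.921,4.761,5.087,5.082,4.805,5.375,5.249,4.85,5.68,5.42,4.895,6.002,33.37417557,14.26421972
Central Asia,3.641,3.55,3.734,3.635,3.361,3.93,3.629,3.18,4.142,3.623,3.008,4.365,3.617,2.845,4.6,130.0082217,-0.698268008
Central Europe,6.489,6.375,6.604,6.753,6.394,7.132,7.027,6.408,7.707,7.313,6.422,8.329,7.611,6.435,9.002,31.75538016,18.13835637
Eastern Europe,4.527,4.245,4.827,4.379,3.592,5.338,4.235,3.03,5.919,4.096,2.556,6.566,3.962,2.155,7.284,21.63644069,-13.9761656
Australasia,7.427,7.211,7.651,7.657,6.988,8.389,7.893,6.764,9.211,8.137,6.545,10.115,8.388,6.334,11.108,28.20263403,13.28506821
High-income Asia Pacific,8.91,8.741,9.082,8.672,8.174,9.201,8.441,7.638,9.328,8.216,7.136,9.458,7.996,6.667,9.591,34.53437194,-10.94308966
High-income North America,8.311,8.167,8.457,8.145,7.718,8.596,7.983,7.289,8.743,7.823,6.882,8.893,7.667,6.498,9.047,24.43271553,-8.622975155
Southern Latin America,7.589,7.376,7.807,7.946,7.28,8.674,8.321,7.176,9.648,8.713,7.072,10.734,9.123,6.969,11.943,31.62030547,21.68729343
Western Europe,8.569,8.417,8.724,8.421,7.968,8.9,8.276,7.538,9.086,8.133,7.13,9.278,7.993,6.744,9.474,45.22488754,-7.282678925
Andean Latin America,4.229,4.037,4.429,4.631,4.013,5.343,5.071,3.982,6.457,5.552,3.949,7.806,6.08,3.917,9.437,196.4701512,47.03825261
Caribbean,3.608,3.507,3.713,3.755,3.438,4.101,3.908,3.367,4.536,4.067,3.297,5.018,4.233,3.228,5.551,217.6179089,18.94236212
Central Latin America,4.099,4.009,4.191,4.455,4.16,4.772,4.843,4.312,5.439,5.264,4.469,6.199,5.721,4.632,7.066,21.99563769,41.53927619
Tropical Latin America,4.271,4.189,4.354,4.32,4.069,4.586,4.369,3.95,4.833,4.419,3.833,5.095,4.47,3.72,5.371,25.18657902,4.710942663
North Africa and Middle East,3.47,3.441,3.499,3.91,3.81,4.013,4.406,4.217,4.603,4.965,4.667,5.281,5.594,5.166,6.058,118.7298474,64.98363238
South Asia,2.093,2.027,2.161,2.374,2.151,2.62,2.693,2.28,3.182,3.056,2.416,3.864,3.467,2.561,4.693,144.8686925,69.2730155
East Asia,3.407,3.325,3.491,3.973,3.745,4.216,4.634,4.214,5.095,5.404,4.741,6.16,6.303,5.334,7.448,73.37105243,89.12314217
Oceania,1.556,1.543,1.569,1.677,1.634,1.721,1.807,1.729,1.888,1.947,1.831,2.072,2.098,1.937,2.273,48.27635807,36.91610623
Southeast Asia,3.17,3.147,3.194,3.569,3.486,3.653,4.017,3.862,4.178,4.521,4.277,4.779,5.089,4.737,5.467,99.08111851,64.48318657
Central Sub-Saharan Africa,1.621,1.6,1.643,1.91,1.832,1.99,2.25,2.098,2.412,2.65,2.402,2.924,3.122,2.75,3.544,42.75499255,99.54882433
Eastern Sub-Saharan Africa,1.932,1.918,1.947,2.275,2.223,2.33,2.68,2.575,2.788,3.155,2.983,3.337,3.716,3.456,3.995,75.13863977,99.21063109
Southern Sub-Saharan Africa,3.641,3.192,4.153,3.649,2.432,5.477,3.657,1.842,7.263,3.666,1.394,9.639,3.674,1.055,12.796,-1.361161098,1.677326633
Western Sub-Saharan Africa,3.542,3.491,3.593,4.027,3.853,4.209,4.579,4.249,4.935,5.207,4.686,5.786,5.921,5.168,6.784,136.3344395,72.13283556
"""

_TABLES = {"both": _BOTH, "male": _MALE, "female": _FEMALE}

#: the 21 GBD reporting regions, in table order
GBD_REGIONS = tuple(
    line.split(",")[0] for line in _BOTH.splitlines() if line and not line.startswith("Global")
)


def load_regional_projections(sex: str = "both", include_global: bool = False) -> pd.DataFrame:
    """Load the published regional projection table for one sex stratum.

    Parameters
    ----------
    sex : {"both", "male", "female"}
        Sex stratum of the table.
    include_global : bool
        If True, keep the Global summary row; by default only the 21
        regions are returned, which is the panel that rankings and
        threshold counts are defined over.

    Returns
    -------
    pandas.DataFrame
        Region-indexed panel with columns ``aspr_YYYY``, ``lower_YYYY``,
        ``upper_YYYY`` for the 5-year grid 2020-2040 plus
        ``pct_1990_2019`` and ``pct_2019_2040``.
    """
    if sex not in _TABLES:
        raise ValueError(f"sex must be one of {sorted(_TABLES)}, got {sex!r}")
    df = pd.read_csv(io.StringIO(_HEADER + "\n" + _TABLES[sex])).set_index("region")
    if not include_global:
        df = df.drop(index="Global")
    return df
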