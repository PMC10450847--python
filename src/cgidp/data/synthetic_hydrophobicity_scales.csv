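one_letter,synthetic_0,synthetic_1,synthetic_2,synthetic_3,synthetic_4,synthetic_5,synthetic_6,synthetic_7,synthetic_8,synthetic_9,synthetic_10,synthetic_11,synthetic_12,synthetic_13,synthetic_14,synthetic_15,synthetic_16,synthetic_17,synthetic_18,synthetic_19,synthetic_20,synthetic_21,synthetic_22,synthetic_23
A,0.0,0.0,0.0,0.096888,0.207802,0.0,0.007007,0.085372,0.0,0.0,0.515099,0.0,0.426751,0.0,0.0,0.0,0.239888,0.215467,0.160467,0.0,0.492045,0.205846,0.0,0.0
C,0.621599,0.649512,0.724551,0.643195,0.725617,0.455193,0.373711,0.370597,0.682386,0.47959,0.716237,0.768437,0.645853,0.274847,0.98384,0.66237,0.950507,0.621456,0.595423,0.337466,0.670646,0.72525,0.662385,0.672086
D,0.320208,0.406238,0.307674,0.364172,0.295578,0.542503,0.460502,0.642369,0.481215,0.26367,0.520078,0.529053,0.392292,0.268786,0.370584,0.562633,0.657278,0.343701,0.422228,0.76117,0.377371,0.271498,0.607381,0.810156
E,0.237235,0.34311,0.33585,0.500839,0.0,0.209977,0.0,0.311877,0.400154,0.301232,0.198632,0.334255,0.293856,0.064681,0.432691,0.373633,0.442382,0.239732,0.365307,0.422617,0.199072,0.398631,0.045782,0.422226
F,0.338693,0.50841,0.119298,0.471036,0.318835,0.313154,0.137036,0.360347,0.389526,0.294789,0.185108,0.12642,0.331373,0.196726,0.398465,0.378162,0.393086,0.310761,0.159502,0.446654,0.384798,0.311095,0.401245,0.622154
G,0.942516,0.49682,0.70814,0.526403,0.620844,0.933452,0.311181,0.993463,0.827818,0.692863,0.812497,0.64075,0.564757,0.93726,0.663718,0.840548,0.955307,0.530602,0.832538,0.767307,0.911602,0.958935,0.873993,1.0
H,0.680462,1.0,0.550825,0.667713,0.807891,0.877176,0.865184,0.990538,0.881927,0.921312,0.810946,0.944068,0.784783,0.783183,0.783148,0.577364,1.0,0.552256,0.871063,0.687201,0.851178,0.748802,0.896333,0.691505
I,0.268158,0.482113,0.027947,0.0,0.369567,0.433466,0.138969,0.281671,0.223593,0.184284,0.0,0.255687,0.0,0.004182,0.019617,0.158335,0.383557,0.0,0.0,0.165605,0.0,0.0,0.612962,0.324533
K,0.355527,0.681106,0.868255,0.704756,0.425376,0.477408,0.619559,0.75905,0.678404,0.542246,0.581111,0.7845,0.594592,0.675365,0.826361,0.536467,0.897499,0.547807,0.583461,0.547979,0.47511,0.685758,0.681699,0.542148
L,0.213949,0.297655,0.1545,0.635752,0.356645,0.042341,0.609088,0.208361,0.443208,0.221333,0.331569,0.573171,0.136224,0.034061,0.147595,0.108637,0.230038,0.318232,0.05799,0.110536,0.375274,0.152156,0.261269,0.381585
M,0.673929,0.658287,1.0,0.9508,1.0,1.0,1.0,0.994339,0.862633,0.772686,1.0,0.931726,0.917469,0.867205,0.972672,1.0,0.681305,1.0,0.807885,1.0,1.0,0.728799,1.0,0.980454
N,1.0,0.821686,0.86564,1.0,0.889157,0.63127,0.653796,1.0,1.0,0.857302,0.819709,1.0,0.7452,1.0,0.490213,0.651614,0.95054,0.801453,0.597268,0.957875,0.856537,1.0,0.784535,0.999982
P,0.643814,0.416859,0.522367,0.505267,0.717817,0.587517,0.923766,0.7025,0.715635,0.597012,0.546856,0.654588,0.550379,0.784388,0.605293,0.406649,0.698867,0.578113,0.596769,0.60366,0.638562,0.659561,0.425379,0.685438
Q,0.803808,0.562741,0.560788,0.627964,0.60717,0.690304,0.481559,0.678612,0.750163,0.953324,0.686886,0.712664,1.0,0.648848,0.885999,0.619766,0.837404,0.826646,1.0,0.633719,0.835468,0.263191,0.762858,0.858502
R,0.270857,0.337542,0.609531,0.24318,0.356557,0.378069,0.501298,0.0,0.448935,0.725507,0.498708,0.528611,0.515498,0.311807,0.612223,0.521425,0.490574,0.322197,0.589797,0.342455,0.673506,0.350217,0.637812,0.498183
S,0.808919,0.659163,0.69288,0.860331,0.882484,0.897332,0.820721,0.843951,0.854753,1.0,0.596376,0.981405,0.714347,0.83366,1.0,0.574098,0.832959,0.557557,0.767287,0.839474,0.689559,0.620596,0.738013,0.683337
T,0.259238,0.475308,0.581446,0.622571,0.489236,0.611189,0.168061,0.452282,0.573349,0.739118,0.527281,0.358833,0.359417,0.427822,0.382571,0.272614,0.59063,0.296476,0.214054,0.628487,0.527413,0.51093,0.539076,0.338713
V,0.160419,0.162409,0.172884,0.308729,0.480862,0.414942,0.411589,0.291483,0.201832,0.190671,0.610484,0.557656,0.124452,0.123589,0.263798,0.317348,0.495598,0.2605,0.287723,0.051418,0.281579,0.524956,0.240996,0.528111
W,0.242839,0.060799,0.223709,0.516542,0.261153,0.302869,0.183476,0.389634,0.303575,0.392788,0.37382,0.548007,0.34689,0.085211,0.387018,0.037376,0.539464,0.47398,0.340803,0.139188,0.220838,0.550703,0.475869,0.591811
Y,0.246741,0.016878,0.232545,0.278602,0.409204,0.28892,0.163388,0.276314,0.256091,0.35796,0.02774,0.301333,0.369473,0.038335,0.139623,0.074444,0.0,0.135594,0.125302,0.163691,0.373611,0.307411,0.217627,0.301049
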