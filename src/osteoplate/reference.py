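"""Reference-cohort PCA results and plate fixtures used as package defaults.

All numbers come from a reference study of 100 adult right femurs: the
principal-component loading matrices of the proximal (4 x 9) and distal
(7 x 16) parameter blocks, the variance contribution rates of the retained
components, the 12-curve adjacency matrix of the eagle-shaped plate
skeleton, and three instantiated plate parameter sets (Plates A/B/C).

The distal table is shipped verbatim as printed.  Its seventh column is a
per-variable communality column (its squared norm is far above one and it
contains the value 1.588), not a loading vector; numeric consumers should
use :func:`distal_loadings_usable` which returns the six genuine columns.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PROXIMAL_LOADINGS",
    "DISTAL_LOADINGS_PRINTED",
    "PROXIMAL_RATES",
    "DISTAL_RATES",
    "PROXIMAL_CUMULATIVE",
    "DISTAL_CUMULATIVE",
    "EAGLE_ADJACENCY",
    "PLATE_A",
    "PLATE_B",
    "PLATE_C",
    "distal_loadings_usable",
]

# Proximal loading matrix a_ij: variables X1..X9 (rows) x components 1..4
# (columns).  Columns are the unit eigenvectors of the proximal correlation
# matrix.
PROXIMAL_LOADINGS = np.array([
    [0.348, 0.291, 0.384, 0.289],
    [-0.070, 0.448, 0.606, 0.137],
    [0.223, -0.571, -0.058, 0.283],
    [0.243, -0.441, 0.353, 0.457],
    [0.466, 0.058, -0.010, -0.178],
    [0.446, 0.137, -0.140, -0.156],
    [0.450, 0.108, -0.177, -0.004],
    [0.275, 0.326, -0.421, 0.273],
    [0.269, -0.233, 0.359, -0.691],
])

# Distal loading matrix b_ij as printed: variables Y1..Y16 (rows) x 7 columns.
# Column 7 is a communality column (see module docstring).
DISTAL_LOADINGS_PRINTED = np.array([
    [-0.020, -0.065, -0.069, -0.164, 0.157, 0.951, 0.944],
    [0.425, -0.033, -0.185, 0.092, -0.094, 0.022, 0.866],
    [0.425, -0.033, -0.185, 0.092, -0.094, 0.021, 0.866],
    [0.230, -0.244, 0.227, -0.230, 0.431, -0.140, 0.988],
    [0.268, -0.032, 0.357, -0.207, 0.384, -0.101, 0.984],
    [0.420, -0.068, -0.198, 0.086, -0.095, 0.018, 0.867],
    [0.427, -0.013, -0.174, 0.096, -0.094, 0.022, 0.862],
    [-0.059, -0.486, -0.212, -0.101, -0.043, -0.053, 0.861],
    [0.040, 0.489, 0.207, 0.080, 0.020, 0.016, 0.794],
    [-0.042, -0.138, 0.171, 0.581, 0.279, 0.053, 0.668],
    [-0.007, -0.142, 0.064, 0.607, 0.309, 0.105, 0.819],
    [0.001, 0.106, -0.472, -0.159, 0.606, -0.166, 0.747],
    [0.162, -0.254, 0.535, -0.041, -0.192, 0.019, 0.979],
    [0.278, 0.393, 0.082, 0.124, -0.037, 0.043, 0.812],
    [-0.202, 0.115, -0.182, 0.251, -0.011, -0.106, 1.588],
    [0.062, 0.415, 0.090, -0.128, 0.163, 0.079, 0.905],
])

# Variance contribution rates (fractions of total block variance).
PROXIMAL_RATES = np.array([0.43054, 0.25449, 0.14176, 0.07795])
DISTAL_RATES = np.array([0.31338, 0.22293, 0.11936, 0.09589, 0.07630, 0.06112, 0.04343])
PROXIMAL_CUMULATIVE = 0.90474
DISTAL_CUMULATIVE = 0.93241


def distal_loadings_usable() -> np.ndarray:
    """The six genuine distal loading columns (16 x 6), excluding the
    communality column printed in position 7."""
    return DISTAL_LOADINGS_PRINTED[:, :6].copy()


# 12 x 12 adjacency matrix of the eagle-plate skeleton curves C0..C11.
# C0 is the closed boundary; C1/C2 the tail/head ridge curves; C3..C11 the
# costal curves.  Upper triangle as published, mirrored to full symmetry.
_UPPER = [
    ["B", "BI_11", "BI_11", "BI_21", "BI_21", "BI_21", "BI_21", "BI_21", "BI_21", "BI_21", "BI_21", "BI_21"],
    [None, "I", "II_11", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0", "II_12", "II_13", "II_13"],
    [None, None, "I", "II_13", "II_13", "II_13", "II_13", "II_13", "II_13", "II_12", "II_0", "II_0"],
    [None, None, None, "I", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0"],
    [None, None, None, None, "I", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0"],
    [None, None, None, None, None, "I", "II_0", "II_0", "II_0", "II_0", "II_0", "II_0"],
    [None, None, None, None, None, None, "I", "II_0", "II_0", "II_0", "II_0", "II_0"],
    [None, None, None, None, None, None, None, "I", "II_0", "II_0", "II_0", "II_0"],
    [None, None, None, None, None, None, None, None, "I", "II_0", "II_0", "II_0"],
    [None, None, None, None, None, None, None, None, None, "I", "II_0", "II_0"],
    [None, None, None, None, None, None, None, None, None, None, "I", "II_0"],
    [None, None, None, None, None, None, None, None, None, None, None, "I"],
]


def _symmetrize(upper):
    n = len(upper)
    out = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(i, n):
            out[i][j] = upper[i][j]
            out[j][i] = upper[i][j]
    return out


EAGLE_ADJACENCY: list[list[str]] = _symmetrize(_UPPER)

# Instantiated eagle plates (all dimensions mm).  The published lists repeat
# the key h2; the second occurrence is read as h6, the only missing index in
# the h2..h8 run.
PLATE_A = {
    "l1": 229.0, "l2": 39.0, "w0": 12.0, "w1": 14.0, "w2": 16.0, "w5": 29.0,
    "w7": 13.0, "h2": 1.6, "h3": 2.4, "h4": 7.9, "h5": 8.3, "h6": 5.2,
    "h7": 0.8, "h8": 0.7, "t1": 3.0, "t2": 3.0, "d1": 7.0, "d2": 5.0,
    "d3": 5.0, "s1": 6.0,
}
PLATE_B = {
    "l1": 204.0, "l2": 44.0, "w0": 12.0, "w1": 14.0, "w2": 15.0, "w5": 25.0,
    "w7": 13.0, "h2": 1.5, "h3": 2.2, "h4": 7.2, "h5": 8.6, "h6": 5.3,
    "h7": 1.0, "h8": 0.9, "t1": 3.0, "t2": 3.0, "d1": 7.0, "d2": 5.0,
    "d3": 5.0, "s1": 6.0,
}
PLATE_C = {
    "l1": 248.0, "l2": 40.0, "w0": 12.0, "w1": 14.0, "w2": 17.0, "w5": 33.0,
    "w7": 14.0, "h2": 1.4, "h3": 2.8, "h4": 7.3, "h5": 8.0, "h6": 4.7,
    "h7": 1.2, "h8": 1.3, "t1": 3.0, "t2": 3.0, "d1": 7.0, "d2": 5.0,
    "d3": 5.0, "s1": 6.0,
}
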