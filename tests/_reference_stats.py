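"""Test-local reference implementations of the neutrality statistics.

Written as literal transcriptions of the original published formulas,
deliberately kept independent of the package code paths: pairwise
differences are enumerated pair by pair, constants are computed with
plain Python floats, and no package helper is imported.
"""

import math


def ref_pi(matrix) -> float:
    """Mean pairwise differences by explicit enumeration of all pairs."""
    n = len(matrix)
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for a, b in zip(matrix[i], matrix[j]) if a != b)
            npairs += 1
    return total / npairs


def ref_tajimas_D(matrix) -> float:
    n = len(matrix)
    S = len(matrix[0])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = ref_pi(matrix)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def ref_fu_li_Dstar(matrix) -> float:
    """Fu & Li (1993) D* without outgroup, with the corrected v* constant."""
    n = len(matrix)
    eta = len(matrix[0])
    eta_s = 0
    for col in range(eta):
        ones = sum(row[col] for row in matrix)
        if ones == 1:
            eta_s += 1
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    an1 = a1 + 1.0 / n
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    vstar = (
        (n / (n - 1.0)) ** 2 * a2
        + a1**2 * dn
        - 2.0 * (n * a1 * (a1 + 1)) / (n - 1.0) ** 2
    ) / (a1**2 + a2)
    ustar = (n / (n - 1.0)) * (a1 - n / (n - 1.0)) - vstar
    num = (n / (n - 1.0)) * eta - a1 * eta_s
    return num / math.sqrt(ustar * eta + vstar * eta**2)
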