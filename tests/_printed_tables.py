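"""Published reference tables, frozen for cell-for-cell comparison.

Values are dicts mapping M -> list of cell values for N = 0..M (gamma_c
tables) or N = 0..min(M, 5) (p-value tables, whose published form covers
N <= 5).
"""

# gamma_c (percent) from two-sided 95% intervals, alpha=0.05, beta=1
GAMMA_TWO_SIDED = {
    1: [0, 0],
    2: [0, 0, 11.4],
    3: [0, 0, 4.7, 25.5],
    4: [0, 0, 1.9, 15.2, 36.6],
    5: [0, 0, 0.3, 10.2, 24.6, 45.1],
    6: [0, 0, 0, 7.2, 18.2, 32.5, 51.7],
    7: [0, 0, 0, 5.2, 14.1, 25.3, 39.1, 56.9],
    8: [0, 0, 0, 3.7, 11.3, 20.5, 31.5, 44.6, 61.1],
    9: [0, 0, 0, 2.6, 9.2, 17.1, 26.2, 36.8, 49.2, 64.6],
    10: [0, 0, 0, 1.8, 7.5, 14.4, 22.4, 31.3, 41.5, 53.2, 67.5],
}

# gamma_c (percent) from one-sided 95% lower bounds, alpha=0.05, beta=1
GAMMA_ONE_SIDED = {
    1: [0, 0],
    2: [0, 0, 18.3],
    3: [0, 0, 9.0, 33.5],
    4: [0, 0, 5.0, 20.9, 44.5],
    5: [0, 0, 2.8, 14.7, 30.8, 52.6],
    6: [0, 0, 1.4, 10.9, 23.3, 38.8, 58.6],
    7: [0, 0, 0.4, 8.3, 18.5, 30.7, 45.2, 63.4],
    8: [0, 0, 0, 6.4, 15.0, 25.2, 36.9, 50.5, 67.1],
    9: [0, 0, 0, 5.0, 12.5, 21.2, 31.0, 42.1, 54.8, 70.2],
    10: [0, 0, 0, 3.9, 10.5, 18.2, 26.7, 36.1, 46.6, 58.5, 72.8],
}

# one-sided p-values under the majority null (gamma0=0.5, p0=0.525)
PVALUES_MAJORITY_NULL = {
    1: [1, 0.525],
    2: [1, 0.7744, 0.2756],
    3: [1, 0.8928, 0.5375, 0.1447],
    4: [1, 0.9491, 0.7240, 0.3509, 0.076],
    5: [1, 0.9758, 0.8422, 0.5468, 0.2203, 0.0399],
    6: [1, 0.9885, 0.9123, 0.7019, 0.3917, 0.1346],
    7: [1, 0.9945, 0.9523, 0.8124, 0.5546, 0.2696],
    8: [1, 0.9974, 0.9745, 0.8859, 0.6899, 0.4192],
    9: [1, 0.9988, 0.9865, 0.9324, 0.7928, 0.5613],
    10: [1, 0.9994, 0.993, 0.9608, 0.8661, 0.6828],
}

# one-sided p-values under the global null (gamma0=0, p0=0.05)
PVALUES_GLOBAL_NULL = {
    1: [1, 0.05],
    2: [1, 0.0975, 0.0025],
    3: [1, 0.1426, 0.0073, 0.0001],
    4: [1, 0.1855, 0.0140, 0.0005, 6.25e-6],
    5: [1, 0.2262, 0.0226, 0.0011, 3.00e-5, 3.13e-7],
    6: [1, 0.2649, 0.0328, 0.0022, 8.64e-5, 1.80e-6],
    7: [1, 0.3017, 0.0444, 0.0038, 0.0001, 6.03e-6],
    8: [1, 0.3366, 0.0572, 0.0058, 0.0003, 1.54e-5],
    9: [1, 0.3698, 0.0712, 0.0084, 0.0006, 3.32e-5],
    10: [1, 0.4013, 0.0861, 0.0115, 0.001, 6.37e-5],
}


def last_place_unit(printed: float) -> float:
    """One unit in the last decimal place at which ``printed`` is stated."""
    from decimal import Decimal

    exponent = Decimal(str(printed)).normalize().as_tuple().exponent
    return float(Decimal(1).scaleb(exponent))
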