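"""Straight-line transcription of the persistence/attractivity/moment
formulas, written independently of bdchain.criteria as a cross-check.

Sup/inf are read directly off the (midline, amplitude) fields of the
sinusoid coefficients as c + |b| and c - |b|; every formula is spelled
out in one expression with no shared helpers.
"""


def _sup(coeff):
    return coeff.midline + abs(coeff.amplitude)


def _inf(coeff):
    return coeff.midline - abs(coeff.amplitude)


def reference_all(params, p=2.0, weights=(1.0, 1.0, 1.0)):
    r1m, r1l = _sup(params.r1), _inf(params.r1)
    r2m, r2l = _sup(params.r2), _inf(params.r2)
    r3m, r3l = _sup(params.r3), _inf(params.r3)
    a11m, a11l = _sup(params.a11), _inf(params.a11)
    a22m, a22l = _sup(params.a22), _inf(params.a22)
    a33m, a33l = _sup(params.a33), _inf(params.a33)
    a12m = _sup(params.a12)
    a21m, a21l = _sup(params.a21), _inf(params.a21)
    a23m = _sup(params.a23)
    a32m, a32l = _sup(params.a32), _inf(params.a32)
    b1m, b1l = _sup(params.beta1), _inf(params.beta1)
    b2m, b2l = _sup(params.beta2), _inf(params.beta2)
    g1m, g1l = _sup(params.gamma1), _inf(params.gamma1)
    g2m, g2l = _sup(params.gamma2), _inf(params.gamma2)
    s1m, s1l = _sup(params.sigma1), _inf(params.sigma1)
    s2m, s2l = _sup(params.sigma2), _inf(params.sigma2)
    s3m, s3l = _sup(params.sigma3), _inf(params.sigma3)

    M1 = (r1m - 0.5 * s1l**2) / a11l
    M2 = (-r2l + a21m / b1l - 0.5 * s2l**2) / a22l
    M3 = (-r3l + a32m / b2l - 0.5 * s3l**2) / a33l
    m1 = (r1l - a12m / g1l - 0.5 * s1m**2) / a11m
    m2 = (-r2m + a21l * m1 / (1 + b1m * M1 + g1m * M2) - a23m / g2l - 0.5 * s2m**2) / a22m
    m3 = (-r3m + a32l * m2 / (1 + b2m * M2 + g2m * M3) - 0.5 * s3l**2) / a33m

    margins = {
        "H1": r1m - 0.5 * s1l**2,
        "H2": a21m / b1l - (r2l + 0.5 * s2l**2),
        "H3": a32m / b2l - (r3l + 0.5 * s3l**2),
        "H4": r1l - (a12m / g1l + 0.5 * s1m**2),
        "H5": a21l * m1 / (1 + b1m * M1 + g1m * M2)
        - (r2m + a23m / g2l + 0.5 * s2m**2),
        "H6": a32l * m2 / (1 + b2m * M2 + g2m * M3) - (r3m + 0.5 * s3m**2),
    }

    l1, l2, l3 = weights
    D1 = 1 + b1l * m1 + g1l * m2
    D2 = 1 + b2l * m2 + g2l * m3
    A = l1 * a11l - l1 * a12m * b1m * M2 / D1**2 - l2 * (a21m + a21m * g1m * M2) / D1**2
    B = (
        l2 * a22l
        - l1 * (a12m + a12m * b1m * M1) / D1**2
        - l2 * a23m * b2m * M3 / D2**2
        - l2 * a21m * g1m * M1 / D1**2
        - l3 * (a32m + a32m * g2m * M3) / D2**2
    )
    C = l3 * a33l - l2 * (a23m + a23m * b2m * M2) / D2**2 - l3 * a32m * g2m * M2 / D2**2

    L1 = (1 + r1m * p + 0.5 * p**2 * s1m**2) ** (p + 1) / ((p + 1) ** (p + 1) * a11l**p)
    G1 = (1 - r2l * p + (a21m / b1l) * p + 0.5 * p**2 * s2m**2) ** (p + 1) / (
        (p + 1) ** (p + 1) * a22l**p
    )
    F1 = (1 - r3l * p + (a32m / b2l) * p + 0.5 * p**2 * s3m**2) ** (p + 1) / (
        (p + 1) ** (p + 1) * a33l**p
    )

    return {
        "bounds": {"M1": M1, "M2": M2, "M3": M3, "m1": m1, "m2": m2, "m3": m3},
        "margins": margins,
        "attractivity": {"A": A, "B": B, "C": C},
        "moments": {"L1": L1, "G1": G1, "F1": F1},
    }
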