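"""Independent brute-force oracles: literal nested-loop transcriptions of the
defining formulas, kept deliberately free of numpy vectorization and of any
code path shared with the package implementation."""

import math


def viola_envelope_literal(x, w):
    """Windowed variance with mean removal, valid indices only."""
    m = len(x)
    width = 2 * w + 1
    out = []
    for n in range(w, m - w):
        mean = sum(x[k] for k in range(n - w, n + w + 1)) / width
        out.append(sum((x[k] - mean) ** 2 for k in range(n - w, n + w + 1)) / width)
    return out


def stmht_kernel_literal(n):
    kernel = []
    for i in range(n):
        if i == (n - 1) // 2:
            kernel.append(0.0)
        else:
            a = n - 1 - 2 * i
            kernel.append(
                (math.cos(a * math.pi / (2 * n)) - math.cos(a * math.pi / 2))
                / (n * math.sin(a * math.pi / (2 * n)))
            )
    return kernel


def stmht_literal(env, n):
    """Moving antisymmetric-kernel sum with a rectangular window, valid range."""
    kernel = stmht_kernel_literal(n)
    half = (n - 1) // 2
    m = len(env)
    out = []
    for center in range(half, m - half):
        acc = 0.0
        for k in range(center - half, center + half + 1):
            acc += env[k] * 1.0 * kernel[k - (center - half)]
        out.append(acc)
    return out


def dft_magnitude_literal(x):
    """O(M^2) magnitude DFT restricted to the half spectrum."""
    m = len(x)
    out = []
    for k in range(m // 2 + 1):
        re = sum(x[l] * math.cos(2 * math.pi * k * l / m) for l in range(m))
        im = -sum(x[l] * math.sin(2 * math.pi * k * l / m) for l in range(m))
        out.append(math.hypot(re, im))
    return out


def _reflect(i, n):
    """Index into [0, n) by mirror reflection without edge repetition."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i %= period
    return i if i < n else period - i


def secondary_envelope_literal(values, l1, l2):
    """Triangular outer window minus inner rectangular window, normalized
    to a unit maximum; reflected padding at the edges; empty inner range
    (l1 <= l2) contributes nothing."""
    n = len(values)
    denom = (2 * l1 + 1) * (2 * l2 + 1)
    raw = []
    for k in range(n):
        acc = 0.0
        for off in range(-(l1 + l2), l1 + l2 + 1):
            acc += (l1 + l2 + 1 - abs(off)) * values[_reflect(k + off, n)]
        inner = l1 - l2 - 1
        if inner >= 0:
            for off in range(-inner, inner + 1):
                acc -= values[_reflect(k + off, n)]
        raw.append(acc / denom)
    peak = max(raw)
    return [v / peak for v in raw]


def gravity_literal(env_values, bin_hz):
    num = sum(k * v for k, v in enumerate(env_values))
    den = sum(env_values)
    return num / den * bin_hz


def widths_literal(env_values, bin_hz, thv_list):
    out = []
    for thv in thv_list:
        above = [k for k, v in enumerate(env_values) if v > thv]
        out.append(0.0 if not above else (above[-1] - above[0]) * bin_hz)
    return out


def mahalanobis_sq_literal(x, mu, sigma):
    """Quadratic form via explicit 3x3 adjugate inversion."""
    d = [x[i] - mu[i] for i in range(3)]
    a, b, c = sigma[0]
    d2, e, f = sigma[1]
    g, h, i = sigma[2]
    det = a * (e * i - f * h) - b * (d2 * i - f * g) + c * (d2 * h - e * g)
    inv = [
        [(e * i - f * h) / det, (c * h - b * i) / det, (b * f - c * e) / det],
        [(f * g - d2 * i) / det, (a * i - c * g) / det, (c * d2 - a * f) / det],
        [(d2 * h - e * g) / det, (b * g - a * h) / det, (a * e - b * d2) / det],
    ]
    return sum(d[r] * inv[r][s] * d[s] for r in range(3) for s in range(3))


def project_literal(ff, mu_ff, sigma_ff, eigenvectors, m):
    """Standardize then dot with each retained loading vector, elementwise."""
    z = [(ff[j] - mu_ff[j]) / sigma_ff[j] for j in range(len(ff))]
    return [sum(z[j] * eigenvectors[i][j] for j in range(len(z))) for i in range(m)]
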