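"""Independent straight-loop reference implementations.

Deliberately naive: plain Python loops and ``numpy.polyfit`` per window,
sharing no code with the package internals, so they can serve as oracles
for the vectorized implementations.
"""

import numpy as np


def profile_loop(z):
    z = np.asarray(z, float)
    mean = sum(z) / len(z)
    out = []
    acc = 0.0
    for v in z:
        acc += v - mean
        out.append(acc)
    return np.array(out)


def windows_loop(N, n):
    """Forward then backward half-open windows, each of length n."""
    n_seg = N // n
    out = []
    for j in range(1, n_seg + 1):          # forward: Z_{(j-1)n + k}, k=1..n
        out.append(((j - 1) * n, (j - 1) * n + n))
    for j in range(n_seg + 1, 2 * n_seg + 1):  # backward: Z_{N-(j-N_n)n + k}
        m = j - n_seg
        out.append((N - m * n, N - m * n + n))
    return out


def detrended_windows_loop(z, n, order):
    """List of detrended profile windows (residuals of a per-window polyfit)."""
    prof = profile_loop(z)
    res = []
    x = np.arange(1, n + 1, dtype=float)
    for a, b in windows_loop(len(prof), n):
        seg = prof[a:b]
        coef = np.polyfit(x, seg, order)
        res.append(seg - np.polyval(coef, x))
    return res


def dfa_variance_loop(z, n, order=2):
    segs = detrended_windows_loop(z, n, order)
    return float(np.mean([np.sum(s * s) / n for s in segs]))


def dcca_covariance_loop(a, b, n, order=2):
    sa = detrended_windows_loop(a, n, order)
    sb = detrended_windows_loop(b, n, order)
    return float(np.mean([np.sum(u * v) / n for u, v in zip(sa, sb)]))


def rho_dcca_loop(a, b, n, order=2):
    return dcca_covariance_loop(a, b, n, order) / np.sqrt(
        dfa_variance_loop(a, n, order) * dfa_variance_loop(b, n, order)
    )


def dfa_betas_loop(y, x1, x2, n, order=2):
    """Scale-dependent coefficients assembled by hand from loop fluctuations."""
    f11 = dfa_variance_loop(x1, n, order)
    f22 = dfa_variance_loop(x2, n, order)
    f12 = dcca_covariance_loop(x1, x2, n, order)
    f1y = dcca_covariance_loop(x1, y, n, order)
    f2y = dcca_covariance_loop(x2, y, n, order)
    det = f11 * f22 - f12**2
    return (
        (f1y * f22 - f2y * f12) / det,
        (f2y * f11 - f1y * f12) / det,
    )


def rho_pdcca_3x3_loop(series, i, j, n, order=2):
    """Partial DCCA for three series via explicit adjugate of the 3x3 matrix."""
    assert len(series) == 3
    R = np.eye(3)
    for a in range(3):
        for b in range(a + 1, 3):
            R[a, b] = R[b, a] = rho_dcca_loop(series[a], series[b], n, order)
    det = np.linalg.det(R)
    # inverse via adjugate: C[a,b] = cofactor(b,a) / det
    C = np.empty((3, 3))
    for a in range(3):
        for b in range(3):
            minor = np.delete(np.delete(R, a, axis=0), b, axis=1)
            C[b, a] = (-1) ** (a + b) * np.linalg.det(minor) / det
    return -C[i, j] / np.sqrt(C[i, i] * C[j, j])
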