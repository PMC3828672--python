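"""Construct the orthogonal wavelet filter banks used by the package.

Generates the decomposition low-pass filters for the ten mother wavelets
(haar, db2/4/6, sym2/4/6, coif2/4/5) from first principles and prints them
as a Python table ready to paste into ``src/muhit/_filters.py``:

* Daubechies: spectral factorization of the maximally-flat half-band
  polynomial, keeping the minimum-phase (inside-unit-circle) roots.
* Symlets: same half-band polynomial, but the spectral factor is chosen
  among all conjugate-consistent root selections as the one with the most
  linear phase (least-asymmetric factorization).
* Coiflets: direct Newton solve of the defining equations (orthonormality,
  2K vanishing wavelet moments, 2K-1 vanishing scaling-function moments
  about the tap center), seeded from the symlet of the same length.

Run:  python scripts/make_filters.py
"""

import numpy as np
from scipy.optimize import least_squares
from scipy.special import comb


def _halfband_roots(p):
    """Roots (in z) of the degree-2(p-1) polynomial z^(p-1) P((2-z-1/z)/4).

    P(y) = sum_k C(p-1+k, k) y^k is the maximally flat half-band factor.
    Roots come in reciprocal pairs (r, 1/r).
    """
    # Build the Laurent polynomial in z: P evaluated at y = (2 - z - z^-1)/4,
    # multiplied by z^(p-1) to clear negative powers.
    coeffs = np.zeros(2 * p - 1)
    for k in range(p):
        c = comb(p - 1 + k, k, exact=True)
        # y^k = ((2 - z - z^-1)/4)^k -> polynomial in z of degree 2k, centered
        yk = np.array([1.0])
        base = np.array([-1.0, 2.0, -1.0]) / 4.0  # -z/4 + 1/2 - z^-1/4
        for _ in range(k):
            yk = np.convolve(yk, base)
        # center yk (length 2k+1) at the middle of coeffs (index p-1)
        lo = (p - 1) - k
        coeffs[lo:lo + 2 * k + 1] += c * yk
    return np.roots(coeffs[::-1])  # ascending -> np.roots wants descending


def _filter_from_roots(selected, p):
    """Assemble h from ((1+z)/2)^p times the chosen spectral-factor roots."""
    poly = np.array([1.0 + 0.0j])
    for r in selected:
        poly = np.convolve(poly, np.array([1.0, -r]))
    for _ in range(p):
        poly = np.convolve(poly, np.array([0.5, 0.5]))
    h = np.real(poly)
    h *= np.sqrt(2.0) / h.sum()
    return h


def daubechies(p):
    roots = _halfband_roots(p)
    inside = roots[np.abs(roots) < 1.0]
    h = _filter_from_roots(inside, p)
    # convention: largest-magnitude taps toward the front (matches the
    # standard published orientation for db filters)
    if np.argmax(np.abs(h)) > len(h) // 2:
        h = h[::-1]
    return h


def _phase_nonlinearity(h):
    """RMS deviation of the unwrapped phase from the best linear fit."""
    w = np.linspace(0.05, np.pi - 0.05, 256)
    H = np.polyval(h[::-1], np.exp(-1j * w))
    ph = np.unwrap(np.angle(H))
    A = np.vstack([w, np.ones_like(w)]).T
    resid = ph - A @ np.linalg.lstsq(A, ph, rcond=None)[0]
    return float(np.sqrt(np.mean(resid ** 2)))


def symlet(p):
    """Least-asymmetric spectral factor: enumerate conjugate-consistent
    root selections and keep the most linear-phase real filter."""
    roots = _halfband_roots(p)
    inside = roots[np.abs(roots) < 1.0]
    # group inside roots into conjugate pairs / real singletons
    groups, used = [], np.zeros(len(inside), bool)
    for i, r in enumerate(inside):
        if used[i]:
            continue
        used[i] = True
        if abs(r.imag) < 1e-9:
            groups.append([r])
        else:
            j = np.argmin(np.abs(inside - np.conj(r)) + used * 1e9)
            used[j] = True
            groups.append([r, inside[j]])
    best, best_score = None, np.inf
    for mask in range(1 << len(groups)):
        sel = []
        for g, grp in enumerate(groups):
            if mask >> g & 1:
                sel.extend(1.0 / np.asarray(grp))  # flip pair outside
            else:
                sel.extend(grp)
        h = _filter_from_roots(sel, p)
        score = _phase_nonlinearity(h)
        if score < best_score:
            best_score, best = score, h
    if np.argmax(np.abs(best)) < len(best) // 2:
        best = best[::-1]
    return best


def _coiflet_residuals(h, K):
    """Defining equations: orthonormality, 2K vanishing wavelet moments,
    2K-1 vanishing scaling moments.  In the stored (decomposition, i.e.
    time-reversed) orientation the moment center of the canonical coiflet
    sits at tap 4K-1.  Moments are centered and scaled by 2K for
    conditioning (vanishing is invariant under both)."""
    L, c = 6 * K, 4 * K - 1
    res = [h.sum() - np.sqrt(2.0)]
    for k in range(1, 3 * K):
        res.append(np.dot(h[:-2 * k], h[2 * k:]))
    res.append(np.dot(h, h) - 1.0)
    n = (np.arange(L) - c) / (2.0 * K)
    sgn = (-1.0) ** np.arange(L)
    for j in range(2 * K):                # wavelet vanishing moments
        res.append(np.dot(sgn * n ** j, h))
    for j in range(1, 2 * K):             # scaling moments
        res.append(np.dot(n ** j, h))
    return np.array(res)


def coiflet(K, h0=None):
    """Solve the coiflet defining equations for the length-6K filter.

    Seeded by continuation from the next-lower coiflet order (coif2 is
    seeded from the length-12 symlet); Levenberg-Marquardt on the
    overdetermined-but-consistent system.
    """
    L, c = 6 * K, 4 * K - 1
    if h0 is None:
        if K <= 2:
            s = symlet(3 * K)
            h0 = np.zeros(L)
            shift = c - int(np.argmax(np.abs(s)))
            h0[shift:shift + len(s) - shift] = s[:L - shift]
        else:
            prev = coiflet(K - 1)
            h0 = np.zeros(L)
            off = c - (4 * (K - 1) - 1)
            h0[off:off + len(prev)] = prev
    sol = least_squares(_coiflet_residuals, h0, args=(K,), method="lm",
                        xtol=1e-15, ftol=1e-15, max_nfev=50000)
    h = sol.x
    resid = np.max(np.abs(_coiflet_residuals(h, K)))
    if resid > 1e-10:
        raise RuntimeError(f"coif{K} solve failed, residual {resid:.2e}")
    return h


def main():
    filters = {
        "haar": np.array([1.0, 1.0]) / np.sqrt(2.0),
        "db2": daubechies(2),
        "db4": daubechies(4),
        "db6": daubechies(6),
        "sym2": symlet(2),
        "sym4": symlet(4),
        "sym6": symlet(6),
        "coif2": coiflet(2),
        "coif4": coiflet(4),
        "coif5": coiflet(5),
    }
    print("DEC_LO = {")
    for name, h in filters.items():
        vals = ",\n        ".join(
            ", ".join(f"{v: .17e}" for v in h[i:i + 3])
            for i in range(0, len(h), 3)
        )
        print(f'    "{name}": [\n        {vals},\n    ],')
    print("}")
    # sanity report
    for name, h in filters.items():
        orth = max(
            abs(np.dot(h[:-2 * k], h[2 * k:]) - 0.0)
            for k in range(1, len(h) // 2)
        ) if len(h) > 2 else 0.0
        print(f"# {name}: len={len(h)} sum-sqrt2={h.sum()-np.sqrt(2):.1e} "
              f"norm-1={h @ h - 1:.1e} orth={orth:.1e}")


if __name__ == "__main__":
    main()
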