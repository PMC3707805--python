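"""Independent brute-force / symbolic oracles used only by the test suite.

Each oracle is written from the defining formula, independently of the
package's vectorised implementations.
"""

from fractions import Fraction
from math import factorial, sqrt

import numpy as np


def kendall_tau_b_bruteforce(x, y) -> float:
    """Tau-B by O(n^2) enumeration of concordant/discordant pairs."""
    x = list(x)
    y = list(y)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom


def wc_theta_symbolic(counts1, counts2):
    """Two-population WC84 theta from genotype counts, in exact rationals.

    ``counts`` are (n_AA, n_AB, n_BB) with the dosage-coded alternate allele
    counted. Returns (a, b, c, theta) as Fractions (theta None when
    a+b+c == 0).
    """
    pops = [tuple(Fraction(c) for c in counts) for counts in (counts1, counts2)]
    r = Fraction(2)
    n = [sum(c) for c in pops]
    p = [(2 * c[2] + c[1]) / (2 * ni) for c, ni in zip(pops, n)]
    h = [c[1] / ni for c, ni in zip(pops, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    tot = a + b + c
    return a, b, c, (a / tot if tot != 0 else None)


def local_moran_bruteforce(chrom, pos, z, window_bp) -> np.ndarray:
    """Plain double-loop local Moran's I with genome-wide moments."""
    z = np.asarray(z, dtype=float)
    n_total = len(z)
    zbar = z.mean()
    s2 = z.var()
    out = np.full(n_total, np.nan)
    for i in range(n_total):
        neigh = [
            j
            for j in range(n_total)
            if j != i and chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp
        ]
        n_i = len(neigh) + 1  # markers within the window, including i
        if n_i < 2:
            continue
        s = sum(z[j] - zbar for j in neigh)
        out[i] = n_i / ((n_i - 1) * s2) * (z[i] - zbar) * s
    return out


def hwe_exact_enumeration(n_het, n_hom1, n_hom2) -> float:
    """Exact HWE p by exhaustive enumeration with rational arithmetic."""
    n = n_het + n_hom1 + n_hom2
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het
    if n == 0 or min(na, nb) == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        ha, hb = (na - h) // 2, (nb - h) // 2
        return Fraction(
            factorial(n) * 2**h * factorial(na) * factorial(nb),
            factorial(ha) * factorial(h) * factorial(hb) * factorial(2 * n),
        )

    rare = min(na, nb)
    hs = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hs}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def centred_gram(genotypes) -> np.ndarray:
    """Centred genotype Gram matrix over the SNP count (complete data)."""
    g = np.asarray(genotypes, dtype=float)
    gc = g - g.mean(axis=0)
    return gc @ gc.T / g.shape[1]
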