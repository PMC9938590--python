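"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation under test: direct formula evaluation with numerically
integrated distribution tails, all-pairs interval scans, per-base signal
summation, exhaustive subset enumeration, and a literal transcription of the
high-confidence filtering clauses.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def welch_oracle(x, y) -> tuple[float, float, float]:
    """Welch t, df and two-sided p by direct formulas + numerical integration.

    The t-distribution tail is integrated from the density written out with
    log-gamma functions — no use of any library t-distribution.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return (0.0, float(nx + ny - 2), 1.0) if mx == my else \
            (math.inf if mx > my else -math.inf, float(nx + ny - 2), 0.0)
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))

    def t_density(u: float) -> float:
        logc = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
                - 0.5 * math.log(df * math.pi))
        return math.exp(logc - (df + 1) / 2 * math.log1p(u * u / df))

    tail, _ = quad(t_density, abs(t), math.inf, epsabs=0.0, epsrel=1e-13,
                   limit=500)
    return t, df, 2.0 * tail


def overlap_bruteforce(query, target) -> int:
    """All-pairs O(n*m) count of query intervals overlapping >=1 target."""
    count = 0
    for qc, qs, qe in zip(query.chroms, query.starts, query.ends):
        hit = False
        for tc, ts, te in zip(target.chroms, target.starts, target.ends):
            if str(qc) == str(tc) and qs < te and ts < qe:
                hit = True
                break
        count += hit
    return count


def profile_row_oracle(track, chrom: str, mid: int, flank: int,
                       bin_size: int) -> np.ndarray:
    """Per-base summation of one region's binned profile."""
    n_bins = 2 * flank // bin_size
    # materialize per-base values over the window
    window_lo = mid - flank
    values = np.zeros(2 * flank)
    if chrom in track.data:
        s, e, v = track.data[chrom]
        for a, b, val in zip(s, e, v):
            lo = max(int(a), window_lo)
            hi = min(int(b), mid + flank)
            if lo < hi:
                values[lo - window_lo:hi - window_lo] += val
    return values.reshape(n_bins, bin_size).mean(axis=1)


def hypergeom_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(|draw ∩ reference| >= k) by enumerating all C(N, K) draws.

    The universe is 0..N-1 with the reference being the first n elements.
    """
    reference = set(range(n))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), K):
        total += 1
        if len(reference.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hci_clauses_oracle(k_nt: int, k_ct: int) -> bool:
    """Literal transcription of the filtering clauses: identified in at
    least two of six datasets, and per terminus in 0 (exclusive to the
    other terminus) or in >= 2 of 3 datasets."""
    at_least_two_of_six = (k_nt + k_ct) >= 2
    nt_ok = (k_nt == 0) or (k_nt >= 2)
    ct_ok = (k_ct == 0) or (k_ct >= 2)
    return at_least_two_of_six and nt_ok and ct_ok
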