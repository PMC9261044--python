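"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by direct enumeration, staying
independent of the library code paths they check.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def choi_wear_oracle(c, window, spike_tol, flank):
    """Direct forward-scan enumeration of candidate non-wear intervals.

    Starting at every zero minute, extend through zeros and through nonzero
    interruptions of <= spike_tol minutes whose flank-minute neighbourhoods
    on both sides are all zero; flag the span as non-wear when it reaches
    window minutes.  Returns a wear mask (True = worn).
    """
    n = len(c)
    wear = np.ones(n, np.bool_)
    i = 0
    while i < n:
        if c[i] != 0:
            i += 1
            continue
        j = i
        end = i
        while j < n:
            if c[j] == 0:
                j += 1
                end = j
                continue
            k = j
            while k < n and c[k] != 0:
                k += 1
            if k - j <= spike_tol:
                ok = (j - flank >= 0) and (k + flank <= n)
                if ok:
                    for t in range(j - flank, j):
                        if c[t] != 0:
                            ok = False
                            break
                if ok:
                    for t in range(k, k + flank):
                        if c[t] != 0:
                            ok = False
                            break
                if ok:
                    j = k
                    continue
            break
        if end - i >= window:
            wear[i:end] = False
        i = end if end > i else i + 1
    return wear


def random_count_series(rng, n=1440, max_zero_run=160, max_spike_run=4, max_count=500):
    """Minute counts mixing zero runs with short nonzero spike runs."""
    out = np.zeros(n, dtype=np.int64)
    pos = 0
    while pos < n:
        pos += int(rng.integers(1, max_zero_run))
        if pos >= n:
            break
        slen = min(int(rng.integers(1, max_spike_run + 1)), n - pos)
        out[pos : pos + slen] = rng.integers(1, max_count, size=slen)
        pos += slen
    return out


def point_in_polygon_bruteforce(lon, lat, polygons):
    """Containment by testing every polygon; boundary -> smallest matching id."""
    from shapely.geometry import Point

    hits = [da for da, poly in polygons.items() if poly.covers(Point(lon, lat))]
    return min(hits) if hits else None


def buffer_counts_bruteforce(centroid, points, radius_m):
    """Count points within radius by exhaustive distance checks."""
    if len(points) == 0:
        return 0
    d = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    return int((d <= radius_m).sum())
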