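"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately written from scratch against the plain
statement of each procedure — pairwise distance matrices, set-based
bookkeeping, no imports from the package internals beyond nothing at all —
so that agreement with the library is a meaningful check.
"""

import math

import numpy as np

EARTH_R = 6_371_000.0


def brute_haversine(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    s = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_R * math.asin(min(1.0, math.sqrt(s)))


def brute_pairwise(lat, lon) -> np.ndarray:
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dp = lat[:, None] - lat[None, :]
    dl = lon[:, None] - lon[None, :]
    s = (np.sin(dp / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dl / 2) ** 2)
    return 2 * EARTH_R * np.arcsin(np.sqrt(np.clip(s, 0, 1)))


def brute_single_linkage(lat, lon, threshold):
    """Union-find single-linkage clustering on the full distance matrix."""
    d = brute_pairwise(lat, lon)
    n = len(d)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < threshold:
                parent[find(i)] = find(j)
    roots = {}
    out = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out.append(roots[r])
    return out


def spacing_oracle(lat, lon, delta):
    """Literal transcription of the six-step greedy spacing procedure.

    Step 1: keep the first image.  Step 2: walk the chronologically ordered
    list, skipping removed images, until the first image at least delta
    from the last kept.  Step 3: keep it, or the not-removed image walked
    over immediately before it, whichever is closer to exactly delta (ties
    keep the later image).  Step 4: remove, among the images still to be
    considered, every image within delta/2 of the kept one.  Step 5: repeat
    from step 2 (the walk never restarts).  Step 6: keep the final image if
    it is at least delta/2 from every kept image.
    """
    d = brute_pairwise(lat, lon)
    n = len(d)
    if n == 1:
        return [0]
    kept = [0]
    removed = set()
    pos = 1
    while True:
        walked_over = None
        found = None
        while pos < n:
            if pos in removed:
                pos += 1
                continue
            if d[kept[-1], pos] >= delta:
                found = pos
                break
            walked_over = pos
            pos += 1
        if found is None:
            break
        pick = found
        if walked_over is not None:
            if (abs(d[kept[-1], walked_over] - delta)
                    < abs(d[kept[-1], found] - delta)):
                pick = walked_over
        kept.append(pick)
        pos = found if pick == walked_over else found + 1
        for j in range(pos, n):
            if j not in removed and d[pick, j] < delta / 2:
                removed.add(j)
    final = n - 1
    if final not in kept and all(d[final, k] >= delta / 2 for k in kept):
        kept.append(final)
    return sorted(kept)


def bilinear_oracle(x, y, x0, x1, y0, y1, q00, q01, q10, q11):
    """Closed-form bilinear interpolation over one cell."""
    tx = (x - x0) / (x1 - x0)
    ty = (y - y0) / (y1 - y0)
    return (q00 * (1 - tx) * (1 - ty) + q01 * (1 - tx) * ty
            + q10 * tx * (1 - ty) + q11 * tx * ty)
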