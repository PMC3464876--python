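"""Independent brute-force oracles shared by unit and acceptance tests.

Everything here is deliberately written as plain Python loops over explicit
definitions, sharing no code path with the package implementation.
"""

import math


def brute_scan(cuts, length, small, bg, step):
    """Per-window (start, n, N, z) by explicit counting."""
    out = []
    cuts = sorted(cuts)
    start = 0
    while start + small <= length:
        n = sum(1 for c in cuts if start <= c < start + small)
        center = start + small / 2
        lo, hi = max(center - bg / 2, 0), min(center + bg / 2, length)
        N = sum(1 for c in cuts if lo <= c < hi)
        p = small / (hi - lo)
        if N > 0 and p < 1:
            z = (n - N * p) / math.sqrt(N * p * (1 - p))
            out.append((start, n, N, z))
        start += step
    return out


def brute_call(cuts, length, small, bg, step, threshold, gap, lib_size, mode_filter=True):
    """Full brute-force hotspot call on one contig: threshold, merge, trim,
    density, mode filter."""
    windows = [(s, z) for s, n, N, z in brute_scan(cuts, length, small, bg, step)
               if z >= threshold]
    cuts = sorted(cuts)
    groups = []
    for s, z in windows:
        if groups and s - (groups[-1][-1][0] + small) <= gap:
            groups[-1].append((s, z))
        else:
            groups.append([(s, z)])
    hotspots = []
    for grp in groups:
        m_start, m_end = grp[0][0], grp[-1][0] + small
        inside = [c for c in cuts if m_start <= c < m_end]
        if not inside:
            continue
        t_start, t_end = inside[0], inside[-1] + 1
        count = len(inside)
        density = count / ((t_end - t_start) / 1000) / (lib_size / 1e6)
        hotspots.append(
            {"start": t_start, "end": t_end, "count": count, "density": density,
             "z": max(z for _, z in grp)}
        )
    if hotspots and mode_filter:
        idx = [math.floor(math.log10(h["density"]) / 0.1 + 1e-9) for h in hotspots]
        votes = {}
        for i in idx:
            votes[i] = votes.get(i, 0) + 1
        modal = min(i for i in votes if votes[i] == max(votes.values()))
        hotspots = [h for h, i in zip(hotspots, idx) if i >= modal]
    return hotspots


def brute_cpg_islands(seq, window=200, min_len=200, min_gc=0.5, min_oe=0.6):
    """Sliding-window island definition evaluated literally.

    str.count("CG") is exact here: CG occurrences cannot overlap.
    """
    qual = []
    for s in range(len(seq) - window + 1):
        w = seq[s : s + window]
        nC, nG = w.count("C"), w.count("G")
        nCG = w.count("CG")
        if nC + nG >= min_gc * window and nC * nG > 0 and nCG * window / (nC * nG) >= min_oe:
            qual.append(s)
    merged = []
    for s in qual:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = s + window
        else:
            merged.append([s, s + window])
    return [(a, b) for a, b in merged if b - a >= min_len]
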