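"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scan/dynamic-programming machinery:
repeat runs are enumerated per (position, unit length), and overlapping runs
are resolved by exhaustive (non-memoized) enumeration of every possible
tiling of the region.
"""

from __future__ import annotations

DEFAULT_THR = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


def _primitive(motif: str) -> bool:
    k = len(motif)
    return not any(k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k))


def _max_repeats(seq: str, i: int, motif: str) -> int:
    k = len(motif)
    r = 1
    while seq[i + r * k : i + (r + 1) * k] == motif:
        r += 1
    return r


def brute_force_candidates(seq: str, thr=DEFAULT_THR):
    """Every maximal primitive-motif run meeting its threshold.

    A run is maximal when it cannot be extended left: neither by a full
    motif copy nor by a single character of the same period (which would
    mean a longer run of a rotated motif starts earlier).
    """
    out = []
    n = len(seq)
    for i in range(n):
        for k in range(1, 7):
            motif = seq[i : i + k]
            if len(motif) < k or "N" in motif or not _primitive(motif):
                continue
            r = _max_repeats(seq, i, motif)
            if r < thr[k]:
                continue
            if i >= 1 and seq[i - 1] == motif[-1] and seq[i - 1] != "N":
                continue  # periodicity extends left: not the leftmost phase
            out.append((i, motif, r))
    return out


def _span_end(seq: str, i: int, motif: str, r: int) -> int:
    """Last position of the full periodic extension (incl. partial units)."""
    k = len(motif)
    t = i + r * k
    while t < len(seq) and seq[t] != "N" and seq[t] == seq[t - k]:
        t += 1
    return t - 1


def _all_tilings(seq: str, pos: int, end: int, thr):
    """Yield every tiling of seq[pos..end] as lists of (start, motif, r)."""
    if pos > end:
        yield []
        return
    # option: leave this residue uncovered
    for rest in _all_tilings(seq, pos + 1, end, thr):
        yield rest
    for k in range(1, 7):
        motif = seq[pos : pos + k]
        if len(motif) < k or "N" in motif or not _primitive(motif):
            continue
        r_max = _max_repeats(seq, pos, motif)
        r_max = min(r_max, (end - pos + 1) // k)
        for r in range(thr[k], r_max + 1):
            for rest in _all_tilings(seq, pos + r * k, end, thr):
                yield [(pos, motif, r)] + rest


def _tiling_key(tiling):
    # max covered, then fewest runs, then earliest-starting / longest runs
    covered = sum(len(m) * r for _, m, r in tiling)
    ordered = sorted(tiling)
    placement = tuple((-start, len(m) * r) for start, m, r in ordered)
    return (covered, -len(tiling), placement)


def brute_force_ssrs(seq: str, thr=DEFAULT_THR):
    """Expected miner output: maximal runs, overlaps resolved exhaustively."""
    seq = seq.upper()
    cands = sorted(
        (i, i + len(m) * r - 1, m, r) for i, m, r in brute_force_candidates(seq, thr)
    )
    clusters = []
    for cand in cands:
        if clusters and cand[0] <= max(c[1] for c in clusters[-1]):
            clusters[-1].append(cand)
        else:
            clusters.append([cand])
    out = []
    for cluster in clusters:
        if len(cluster) == 1:
            i, _, m, r = cluster[0]
            out.append((i, m, r))
            continue
        region_start = min(c[0] for c in cluster)
        region_end = max(_span_end(seq, c[0], c[2], c[3]) for c in cluster)
        best = max(_all_tilings(seq, region_start, region_end, thr), key=_tiling_key)
        out.extend(sorted(best))
    return sorted(out)


def best_exact_segmentation(segment: str, thr=DEFAULT_THR):
    """Optimal exact-cover key (n_components, lengths) or None.

    Enumerates every tiling of the whole segment into qualifying runs and
    returns (n_components, component length tuple) of the optimum: fewest
    components, then longest earliest component.
    """
    best = None
    for tiling in _all_tilings(segment, 0, len(segment) - 1, thr):
        if sum(len(m) * r for _, m, r in tiling) != len(segment):
            continue
        ordered = sorted(tiling)
        key = (-len(ordered), tuple(len(m) * r for _, m, r in ordered))
        if best is None or key > best:
            best = key
    if best is None:
        return None
    return (-best[0], best[1])
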