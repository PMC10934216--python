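"""Optimal segmentation of a repetitive region into adjacent perfect repeat runs.

A repetitive region is a stretch of sequence in which two or more maximal
tandem-repeat runs overlap (the situation MISA renders with shared-nucleotide
notation such as ``(GTAT)2(GTA<T>G)(TG)12``).  The segmentation below
re-describes such a region as plain adjacent perfect runs, preferring

1. maximal total covered length,
2. the fewest components,
3. the longest earliest component (lexicographically).

Both the miner (to resolve overlapping candidate runs) and the public
compound-normalization entry point use this dynamic program.
"""

from __future__ import annotations

from typing import Mapping, Sequence

MAX_MOTIF_LEN = 6


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _piece_starts(s: str, i: int, min_repeats: Mapping[int, int]):
    """All (unit_len, motif, min_r, max_r) for qualifying runs starting at i."""
    n = len(s)
    out = []
    for k in range(1, MAX_MOTIF_LEN + 1):
        if i + k > n:
            break
        motif = s[i : i + k]
        if "N" in motif or not is_primitive(motif):
            continue
        t = i + k
        while t < n and s[t] == s[t - k]:
            t += 1
        r_max = (t - i) // k
        thr = min_repeats[k]
        if r_max >= thr:
            out.append((k, motif, thr, r_max))
    return out


def segment(
    s: str,
    min_repeats: Mapping[int, int],
    require_exact: bool = False,
) -> list[tuple[int, str, int]] | None:
    """Segment *s* into perfect runs, each meeting its class threshold.

    Returns a list of ``(start0, motif, repeats)`` with 0-based starts, sorted
    left to right.  Residues not covered by any qualifying run are left out.
    With ``require_exact=True``, returns ``None`` unless the runs tile *s*
    exactly (the lossless-normalization contract).
    """
    n = len(s)
    pieces = [_piece_starts(s, i, min_repeats) for i in range(n)]

    # best[i]: (covered_length, -n_components) achievable on s[i:]
    best: list[tuple[int, int]] = [(0, 0)] * (n + 1)
    for i in range(n - 1, -1, -1):
        cand = best[i + 1]  # leave residue i uncovered
        for k, _motif, thr, r_max in pieces[i]:
            for r in range(thr, r_max + 1):
                length = k * r
                nxt = best[i + length]
                c = (length + nxt[0], nxt[1] - 1)
                if c > cand:
                    cand = c
        best[i] = cand

    if require_exact and best[0][0] != n:
        return None

    # Greedy left-to-right reconstruction: among moves that preserve the
    # optimum, take the longest piece (then the shortest motif) first.
    out: list[tuple[int, str, int]] = []
    i = 0
    while i < n:
        target = best[i]
        options = []
        for k, motif, thr, r_max in pieces[i]:
            for r in range(thr, r_max + 1):
                length = k * r
                nxt = best[i + length]
                if (length + nxt[0], nxt[1] - 1) == target:
                    options.append((length, k, r, motif))
        if options:
            options.sort(key=lambda t: (-t[0], t[1]))
            length, _k, r, motif = options[0]
            out.append((i, motif, r))
            i += length
        else:
            i += 1
    return out
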