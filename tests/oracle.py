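"""Independent brute-force oracle for read-to-barcode assignment.

Slides every barcode (both orientations) across every alignment offset
against the read and applies the acceptance rule directly: a full
occurrence anywhere, or a terminal barcode fragment flush with a read
end covering strictly more than the minimum overlap fraction. Written
deliberately as a plain offset enumeration, independent of the package's
indexed matcher.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def oracle_candidates(
    read: str,
    library,
    min_overlap_fraction: float = 0.5,
    max_mismatches: int = 0,
    count_reverse_complement: bool = True,
) -> set[str]:
    read = read.upper()
    R = len(read)
    L = library.barcode_length
    kmin = math.floor(min_overlap_fraction * L + 1e-9) + 1
    hits: set[str] = set()
    for bc in library:
        orientations = [bc.sequence]
        if count_reverse_complement:
            orientations.append(_rc(bc.sequence))
        found = False
        for seq in orientations:
            for offset in range(-(L - 1), R):
                start = max(offset, 0)
                end = min(offset + L, R)
                k = end - start
                if k <= 0:
                    continue
                bc_start = start - offset
                window_ok = _mismatches(
                    read[start:end], seq[bc_start:bc_start + k]
                ) <= max_mismatches
                if not window_ok:
                    continue
                if k == L:
                    found = True  # full containment
                elif k >= kmin:
                    # flush terminal fragment: barcode suffix at the read
                    # 5' end (offset < 0) or barcode prefix at the 3' end
                    if offset < 0 and offset + L <= R and bc_start + k == L:
                        found = True
                    elif offset >= 0 and offset + L > R and bc_start == 0:
                        found = True
                if found:
                    break
            if found:
                break
        if found:
            hits.add(bc.id)
    return hits


def oracle_assignment(read: str, library, **kwargs) -> str | None:
    cands = oracle_candidates(read, library, **kwargs)
    if not cands:
        return None
    if len(cands) == 1:
        return next(iter(cands))
    return "ambiguous"
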