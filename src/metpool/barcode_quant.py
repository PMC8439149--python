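"""Assign sequencing reads to clonal barcodes and estimate pool composition.

Amplicon/RNA-seq libraries shear the cDNA randomly, so a read may carry a
barcode in full or only a terminal piece of one. A barcode is accepted for
a read if either

* the full barcode sequence occurs anywhere in the read (within the
  configured Hamming mismatch budget), or
* a terminal fragment of the barcode covering more than half of it (by
  default; ``min_overlap_fraction`` is configurable) runs off one end of
  the read — i.e. a barcode *prefix* flush with the read's 3' end, or a
  barcode *suffix* flush with the read's 5' end.

Reverse-complement orientation is searched as well by default, since
library preparation does not fix read orientation. A read matching
exactly one barcode is assigned to it; a read matching several is
*ambiguous* and excluded from counts (multi-hit resolution would bias
assignment); a read matching none is *unassigned*. ``N`` bases never
match. Counting is fragment-level: a read pair contributes one fragment,
assigned from the union of the two mates' candidate sets.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .core_io import (
    BarcodeCountTable,
    BarcodeLibrary,
    SampleMeta,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_READ_ALPHABET = frozenset("ACGTN")

AMBIGUOUS = "ambiguous"


class InvalidReadError(ValueError):
    """Read contains characters outside A/C/G/T/N."""


class TruncatedFastqError(ValueError):
    """FASTQ stream ended mid-record."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchParams:
    """Acceptance rule parameters.

    min_overlap_fraction: a terminal barcode fragment must cover strictly
        more than this fraction of the barcode (default 0.5, i.e. >13 of
        26 nt, hence >=14).
    max_mismatches: Hamming mismatch budget within the compared region
        (no indels). Default 0.
    count_reverse_complement: also search the reverse complement of each
        barcode. Default True.
    """

    min_overlap_fraction: float = 0.5
    max_mismatches: int = 0
    count_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap_fraction <= 1.0):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def min_overlap_nt(self, barcode_length: int) -> int:
        """Smallest integer overlap satisfying the strict >fraction rule."""
        return math.floor(self.min_overlap_fraction * barcode_length + 1e-9) + 1


@dataclass
class CompositionEstimate:
    """Fractional barcode composition per sample (the p_j of each line).

    ``fractions`` is NaN for samples with no assigned reads and zero
    pseudocount (flagged in ``defined``).
    """

    fractions: np.ndarray  # (n_barcodes, n_samples)
    assigned_total: np.ndarray  # (n_samples,)
    barcode_ids: list[str]
    samples: list[SampleMeta]

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.fractions).any(axis=0)

    def for_sample(self, sample_id: str) -> dict[str, float]:
        idx = [s.sample_id for s in self.samples].index(sample_id)
        return dict(zip(self.barcode_ids, self.fractions[:, idx]))


def _hamming_within(a: str, b: str, budget: int) -> bool:
    """True if Hamming(a, b) <= budget; N mismatches everything."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > budget:
                return False
    return True


class _Matcher:
    """Pre-indexed matcher for one library + parameter set.

    With a zero mismatch budget, containment uses ``str.find`` and
    terminal overlaps use hash lookups on pre-built prefix/suffix maps;
    with mismatches allowed, it falls back to explicit Hamming scans.
    """

    def __init__(self, library: BarcodeLibrary, params: MatchParams):
        self.library = library
        self.params = params
        self.L = library.barcode_length
        self.kmin = params.min_overlap_nt(self.L)
        # (barcode_id, oriented sequence) in both orientations
        self.targets: list[tuple[str, str]] = []
        for bc in library:
            self.targets.append((bc.id, bc.sequence))
            if params.count_reverse_complement:
                self.targets.append((bc.id, reverse_complement(bc.sequence)))
        if params.max_mismatches == 0:
            # prefix_map[k][s] / suffix_map[k][s] -> set of barcode ids
            self.prefix_map: dict[int, dict[str, set[str]]] = {}
            self.suffix_map: dict[int, dict[str, set[str]]] = {}
            for k in range(self.kmin, self.L):
                pm: dict[str, set[str]] = {}
                sm: dict[str, set[str]] = {}
                for bc_id, seq in self.targets:
                    pm.setdefault(seq[:k], set()).add(bc_id)
                    sm.setdefault(seq[-k:], set()).add(bc_id)
                self.prefix_map[k] = pm
                self.suffix_map[k] = sm

    def candidates(self, read: str) -> set[str]:
        bad = set(read) - _READ_ALPHABET
        if bad:
            raise InvalidReadError(
                f"read contains non-ACGTN characters {sorted(bad)!r}"
            )
        if self.params.max_mismatches == 0:
            return self._candidates_exact(read)
        return self._candidates_hamming(read)

    def _candidates_exact(self, read: str) -> set[str]:
        out: set[str] = set()
        R = len(read)
        for bc_id, seq in self.targets:
            if bc_id not in out and read.find(seq) != -1:
                out.add(bc_id)
        for k in range(self.kmin, min(self.L, R + 1)):
            if k > R:
                break
            hits = self.prefix_map[k].get(read[R - k:])
            if hits:  # barcode prefix flush with read 3' end
                out.update(hits)
            hits = self.suffix_map[k].get(read[:k])
            if hits:  # barcode suffix flush with read 5' end
                out.update(hits)
        return out

    def _candidates_hamming(self, read: str) -> set[str]:
        out: set[str] = set()
        R = len(read)
        budget = self.params.max_mismatches
        for bc_id, seq in self.targets:
            if bc_id in out:
                continue
            hit = False
            for off in range(0, R - self.L + 1):  # full containment
                if _hamming_within(read[off:off + self.L], seq, budget):
                    hit = True
                    break
            if not hit:
                for k in range(self.kmin, min(self.L, R + 1)):
                    # barcode prefix at read 3' end, suffix at 5' end
                    if _hamming_within(read[R - k:], seq[:k], budget) or \
                            _hamming_within(read[:k], seq[self.L - k:], budget):
                        hit = True
                        break
            if hit:
                out.add(bc_id)
        return out


def match_read(
    read_sequence: str,
    library: BarcodeLibrary,
    params: MatchParams = MatchParams(),
    _matcher: _Matcher | None = None,
) -> str | None:
    """Assign one read: a barcode id, ``None`` (unassigned), or
    ``"ambiguous"`` (more than one candidate barcode).

    Raises :class:`InvalidReadError` for non-ACGTN characters.
    """
    if len(read_sequence) < 1:
        raise ValueError("empty read")
    matcher = _matcher or _Matcher(library, params)
    cands = matcher.candidates(read_sequence.upper())
    if not cands:
        return None
    if len(cands) == 1:
        return next(iter(cands))
    return AMBIGUOUS


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file (optionally gzipped).

    Raises :class:`TruncatedFastqError` with the record index on a
    mid-record truncation or malformed separator line.
    """
    with _open_maybe_gzip(path) as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise TruncatedFastqError(
                    f"record {record_idx}: expected '@' header, got {header[:30]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise TruncatedFastqError(f"record {record_idx}: truncated record")
            if not plus.startswith("+"):
                raise TruncatedFastqError(
                    f"record {record_idx}: expected '+' separator"
                )
            if len(qual) != len(seq):
                raise TruncatedFastqError(
                    f"record {record_idx}: quality length != sequence length"
                )
            yield header[1:].split()[0], seq.upper()
            record_idx += 1


def count_barcodes(
    reads: str | Path | Iterable[tuple[str, str]],
    library: BarcodeLibrary,
    params: MatchParams = MatchParams(),
    sample: SampleMeta | None = None,
    reads2: str | Path | Iterable[tuple[str, str]] | None = None,
) -> BarcodeCountTable:
    """Count barcode-assigned fragments into a one-column table.

    ``reads`` is a FASTQ path or an iterable of (name, sequence) pairs;
    ``reads2`` optionally supplies the second mates. A fragment is
    assigned from the union of its mates' candidate barcodes: exactly one
    candidate assigns it, several make it ambiguous, none leaves it
    unassigned. Reads with invalid characters contribute no candidates
    and are tallied under ``rejected`` (and counted as unassigned if the
    fragment ends up with no candidates). Always conserves fragments:
    assigned + unassigned + ambiguous == fragment count.
    """
    if sample is None:
        sample = SampleMeta(sample_id="sample")
    matcher = _Matcher(library, params)
    idx = {bc_id: i for i, bc_id in enumerate(library.ids)}
    counts = np.zeros((len(library), 1), dtype=np.int64)
    unassigned = 0
    ambiguous = 0
    rejected = 0

    def _as_iter(src):
        if isinstance(src, (str, Path)):
            return iter_fastq(src)
        return iter(src)

    it1 = _as_iter(reads)
    it2 = _as_iter(reads2) if reads2 is not None else None

    for name1, seq1 in it1:
        cands: set[str] = set()
        try:
            cands |= matcher.candidates(seq1.upper())
        except InvalidReadError:
            rejected += 1
        if it2 is not None:
            try:
                name2, seq2 = next(it2)
            except StopIteration:
                raise TruncatedFastqError(
                    "mate file exhausted before first-mate file"
                ) from None
            try:
                cands |= matcher.candidates(seq2.upper())
            except InvalidReadError:
                rejected += 1
        if len(cands) == 1:
            counts[idx[next(iter(cands))], 0] += 1
        elif len(cands) == 0:
            unassigned += 1
        else:
            ambiguous += 1

    table = BarcodeCountTable(
        counts=counts,
        library=library,
        samples=[sample],
        unassigned=np.array([unassigned]),
        ambiguous=np.array([ambiguous]),
    )
    table.rejected_reads = rejected
    return table


def estimate_composition(
    counts: BarcodeCountTable, pseudocount: float = 0.0
) -> CompositionEstimate:
    """Barcode fractions p_j = (count_j + pseudocount) / sum_k (count_k +
    pseudocount) per sample. A sample with no assigned reads and zero
    pseudocount has undefined (NaN) fractions."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if len(counts.samples) < 1:
        raise ValueError("need at least one sample")
    x = counts.counts.astype(float) + pseudocount
    totals = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals > 0, x / np.where(totals > 0, totals, 1.0), np.nan)
    return CompositionEstimate(
        fractions=fractions,
        assigned_total=counts.counts.sum(axis=0),
        barcode_ids=list(counts.library.ids),
        samples=list(counts.samples),
    )


def depth_normalize(counts: BarcodeCountTable, scale: float = 1e6) -> np.ndarray:
    """Scale each sample column to sum to ``scale`` (counts-per-million by
    default). A zero-total sample is an error."""
    totals = counts.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [counts.samples[i].sample_id for i in zero]
        raise ValueError(f"cannot depth-normalize zero-total samples: {names}")
    return counts.counts * (scale / totals)
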