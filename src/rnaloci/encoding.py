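"""Feature encoding: one-hot sequence, dot-bracket structure, conservation.

A genomic window becomes three aligned blocks of length L (default 100):

* ``seq_block``    L x 4 one-hot over (A, C, G, T); N rows are all-zero
* ``struct_block`` L x 3 one-hot over (".", "(", ")")
* ``cons_block``   L x 1 raw per-base conservation (missing positions -> 0.0)

Minus-strand windows are reverse-complemented before folding/encoding and
their conservation vector is reversed to stay base-aligned.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numba
import numpy as np

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

SEQ_ALPHABET = "ACGT"
STRUCT_ALPHABET = ".()"

__all__ = [
    "EncodingError",
    "EncodedWindow",
    "ConservationTrack",
    "NussinovBackend",
    "DotBracketFileBackend",
    "one_hot_sequence",
    "encode_structure",
    "fold_sequence",
    "reverse_complement",
    "extract_conservation",
    "encode_window",
    "encode_windows",
]


class EncodingError(ValueError):
    """Input that cannot be encoded (foreign symbol, empty sequence, ...)."""


_COMPLEMENT = str.maketrans("ACGTUN acgtun", "TGCAAN tgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- one-hot encoders --------------------------------------------------------

_SEQ_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(SEQ_ALPHABET):
    _SEQ_INDEX[ord(_c)] = _i
    _SEQ_INDEX[ord(_c.lower())] = _i
_SEQ_INDEX[ord("N")] = 4  # sentinel: encodes as all-zero row
_SEQ_INDEX[ord("n")] = 4

_STRUCT_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(STRUCT_ALPHABET):
    _STRUCT_INDEX[ord(_c)] = _i


def _codes(s: str, table: np.ndarray, what: str) -> np.ndarray:
    raw = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = table[np.minimum(raw, 127)]
    bad = np.flatnonzero(codes < 0)
    if bad.size:
        raise EncodingError(
            f"invalid {what} symbol {s[bad[0]]!r} at offset {int(bad[0])}"
        )
    return codes


def one_hot_sequence(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix over (A, C, G, T), case-insensitive.

    ``N`` encodes as an all-zero row.  Any other character raises
    :class:`EncodingError` naming the offset.
    """
    codes = _codes(seq, _SEQ_INDEX, "nucleotide")
    out = np.zeros((len(seq), 4), dtype=np.float32)
    known = codes < 4
    out[np.flatnonzero(known), codes[known]] = 1.0
    return out


def encode_structure(dotbracket: str) -> np.ndarray:
    """L x 3 one-hot matrix over (".", "(", ")"); purely positional, the
    string need not be balanced."""
    codes = _codes(dotbracket, _STRUCT_INDEX, "structure")
    out = np.zeros((len(dotbracket), 3), dtype=np.float32)
    out[np.arange(len(dotbracket)), codes] = 1.0
    return out


# -- folding -----------------------------------------------------------------

# canonical + wobble pairs on RNA
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_PAIR_MATRIX = np.zeros((5, 5), dtype=np.uint8)  # indices A,C,G,U, N
_RNA_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
for _a, _b in _PAIRS:
    _PAIR_MATRIX[_RNA_INDEX[_a], _RNA_INDEX[_b]] = 1


@numba.njit(cache=True)
def _nussinov_fill(codes: np.ndarray, pair_ok: np.ndarray, h: int) -> np.ndarray:
    L = codes.shape[0]
    dp = np.zeros((L, L), np.int16)
    for span in range(h + 1, L):
        for i in range(L - span):
            j = i + span
            best = dp[i + 1, j]  # i left unpaired
            for k in range(i + h + 1, j + 1):
                if pair_ok[codes[i], codes[k]]:
                    v = 1 + dp[i + 1, k - 1]
                    if k < j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _nussinov_traceback(dp: np.ndarray, codes: np.ndarray, h: int) -> str:
    # deterministic: at (i, j) prefer pairing i (the smallest index) with the
    # largest admissible partner; otherwise leave i unpaired.
    L = codes.shape[0]
    struct = ["."] * L
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= h:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(j, i + h, -1):
            if not _PAIR_MATRIX[codes[i], codes[k]]:
                continue
            v = 1 + dp[i + 1, k - 1]
            if k < j:
                v += dp[k + 1, j]
            if v == target:
                struct[i], struct[k] = "(", ")"
                stack.append((i + 1, k - 1))
                if k < j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(struct)


def _rna_codes(seq: str) -> np.ndarray:
    rna = seq.upper().replace("T", "U")
    codes = np.empty(len(rna), dtype=np.int8)
    for i, c in enumerate(rna):
        idx = _RNA_INDEX.get(c)
        if idx is None:
            raise EncodingError(f"invalid nucleotide {c!r} at offset {i}")
        codes[i] = idx
    return codes


def fold_sequence(seq: str, min_loop: int = 3) -> str:
    """Maximum-base-pair nested fold (Nussinov-style DP), dot-bracket output.

    Allowed pairs: AU/UA, GC/CG, GU/UG; N pairs with nothing; hairpin loops
    span at least *min_loop* unpaired bases.  Deterministic traceback:
    prefer pairing the smallest i with the largest j.
    """
    if not seq:
        raise EncodingError("cannot fold an empty sequence")
    codes = _rna_codes(seq)
    if len(seq) <= min_loop + 1:
        return "." * len(seq)
    dp = _nussinov_fill(codes, _PAIR_MATRIX, min_loop)
    return _nussinov_traceback(dp, codes, min_loop)


class NussinovBackend:
    """Internal folding backend; no external executables required."""

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def fold(self, seq: str, key: str | None = None) -> str:
        return fold_sequence(seq, self.min_loop)


class DotBracketFileBackend:
    """Precomputed structures from a two-column TSV: ``<window_id>\\t<dotbracket>``.

    This is the production path for thermodynamic folds computed outside the
    package (e.g. by RNAfold); the id must match the window's ``name``.
    """

    def __init__(self, path: str | Path):
        self.structures: dict[str, str] = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise EncodingError(f"{path}: line {line_no}: expected 2 columns")
                self.structures[parts[0]] = parts[1]

    def fold(self, seq: str, key: str | None = None) -> str:
        if key is None or key not in self.structures:
            raise EncodingError(f"no precomputed structure for window {key!r}")
        db = self.structures[key]
        if len(db) != len(seq):
            raise EncodingError(
                f"structure length {len(db)} != sequence length {len(seq)} for {key!r}"
            )
        return db


# -- conservation ------------------------------------------------------------


class ConservationTrack:
    """Per-chromosome map from base position to a real conservation score.

    Backed either by dense per-chromosome arrays (anchored at position 0) or
    sparse ``{position: score}`` dicts; positions absent from the track read
    as 0.0.
    """

    def __init__(self, data: Mapping[str, Mapping[int, float] | np.ndarray] | None = None):
        self._dense: dict[str, np.ndarray] = {}
        self._sparse: dict[str, dict[int, float]] = {}
        for chrom, values in (data or {}).items():
            if isinstance(values, np.ndarray):
                self.set_dense(chrom, values)
            else:
                self.set_sparse(chrom, dict(values))

    def set_dense(self, chrom: str, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite conservation scores on {chrom}")
        self._dense[chrom] = arr

    def set_sparse(self, chrom: str, values: dict[int, float]) -> None:
        if any(p < 0 for p in values):
            raise ValueError(f"negative position in conservation track on {chrom}")
        if any(not np.isfinite(v) for v in values.values()):
            raise ValueError(f"non-finite conservation scores on {chrom}")
        self._sparse[chrom] = values

    def chroms(self) -> list[str]:
        return sorted(set(self._dense) | set(self._sparse))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for [start, end) in genomic order; missing -> 0.0."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom in self._dense:
            arr = self._dense[chrom]
            lo, hi = max(start, 0), min(end, arr.shape[0])
            if hi > lo:
                out[lo - start : hi - start] = arr[lo:hi]
        elif chrom in self._sparse:
            for pos, score in self._sparse[chrom].items():
                if start <= pos < end:
                    out[pos - start] = score
        return out

    @classmethod
    def from_wiggle(cls, path: str | Path) -> "ConservationTrack":
        """Parse fixedStep / variableStep wiggle (1-based, per UCSC spec)."""
        per_chrom: dict[str, dict[int, float]] = {}
        mode = None
        chrom = step = span = pos = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                if line.startswith("fixedStep") or line.startswith("variableStep"):
                    fields = dict(
                        kv.split("=", 1) for kv in line.split()[1:]
                    )
                    mode = line.split()[0]
                    chrom = fields["chrom"]
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    pos = int(fields["start"]) - 1 if mode == "fixedStep" else None
                    per_chrom.setdefault(chrom, {})
                    continue
                if mode is None:
                    raise ValueError(f"{path}: data before any wiggle header")
                if mode == "fixedStep":
                    value = float(line)
                    for off in range(span):
                        per_chrom[chrom][pos + off] = value
                    pos += step
                else:
                    p_str, v_str = line.split()
                    p, value = int(p_str) - 1, float(v_str)
                    for off in range(span):
                        per_chrom[chrom][p + off] = value
        track = cls()
        for c, mapping in per_chrom.items():
            max_pos = max(mapping)
            if len(mapping) > max_pos * 0.5:  # mostly dense: use an array
                arr = np.zeros(max_pos + 1)
                arr[list(mapping.keys())] = list(mapping.values())
                track.set_dense(c, arr)
            else:
                track.set_sparse(c, mapping)
        return track

    def to_wiggle(self, path: str | Path, precision: int = 4) -> None:
        """Write fixedStep (dense chroms) / variableStep (sparse) wiggle."""
        with open(path, "w") as fh:
            for chrom in self.chroms():
                if chrom in self._dense:
                    fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                    for v in self._dense[chrom]:
                        fh.write(f"{v:.{precision}f}\n")
                else:
                    fh.write(f"variableStep chrom={chrom}\n")
                    for pos in sorted(self._sparse[chrom]):
                        fh.write(f"{pos + 1}\t{self._sparse[chrom][pos]:.{precision}f}\n")


def extract_conservation(
    track: ConservationTrack | None, interval: GenomicInterval
) -> np.ndarray:
    """Per-base scores for *interval*; reversed for minus-strand intervals so
    the vector aligns with the reverse-complemented sequence.  A ``None``
    track yields zeros."""
    if track is None:
        return np.zeros(interval.length)
    v = track.values(interval.chrom, interval.start, interval.end)
    return v[::-1].copy() if interval.strand == "-" else v


# -- window assembly ---------------------------------------------------------


@dataclass
class EncodedWindow:
    """Aligned feature blocks for one window; blocks not requested are None."""

    interval: GenomicInterval
    seq_block: np.ndarray | None
    struct_block: np.ndarray | None
    cons_block: np.ndarray | None
    label: int | None = None

    @property
    def length(self) -> int:
        for block in (self.seq_block, self.struct_block, self.cons_block):
            if block is not None:
                return block.shape[0]
        raise ValueError("window has no blocks")


def _fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    if chrom not in genome:
        raise EncodingError(f"chromosome {chrom!r} not in genome")
    ref = genome[chrom]
    if end > len(ref):
        raise EncodingError(
            f"interval {chrom}:{start}-{end} exceeds chromosome end ({len(ref)})"
        )
    return str(ref[start:end]).upper()


def encode_window(
    interval: GenomicInterval,
    genome,
    track: ConservationTrack | None = None,
    fold_backend=None,
    target_length: int = 100,
    branches: Sequence[str] = ("S", "F", "C"),
    label: int | None = None,
) -> EncodedWindow:
    """Encode one genomic interval into aligned fixed-length feature blocks.

    *genome* is any mapping from chromosome name to a sliceable sequence
    (``pyfaidx.Fasta`` or a plain ``dict[str, str]``).  Minus-strand
    intervals are reverse-complemented before folding and one-hot encoding.
    Intervals longer than *target_length* are center-cropped (floor offset on
    the left); shorter ones are symmetrically zero-padded (odd remainder on
    the right), with padded structure rows encoding ".".
    """
    seq = _fetch_sequence(genome, interval.chrom, interval.start, interval.end)
    if interval.strand == "-":
        seq = reverse_complement(seq)
    cons = extract_conservation(track, interval) if "C" in branches else None

    # center-crop in oriented coordinates
    L = target_length
    n = len(seq)
    if n > L:
        left = (n - L) // 2
        seq = seq[left : left + L]
        if cons is not None:
            cons = cons[left : left + L]
        n = L
    pad_left = (L - n) // 2
    pad_right = L - n - pad_left

    seq_block = struct_block = cons_block = None
    if "S" in branches:
        core = one_hot_sequence(seq)
        seq_block = np.zeros((L, 4), dtype=np.float32)
        seq_block[pad_left : pad_left + n] = core
    if "F" in branches:
        backend = fold_backend or NussinovBackend()
        db = backend.fold(seq, key=interval.name)
        core = encode_structure(db)
        struct_block = np.zeros((L, 3), dtype=np.float32)
        struct_block[:, 0] = 1.0  # padding is unpaired
        struct_block[pad_left : pad_left + n] = core
    if "C" in branches:
        cons_block = np.zeros((L, 1), dtype=np.float32)
        cons_block[pad_left : pad_left + n, 0] = cons
    return EncodedWindow(interval, seq_block, struct_block, cons_block, label)


def encode_windows(
    intervals: Sequence[GenomicInterval],
    genome,
    track: ConservationTrack | None = None,
    fold_backend=None,
    target_length: int = 100,
    branches: Sequence[str] = ("S", "F", "C"),
    label: int | None = None,
) -> list[EncodedWindow]:
    return [
        encode_window(iv, genome, track, fold_backend, target_length, branches, label)
        for iv in intervals
    ]
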