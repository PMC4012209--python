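"""Local protein alignment and bit-score conversion.

Smith-Waterman local alignment under BLOSUM62 with affine gaps is the
primitive beneath the clustering thresholds used throughout the package:
the *score density* (bit score divided by alignment length) and the
per-sequence *length coverage* of the optimal local alignment.

Raw scores are converted to bits with the Karlin-Altschul formula

    bits = (lambda * S - ln K) / ln 2

using the standard gapped BLOSUM62/(11,1) parameters lambda = 0.267 and
K = 0.041.  Gap costs follow the NCBI convention: a gap of length k costs
``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

#: the 20 standard residues plus the ambiguity code X
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def validate_protein(seq: str) -> None:
    """Raise ``ValueError`` for an empty sequence or a non-standard letter."""
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in protein sequence")


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    Defaults are the classic gapped BLOSUM62/(11,1) setting.  ``gap_open``
    and ``gap_extend`` are positive costs; a gap of length k is charged
    ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    @property
    def int_matrix(self) -> np.ndarray:
        return _int_matrix(self.matrix_name)

    @property
    def alphabet(self) -> str:
        return str(self.matrix.alphabet)

    def encode(self, seq: str) -> np.ndarray:
        """Encode a protein string as int8 indices into the matrix alphabet."""
        table = _code_table(self.matrix_name)
        out = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (out < 0).any():
            raise ValueError("sequence contains letters outside the matrix alphabet")
        return out

    def aligner(self) -> Align.PairwiseAligner:
        """A Biopython local aligner equivalent to the numba score kernel."""
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = self.matrix
        # PairwiseAligner charges open on the first gap position, so the
        # NCBI cost open + k*ext maps to (open+ext, ext).
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    # a built-in matrix name, or a path to an NCBI-format matrix file
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        from pathlib import Path

        if Path(name).is_file():
            return substitution_matrices.read(name)
        raise


@lru_cache(maxsize=None)
def _int_matrix(name: str) -> np.ndarray:
    return np.ascontiguousarray(np.array(_load_matrix(name)).astype(np.int32))


@lru_cache(maxsize=None)
def _code_table(name: str) -> np.ndarray:
    alphabet = str(_load_matrix(name).alphabet)
    table = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        table[ord(c)] = i
    return table


def load_matrix_file(path) -> substitution_matrices.Array:
    """Read an NCBI-format substitution matrix text file."""
    return substitution_matrices.read(str(path))


@dataclass(frozen=True)
class AlignmentResult:
    """Metrics of one optimal local alignment between two proteins.

    ``aln_length`` counts alignment columns including gap columns.
    ``coverage_a``/``coverage_b`` are the aligned span on each sequence
    (end - start + 1 in residues) divided by that sequence's full length.
    """

    raw_score: int
    bit_score: float
    aln_length: int
    coverage_a: float
    coverage_b: float

    @property
    def score_density(self) -> float:
        """Bit score per alignment column; 0 for an empty alignment."""
        if self.aln_length == 0:
            return 0.0
        return self.bit_score / self.aln_length


def bit_score(raw: float, params: ScoringParams | None = None) -> float:
    """Karlin-Altschul bit score: ``(lambda * raw - ln K) / ln 2``."""
    if raw < 0:
        raise ValueError("raw score must be non-negative")
    p = params or ScoringParams()
    return (p.karlin_lambda * raw - math.log(p.karlin_k)) / math.log(2)


def min_raw_score(bits: float, params: ScoringParams | None = None) -> float:
    """Raw score needed to reach ``bits`` (inverse of :func:`bit_score`)."""
    p = params or ScoringParams()
    return (bits * math.log(2) + math.log(p.karlin_k)) / p.karlin_lambda


@njit(cache=True)
def _sw_score_kernel(prof, b, gap_first, gap_ext):  # pragma: no cover - jit
    n = len(b)
    H = np.zeros(n + 1, np.int32)
    E = np.zeros(n + 1, np.int32)
    best = 0
    for i in range(prof.shape[0]):
        row = prof[i]
        diag = 0
        F = 0
        for j in range(1, n + 1):
            e = E[j] - gap_ext
            t = H[j] - gap_first
            if t > e:
                e = t
            E[j] = e
            f = F - gap_ext
            t = H[j - 1] - gap_first
            if t > f:
                f = t
            F = f
            h = diag + row[b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def sw_score(a_codes: np.ndarray, b_codes: np.ndarray, params: ScoringParams) -> int:
    """Optimal Smith-Waterman raw score (score only, no traceback)."""
    prof = np.ascontiguousarray(params.int_matrix[a_codes.astype(np.int64)])
    return int(
        _sw_score_kernel(
            prof, b_codes, params.gap_open + params.gap_extend, params.gap_extend
        )
    )


def profile(a_codes: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Query profile for repeated calls of :func:`sw_score_profile`."""
    return np.ascontiguousarray(params.int_matrix[a_codes.astype(np.int64)])


def sw_score_profile(prof: np.ndarray, b_codes: np.ndarray, params: ScoringParams) -> int:
    return int(
        _sw_score_kernel(
            prof, b_codes, params.gap_open + params.gap_extend, params.gap_extend
        )
    )


def local_align(a: str, b: str, params: ScoringParams | None = None) -> AlignmentResult:
    """Optimal local alignment of two proteins with full metrics.

    Returns raw and bit score, the number of alignment columns (gap
    columns included) and the coverage of each sequence by the aligned
    span.  When no residue pair scores positive the result is the empty
    alignment with raw score 0 and zero coverage.

    Ties between co-optimal alignments are resolved deterministically by
    the traceback order of the underlying dynamic program.
    """
    p = params or ScoringParams()
    validate_protein(a)
    validate_protein(b)
    aligner = p.aligner()
    alignments = aligner.align(a, b)
    try:
        aln = alignments[0]
    except IndexError:
        return AlignmentResult(0, bit_score(0, p), 0, 0.0, 0.0)
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return AlignmentResult(0, bit_score(0, p), 0, 0.0, 0.0)
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    raw = int(round(aln.score))
    return AlignmentResult(
        raw_score=raw,
        bit_score=bit_score(raw, p),
        aln_length=int(aln.length),
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
    )
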