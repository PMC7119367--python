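"""Local protein alignment with bit scores and E-values.

The similarity engine behind the bait scan and the region comparisons: an
exact affine-gap Smith–Waterman (no heuristic seeding), scored with
BLOSUM62 by default, with raw scores converted to bit scores and
expectation values through the Karlin–Altschul parameterization

    bit = (lambda * raw - ln K) / ln 2,      E = m * n * 2^(-bit)

using the classical gapped BLOSUM62/11/1 parameters lambda = 0.267 nats,
K = 0.041.  No composition-based statistics or length-adjusted effective
search space are applied, so E-values are conservative approximations;
every E-value threshold in the pipeline (1e-4) is applied to these
approximations.

Conventions: a gap of length L costs ``gap_open + L * gap_extend`` (open
and extend both charged on the first gap position).  The unknown residue
``X`` scores 0 against everything.  A "similar" (positive) aligned column
is one whose substitution score is > 0, the BLAST positives convention;
identity and similarity percentages are taken over all aligned columns,
gap columns included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from numba import njit

#: residue order of the internal substitution matrix
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CHAR_TO_IDX = {c: i for i, c in enumerate(ALPHABET)}


@lru_cache(maxsize=None)
def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            mat[i, j] = int(blosum[a][b])
    # X scores 0 vs everything, including itself
    mat[-1, :] = 0
    mat[:, -1] = 0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin–Altschul parameters."""

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267  # nats, gapped BLOSUM62/11/1
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_CHAR_TO_IDX[a], _CHAR_TO_IDX[b]])


def load_matrix(path) -> np.ndarray:
    """Load a substitution matrix in NCBI text format into ALPHABET order."""
    with open(path) as fh:
        lines = [l for l in fh if not l.startswith("#") and l.strip()]
    cols = lines[0].split()
    values: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for c, v in zip(cols, parts[1:]):
            values[(row, c)] = int(v)
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = values.get((a, b), 0)
    mat[-1, :] = 0
    mat[:, -1] = 0
    return mat


def encode(seq: str) -> np.ndarray:
    """Protein string → int8 indices into ALPHABET; rejects other letters."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return np.array([_CHAR_TO_IDX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


@njit(cache=False)
def _sw_kernel(a, b, mat, gap_open, gap_extend, H, E, F):  # pragma: no cover
    """Fill full DP matrices; returns (best score, end_i, end_j)."""
    m, n = a.size, b.size
    first = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - first
            e2 = E[i, j - 1] - gap_extend
            E[i, j] = e if e > e2 else e2
            f = H[i - 1, j] - first
            f2 = F[i - 1, j] - gap_extend
            F[i, j] = f if f > f2 else f2
            h = H[i - 1, j - 1] + mat[ai, b[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=False)
def _sw_score_rows(a, b, mat, gap_open, gap_extend):  # pragma: no cover - jit
    """Score-only Smith–Waterman with two-row memory."""
    m, n = a.size, b.size
    first = gap_open + gap_extend
    Hprev = np.zeros(n + 1, dtype=np.int32)
    Hcur = np.zeros(n + 1, dtype=np.int32)
    Fprev = np.full(n + 1, -1_000_000, dtype=np.int32)
    Fcur = np.zeros(n + 1, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        Hcur[0] = 0
        e = -1_000_000
        for j in range(1, n + 1):
            e1 = Hcur[j - 1] - first
            e2 = e - gap_extend
            e = e1 if e1 > e2 else e2
            f1 = Hprev[j] - first
            f2 = Fprev[j] - gap_extend
            f = f1 if f1 > f2 else f2
            Fcur[j] = f
            h = Hprev[j - 1] + mat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
        Fprev, Fcur = Fcur, Fprev
    return best


@dataclass
class AlignmentHit:
    """A scored local protein alignment."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_pct: float
    similarity_pct: float
    aligned_length: int
    query_cover_pct: float
    query_length: int = 0
    subject_length: int = 0
    query_span: tuple[int, int] = (0, 0)  # 0-based half-open on query
    subject_span: tuple[int, int] = (0, 0)


def score_statistics(
    raw_score: int, scheme: ScoringScheme, m: int, n: int
) -> tuple[float, float]:
    """Bit score and E-value of a raw local score in an m × n search space."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    if raw_score < 0:
        raise ValueError("local raw score cannot be negative")
    bit = (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)
    e_value = m * n * 2.0 ** (-bit)
    return bit, e_value


def raw_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Optimal local alignment score only (no traceback) — the fast path."""
    scheme = scheme or ScoringScheme()
    return int(
        _sw_score_rows(
            encode(a), encode(b), scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
    )


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal local affine-gap alignment of two proteins, with traceback.

    Statistics use m = len(a), n = len(b) as the search space.
    """
    scheme = scheme or ScoringScheme()
    ea, eb = encode(a), encode(b)
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -(10**6), dtype=np.int32)
    F = np.full((m + 1, n + 1), -(10**6), dtype=np.int32)
    best, bi, bj = _sw_kernel(
        ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend, H, E, F
    )
    first = scheme.gap_open + scheme.gap_extend
    # traceback from (bi, bj) in state H
    i, j, state = bi, bj, "H"
    columns: list[tuple[str, str]] = []  # (a_char or '-', b_char or '-')
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + scheme.matrix[ea[i - 1], eb[j - 1]]:
                columns.append((a[i - 1], b[j - 1]))
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("traceback inconsistency")
        elif state == "E":  # gap in query, consume b[j-1]
            columns.append(("-", b[j - 1]))
            if E[i, j] == E[i, j - 1] - scheme.gap_extend:
                j -= 1
            else:  # opened here
                j -= 1
                state = "H"
        else:  # state F: gap in subject, consume a[i-1]
            columns.append((a[i - 1], "-"))
            if F[i, j] == F[i - 1, j] - scheme.gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    columns.reverse()
    aligned_length = len(columns)
    n_ident = sum(1 for x, y in columns if x == y and x != "-")
    n_pos = sum(
        1
        for x, y in columns
        if x != "-" and y != "-" and scheme.score(x, y) > 0
    )
    q_start, q_end = i, bi
    s_start, s_end = j, bj
    bit, e_val = score_statistics(best, scheme, m, n)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(best),
        bit_score=bit,
        e_value=e_val,
        identity_pct=100.0 * n_ident / aligned_length if aligned_length else 0.0,
        similarity_pct=100.0 * n_pos / aligned_length if aligned_length else 0.0,
        aligned_length=aligned_length,
        query_cover_pct=100.0 * (q_end - q_start) / m,
        query_length=m,
        subject_length=n,
        query_span=(q_start, q_end),
        subject_span=(s_start, s_end),
    )


@dataclass(frozen=True)
class HitFilters:
    """Significance filters applied to alignment hits."""

    min_similarity_pct: float = 25.0
    max_evalue: float = 1e-4
    min_shorter_coverage: float | None = None  # fraction of the shorter seq

    def passes(self, hit: AlignmentHit) -> bool:
        if hit.e_value > self.max_evalue:
            return False
        if hit.similarity_pct < self.min_similarity_pct:
            return False
        if self.min_shorter_coverage is not None:
            shorter = min(hit.query_length, hit.subject_length)
            if hit.aligned_length < self.min_shorter_coverage * shorter:
                return False
        return True


def best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    filters: HitFilters | None = None,
) -> dict[str, AlignmentHit]:
    """Best passing subject per query.

    Ties broken deterministically: higher bit score, then lower E-value,
    then lexicographically smaller subject id.  Queries with no passing hit
    are absent from the result.
    """
    if not queries or not subjects:
        raise ValueError("query and subject sets must be non-empty")
    scheme = scheme or ScoringScheme()
    filters = filters or HitFilters()
    out: dict[str, AlignmentHit] = {}
    for qid, qseq in queries.items():
        best: AlignmentHit | None = None
        for sid in sorted(subjects):
            hit = smith_waterman(qseq, subjects[sid], scheme, qid, sid)
            if not filters.passes(hit):
                continue
            if (
                best is None
                or hit.bit_score > best.bit_score
                or (hit.bit_score == best.bit_score and hit.e_value < best.e_value)
            ):
                best = hit
        if best is not None:
            out[qid] = best
    return out


def hit_table(hits: Mapping[str, AlignmentHit]) -> "object":
    """Hit map as a pandas DataFrame with the canonical tabular columns."""
    import pandas as pd

    rows = []
    for hit in hits.values():
        rows.append(
            {
                "qseqid": hit.query_id,
                "sseqid": hit.subject_id,
                "pident": round(hit.identity_pct, 2),
                "length": hit.aligned_length,
                "qstart": hit.query_span[0] + 1,
                "qend": hit.query_span[1],
                "sstart": hit.subject_span[0] + 1,
                "send": hit.subject_span[1],
                "evalue": hit.e_value,
                "bitscore": round(hit.bit_score, 1),
                "ppos": round(hit.similarity_pct, 2),
                "qcovs": round(hit.query_cover_pct, 1),
            }
        )
    return pd.DataFrame(rows)
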