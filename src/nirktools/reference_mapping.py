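"""Reference-anchored pairwise alignment and residue-coordinate mapping.

Every per-sequence feature (conserved-residue rules, active-site motifs,
clade-diagnostic indels, terminal extensions) is defined in the coordinates
of a full-length reference NirK (numbering starts at residue 1; the
canonical reference is 375 aa).  Each candidate is globally aligned to the
reference with an affine-gap Needleman–Wunsch and the alignment is reduced
to a :class:`ReferenceMap` translating between target indices and reference
positions.  Stacking reference-anchored rows yields a star multiple
alignment for phylogeny without an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import GAP, Alignment, SequenceRecord

NEG_INF = float("-inf")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring: total gap penalty = open + extend × (length − 1)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def _matrix(self):
        if self.matrix_name == "BLOSUM62":
            return _BLOSUM62
        return substitution_matrices.load(self.matrix_name)

    def substitution(self, a: str, b: str) -> float:
        m = self._matrix()
        try:
            return float(m[a, b])
        except (KeyError, IndexError):
            return float(m["X", "X"]) if "X" in m.alphabet else 0.0

    def pair_scores(self, a: str, b: str) -> np.ndarray:
        """len(a) × len(b) substitution score table (vectorised lookup)."""
        m = self._matrix()
        alpha = m.alphabet
        lut = {c: i for i, c in enumerate(alpha)}
        fallback = lut.get("X", 0)
        arr = np.asarray(m, dtype=float)
        ai = np.array([lut.get(c, fallback) for c in a])
        bi = np.array([lut.get(c, fallback) for c in b])
        return arr[np.ix_(ai, bi)]


@dataclass(frozen=True)
class ReferenceSequence:
    """The reference NirK used for residue numbering (position 1 = residue 1)."""

    record: SequenceRecord
    canonical_length: int = 375

    def __post_init__(self) -> None:
        if self.record.alphabet != "protein":
            raise ValueError("reference must be a protein sequence")

    def __len__(self) -> int:
        return len(self.record)


@dataclass
class ReferenceMap:
    """Mapping between 1-based target indices and 1-based reference positions.

    ``target_of[p]`` gives the target index aligned to reference position
    ``p`` (or None when ``p`` is deleted in the target); ``insertions[p]``
    counts target residues inserted immediately after reference position
    ``p`` (key 0 collects insertions before position 1 that are not part of
    the N-terminal overhang — by construction terminal gap runs are overhang,
    so key 0 stays empty).  ``n_term_overhang`` / ``c_term_overhang`` count
    target residues aligned entirely before/after the reference span; they
    carry the N/C-terminal extension concept.
    """

    target_id: str
    reference_length: int
    target_of: dict[int, int | None]
    insertions: dict[int, int]
    n_term_overhang: int
    c_term_overhang: int
    score: float
    aligned_target: str = ""
    aligned_reference: str = ""

    def deleted_positions(self) -> list[int]:
        return [p for p in range(1, self.reference_length + 1) if self.target_of[p] is None]

    def pairs(self) -> list[tuple[int, int | None]]:
        """(target_index, reference_position) for mapped residues, ascending."""
        out = [
            (t, p)
            for p, t in self.target_of.items()
            if t is not None
        ]
        out.sort()
        return out


def global_align(
    a: str,
    b: str,
    scoring: Scoring | None = None,
) -> tuple[str, str, float]:
    """Optimal global alignment of two protein strings with affine gaps.

    Returns ``(aligned_a, aligned_b, score)``.  Deterministic: ties in the
    dynamic program are broken preferring match/mismatch, then a gap in
    ``b`` (consuming ``a``), then a gap in ``a``.  Degapping each row
    reproduces the inputs.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    scoring = scoring or Scoring()
    n, m = len(a), len(b)
    sub = scoring.pair_scores(a, b)
    go, ge = scoring.gap_open, scoring.gap_extend

    # Three-state affine DP: M (a[i] ~ b[j]), X (gap in b, consumes a), Y (gap in a).
    # Rows are swept with numpy: M and X depend only on the previous row; the
    # within-row Y recursion Y[i,j] = max(Z[i,j-1]-go, Y[i,j-1]-ge) with
    # Z = max(M, X) unrolls to a running maximum of Z[i,k] + ge*k.
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    X[1:, 0] = -go - ge * np.arange(n)
    js = np.arange(1, m + 1)
    Y[0, 1:] = -go - ge * (js - 1)
    for i in range(1, n + 1):
        M[i, 1:] = (
            np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
            + sub[i - 1]
        )
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] - go, X[i - 1, 1:] - ge, Y[i - 1, 1:] - go]
        )
        Z = np.maximum(M[i], X[i])
        with np.errstate(invalid="ignore"):
            run = np.maximum.accumulate(Z[:-1] + ge * np.arange(m))
        Y[i, 1:] = run - go - ge * (js - 1)

    # Backtrace with the fixed tie-break order M > X > Y.
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax returns first max: M preferred, then X, then Y
    score = float(finals[state])
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = sub[i - 1, j - 1]
            prevs = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            target = M[i, j] - s
            state = _pick(prevs, target)
            i, j = i - 1, j - 1
        elif state == 1:  # X: gap in b
            ra.append(a[i - 1])
            rb.append(GAP)
            prevs = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            state = _pick(prevs, X[i, j])
            i -= 1
        else:  # Y: gap in a
            ra.append(GAP)
            rb.append(b[j - 1])
            prevs = (M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            state = _pick(prevs, Y[i, j])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(ra)), "".join(reversed(rb)), score


def _pick(prevs: tuple[float, float, float], target: float, tol: float = 1e-9) -> int:
    for k, v in enumerate(prevs):
        if abs(v - target) <= tol:
            return k
    raise AssertionError("backtrace inconsistency")


def map_to_reference(
    target: SequenceRecord,
    ref: ReferenceSequence,
    scoring: Scoring | None = None,
) -> ReferenceMap:
    """Align ``target`` to the reference and classify every target residue.

    Each residue is mapped to a reference position, counted as an insertion
    between reference positions, or assigned to a terminal overhang
    (residues before reference position 1 / after the reference end).
    Reference positions with no aligned target residue are deletions.
    """
    if target.alphabet != "protein":
        raise ValueError("map_to_reference requires a protein target")
    at, ar, score = global_align(target.residues, ref.record.residues, scoring)
    L = len(ref)
    target_of: dict[int, int | None] = {}
    insertions: dict[int, int] = {}
    ti = 0  # 1-based target index of last consumed target residue
    rp = 0  # 1-based reference position of last consumed reference residue
    n_over = 0
    c_over = 0
    for ca, cr in zip(at, ar):
        if cr != GAP:
            rp += 1
            if ca != GAP:
                ti += 1
                target_of[rp] = ti
            else:
                target_of[rp] = None
        else:
            ti += 1
            if rp == 0:
                n_over += 1
            elif rp == L:
                c_over += 1
            else:
                insertions[rp] = insertions.get(rp, 0) + 1
    return ReferenceMap(
        target_id=target.id,
        reference_length=L,
        target_of=target_of,
        insertions=insertions,
        n_term_overhang=n_over,
        c_term_overhang=c_over,
        score=score,
        aligned_target=at,
        aligned_reference=ar,
    )


def residue_at(rmap: ReferenceMap, target: SequenceRecord, reference_position: int) -> str:
    """Target residue aligned to a reference position, or ``"deleted"``."""
    if not 1 <= reference_position <= rmap.reference_length:
        raise ValueError(
            f"reference position {reference_position} outside 1..{rmap.reference_length}"
        )
    ti = rmap.target_of[reference_position]
    if ti is None:
        return "deleted"
    return target.residues[ti - 1]


def stack_alignment(
    targets: Sequence[SequenceRecord],
    maps: Sequence[ReferenceMap],
    trim_to_reference: bool = True,
) -> Alignment:
    """Stack reference-anchored rows into a star multiple alignment.

    One column per reference position; insertions relative to the reference
    get extra padded columns (gapped in rows lacking them).  With
    ``trim_to_reference`` terminal overhangs are dropped, mirroring the
    practice of trimming an alignment to the span shared by all sequences
    before phylogeny.
    """
    if len(targets) != len(maps):
        raise ValueError("targets and maps differ in length")
    L = maps[0].reference_length if maps else 0
    ins_width = {p: 0 for p in range(0, L + 1)}
    for m in maps:
        if m.reference_length != L:
            raise ValueError("maps built against different references")
        for p, k in m.insertions.items():
            ins_width[p] = max(ins_width[p], k)
        if not trim_to_reference:
            ins_width[0] = max(ins_width[0], m.n_term_overhang)
            ins_width[L] = max(ins_width[L], m.c_term_overhang)

    rows = []
    for rec, m in zip(targets, maps):
        chunks: list[str] = []
        if not trim_to_reference:
            lead = rec.residues[: m.n_term_overhang]
            chunks.append(lead.rjust(ins_width[0], GAP))
        for p in range(1, L + 1):
            ti = m.target_of[p]
            chunks.append(GAP if ti is None else rec.residues[ti - 1])
            k = m.insertions.get(p, 0)
            if p < L:
                width = ins_width[p]
            else:
                width = ins_width[L] if not trim_to_reference else ins_width.get(L, 0)
            if p < L and width:
                if k:
                    start = _insertion_start(m, p)
                    chunks.append(rec.residues[start : start + k].ljust(width, GAP))
                else:
                    chunks.append(GAP * width)
        if not trim_to_reference:
            tail = rec.residues[len(rec) - m.c_term_overhang :] if m.c_term_overhang else ""
            chunks.append(tail.ljust(ins_width[L], GAP))
        rows.append("".join(chunks))
    return Alignment(ids=[t.id for t in targets], rows=rows)


def _insertion_start(m: ReferenceMap, p: int) -> int:
    """0-based target index where the insertion block after ref position p begins."""
    for q in range(p, 0, -1):
        ti = m.target_of[q]
        if ti is not None:
            return ti
    return m.n_term_overhang
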