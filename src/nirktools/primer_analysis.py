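"""Degenerate primer evaluation: mismatch profiles, logos and in-silico PCR.

Primer coverage is a chronic problem for the highly divergent nirK gene:
published primer pairs (e.g. F1aCu/R3Cu, nirK1F/nirK5R) bind supposedly
conserved copper-binding regions yet still miss most Clade II sequences.
This module quantifies that failure mode: for each primer and each
candidate gene it finds the best (fewest-mismatch) binding site under
IUPAC degeneracy semantics, aggregates per-position mismatch frequencies
by clade, summarises binding-region variability as sequence-logo
frequencies/information content, and predicts amplicons under a mismatch
budget with an optional 3'-clean requirement.

Primer sequences are configuration inputs, never hardcoded: the published
primer papers, not this package, are their source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    IUPAC_SETS,
    SequenceRecord,
    SequenceError,
    iupac_compatible,
    reverse_complement,
)

THREE_PRIME_WINDOW = 3


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # IUPAC, written 5'->3'
    orientation: str = "forward"  # {"forward", "reverse"}

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError(f"primer {self.name!r}: empty sequence")
        for ch in seq:
            if ch not in IUPAC_SETS:
                raise SequenceError(f"primer {self.name!r}: non-IUPAC symbol {ch!r}")
        if self.orientation not in ("forward", "reverse"):
            raise SequenceError(f"primer {self.name!r}: bad orientation")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BindingResult:
    """Best binding site of one primer on one sequence."""

    sequence_id: str
    primer_name: str
    site_start: int  # 1-based on the scanned strand
    per_position_mismatches: list[bool]  # primer 5'->3'
    strand: str  # {"given", "reverse_complement"}
    three_prime_window: int = THREE_PRIME_WINDOW

    @property
    def total_mismatches(self) -> int:
        return sum(self.per_position_mismatches)

    @property
    def three_prime_mismatches(self) -> int:
        k = self.three_prime_window
        return sum(self.per_position_mismatches[-k:])


def _mismatch_vector(primer_seq: str, window: str) -> list[bool]:
    return [not iupac_compatible(p, t) for p, t in zip(primer_seq, window)]


def best_binding_site(
    primer: Primer,
    seq: SequenceRecord,
    three_prime_window: int = THREE_PRIME_WINDOW,
) -> BindingResult:
    """Minimal-mismatch binding site; ties go to the leftmost offset.

    Reverse primers are scanned against the reverse complement of the
    sequence, so the mismatch vector always reads primer 5'->3'.  A primer
    position mismatches iff its IUPAC base set does not intersect the
    template's.
    """
    if seq.alphabet != "nucleotide":
        raise SequenceError("best_binding_site requires a nucleotide sequence")
    template = seq.residues if primer.orientation == "forward" else reverse_complement(seq.residues)
    strand = "given" if primer.orientation == "forward" else "reverse_complement"
    L, n = len(primer), len(template)
    if n < L:
        raise SequenceError(
            f"sequence {seq.id!r} shorter ({n}) than primer {primer.name!r} ({L})"
        )
    best_vec: list[bool] | None = None
    best_off = 0
    for off in range(n - L + 1):
        vec = _mismatch_vector(primer.sequence, template[off : off + L])
        if best_vec is None or sum(vec) < sum(best_vec):
            best_vec, best_off = vec, off
            if sum(vec) == 0:
                break
    return BindingResult(
        sequence_id=seq.id,
        primer_name=primer.name,
        site_start=best_off + 1,
        per_position_mismatches=best_vec,
        strand=strand,
        three_prime_window=three_prime_window,
    )


def mismatch_profile(
    primer: Primer,
    seqs: Sequence[SequenceRecord],
    group_of: Mapping[str, str] | None = None,
    combined_label: str = "I+II",
) -> pd.DataFrame:
    """Per-group per-primer-position mismatch frequencies at best binding sites.

    Rows: one per group present plus a combined row (the count-weighted mean
    of the group rows, equal to pooling all sequences).  Columns: primer
    positions 1..len(primer).  Empty groups are simply absent.
    """
    group_of = group_of or {}
    hits: dict[str, list[list[bool]]] = {}
    for seq in seqs:
        res = best_binding_site(primer, seq)
        g = group_of.get(seq.id, "ungrouped")
        hits.setdefault(g, []).append(res.per_position_mismatches)
    rows = {}
    all_vecs = []
    for g, vecs in sorted(hits.items()):
        arr = np.array(vecs, dtype=float)
        rows[g] = arr.mean(axis=0)
        all_vecs.extend(vecs)
    rows[combined_label] = np.array(all_vecs, dtype=float).mean(axis=0)
    return pd.DataFrame(
        rows, index=pd.RangeIndex(1, len(primer) + 1, name="position")
    ).T


@dataclass
class PositionLogo:
    """Per-column symbol frequencies and information content of a region."""

    frequencies: pd.DataFrame  # columns: symbols; index: 1-based position
    alphabet_size: int = 4

    @property
    def information_content(self) -> pd.Series:
        """IC per column in bits: log2(|alphabet|) - Shannon entropy."""
        p = self.frequencies.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        return pd.Series(
            np.log2(self.alphabet_size) - h, index=self.frequencies.index, name="IC_bits"
        )


def binding_region_logo(
    seqs: Sequence[SequenceRecord],
    primer: Primer,
    anchors: Mapping[str, int] | None = None,
) -> PositionLogo:
    """Logo of the aligned binding regions of ``primer`` across ``seqs``.

    ``anchors`` maps sequence id to the 1-based site start on the scanned
    strand; by default each sequence's best binding site is used.  Columns
    run 5'->3' along the primer.
    """
    L = len(primer)
    windows = []
    for seq in seqs:
        template = (
            seq.residues if primer.orientation == "forward" else reverse_complement(seq.residues)
        )
        start = (anchors or {}).get(seq.id) or best_binding_site(primer, seq).site_start
        window = template[start - 1 : start - 1 + L]
        if len(window) != L:
            raise SequenceError(f"sequence {seq.id!r}: anchored region truncated")
        windows.append(window)
    counts = pd.DataFrame(
        0.0, index=pd.RangeIndex(1, L + 1, name="position"), columns=list("ACGT")
    )
    for window in windows:
        for pos, ch in enumerate(window, start=1):
            if ch in counts.columns:
                counts.loc[pos, ch] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.where(totals > 0, 1.0), axis=0)
    return PositionLogo(frequencies=freqs)


def plot_logo(logo: PositionLogo, path) -> None:
    """Render a minimal IC-scaled letter plot (matplotlib, optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = logo.information_content
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(ic)), 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for pos in logo.frequencies.index:
        bottom = 0.0
        col = logo.frequencies.loc[pos].sort_values()
        for sym, f in col.items():
            h = f * ic.loc[pos]
            if h <= 0:
                continue
            ax.bar(pos, h, bottom=bottom, color=colors.get(sym, "grey"), width=0.8)
            bottom += h
    ax.set_xlabel("position (5'->3')")
    ax.set_ylabel("bits")
    ax.set_ylim(0, np.log2(logo.alphabet_size))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class Amplicon:
    start: int  # 1-based, on the given strand, inclusive of the forward site
    end: int  # 1-based, inclusive of the reverse site
    length: int
    fwd_mismatches: int
    rev_mismatches: int


def _sites_under_budget(
    primer: Primer,
    template: str,
    max_mismatch: int,
    require_3prime_clean: bool,
    k: int,
) -> list[tuple[int, int]]:
    """(0-based offset, total mismatches) for every qualifying site."""
    L = len(primer)
    out = []
    for off in range(len(template) - L + 1):
        vec = _mismatch_vector(primer.sequence, template[off : off + L])
        total = sum(vec)
        if total > max_mismatch:
            continue
        if require_3prime_clean and sum(vec[-k:]) > 0:
            continue
        out.append((off, total))
    return out


def in_silico_pcr(
    fwd: Primer,
    rev: Primer,
    seq: SequenceRecord,
    max_mismatch: int = 0,
    require_3prime_clean: bool = False,
    three_prime_window: int = THREE_PRIME_WINDOW,
) -> list[Amplicon]:
    """Predict amplicons for a primer pair on one template.

    Forward sites are scanned on the given strand, reverse sites on the
    reverse complement; an amplicon is reported for every pair with the
    reverse site strictly downstream of the forward site, each site within
    the mismatch budget.  Lengths include both primer footprints.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise SequenceError("in_silico_pcr needs one forward and one reverse primer")
    template = seq.residues
    n = len(template)
    f_sites = _sites_under_budget(fwd, template, max_mismatch, require_3prime_clean, three_prime_window)
    r_sites_rc = _sites_under_budget(
        rev, reverse_complement(template), max_mismatch, require_3prime_clean, three_prime_window
    )
    amplicons = []
    for f_off, f_mm in f_sites:
        f_start = f_off + 1
        for r_off, r_mm in r_sites_rc:
            # reverse site occupies given-strand positions [n-r_off-len(rev)+1, n-r_off]
            r_end = n - r_off
            r_start = r_end - len(rev) + 1
            if r_start > f_off + len(fwd):
                amplicons.append(
                    Amplicon(
                        start=f_start,
                        end=r_end,
                        length=r_end - f_start + 1,
                        fwd_mismatches=f_mm,
                        rev_mismatches=r_mm,
                    )
                )
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons
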