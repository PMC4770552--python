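"""Conserved-residue validation, motif/indel/extension calling and clade typing.

A candidate sequence counts as a genuine NirK when it carries, at reference
positions, the seven copper-ligand residues (His59, His64, His99, Cys100,
His110, Met115, His298) and the two active-site residues (Asp62, His237)
required for nitrite reduction.  Clade membership follows the two
clade-II-diagnostic 7-aa deletions (coinciding with the linker and tower
loops); the 5-mer motif around the active-site His (TRPHL-type in Clade I,
SSFHV-type in Clade II) is extracted but deliberately not used for typing,
since motif variability makes it a weak discriminator.  Terminal extensions
are scanned for the c-type heme (C-X2-C-H-X50-M) and cupredoxin
(C-X4-H-X4-M) spaced patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .reference_mapping import ReferenceMap, residue_at
from .sequence_io import GAP, Alignment, SequenceRecord


@dataclass(frozen=True)
class ResidueRule:
    reference_position: int
    allowed_residues: frozenset[str]
    role: str  # {"Cu_ligand", "active_site"}

    def __post_init__(self) -> None:
        if not self.allowed_residues:
            raise ValueError("allowed_residues must be non-empty")


@dataclass(frozen=True)
class ResidueRuleSet:
    """Positions that must carry specific residues for the sequence to be NirK."""

    rules: tuple[ResidueRule, ...]
    reference_length: int = 375

    def __post_init__(self) -> None:
        positions = [r.reference_position for r in self.rules]
        if positions != sorted(set(positions)):
            raise ValueError("rule positions must be strictly increasing")
        if positions and positions[-1] > self.reference_length:
            raise ValueError(
                f"rule position {positions[-1]} beyond reference length "
                f"{self.reference_length}"
            )

    @classmethod
    def default(cls) -> "ResidueRuleSet":
        cu = [(59, "H"), (64, "H"), (99, "H"), (100, "C"), (110, "H"), (115, "M"), (298, "H")]
        active = [(62, "D"), (237, "H")]
        rules = sorted(
            [ResidueRule(p, frozenset(aa), "Cu_ligand") for p, aa in cu]
            + [ResidueRule(p, frozenset(aa), "active_site") for p, aa in active],
            key=lambda r: r.reference_position,
        )
        return cls(rules=tuple(rules))


@dataclass(frozen=True)
class IndelRegion:
    """A clade- or taxon-diagnostic indel in reference coordinates (closed interval)."""

    label: str  # {"linker", "tower", "bacillus_loop", "other"}
    start: int
    end: int
    kind: str = "deletion"  # {"deletion", "insertion"}
    expected_length: int = 7

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.expected_length < 1:
            raise ValueError("expected_length must be >= 1")
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


#: Default diagnostic regions.  The linker/tower coordinates are pipeline
#: parameters expressed in surrogate-reference coordinates (the literature
#: shows the loops only graphically), shared with the synthetic generator.
DEFAULT_INDEL_REGIONS: tuple[IndelRegion, ...] = (
    IndelRegion("linker", 190, 196, "deletion", 7),
    IndelRegion("tower", 258, 264, "deletion", 7),
    IndelRegion("bacillus_loop", 300, 301, "insertion", 6),
)


@dataclass(frozen=True)
class DomainPattern:
    """Spaced single-residue template, e.g. heme c: C,x2,C,H,x50,M."""

    name: str  # {"heme_c", "cupredoxin"}
    anchors: tuple[str, ...]
    spacers: tuple[int, ...]  # residue counts between consecutive anchors
    search_zone: str  # {"c_term_overhang", "n_term_overhang"}
    spacer_tolerance: int = 0

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.anchors) - 1:
            raise ValueError("need len(anchors)-1 spacers")
        if self.spacer_tolerance < 0:
            raise ValueError("spacer_tolerance must be >= 0")

    def span(self) -> int:
        return len(self.anchors) + sum(self.spacers)

    @classmethod
    def heme_c(cls, tolerance: int = 0) -> "DomainPattern":
        return cls("heme_c", ("C", "C", "H", "M"), (2, 0, 50), "c_term_overhang", tolerance)

    @classmethod
    def cupredoxin(cls, tolerance: int = 0) -> "DomainPattern":
        return cls("cupredoxin", ("C", "H", "M"), (4, 4), "n_term_overhang", tolerance)


DEFAULT_DOMAIN_PATTERNS: tuple[DomainPattern, ...] = (
    DomainPattern.heme_c(),
    DomainPattern.cupredoxin(),
)


@dataclass
class ExtensionReport:
    n_overhang_len: int
    c_overhang_len: int
    heme_found: bool = False
    cupredoxin_found: bool = False
    offsets: dict[str, int] = field(default_factory=dict)  # 0-based offset in overhang


@dataclass
class IndelCall:
    region: IndelRegion
    present: bool
    observed_length: int


@dataclass
class NirKProfile:
    """Full validation and feature report for one candidate sequence."""

    id: str
    residue_report: list[dict]
    is_nirk: bool
    his237_motif: str
    asp62_motif: str
    indel_calls: list[IndelCall]
    extension_report: ExtensionReport
    clade: str = "unclassified"
    evidence: str = ""

    def motif_defined(self, which: str = "his237") -> bool:
        motif = self.his237_motif if which == "his237" else self.asp62_motif
        return len(motif) == 5 and "!" not in motif


UNDEFINED_MARK = "!"

HIS237_WINDOW = (-3, 1)  # printed motifs place the His fourth of five
ASP62_WINDOW = (-2, 2)


def validate_residues(
    target: SequenceRecord,
    rmap: ReferenceMap,
    rules: ResidueRuleSet | None = None,
) -> tuple[list[dict], bool]:
    """Check every conserved-residue rule; deleted positions count as failures.

    'X' never satisfies a rule (draft-genome placeholders are legal input but
    carry no evidence).
    """
    rules = rules or ResidueRuleSet.default()
    report = []
    for rule in rules.rules:
        observed = residue_at(rmap, target, rule.reference_position)
        ok = observed in rule.allowed_residues and observed != "X"
        report.append(
            {
                "position": rule.reference_position,
                "role": rule.role,
                "expected": "".join(sorted(rule.allowed_residues)),
                "observed": observed,
                "pass": ok,
            }
        )
    return report, all(r["pass"] for r in report)


def _window_motif(
    target: SequenceRecord, rmap: ReferenceMap, centre: int, window: tuple[int, int]
) -> str:
    chars = []
    for p in range(centre + window[0], centre + window[1] + 1):
        if not 1 <= p <= rmap.reference_length:
            chars.append(UNDEFINED_MARK)
            continue
        aa = residue_at(rmap, target, p)
        chars.append(UNDEFINED_MARK if aa == "deleted" else aa)
    return "".join(chars)


def extract_motifs(
    target: SequenceRecord,
    rmap: ReferenceMap,
    his237_window: tuple[int, int] = HIS237_WINDOW,
    asp62_window: tuple[int, int] = ASP62_WINDOW,
) -> tuple[str, str]:
    """5-mers around the active-site His237 and Asp62 in reference coordinates.

    Window positions that are deleted in the target are marked ``!`` and the
    motif counts as undefined.
    """
    return (
        _window_motif(target, rmap, 237, his237_window),
        _window_motif(target, rmap, 62, asp62_window),
    )


def detect_indels(
    target: SequenceRecord,
    rmap: ReferenceMap,
    regions: Sequence[IndelRegion] = DEFAULT_INDEL_REGIONS,
) -> list[IndelCall]:
    """Call each diagnostic indel region on one mapped sequence.

    A deletion region is present when the majority of its reference interval
    (>= ceil(L/2)+1 positions, L = expected length) is deleted in the target;
    the majority rule tolerates ragged alignment edges under point indels.
    An insertion region reports the number of target residues inserted
    between its flanking reference positions, with the same majority
    threshold on the expected insert length.
    """
    calls = []
    for region in regions:
        if region.end > rmap.reference_length:
            raise ValueError(f"region {region.label} outside reference")
        threshold = ceil(region.expected_length / 2) + 1
        if region.kind == "deletion":
            deleted = sum(
                1
                for p in range(region.start, region.end + 1)
                if rmap.target_of[p] is None
            )
            calls.append(IndelCall(region, deleted >= threshold, deleted))
        else:
            inserted = sum(
                k for p, k in rmap.insertions.items() if region.start <= p < region.end
            )
            calls.append(IndelCall(region, inserted >= threshold, inserted))
    return calls


def _scan_pattern(zone: str, pattern: DomainPattern) -> int | None:
    """0-based offset of the first pattern match in the overhang, else None."""
    for off in range(len(zone)):
        if _match_at(zone, off, pattern):
            return off
    return None


def _match_at(zone: str, off: int, pattern: DomainPattern) -> bool:
    def try_spacers(pos: int, ai: int) -> bool:
        if zone[pos] != pattern.anchors[ai]:
            return False
        if ai == len(pattern.anchors) - 1:
            return True
        base = pattern.spacers[ai]
        for d in range(-pattern.spacer_tolerance, pattern.spacer_tolerance + 1):
            k = base + d
            if k < 0:
                continue
            nxt = pos + 1 + k
            if nxt < len(zone) and try_spacers(nxt, ai + 1):
                return True
        return False

    return try_spacers(off, 0)


def detect_extensions(
    target: SequenceRecord,
    rmap: ReferenceMap,
    patterns: Sequence[DomainPattern] = DEFAULT_DOMAIN_PATTERNS,
) -> ExtensionReport:
    """Scan terminal overhangs (never the mapped reference span) for domain patterns."""
    n_zone = target.residues[: rmap.n_term_overhang]
    c_zone = target.residues[len(target) - rmap.c_term_overhang :] if rmap.c_term_overhang else ""
    report = ExtensionReport(
        n_overhang_len=rmap.n_term_overhang, c_overhang_len=rmap.c_term_overhang
    )
    for pattern in patterns:
        zone = c_zone if pattern.search_zone == "c_term_overhang" else n_zone
        off = _scan_pattern(zone, pattern)
        if off is not None:
            report.offsets[pattern.name] = off
            if pattern.name == "heme_c":
                report.heme_found = True
            elif pattern.name == "cupredoxin":
                report.cupredoxin_found = True
    return report


def assign_clade(indel_calls: Sequence[IndelCall]) -> str:
    """Clade II iff both linker and tower deletions present; Clade I iff neither.

    A sequence with exactly one diagnostic deletion is left ``unclassified``
    rather than guessed.
    """
    linker = next((c for c in indel_calls if c.region.label == "linker"), None)
    tower = next((c for c in indel_calls if c.region.label == "tower"), None)
    if linker is None or tower is None:
        return "unclassified"
    if linker.present and tower.present:
        return "II"
    if not linker.present and not tower.present:
        return "I"
    return "unclassified"


def build_profile(
    target: SequenceRecord,
    rmap: ReferenceMap,
    rules: ResidueRuleSet | None = None,
    regions: Sequence[IndelRegion] = DEFAULT_INDEL_REGIONS,
    patterns: Sequence[DomainPattern] = DEFAULT_DOMAIN_PATTERNS,
) -> NirKProfile:
    """Run the full per-sequence feature battery and assemble a profile."""
    residue_report, is_nirk = validate_residues(target, rmap, rules)
    his_m, asp_m = extract_motifs(target, rmap)
    indel_calls = detect_indels(target, rmap, regions)
    ext = detect_extensions(target, rmap, patterns)
    clade = assign_clade(indel_calls)
    failed = [str(r["position"]) for r in residue_report if not r["pass"]]
    evidence = "" if is_nirk else "failed residue rules at " + ",".join(failed)
    return NirKProfile(
        id=target.id,
        residue_report=residue_report,
        is_nirk=is_nirk,
        his237_motif=his_m,
        asp62_motif=asp_m,
        indel_calls=indel_calls,
        extension_report=ext,
        clade=clade,
        evidence=evidence,
    )


def profiles_to_frame(profiles: Iterable[NirKProfile]) -> pd.DataFrame:
    """Flatten profiles into a one-row-per-sequence table (TSV-friendly)."""
    rows = []
    for p in profiles:
        row = {
            "id": p.id,
            "is_nirk": p.is_nirk,
            "his237_motif": p.his237_motif,
            "asp62_motif": p.asp62_motif,
            "clade": p.clade,
            "n_overhang": p.extension_report.n_overhang_len,
            "c_overhang": p.extension_report.c_overhang_len,
            "heme_c": p.extension_report.heme_found,
            "cupredoxin": p.extension_report.cupredoxin_found,
            "evidence": p.evidence,
        }
        for call in p.indel_calls:
            row[f"indel_{call.region.label}"] = call.present
            row[f"indel_{call.region.label}_len"] = call.observed_length
        rows.append(row)
    return pd.DataFrame(rows)


def filter_redundant(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[dict]]:
    """Drop different strains of the same species with identical sequences.

    Among records sharing species AND residues, the lexicographically
    smallest id is retained.  Identical sequences from different species, or
    near-identical sequences from one species, are all retained.
    """
    groups: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species, rec.residues), []).append(rec)
    retained: list[SequenceRecord] = []
    removal_log: list[dict] = []
    keep_ids = set()
    for (species, _), members in groups.items():
        keeper = min(members, key=lambda r: r.id)
        keep_ids.add(keeper.id)
        for rec in members:
            if rec.id != keeper.id:
                removal_log.append(
                    {"removed": rec.id, "kept": keeper.id, "species": species}
                )
    retained = [r for r in records if r.id in keep_ids]
    return retained, removal_log


def pairwise_identity(row_a: str, row_b: str) -> float | None:
    """Percent identity over columns where neither row is gapped (pairwise deletion)."""
    same = 0
    compared = 0
    for ca, cb in zip(row_a, row_b):
        if ca == GAP or cb == GAP:
            continue
        compared += 1
        if ca == cb:
            same += 1
    if compared == 0:
        return None
    return 100.0 * same / compared


def group_similarity(
    aln: Alignment, grouping: Mapping[str, str] | None = None
) -> dict[str, float | None]:
    """Mean pairwise percent identity per group plus ``overall``.

    Groups of size < 2 report None.  Identity uses pairwise deletion:
    columns gapped in either row of a pair are skipped for that pair.
    """
    idx = {rid: i for i, rid in enumerate(aln.ids)}
    groups: dict[str, list[str]] = {"overall": list(aln.ids)}
    if grouping:
        for rid, g in grouping.items():
            if rid in idx:
                groups.setdefault(g, []).append(rid)
    out: dict[str, float | None] = {}
    for g, members in groups.items():
        if len(members) < 2:
            out[g] = None
            continue
        vals = []
        for a, b in combinations(members, 2):
            ident = pairwise_identity(aln.rows[idx[a]], aln.rows[idx[b]])
            if ident is not None:
                vals.append(ident)
        out[g] = sum(vals) / len(vals) if vals else None
    return out


def count_copies(
    records: Sequence[SequenceRecord], genome_of: Mapping[str, str]
) -> tuple[dict[str, int], float]:
    """Per-genome gene copy counts and the fraction of genomes with >= 2 copies."""
    counts: dict[str, int] = {}
    for rec in records:
        genome = genome_of[rec.id]
        counts[genome] = counts.get(genome, 0) + 1
    if not counts:
        return counts, 0.0
    multi = sum(1 for v in counts.values() if v >= 2)
    return counts, multi / len(counts)
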