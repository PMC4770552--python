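"""Synthetic NirK sequence sets and genome inventories with ground truth.

The generator emulates the statistical structure of a curated full-length
NirK dataset so every pipeline stage is testable without downloads:

* a 375-aa surrogate reference carrying the conserved copper-ligand and
  active-site residues at their canonical positions;
* Clade I sequences (TRPHL active-site motif, no diagnostic deletions) and
  Clade II sequences (SSFHV motif, 7-aa linker and tower deletions), with
  an optional Bacillus-type extra-loop insertion;
* optional N-terminal cupredoxin (C-X4-H-X4-M) and C-terminal c-type heme
  (C-X2-C-H-X50-M) extensions;
* i.i.d. substitutions outside protected positions (rule positions, motif
  windows, indel flanks);
* codon-random back-translations and planted primer binding sites with
  per-clade mismatch probabilities;
* genome inventories with per-phylum gene frequencies and exact pairwise
  odds-ratio associations (association pairs must form a forest).

Every generator is a pure function of (config, seed); a TruthTable row per
sequence records exactly what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_name
from Bio.Seq import Seq

from .nirk_features import DEFAULT_INDEL_REGIONS, IndelRegion, ResidueRuleSet
from .pathway_inventory import GENE_FLAGS, GenomeInventory
from .primer_analysis import Primer
from .reference_mapping import ReferenceSequence
from .sequence_io import IUPAC_SETS, SequenceRecord, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed seed for the surrogate reference so the bundled fixture is stable.
_REFERENCE_SEED = 20160229

REFERENCE_LENGTH = 375

#: Residues pinned in the surrogate reference: the nine conserved-rule
#: positions plus the full active-site motif windows (Clade I template).
_PINNED: dict[int, str] = {
    59: "H",
    60: "A", 61: "G", 62: "D", 63: "S", 64: "H",  # Asp62 window (D62, H64 conserved)
    99: "H", 100: "C", 110: "H", 115: "M",
    234: "T", 235: "R", 236: "P", 237: "H", 238: "L",  # His237 window, Clade I motif
    298: "H",
}

CLADE1_HIS237_MOTIF = "TRPHL"
CLADE2_HIS237_MOTIF = "SSFHV"
ASP62_MOTIF = "AGDSH"


def surrogate_reference() -> ReferenceSequence:
    """Deterministic 375-aa surrogate reference satisfying every residue rule."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    chars = list(rng.choice(list(AA20), size=REFERENCE_LENGTH))
    for pos, aa in _PINNED.items():
        chars[pos - 1] = aa
    rec = SequenceRecord(
        id="surrogate_reference",
        residues="".join(chars),
        alphabet="protein",
        description="synthetic surrogate reference NirK (375 aa)",
        source="synthetic",
    )
    return ReferenceSequence(record=rec, canonical_length=REFERENCE_LENGTH)


@dataclass(frozen=True)
class SequenceGenConfig:
    """Study conditions for the synthetic NirK sequence set.

    Defaults: ten sequences per clade with no substitution noise — the
    cleanest configuration for exercising the callers; extension fractions
    reflect a dataset where roughly 30 % of sequences carry a terminal
    extension, split evenly between the heme and cupredoxin types; 5 % of
    genomes carry two gene copies.
    """

    n_clade1: int = 10
    n_clade2: int = 10
    n_bacillus_loop: int = 0
    substitution_rate: float = 0.0
    indel_regions: tuple[IndelRegion, ...] = DEFAULT_INDEL_REGIONS
    fraction_with_heme_ext: float = 0.15
    fraction_with_cupredoxin_ext: float = 0.15
    multi_copy_fraction: float = 0.05
    clade2_his237_motif: str = CLADE2_HIS237_MOTIF
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clade1, self.n_clade2, self.n_bacillus_loop) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        for frac in (
            self.fraction_with_heme_ext,
            self.fraction_with_cupredoxin_ext,
            self.multi_copy_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        ivs = sorted((r.start, r.end) for r in self.indel_regions)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("indel regions overlap")
        for r in self.indel_regions:
            if any(s in _PINNED for s in range(r.start - 1, r.end + 2)):
                raise ValueError(f"indel region {r.label} overlaps protected positions")


def protected_positions(cfg: SequenceGenConfig) -> set[int]:
    """Rule positions, motif windows and indel flanks excluded from noise."""
    protected = set(_PINNED)
    for region in cfg.indel_regions:
        protected.update((region.start - 1, region.end + 1))
    return protected


def _substitute(chars: list[str], protected: set[int], rate: float, rng) -> list[str]:
    if rate <= 0:
        return chars
    out = list(chars)
    for i in range(len(out)):
        pos = i + 1
        if pos in protected:
            continue
        if rng.random() < rate:
            choices = [aa for aa in AA20 if aa != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return out


def _random_aa(rng, k: int) -> str:
    return "".join(rng.choice(list(AA20), size=k)) if k else ""


def generate_nirk_set(
    cfg: SequenceGenConfig | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame, ReferenceSequence]:
    """Generate a NirK sequence set, its truth table and the surrogate reference.

    Clade I rows are reference-like; Clade II rows carry the SSFHV-type
    motif and both 7-aa deletions; ``n_bacillus_loop`` of the Clade II rows
    additionally carry the extra-loop insertion.  Terminal extensions are
    appended/prepended by Bernoulli draws per sequence (never both on one
    sequence).  The truth table has one row per sequence.
    """
    cfg = cfg or SequenceGenConfig()
    ref = surrogate_reference()
    rng = np.random.default_rng(cfg.seed)
    protected = protected_positions(cfg)
    deletions = [r for r in cfg.indel_regions if r.kind == "deletion"]
    insertions = [r for r in cfg.indel_regions if r.kind == "insertion"]

    plan = (
        [("I", False)] * cfg.n_clade1
        + [("II", False)] * (cfg.n_clade2 - cfg.n_bacillus_loop)
        + [("II", True)] * cfg.n_bacillus_loop
    )
    if cfg.n_bacillus_loop > cfg.n_clade2:
        raise ValueError("n_bacillus_loop cannot exceed n_clade2")

    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    clade2_phyla = ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Euryarchaeota"]
    for k, (clade, bacillus) in enumerate(plan):
        chars = list(ref.record.residues)
        if clade == "II":
            for offset, aa in zip(range(-3, 2), cfg.clade2_his237_motif):
                chars[237 + offset - 1] = aa
        chars = _substitute(chars, protected, cfg.substitution_rate, rng)
        if clade == "II":
            # delete highest-coordinate region first so indices stay valid
            for region in sorted(deletions, key=lambda r: -r.start):
                del chars[region.start - 1 : region.end]
            if bacillus:
                shift = sum(
                    r.end - r.start + 1 for r in deletions if r.end < insertions[0].start
                )
                at = insertions[0].start - shift  # insert after this 0-based boundary
                loop = _random_aa(rng, insertions[0].expected_length)
                chars[at:at] = list(loop)
        seq = "".join(chars)

        heme = False
        cupredoxin = False
        draw = rng.random()
        if draw < cfg.fraction_with_heme_ext:
            heme = True
            ext = (
                _random_aa(rng, 3)
                + "C" + _random_aa(rng, 2) + "CH" + _random_aa(rng, 50) + "M"
            )
            seq = seq + ext
        elif draw < cfg.fraction_with_heme_ext + cfg.fraction_with_cupredoxin_ext:
            cupredoxin = True
            ext = "C" + _random_aa(rng, 4) + "H" + _random_aa(rng, 4) + "M" + _random_aa(rng, 3)
            seq = ext + seq

        phylum = (
            "Alphaproteobacteria" if clade == "I" else clade2_phyla[k % len(clade2_phyla)]
        )
        records.append(
            SequenceRecord(
                id=f"syn{k:04d}",
                residues=seq,
                alphabet="protein",
                description=f"synthetic clade {clade} NirK",
                species=f"Synthetobacter sp{k}",
                strain=f"S{k}",
                phylum=phylum,
                source="synthetic",
            )
        )
        truth_rows.append(
            {
                "id": f"syn{k:04d}",
                "clade": clade,
                "his237_motif": CLADE1_HIS237_MOTIF if clade == "I" else cfg.clade2_his237_motif,
                "asp62_motif": ASP62_MOTIF,
                "linker_deleted": clade == "II",
                "tower_deleted": clade == "II",
                "bacillus_loop": bacillus,
                "heme_ext": heme,
                "cupredoxin_ext": cupredoxin,
            }
        )

    # genome assignment: a fraction of genomes carries two gene copies
    genome_ids: list[str] = []
    copy_idx: list[int] = []
    g = 0
    i = 0
    while i < len(records):
        gid = f"genome{g:04d}"
        if rng.random() < cfg.multi_copy_fraction and i + 1 < len(records):
            genome_ids += [gid, gid]
            copy_idx += [1, 2]
            i += 2
        else:
            genome_ids.append(gid)
            copy_idx.append(1)
            i += 1
        g += 1
    truth = pd.DataFrame(truth_rows)
    truth["genome_id"] = genome_ids
    truth["copy_index"] = copy_idx
    # species follows the genome so strain-level redundancy rules are exercisable
    records = [
        replace(rec, species=f"Synthetobacter {gid}")
        for rec, gid in zip(records, genome_ids)
    ]
    return records, truth, ref


_STANDARD_TABLE = unambiguous_dna_by_name["Standard"]


def _codon_map() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        table.setdefault(aa, []).append(codon)
    for aa in table:
        table[aa].sort()
    return table


def backtranslate(
    records: Sequence[SequenceRecord], seed: int = 0
) -> list[SequenceRecord]:
    """Map each amino acid to a uniformly chosen synonymous codon.

    ``translate(backtranslate(s)) == s`` for any protein without ``X``.
    """
    codons = _codon_map()
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        if "X" in rec.residues:
            raise ValueError(f"record {rec.id!r}: cannot backtranslate 'X'")
        nt = "".join(
            codons[aa][rng.integers(0, len(codons[aa]))] for aa in rec.residues
        )
        out.append(
            SequenceRecord(
                id=rec.id,
                residues=nt,
                alphabet="nucleotide",
                description=rec.description,
                species=rec.species,
                strain=rec.strain,
                phylum=rec.phylum,
                source="synthetic",
            )
        )
    return out


def translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _concrete_site(primer: Primer, rng) -> str:
    """One concrete base per primer position, compatible with the primer."""
    return "".join(
        sorted(IUPAC_SETS[ch])[rng.integers(0, len(IUPAC_SETS[ch]))]
        for ch in primer.sequence
    )


def _mismatch_base(primer_symbol: str, rng) -> str:
    incompatible = sorted(set("ACGT") - IUPAC_SETS[primer_symbol])
    if not incompatible:
        raise ValueError(
            f"primer symbol {primer_symbol!r} matches every base; cannot plant a mismatch"
        )
    return incompatible[rng.integers(0, len(incompatible))]


def plant_primer_sites(
    nt_records: Sequence[SequenceRecord],
    primer: Primer,
    per_clade_mismatch_spec: Mapping[str, Mapping[int, float]],
    clade_of: Mapping[str, str],
    seed: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Embed one primer binding site per record with controlled mismatches.

    ``per_clade_mismatch_spec`` maps clade -> {primer position (1-based,
    5'->3') -> mismatch probability}.  For each record a concrete site is
    drawn, mismatches planted by the clade's spec, and the site written
    into the record at a random offset (on the reverse-complement strand
    for reverse primers).  The truth table lists the planted offset and
    mismatch positions per sequence.
    """
    rng = np.random.default_rng(seed)
    L = len(primer)
    out = []
    rows = []
    for rec in nt_records:
        if len(rec) < L:
            raise ValueError(f"record {rec.id!r} shorter than primer")
        clade = clade_of.get(rec.id, "I")
        spec = per_clade_mismatch_spec.get(clade, {})
        if any(p < 1 or p > L for p in spec):
            raise ValueError("mismatch positions must lie within the primer")
        site = list(_concrete_site(primer, rng))
        planted = []
        for pos, prob in sorted(spec.items()):
            if rng.random() < prob:
                site[pos - 1] = _mismatch_base(primer.sequence[pos - 1], rng)
                planted.append(pos)
        site_str = "".join(site)
        offset = int(rng.integers(0, len(rec) - L + 1))
        template = rec.residues
        if primer.orientation == "forward":
            new = template[:offset] + site_str + template[offset + L :]
        else:
            rc = reverse_complement(template)
            rc = rc[:offset] + site_str + rc[offset + L :]
            new = reverse_complement(rc)
        out.append(rec.with_residues(new))
        rows.append(
            {
                "id": rec.id,
                "clade": clade,
                "primer": primer.name,
                "offset": offset + 1,
                "planted_mismatches": ",".join(map(str, planted)),
                "n_mismatches": len(planted),
            }
        )
    return out, pd.DataFrame(rows)


#: Default per-phylum cohort sizes for inventory simulation: the fifteen
#: phyla of the 249-genome NirK survey cohort with their genome counts.
DEFAULT_N_PER_PHYLUM: dict[str, int] = {
    "Acidobacteria": 1,
    "Actinobacteria": 28,
    "Alphaproteobacteria": 82,
    "Bacteroidetes": 21,
    "Betaproteobacteria": 39,
    "Verrucomicrobia": 2,
    "Chloroflexi": 5,
    "Deltaproteobacteria": 2,
    "Euryarcheaota": 13,
    "Firmicutes": 27,
    "Gammaproteobacteria": 23,
    "Gemmatimonadetes": 1,
    "Nitrospirae": 2,
    "Planctomycetes": 1,
    "Spirochaetae": 2,
}

#: Default marginal gene frequencies, loosely matching the cohort-wide
#: prevalences implied by the survey's pathway table.
DEFAULT_GENE_FREQS: dict[str, float] = {
    "nirS": 0.05,
    "nor": 0.71,
    "nosZ": 0.40,
    "napA": 0.45,
    "narG": 0.27,
    "nrfA": 0.20,
    "nirB": 0.60,
    "nirV": 0.61,
}

#: Default planted association: the narG-nrfA avoidance pattern (odds
#: ratio 0.2, i.e. a clearly negative co-occurrence).
DEFAULT_ASSOCIATIONS: tuple[tuple[str, str, float], ...] = (("narG", "nrfA", 0.2),)


def _joint_p11(p1: float, p2: float, odds_ratio: float) -> float:
    """P(both present) for given marginals and odds ratio (exact 2x2 solve)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    if odds_ratio == 1.0:
        p11 = p1 * p2
    else:
        a = odds_ratio - 1.0
        b = 1.0 + (p1 + p2) * a
        disc = b * b - 4.0 * a * odds_ratio * p1 * p2
        if disc < 0:
            raise ValueError("infeasible odds ratio for these marginals")
        p11 = (b - math.sqrt(disc)) / (2.0 * a)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(
            f"odds ratio {odds_ratio} incompatible with marginals ({p1}, {p2})"
        )
    return min(max(p11, lo), hi)


def _check_forest(genes: Sequence[str], associations) -> dict[str, list[tuple[str, float]]]:
    adjacency: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    parent: dict[str, str] = {g: g for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, orr in associations:
        if a not in adjacency or b not in adjacency:
            raise ValueError(f"association references unknown gene ({a}, {b})")
        ra, rb = find(a), find(b)
        if ra == rb:
            raise ValueError("association pairs must form a forest (cycle detected)")
        parent[ra] = rb
        adjacency[a].append((b, orr))
        adjacency[b].append((a, orr))
    return adjacency


def generate_inventory(
    n_per_phylum: Mapping[str, int] | None = None,
    gene_freqs: Mapping[str, float] | Mapping[str, Mapping[str, float]] | None = None,
    associations: Sequence[tuple[str, str, float]] | None = None,
    multi_copy_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[list[GenomeInventory], pd.DataFrame]:
    """Sample genome inventories with planted marginals and associations.

    ``gene_freqs`` is either one gene->probability map applied to every
    phylum or a phylum->gene->probability map.  Associated gene pairs are
    sampled from the exact 2x2 joint distribution matching their odds
    ratio; the pairs must form a forest so the joint factorises along
    trees.  All genomes receive nirK_copies >= 1.
    """
    n_per_phylum = dict(n_per_phylum or DEFAULT_N_PER_PHYLUM)
    gene_freqs = gene_freqs or DEFAULT_GENE_FREQS
    associations = list(associations if associations is not None else DEFAULT_ASSOCIATIONS)
    rng = np.random.default_rng(seed)

    per_phylum = isinstance(next(iter(gene_freqs.values())), Mapping)
    inventories: list[GenomeInventory] = []
    truth_rows: list[dict] = []
    g = 0
    for phylum in sorted(n_per_phylum):
        freqs: Mapping[str, float] = gene_freqs[phylum] if per_phylum else gene_freqs
        for gene, p in freqs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{phylum}/{gene}: probability {p} out of range")
        genes = [gene for gene in GENE_FLAGS if gene in freqs]
        adjacency = _check_forest(genes, associations)
        # precompute joint feasibility once per phylum
        for a, b, orr in associations:
            _joint_p11(freqs[a], freqs[b], orr)
        for _ in range(n_per_phylum[phylum]):
            flags: dict[str, bool] = {}
            for gene in genes:
                if gene in flags:
                    continue
                # BFS over this gene's association tree
                flags[gene] = bool(rng.random() < freqs[gene])
                queue = [gene]
                while queue:
                    cur = queue.pop(0)
                    for nxt, orr in adjacency[cur]:
                        if nxt in flags:
                            continue
                        p11 = _joint_p11(freqs[cur], freqs[nxt], orr)
                        if flags[cur]:
                            cond = p11 / freqs[cur] if freqs[cur] > 0 else 0.0
                        else:
                            cond = (
                                (freqs[nxt] - p11) / (1.0 - freqs[cur])
                                if freqs[cur] < 1
                                else 0.0
                            )
                        flags[nxt] = bool(rng.random() < cond)
                        queue.append(nxt)
            copies = 2 if rng.random() < multi_copy_fraction else 1
            inv = GenomeInventory(
                genome_id=f"g{g:04d}",
                phylum=phylum,
                nirK_copies=copies,
                **{gene: flags.get(gene, False) for gene in GENE_FLAGS},
            )
            inventories.append(inv)
            row = {"genome_id": inv.genome_id, "phylum": phylum, "nirK": copies}
            row.update({gene: int(flags.get(gene, False)) for gene in GENE_FLAGS})
            truth_rows.append(row)
            g += 1
    return inventories, pd.DataFrame(truth_rows)


def cohort_from_summary(
    per_phylum_spec: Mapping[str, Mapping[str, object]],
) -> list[GenomeInventory]:
    """Deterministically construct a cohort reproducing a printed summary.

    ``per_phylum_spec`` maps phylum to a dict with keys: ``n`` (genomes),
    optional ``categories`` (counts per denitrification category, summing
    to n), optional ``combined`` (genomes with DNRA capability, realised
    as nrfA presence) and optional ``multi_copy``.  Classifying and
    summarising the returned table reproduces the specified counts
    exactly; no sampling is involved.
    """
    out: list[GenomeInventory] = []
    for phylum in sorted(per_phylum_spec):
        spec = per_phylum_spec[phylum]
        n = int(spec["n"])
        cats = dict(spec.get("categories") or {})
        if cats:
            unknown = set(cats) - set(DENIT_CATEGORIES_SET)
            if unknown:
                raise ValueError(f"{phylum}: unknown categories {sorted(unknown)}")
            if sum(cats.values()) != n:
                raise ValueError(
                    f"{phylum}: category counts sum to {sum(cats.values())}, n is {n}"
                )
        else:
            cats = {"no_nor_no_nos": n}
        combined = int(spec.get("combined", 0))
        multi = int(spec.get("multi_copy", 0))
        if combined > n or multi > n:
            raise ValueError(f"{phylum}: combined/multi_copy exceed n")
        cat_seq: list[str] = []
        for cat in ("complete", "no_nor", "no_nos", "no_nor_no_nos"):
            cat_seq += [cat] * int(cats.get(cat, 0))
        for k in range(n):
            cat = cat_seq[k]
            out.append(
                GenomeInventory(
                    genome_id=f"{phylum}_{k:03d}",
                    phylum=phylum,
                    nirK_copies=2 if k < multi else 1,
                    nor=cat in ("complete", "no_nos"),
                    nosZ=cat in ("complete", "no_nor"),
                    nrfA=k < combined,
                )
            )
    if not out:
        raise ValueError("empty specification")
    return out


DENIT_CATEGORIES_SET = {"complete", "no_nor", "no_nos", "no_nor_no_nos"}

#: Per-phylum genome counts and printed combined denitrification+DNRA
#: percentages of the 249-genome NirK survey cohort.  These printed values
#: are analysis inputs: `survey_cohort_spec` turns them back into a concrete
#: cohort whose summary reproduces the printed total.
SURVEY_PHYLUM_COMBINED: dict[str, tuple[int, float]] = {
    "Acidobacteria": (1, 0.0),
    "Actinobacteria": (28, 64.3),
    "Alphaproteobacteria": (82, 78.0),
    "Bacteroidetes": (21, 66.7),
    "Betaproteobacteria": (39, 74.4),
    "Verrucomicrobia": (2, 100.0),
    "Chloroflexi": (5, 40.0),
    "Deltaproteobacteria": (2, 50.0),
    "Euryarcheaota": (13, 7.7),
    "Firmicutes": (27, 55.6),
    "Gammaproteobacteria": (23, 73.9),
    "Gemmatimonadetes": (1, 0.0),
    "Nitrospirae": (2, 0.0),
    "Planctomycetes": (1, 100.0),
    "Spirochaetae": (2, 100.0),
}


def survey_cohort_spec() -> dict[str, dict[str, int]]:
    """Cohort spec from the printed per-phylum counts and combined percentages.

    Combined counts are the nearest integer of n × % / 100 (half away from
    zero), the only lossless way back from one-decimal percentages.
    """
    return {
        phylum: {"n": n, "combined": int(math.floor(n * pct / 100.0 + 0.5))}
        for phylum, (n, pct) in SURVEY_PHYLUM_COMBINED.items()
    }
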