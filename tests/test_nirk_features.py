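"""Residue validation, motif/indel/extension calling, clade typing, redundancy."""

import numpy as np
import pytest

from nirktools.nirk_features import (
    DEFAULT_INDEL_REGIONS,
    DomainPattern,
    IndelRegion,
    ResidueRule,
    ResidueRuleSet,
    assign_clade,
    build_profile,
    count_copies,
    detect_extensions,
    detect_indels,
    extract_motifs,
    filter_redundant,
    group_similarity,
    pairwise_identity,
    validate_residues,
)
from nirktools.reference_mapping import map_to_reference
from nirktools.sequence_io import Alignment, SequenceRecord
from nirktools.synthetic_data import AA20, SequenceGenConfig, generate_nirk_set


def _map(rec, ref):
    return map_to_reference(rec, ref)


def test_reference_satisfies_all_nine_rules(reference):
    report, is_nirk = validate_residues(reference.record, _map(reference.record, reference))
    assert len(report) == 9
    assert is_nirk
    roles = {r["role"] for r in report}
    assert roles == {"Cu_ligand", "active_site"}
    assert sum(r["role"] == "Cu_ligand" for r in report) == 7


def test_single_point_mutation_fails_exactly_one_rule(reference):
    s = list(reference.record.residues)
    assert s[99] == "C"  # Cys100
    s[99] = "S"
    rec = SequenceRecord(id="mut", residues="".join(s))
    report, is_nirk = validate_residues(rec, _map(rec, reference))
    assert not is_nirk
    assert sum(r["pass"] for r in report) == 8
    failed = [r for r in report if not r["pass"]]
    assert failed[0]["position"] == 100 and failed[0]["observed"] == "S"


def test_all_alanine_fails_every_rule(reference):
    rec = SequenceRecord(id="ala", residues="A" * 375)
    report, is_nirk = validate_residues(rec, _map(rec, reference))
    assert not is_nirk
    assert not any(r["pass"] for r in report)


def test_x_placeholder_never_satisfies_a_rule(reference):
    s = list(reference.record.residues)
    s[236] = "X"  # His237
    rec = SequenceRecord(id="x", residues="".join(s))
    report, is_nirk = validate_residues(rec, _map(rec, reference))
    assert not is_nirk


def test_rules_beyond_reference_rejected():
    with pytest.raises(ValueError):
        ResidueRuleSet(
            rules=(ResidueRule(400, frozenset("H"), "Cu_ligand"),), reference_length=375
        )


def test_motifs_on_clean_generated_clades(clean_set):
    records, truth, ref = clean_set
    for rec, (_, t) in zip(records, truth.iterrows()):
        his, asp = extract_motifs(rec, _map(rec, ref))
        assert his == t.his237_motif
        assert asp == t.asp62_motif


def test_deleted_his237_motif_flagged(reference):
    s = reference.record.residues
    rec = SequenceRecord(id="d", residues=s[:233] + s[240:])  # drop 234-240
    his, asp = extract_motifs(rec, _map(rec, reference))
    assert "!" in his
    assert asp == "AGDSH"


def test_indel_calls_on_generated_truth(clean_set):
    records, truth, ref = clean_set
    for rec, (_, t) in zip(records, truth.iterrows()):
        calls = {c.region.label: c for c in detect_indels(rec, _map(rec, ref))}
        if t.clade == "II":
            assert calls["linker"].present and calls["linker"].observed_length == 7
            assert calls["tower"].present and calls["tower"].observed_length == 7
        else:
            assert not calls["linker"].present and calls["linker"].observed_length == 0
            assert not calls["tower"].present and calls["tower"].observed_length == 0


def test_bacillus_loop_insertion_called():
    records, truth, ref = generate_nirk_set(
        SequenceGenConfig(n_clade1=2, n_clade2=4, n_bacillus_loop=2, seed=3)
    )
    for rec, (_, t) in zip(records, truth.iterrows()):
        calls = {c.region.label: c for c in detect_indels(rec, _map(rec, ref))}
        assert calls["bacillus_loop"].present == t.bacillus_loop
        if t.bacillus_loop:
            assert calls["bacillus_loop"].observed_length == 6


def test_partial_deletion_majority_threshold(reference):
    s = reference.record.residues
    # delete 5 of 7 linker positions (190-194): majority rule calls it present
    rec5 = SequenceRecord(id="p5", residues=s[:189] + s[194:])
    calls = {c.region.label: c for c in detect_indels(rec5, _map(rec5, reference))}
    assert calls["linker"].present and calls["linker"].observed_length == 5
    # delete 3 of 7: below ceil(7/2)+1 = 4, absent
    rec3 = SequenceRecord(id="p3", residues=s[:189] + s[192:])
    calls = {c.region.label: c for c in detect_indels(rec3, _map(rec3, reference))}
    assert not calls["linker"].present and calls["linker"].observed_length == 3


def test_heme_pattern_found_in_c_overhang(reference):
    rng = np.random.default_rng(2)
    pad = lambda k: "".join(rng.choice([c for c in AA20 if c not in "CHM"], size=k))
    ext = pad(3) + "C" + pad(2) + "CH" + pad(50) + "M"
    rec = SequenceRecord(id="h", residues=reference.record.residues + ext)
    rep = detect_extensions(rec, _map(rec, reference))
    assert rep.heme_found and not rep.cupredoxin_found
    assert rep.offsets["heme_c"] == 3
    assert rep.c_overhang_len == len(ext)


def test_cupredoxin_pattern_found_in_n_overhang(reference):
    rng = np.random.default_rng(3)
    pad = lambda k: "".join(rng.choice([c for c in AA20 if c not in "CHM"], size=k))
    ext = "C" + pad(4) + "H" + pad(4) + "M"
    rec = SequenceRecord(id="c", residues=ext + reference.record.residues)
    rep = detect_extensions(rec, _map(rec, reference))
    assert rep.cupredoxin_found and not rep.heme_found
    assert rep.offsets["cupredoxin"] == 0


def test_overhang_without_cys_finds_nothing(reference):
    rec = SequenceRecord(id="n", residues=reference.record.residues + "A" * 60)
    rep = detect_extensions(rec, _map(rec, reference))
    assert not rep.heme_found and not rep.cupredoxin_found


def test_extensions_never_fire_inside_reference_span(clean_set):
    """The mapped core contains Cys100/His/Met residues; zone restriction must hold."""
    records, truth, ref = clean_set
    for rec, (_, t) in zip(records, truth.iterrows()):
        rep = detect_extensions(rec, _map(rec, ref))
        assert rep.heme_found == t.heme_ext
        assert rep.cupredoxin_found == t.cupredoxin_ext


def test_clade_assignment_rules():
    linker = IndelRegion("linker", 190, 196)
    tower = IndelRegion("tower", 258, 264)
    from nirktools.nirk_features import IndelCall

    both = [IndelCall(linker, True, 7), IndelCall(tower, True, 7)]
    neither = [IndelCall(linker, False, 0), IndelCall(tower, False, 0)]
    one = [IndelCall(linker, True, 7), IndelCall(tower, False, 0)]
    assert assign_clade(both) == "II"
    assert assign_clade(neither) == "I"
    assert assign_clade(one) == "unclassified"


def test_filter_redundant_species_scoped():
    mk = lambda i, sp, seq: SequenceRecord(id=i, residues=seq, species=sp, strain=i)
    seq = "MKVLYTTEGH"
    recs = [
        mk("b_strain", "Bacillus azotoformans", seq),
        mk("a_strain", "Bacillus azotoformans", seq),  # identical, same species
        mk("c_other", "Bacillus bataviensis", seq),  # identical, other species
        mk("d_mut", "Bacillus azotoformans", "MKVLYTTEGY"),  # 1 substitution
    ]
    kept, log = filter_redundant(recs)
    assert {r.id for r in kept} == {"a_strain", "c_other", "d_mut"}
    assert log == [
        {"removed": "b_strain", "kept": "a_strain", "species": "Bacillus azotoformans"}
    ]


def test_group_similarity_hand_counts():
    aln = Alignment(["a", "b"], ["AAAA", "AATT"])
    out = group_similarity(aln)
    assert out["overall"] == pytest.approx(50.0)
    aln2 = Alignment(["a", "b"], ["AAAA", "AAAA"])
    assert group_similarity(aln2)["overall"] == pytest.approx(100.0)
    assert pairwise_identity("AA--", "--AA") is None


def test_group_similarity_matches_bruteforce_and_is_permutation_invariant():
    rng = np.random.default_rng(8)
    rows = ["".join(rng.choice(list("ACDE-"), size=30)) for _ in range(5)]
    ids = [f"r{i}" for i in range(5)]
    aln = Alignment(ids, rows)
    got = group_similarity(aln)["overall"]
    # brute-force all-pairs recount
    vals = []
    for i in range(5):
        for j in range(i + 1, 5):
            same = compared = 0
            for ca, cb in zip(rows[i], rows[j]):
                if ca != "-" and cb != "-":
                    compared += 1
                    same += ca == cb
            vals.append(100.0 * same / compared)
    assert got == pytest.approx(sum(vals) / len(vals))
    assert 0 <= got <= 100
    perm = [3, 1, 4, 0, 2]
    aln_p = Alignment([ids[k] for k in perm], [rows[k] for k in perm])
    assert group_similarity(aln_p)["overall"] == pytest.approx(got)


def test_group_of_one_flagged_undefined():
    aln = Alignment(["a", "b"], ["AAAA", "AATT"])
    out = group_similarity(aln, {"a": "g1", "b": "g2"})
    assert out["g1"] is None and out["g2"] is None


def test_count_copies():
    mk = lambda i: SequenceRecord(id=i, residues="MKV")
    recs = [mk("s1"), mk("s2"), mk("s3")]
    counts, frac = count_copies(recs, {"s1": "g1", "s2": "g1", "s3": "g2"})
    assert counts == {"g1": 2, "g2": 1}
    assert frac == pytest.approx(0.5)
    counts, frac = count_copies(recs, {"s1": "g1", "s2": "g2", "s3": "g3"})
    assert frac == 0.0


def test_multi_copy_fraction_recovered_from_generator():
    records, truth, _ = generate_nirk_set(
        SequenceGenConfig(n_clade1=100, n_clade2=100, multi_copy_fraction=0.05, seed=9)
    )
    genome_of = dict(zip(truth.id, truth.genome_id))
    _, frac = count_copies(records, genome_of)
    # binomial tolerance around the configured 5 %
    assert 0.0 < frac < 0.12
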