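"""Generator determinism, planted structure, association sampling, cohort rebuild."""

import numpy as np
import pytest

from nirktools.nirk_features import build_profile
from nirktools.pathway_inventory import summarize_cohort
from nirktools.reference_mapping import map_to_reference
from nirktools.sequence_io import SequenceRecord
from nirktools.synthetic_data import (
    SequenceGenConfig,
    backtranslate,
    cohort_from_summary,
    generate_inventory,
    generate_nirk_set,
    plant_primer_sites,
    surrogate_reference,
    survey_cohort_spec,
    translate,
)
from nirktools.primer_analysis import Primer, best_binding_site, mismatch_profile


def test_surrogate_reference_is_stable_and_valid():
    r1, r2 = surrogate_reference(), surrogate_reference()
    assert r1.record.residues == r2.record.residues
    assert len(r1) == 375
    s = r1.record.residues
    for pos, aa in [(59, "H"), (62, "D"), (64, "H"), (99, "H"), (100, "C"),
                    (110, "H"), (115, "M"), (237, "H"), (298, "H")]:
        assert s[pos - 1] == aa
    assert s[233:238] == "TRPHL"


def test_generator_reproducible_under_seed():
    a, ta, _ = generate_nirk_set(SequenceGenConfig(substitution_rate=0.1, seed=5))
    b, tb, _ = generate_nirk_set(SequenceGenConfig(substitution_rate=0.1, seed=5))
    assert [r.residues for r in a] == [r.residues for r in b]
    assert ta.equals(tb)
    c, _, _ = generate_nirk_set(SequenceGenConfig(substitution_rate=0.1, seed=6))
    assert [r.residues for r in a] != [r.residues for r in c]


def test_heme_extension_length_arithmetic():
    records, truth, ref = generate_nirk_set(
        SequenceGenConfig(n_clade1=0, n_clade2=10, fraction_with_heme_ext=1.0,
                          fraction_with_cupredoxin_ext=0.0, seed=2)
    )
    assert truth.heme_ext.all()
    for rec in records:
        m = map_to_reference(rec, ref)
        assert m.c_term_overhang >= 57  # C + 2 + CH + 50 + M


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SequenceGenConfig(substitution_rate=1.0)
    with pytest.raises(ValueError):
        SequenceGenConfig(n_clade1=-1)
    from nirktools.nirk_features import IndelRegion

    with pytest.raises(ValueError, match="overlap"):
        SequenceGenConfig(indel_regions=(
            IndelRegion("linker", 190, 196), IndelRegion("other", 195, 200),
        ))


def test_zero_noise_full_truth_recovery(clean_set):
    records, truth, ref = clean_set
    for rec, (_, t) in zip(records, truth.iterrows()):
        p = build_profile(rec, map_to_reference(rec, ref))
        assert p.is_nirk
        assert p.clade == t.clade
        assert p.his237_motif == t.his237_motif
        assert p.extension_report.heme_found == t.heme_ext
        assert p.extension_report.cupredoxin_found == t.cupredoxin_ext


def test_clade_recovery_under_noise_with_protected_positions():
    records, truth, ref = generate_nirk_set(
        SequenceGenConfig(n_clade1=15, n_clade2=15, substitution_rate=0.10, seed=13)
    )
    for rec, (_, t) in zip(records, truth.iterrows()):
        p = build_profile(rec, map_to_reference(rec, ref))
        assert p.clade == t.clade
        assert p.is_nirk  # rule positions are protected from noise


def test_backtranslate_round_trip_and_determinism():
    recs = [SequenceRecord(id="a", residues="MKVLYTTEGH"), SequenceRecord(id="b", residues="M")]
    nt1 = backtranslate(recs, seed=4)
    nt2 = backtranslate(recs, seed=4)
    assert [r.residues for r in nt1] == [r.residues for r in nt2]
    for prot, nt in zip(recs, nt1):
        assert translate(nt.residues) == prot.residues
    assert nt1[1].residues == "ATG"  # Met has a single codon
    with pytest.raises(ValueError):
        backtranslate([SequenceRecord(id="x", residues="MX")], seed=0)


def test_planted_primer_sites_recovered_by_scan():
    records, truth, _ = generate_nirk_set(SequenceGenConfig(seed=3))
    nt = backtranslate(records, seed=3)
    primer = Primer("synF", "GGWCAYGCNAARATHGT", "forward")
    clade_of = dict(zip(truth.id, truth.clade))
    planted, ptruth = plant_primer_sites(
        nt, primer, {"I": {}, "II": {1: 1.0}}, clade_of, seed=5
    )
    for rec, (_, row) in zip(planted, ptruth.iterrows()):
        res = best_binding_site(primer, rec)
        assert res.site_start == row.offset
        assert res.total_mismatches == row.n_mismatches


def test_planted_mismatch_rate_recovered_in_profile():
    records, truth, _ = generate_nirk_set(
        SequenceGenConfig(n_clade1=100, n_clade2=100, seed=6)
    )
    nt = backtranslate(records, seed=7)
    primer = Primer("synF", "GGWCAYGCNAARATHGT", "forward")
    clade_of = dict(zip(truth.id, truth.clade))
    planted, _ = plant_primer_sites(
        nt, primer, {"I": {}, "II": {1: 0.3}}, clade_of, seed=8
    )
    prof = mismatch_profile(primer, planted, clade_of)
    # binomial CI at n=100 around the planted 0.3; Clade I stays clean
    assert 0.17 <= prof.loc["II", 1] <= 0.43
    assert prof.loc["I", 1] == 0.0
    assert prof.loc["I"].sum() == 0.0


def test_inventory_reproducible_and_all_nirk_positive():
    t1, df1 = generate_inventory(seed=3)
    t2, df2 = generate_inventory(seed=3)
    assert df1.equals(df2)
    assert len(t1) == 249  # default cohort size across the fifteen phyla
    assert all(g.nirK_copies >= 1 for g in t1)


def test_planted_negative_association_recovered():
    from nirktools.pathway_inventory import cooccurrence_test

    inv, _ = generate_inventory(
        n_per_phylum={"syn": 250}, associations=[("narG", "nrfA", 0.2)], seed=1
    )
    x = np.array([int(g.narG) for g in inv])
    y = np.array([int(g.nrfA) for g in inv])
    st = cooccurrence_test(x, y)
    assert st.phi < 0
    assert st.p_lt < 0.05


def test_independent_genes_give_small_phi():
    from nirktools.pathway_inventory import cooccurrence_test

    phis = []
    for seed in range(30):
        inv, _ = generate_inventory(
            n_per_phylum={"syn": 200}, associations=[], seed=seed
        )
        x = np.array([int(g.napA) for g in inv])
        y = np.array([int(g.nirB) for g in inv])
        phis.append(cooccurrence_test(x, y).phi)
    assert abs(np.mean(phis)) < 0.05


def test_cyclic_association_spec_rejected():
    with pytest.raises(ValueError, match="association pairs must form a forest"):
        generate_inventory(
            n_per_phylum={"syn": 10},
            associations=[("narG", "nrfA", 0.5), ("nrfA", "napA", 0.5),
                          ("napA", "narG", 0.5)],
            seed=0,
        )
    with pytest.raises(ValueError, match="> 0"):
        generate_inventory(
            n_per_phylum={"syn": 10},
            associations=[("narG", "nrfA", 0.0)],
            seed=0,
        )


def test_cohort_from_summary_exact_round_trip():
    spec = {
        "P1": {"n": 4, "categories": {"complete": 2, "no_nor": 1, "no_nor_no_nos": 1},
               "combined": 3, "multi_copy": 1},
        "P2": {"n": 2, "categories": {"no_nos": 2}, "combined": 0},
    }
    cohort = cohort_from_summary(spec)
    s = summarize_cohort(cohort)
    assert s.loc["P1", "n"] == 4
    assert s.loc["P1", "pct_complete"] == 50.0
    assert s.loc["P1", "pct_combined"] == 75.0
    assert s.loc["P1", "pct_multi_copy"] == 25.0
    assert s.loc["P2", "pct_no_nos"] == 100.0
    assert s.loc["Total", "pct_combined"] == 50.0


def test_cohort_from_summary_two_genomes_half_complete():
    cohort = cohort_from_summary({"P": {"n": 2, "categories": {"complete": 1, "no_nor_no_nos": 1}}})
    assert summarize_cohort(cohort).loc["P", "pct_complete"] == 50.0


def test_cohort_from_summary_rejects_inconsistent_spec():
    with pytest.raises(ValueError, match="sum"):
        cohort_from_summary({"P": {"n": 2, "categories": {"complete": 1}}})
    with pytest.raises(ValueError, match="exceed"):
        cohort_from_summary({"P": {"n": 2, "combined": 3}})


def test_survey_spec_totals():
    spec = survey_cohort_spec()
    assert sum(v["n"] for v in spec.values()) == 249
    assert sum(v["combined"] for v in spec.values()) == 166
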