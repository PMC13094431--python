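"""Accurate-mass search, fragment rules, MS2 matching, Level-2 crossmatch."""

import numpy as np
import pytest

from lipidmsi.annotation import (
    MS2Spectrum,
    UnsupportedClassError,
    accurate_mass_search,
    build_database,
    enumerate_acyl_decompositions,
    fragment_rules,
    level2_crossmatch,
    match_ms2,
    replay_table1_crossmatch,
)
from lipidmsi.chem import ADDUCTS, adduct_mz, parse_shorthand
from lipidmsi.phantom import simulate_ms2


def test_database_fa_grid_enumeration():
    # 13 carbon values x 7 double-bond values per oxidation level
    db0 = build_database([("FA", (12, 24), (0, 6), (0, 0))])
    assert len(db0) == 91
    db1 = build_database([("FA", (12, 24), (0, 6), (0, 1))])
    assert len(db1) == 182
    with pytest.raises(ValueError):
        build_database([])


def test_default_database_covers_table1_species(lipid_db, table1_records):
    for rec in table1_records:
        assert rec.annotation in lipid_db, rec.annotation


def test_accurate_mass_search_finds_oxidized_fa(lipid_db):
    hits = accurate_mass_search(295.23, "negative", lipid_db, tol_da=0.05)
    names = [(h.lipid.species_name, h.adduct.name) for h in hits]
    assert ("FA(18:2;O)", "[M-H]-") in names


def test_accurate_mass_search_edge_cases(lipid_db):
    assert accurate_mass_search(100.0, "negative", lipid_db) == []
    tg = parse_shorthand("TG(52:2)")
    q = adduct_mz(tg.monoisotopic_mass, "[M+Na]+")
    hits = accurate_mass_search(q, "positive", lipid_db)
    assert hits[0].lipid.species_name == "TG(52:2)"
    assert hits[0].delta_ppm == pytest.approx(0.0, abs=1e-9)


def test_search_sorted_by_abs_ppm(lipid_db):
    hits = accurate_mass_search(827.71, "positive", lipid_db, tol_da=0.05)
    ppms = [abs(h.delta_ppm) for h in hits]
    assert ppms == sorted(ppms)


def test_fa_fragment_rules():
    fa = parse_shorthand("FA (18:2;O)")
    frags = fragment_rules(fa, "[M-H]-")
    prec = adduct_mz(fa.monoisotopic_mass, "[M-H]-")
    assert prec == pytest.approx(295.2279, abs=5e-4)
    assert any(abs(f - (prec - 18.0106)) < 1e-3 for f in frags)  # water loss
    assert any(abs(f - (prec - 43.9898)) < 1e-3 for f in frags)  # CO2 loss


def test_tg_fragment_rules_neutral_losses():
    tg = parse_shorthand("TG 14:0_16:0_18:1")
    frags = fragment_rules(tg, "[M+Na]+")
    assert len(frags) == 3  # one loss per distinct acyl
    prec = adduct_mz(tg.monoisotopic_mass, "[M+Na]+")
    from lipidmsi.chem import acyl_mass
    for c, d in [(14, 0), (16, 0), (18, 1)]:
        assert any(abs(f - (prec - acyl_mass(c, d))) < 1e-6 for f in frags)
    # NH4 adduct additionally sheds ammonia
    frags_nh4 = fragment_rules(tg, "[M+NH4]+")
    want = adduct_mz(tg.monoisotopic_mass, "[M+NH4]+") \
        - acyl_mass(18, 1) - 17.02655
    assert any(abs(f - want) < 1e-4 for f in frags_nh4)


def test_pc_headgroup_fragment():
    pc = parse_shorthand("PC(40:7)")
    assert fragment_rules(pc, "[M+Na]+") == [pytest.approx(184.0733, abs=1e-3)]


def test_unsupported_class_adduct_raises():
    fa = parse_shorthand("FA (16:0)")
    with pytest.raises(UnsupportedClassError):
        fragment_rules(fa, "[M+Na]+")
    tg = parse_shorthand("TG(48:1)")  # no chain composition available
    with pytest.raises(ValueError):
        fragment_rules(tg, "[M+Na]+")


def test_acyl_decomposition_enumeration():
    decomps = enumerate_acyl_decompositions(48, 1, 3)
    assert ((14, 0), (16, 0), (18, 1)) in decomps
    assert all(sum(c for c, _ in d) == 48 and sum(b for _, b in d) == 1
               for d in decomps)


def test_match_ms2_identifies_generator_lipid(lipid_db):
    fa = parse_shorthand("FA (18:2;O)")
    spec = simulate_ms2(fa, "[M-H]-", seed=11)
    hits = accurate_mass_search(spec.precursor_mz, "negative", lipid_db)
    best = match_ms2(spec, hits)
    assert best is not None
    assert best.hit.lipid.species_name == "FA(18:2;O)"


def test_match_ms2_no_diagnostic_fragments_rejected(lipid_db):
    spec = MS2Spectrum(precursor_mz=295.2279, polarity="negative",
                       fragments=[(150.0, 5.0)])
    hits = accurate_mass_search(295.2279, "negative", lipid_db)
    assert match_ms2(spec, hits) is None


def test_match_ms2_all_rule_fragments_counted():
    fa = parse_shorthand("FA (16:0)")
    prec = adduct_mz(fa.monoisotopic_mass, "[M-H]-")
    frags = fragment_rules(fa, "[M-H]-")
    spec = MS2Spectrum(prec, "negative", [(f, 10.0) for f in frags])
    hits = accurate_mass_search(prec, "negative", build_database(
        [("FA", (12, 24), (0, 6), (0, 1))]))
    best = match_ms2(spec, hits)
    assert best.matched_fragments == best.rule_fragments == len(frags)


def test_match_ms2_recovers_generator_across_panel(lipid_db):
    """Noiseless simulated spectra identify the generating lipid."""
    cases = [
        ("FA (16:0)", "[M-H]-"), ("FA (18:1;O)", "[M-H]-"),
        ("TG 14:0_16:0_18:1", "[M+Na]+"), ("TG 16:0_18:1_18:1", "[M+NH4]+"),
        ("DG 16:0_16:1", "[M+H-H2O]+"), ("PC(40:6)", "[M+Na]+"),
        ("PE 18:0_22:6", "[M-H]-"), ("PI 18:0_22:6", "[M-H]-"),
        ("LPE (16:0)", "[M-H]-"),
    ]
    for name, adduct in cases:
        lip = parse_shorthand(name)
        spec = simulate_ms2(lip, adduct, seed=5, n_noise_peaks=0)
        hits = accurate_mass_search(spec.precursor_mz,
                                    ADDUCTS[adduct].polarity, lipid_db)
        best = match_ms2(spec, hits)
        assert best is not None, name
        assert best.hit.lipid.species_name == lip.species_name, name


def test_level2_requires_same_lipid_and_adduct():
    dg = parse_shorthand("DG(32:1)")
    tg = parse_shorthand("TG(50:4)")
    hit = lambda lip, add: __import__("lipidmsi").annotation.AnnotationHit(  # noqa: E731
        query_mz=0.0, lipid=lip, adduct=ADDUCTS[add],
        theoretical_mz=adduct_mz(lip.monoisotopic_mass, add),
        delta_da=0.0, delta_ppm=0.0)
    desi = [("f1", hit(dg, "[M+H-H2O]+")), ("f2", hit(tg, "[M+Na]+"))]
    lesa = [(dg, "[M+H-H2O]+", "ms2"), (tg, "[M+NH4]+", "ms2")]
    recs = level2_crossmatch(desi, lesa)
    assert [(r.feature_id, r.lipid_name) for r in recs] == [("f1", "DG(32:1)")]


def test_table1_replay_yields_52_level2_records(table1_records):
    recs = replay_table1_crossmatch(table1_records)
    assert len(recs) == 52


def test_table1_theoretical_masses_within_10ppm(table1_records):
    """Parser + adduct arithmetic reproduce every printed LESA mass."""
    from lipidmsi.chem import ppm_deviation

    worst = 0.0
    for rec in table1_records:
        lip = parse_shorthand(rec.annotation)
        theo = adduct_mz(lip.monoisotopic_mass, rec.lesa_adduct)
        worst = max(worst, abs(ppm_deviation(rec.lesa_observed_ms1, theo)))
    assert worst <= 10.0
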