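import pytest
from hypothesis import given
from hypothesis import strategies as st

from serpinms.glycan_model import AntennaSpec, biantennary, build_nglycan
from serpinms.proteoform_library import (
    AVERAGE_AA_MASS,
    GLYCOSITE_PRESETS,
    SERPINA1_NTERM_TRUNCATION,
    SERPINA1_VARIANTS,
    ProteinSequence,
    VariantDef,
    apply_variant,
    backbone_mass,
    collision_report,
    complex_mass,
    enumerate_proteoforms,
    find_sequons,
    library_frame,
    make_complex,
    make_proteoform,
)


def test_bundled_serpina1_fixture(serpina1):
    assert len(serpina1) == 418
    # the paper's residue labels resolve on the canonical M1V backbone
    for pos, aa in [(70, "N"), (107, "N"), (271, "N"), (256, "C"),
                    (125, "R"), (237, "V"), (400, "E"), (382, "M"), (383, "S")]:
        assert serpina1.residue_at(pos) == aa


def test_sequon_scan_serpina1(serpina1):
    assert find_sequons(serpina1) == [70, 107, 271]


@pytest.mark.parametrize(
    "residues, expected",
    [("NPS", []), ("NAS", [1]), ("NAT", [1]), ("NASNAT", [1, 4])],
)
def test_sequon_scan_motifs(residues, expected):
    assert find_sequons(ProteinSequence("x", residues)) == expected


def test_canonical_variant_is_identity(serpina1):
    assert apply_variant(serpina1, SERPINA1_VARIANTS["M1V"]).residues == serpina1.residues


@pytest.mark.parametrize(
    "name, delta",
    [("M3", -14.03), ("M2", -33.07), ("M1A", -28.05)],
)
def test_variant_mass_deltas(serpina1, name, delta):
    variant = SERPINA1_VARIANTS[name]
    base = backbone_mass(serpina1)
    varied = backbone_mass(apply_variant(serpina1, variant))
    assert varied - base == pytest.approx(delta, abs=0.005)
    assert variant.mass_delta() == pytest.approx(delta, abs=0.005)


def test_variant_ref_mismatch_names_position(serpina1):
    bad = VariantDef("bogus", ((400, "K", "D"),))
    with pytest.raises(ValueError, match="400"):
        apply_variant(serpina1, bad)


@given(
    position=st.integers(30, 418),
    alt=st.sampled_from(sorted(AVERAGE_AA_MASS)),
)
def test_variant_delta_depends_only_on_residue_identities(serpina1, position, alt):
    ref = serpina1.residue_at(position)
    variant = VariantDef("v", ((position, ref, alt),))
    base = backbone_mass(serpina1)
    assert backbone_mass(apply_variant(serpina1, variant)) - base == pytest.approx(
        AVERAGE_AA_MASS[alt] - AVERAGE_AA_MASS[ref], abs=1e-9
    )


def test_backbone_masses():
    assert backbone_mass("G") == pytest.approx(75.07, abs=0.005)
    assert backbone_mass("GG") - backbone_mass("G") == pytest.approx(57.05, abs=0.005)
    # empty chain weighs one water (documented boundary, useful for fragments)
    assert backbone_mass("") == pytest.approx(18.02, abs=0.005)
    with pytest.raises(ValueError, match="X"):
        backbone_mass("GXG")


def test_mature_chain_masses(serpina1, a2g2s2):
    # native MS observes the secreted chain: 51-53 kDa with three N-glycans
    p = make_proteoform(
        serpina1, SERPINA1_VARIANTS["M1V"], site_glycans={s: a2g2s2 for s in (70, 107, 271)}
    )
    assert 50_700 < p.mass < 51_200
    trunc = make_proteoform(
        serpina1,
        SERPINA1_VARIANTS["M1V"],
        truncation=SERPINA1_NTERM_TRUNCATION,
        site_glycans={s: a2g2s2 for s in (70, 107, 271)},
    )
    assert p.mass - trunc.mass == pytest.approx(526.50, abs=0.01)  # EDPQG


def test_library_product_count_and_spacings(serpina1, a2g2s2):
    variants = [SERPINA1_VARIANTS[v] for v in ("M1V", "M1A", "M2", "M3")]
    lib = enumerate_proteoforms(
        serpina1, variants, (None,), (0, 1), {s: [a2g2s2] for s in (70, 107, 271)}
    )
    assert len(lib) == 8  # 4 variants x 1 truncation x 2 cys x 1 glycoform
    masses = {p.label: p.mass for p in lib}
    m1v = next(p for p in lib if p.variant.name == "M1V" and not p.cysteinylation_count)
    m3 = next(p for p in lib if p.variant.name == "M3" and not p.cysteinylation_count)
    assert m1v.mass - m3.mass == pytest.approx(14.03, abs=0.005)

    tri = build_nglycan([AntennaSpec(True, True, True)] * 3, name="A3G3S3")
    extra = make_proteoform(
        serpina1, SERPINA1_VARIANTS["M1V"], site_glycans={70: a2g2s2, 107: tri, 271: a2g2s2}
    )
    assert extra.mass - m1v.mass == pytest.approx(656.60, abs=0.005)


def test_library_spans_reported_mass_window(serpina1, a2g2s2):
    """M1V with three bi-antennary glycans + 0-3 extra branch units covers
    the 51-53 kDa window seen for plasma SERPINA1."""
    tri = build_nglycan([AntennaSpec(True, True, True)] * 3, name="A3G3S3")
    lib = enumerate_proteoforms(
        serpina1,
        [SERPINA1_VARIANTS["M1V"]],
        (None,),
        (0,),
        {70: [a2g2s2, tri], 107: [a2g2s2, tri], 271: [a2g2s2, tri]},
    )
    masses = [p.mass for p in lib]
    assert min(masses) == pytest.approx(51_000, abs=200)
    assert max(masses) == pytest.approx(53_000, abs=200)


def test_empty_inputs_give_empty_library(serpina1):
    assert enumerate_proteoforms(serpina1, [], (None,), (0,), {}) == []


def test_dedup_modes_for_isomeric_glycoforms(serpina1, core_fuc_a2g2s2, antennary_fuc_a2g2s2):
    variants = [SERPINA1_VARIANTS["M1V"]]
    sets = {271: [core_fuc_a2g2s2, antennary_fuc_a2g2s2]}
    by_comp = enumerate_proteoforms(serpina1, variants, (None,), (0,), sets)
    by_topo = enumerate_proteoforms(serpina1, variants, (None,), (0,), sets, dedup="topology")
    assert len(by_comp) == 1  # isomers are one intact-level mass class
    assert len(by_topo) == 2  # but two distinct binding classes


def test_collision_report_flags_near_isobaric_pairs(serpina1, a2g2s2):
    from serpinms.glycan_model import GlycanComposition

    variants = [SERPINA1_VARIANTS[v] for v in ("M1V", "M1A", "M2")]
    plus2fuc = GlycanComposition({"HexNAc": 4, "Hex": 5, "Neu5Ac": 2, "Fuc": 2})
    plus1neu = GlycanComposition({"HexNAc": 4, "Hex": 5, "Neu5Ac": 3})
    lib = enumerate_proteoforms(
        serpina1, variants, (None,), (0,),
        {70: [a2g2s2], 107: [a2g2s2], 271: [a2g2s2, plus2fuc, plus1neu]},
    )
    report = collision_report(lib, threshold=6.0)
    deltas = sorted(report["delta_da"].round(2).unique())
    assert 5.02 in deltas  # M2 vs M1A backbones
    assert 1.03 in deltas  # +2 Fuc vs +1 Neu5Ac glycoforms


def test_complex_mass_modes(serpina1, a2g2s2):
    p = make_proteoform(
        serpina1, SERPINA1_VARIANTS["M1V"], site_glycans={s: a2g2s2 for s in (70, 107, 271)}
    )
    intact = make_complex(p, 25_900.0, protease_name="elastase")
    assert intact.mass == pytest.approx(p.mass + 25_900.0, abs=1e-6)

    released = make_complex(
        p, 25_900.0, mode="loop_fragment_released", sequence=serpina1, cleavage_position=383
    )
    fragment = backbone_mass(serpina1.residues[382:])  # Ser383..Lys418 peptide
    assert released.mass == pytest.approx(intact.mass - fragment, abs=1e-6)

    with pytest.raises(ValueError):
        make_complex(p, 0.0)
    with pytest.raises(ValueError):
        make_complex(p, 25_900.0, mode="loop_fragment_released")  # no cleavage site


def test_glycosite_presets_kept_verbatim():
    assert GLYCOSITE_PRESETS["SERPINA1"] == (70, 107, 271)
    assert 133 in GLYCOSITE_PRESETS["SERPINA3_main"]
    assert 33 in GLYCOSITE_PRESETS["SERPINA3_alt"]
    assert len(GLYCOSITE_PRESETS["SERPINA3_main"]) == len(GLYCOSITE_PRESETS["SERPINA3_alt"]) == 6


def test_library_frame_columns(serpina1, a2g2s2, core_fuc_a2g2s2):
    lib = enumerate_proteoforms(
        serpina1, [SERPINA1_VARIANTS["M1V"]], (None,), (0,),
        {271: [a2g2s2, core_fuc_a2g2s2]}, dedup="topology",
    )
    df = library_frame(lib)
    assert {"label", "variant", "average_mass", "core_fucoses"} <= set(df.columns)
    assert df["average_mass"].is_monotonic_increasing
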