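import numpy as np
import pytest

from serpinms.deconv_assign import (
    PeakList,
    assign,
    assignments_frame,
    infer_charge,
    neutral_mass,
    pick_peaks,
    read_peaklist_csv,
)
from serpinms.glycan_model import GlycanComposition, biantennary
from serpinms.proteoform_library import SERPINA1_VARIANTS, enumerate_proteoforms, make_proteoform
from serpinms.spectrum_sim import PROTON_MASS, EnsembleMember, SimParams, Spectrum, mz_of, simulate_spectrum


def _gaussian(grid, mu, sigma, h=1.0):
    return h * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)


def test_pick_single_noiseless_gaussian():
    grid = np.arange(3000.0, 3010.0, 0.01)
    spectrum = Spectrum(grid, _gaussian(grid, 3005.0, 0.06))
    peaks = pick_peaks(spectrum)
    assert len(peaks) == 1
    assert peaks.mz[0] == pytest.approx(3005.0, abs=1e-3)


def test_pick_two_separated_gaussians():
    grid = np.arange(3000.0, 3010.0, 0.01)
    y = _gaussian(grid, 3004.0, 0.06) + _gaussian(grid, 3006.0, 0.06, h=0.5)
    peaks = pick_peaks(Spectrum(grid, y))
    assert len(peaks) == 2
    assert peaks.intensity[0] == pytest.approx(1.0, abs=0.01)
    assert peaks.intensity[1] == pytest.approx(0.5, abs=0.01)


def test_flat_spectrum_yields_no_peaks():
    grid = np.arange(3000.0, 3010.0, 0.01)
    assert len(pick_peaks(Spectrum(grid, np.ones_like(grid)))) == 0
    assert len(pick_peaks(Spectrum(np.array([1.0]), np.array([0.0])))) == 0


def test_min_spacing_merges_shoulders():
    grid = np.arange(3000.0, 3010.0, 0.01)
    y = _gaussian(grid, 3005.0, 0.06) + _gaussian(grid, 3005.1, 0.06, h=0.4)
    assert len(pick_peaks(Spectrum(grid, y), min_spacing=0.5)) == 1


def test_peaklist_invariants():
    with pytest.raises(ValueError):
        PeakList(np.array([2.0, 1.0]), np.array([1.0, 1.0]))  # not increasing
    with pytest.raises(ValueError):
        PeakList(np.array([1.0, 2.0]), np.array([1.0, -1.0]))  # negative intensity


def test_peaklist_csv_round_trip(tmp_path):
    pl = PeakList(np.array([100.0, 200.0]), np.array([1.0, 2.0]))
    path = tmp_path / "peaks.csv"
    pl.write_csv(path)
    back = read_peaklist_csv(path)
    assert np.allclose(back.mz, pl.mz) and np.allclose(back.intensity, pl.intensity)


def test_infer_charge_from_adjacent_pair():
    # two charge states of one ~50 kDa species
    peaks = PeakList(np.array([3572.58, 3847.31]), np.array([1.0, 1.0]))
    zs = infer_charge(peaks, z_range=(10, 18), mass_tol=2.0)
    assert zs.tolist() == [14, 13]
    # implied neutral masses agree
    assert neutral_mass(3847.31, 13) == pytest.approx(neutral_mass(3572.58, 14), abs=0.5)


def test_infer_charge_fixed_z():
    peaks = PeakList(np.array([3655.0]), np.array([1.0]))
    assert infer_charge(peaks, fixed_z=14).tolist() == [14]


def test_unrelated_peaks_are_flagged():
    peaks = PeakList(np.array([1234.5, 2718.3, 4242.0]), np.array([1.0, 1.0, 1.0]))
    zs = infer_charge(peaks, z_range=(10, 18), mass_tol=0.5)
    assert zs.tolist() == [0, 0, 0]


@pytest.fixture
def small_library(serpina1, a2g2s2):
    variants = [SERPINA1_VARIANTS[v] for v in ("M1V", "M1A", "M2", "M3")]
    return enumerate_proteoforms(
        serpina1, variants, (None,), (0,), {s: [a2g2s2] for s in (70, 107, 271)}
    )


def test_assign_unique_closure(small_library):
    entry = small_library[0]
    peaks = PeakList(np.array([mz_of(entry.mass, 14)]), np.array([1.0]))
    assignments = assign(peaks, [14], small_library, tolerance=1.0)
    assert assignments[0].unique
    assert assignments[0].best.label == entry.label
    assert abs(assignments[0].best.error_da) < 1e-6


def test_fucose_vs_sialic_acid_ambiguity(serpina1, a2g2s2):
    """+2 Fuc and +1 Neu5Ac explanations differ by 1.03 Da: at 2 Da tolerance
    both candidates must be reported in one ambiguity group."""
    base = {"HexNAc": 4, "Hex": 5, "Neu5Ac": 2}
    plus2fuc = GlycanComposition(base) + GlycanComposition({"Fuc": 2})
    plus1neu = GlycanComposition(base) + GlycanComposition({"Neu5Ac": 1})
    lib = enumerate_proteoforms(
        serpina1, [SERPINA1_VARIANTS["M1V"]], (None,), (0,),
        {70: [a2g2s2], 107: [a2g2s2], 271: [plus2fuc, plus1neu]},
    )
    assert len(lib) == 2
    observed = (lib[0].mass + lib[1].mass) / 2
    peaks = PeakList(np.array([mz_of(observed, 14)]), np.array([1.0]))
    result = assign(peaks, [14], lib, tolerance=2.0)[0]
    assert len(result.candidates) == 2
    assert result.ambiguity_group == 1


def test_m2_m1a_pair_resolved_by_tolerance(small_library):
    m2 = next(p for p in small_library if p.variant.name == "M2")
    peaks = PeakList(np.array([mz_of(m2.mass, 14)]), np.array([1.0]))
    tight = assign(peaks, [14], small_library, tolerance=1.0)[0]
    assert tight.unique and tight.best.label == m2.label
    loose = assign(peaks, [14], small_library, tolerance=6.0)[0]
    labels = {c.label for c in loose.candidates}
    assert any("M1A" in label for label in labels)  # 5.02 Da away -> grouped
    assert loose.ambiguity_group is not None


def test_assignment_symmetric_in_library_order(small_library):
    m2 = next(p for p in small_library if p.variant.name == "M2")
    peaks = PeakList(np.array([mz_of(m2.mass, 14)]), np.array([1.0]))
    forward = assign(peaks, [14], small_library, tolerance=6.0)[0]
    backward = assign(peaks, [14], list(reversed(small_library)), tolerance=6.0)[0]
    assert [c.label for c in forward.candidates] == [c.label for c in backward.candidates]


def test_ppm_error_consistency(small_library):
    entry = small_library[0]
    peaks = PeakList(np.array([mz_of(entry.mass + 0.5, 14)]), np.array([1.0]))
    result = assign(peaks, [14], small_library, tolerance=1.0)[0]
    c = result.best
    assert c.error_ppm == pytest.approx(c.error_da / result.neutral_mass * 1e6, rel=1e-12)


def test_assign_validation(small_library):
    peaks = PeakList(np.array([3000.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        assign(peaks, [14], small_library, tolerance=-1.0)
    with pytest.raises(ValueError):
        assign(peaks, [14], [], tolerance=1.0)


def test_round_trip_simulate_pick_infer_assign(serpina1, small_library):
    """Noiseless closure: every simulated member recovered uniquely, every
    recovered mass within 0.1 Da of truth."""
    members = [EnsembleMember(p, 1.0 + 0.05 * i) for i, p in enumerate(small_library)]
    params = SimParams(charge_center=13.5, charge_spread=0.8, resolution=25_000, seed=0)
    spectrum = simulate_spectrum(members, params)
    peaks = pick_peaks(spectrum)
    zs = infer_charge(peaks, z_range=(10, 18), mass_tol=2.0)
    assert (zs > 0).all()
    assignments = assign(peaks, zs, small_library, tolerance=1.0)
    recovered = {}
    for a in assignments:
        assert a.unique
        recovered.setdefault(a.best.label, []).append(abs(a.best.error_da))
    assert set(recovered) == {p.label for p in small_library}
    assert max(max(v) for v in recovered.values()) < 0.1


def test_assignments_frame_export(small_library):
    entry = small_library[0]
    peaks = PeakList(np.array([mz_of(entry.mass, 14)]), np.array([1.0]))
    df = assignments_frame(assign(peaks, [14], small_library, tolerance=1.0, replicate=2))
    assert df.loc[0, "best_match"] == entry.label
    assert df.loc[0, "replicate"] == 2
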