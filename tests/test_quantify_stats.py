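import numpy as np
import pandas as pd
import pytest

from serpinms.deconv_assign import PeakList, assign
from serpinms.glycan_model import biantennary
from serpinms.proteoform_library import SERPINA1_VARIANTS, make_complex, make_proteoform
from serpinms.quantify_stats import (
    GlycopeptideRecord,
    abundance_table,
    compare_ratio_groups,
    complex_apo_ratio,
    feature_trend,
    site_fucosylation_summary,
)
from serpinms.spectrum_sim import mz_of


@pytest.fixture
def two_class_assignments(serpina1, a2g2s2, core_fuc_a2g2s2):
    """Two apo proteoforms + their complexes, one peak each, chosen intensities."""
    p1 = make_proteoform(serpina1, SERPINA1_VARIANTS["M1V"], site_glycans={271: a2g2s2})
    p2 = make_proteoform(serpina1, SERPINA1_VARIANTS["M3"], site_glycans={271: a2g2s2})
    c1 = make_complex(p1, 25_900.0)
    c2 = make_complex(p2, 25_900.0)
    library = [p1, p2, c1, c2]

    def build(intensities):
        order = np.argsort([mz_of(e.mass, 14) for e in library])
        mzs = np.array([mz_of(library[i].mass, 14) for i in order])
        heights = np.array([intensities[i] for i in order])
        peaks = PeakList(mzs, heights)
        return assign(peaks, [14] * 4, library, tolerance=1.0)

    return library, build


def test_single_class_abundance_is_one(serpina1, a2g2s2):
    p = make_proteoform(serpina1, SERPINA1_VARIANTS["M1V"], site_glycans={271: a2g2s2})
    peaks = PeakList(np.array([mz_of(p.mass, 14)]), np.array([7.0]))
    table = abundance_table(assign(peaks, [14], [p], tolerance=1.0))
    assert table["abundance"].tolist() == [1.0]


def test_equal_intensities_split_half(two_class_assignments):
    _, build = two_class_assignments
    table = abundance_table(build([3.0, 3.0, 5.0, 5.0]))
    apo = table[table["condition"] == "apo"]["abundance"]
    assert np.allclose(apo, 0.5)


def test_charge_state_intensities_are_summed(serpina1, a2g2s2):
    p = make_proteoform(serpina1, SERPINA1_VARIANTS["M1V"], site_glycans={271: a2g2s2})
    q = make_proteoform(serpina1, SERPINA1_VARIANTS["M3"], site_glycans={271: a2g2s2})
    rows = sorted(
        [
            (mz_of(p.mass, 13), 13, 1.0),
            (mz_of(q.mass, 13), 13, 3.0),
            (mz_of(p.mass, 14), 14, 2.0),
            (mz_of(q.mass, 14), 14, 2.0),
        ]
    )
    peaks = PeakList(np.array([r[0] for r in rows]), np.array([r[2] for r in rows]))
    zs = [r[1] for r in rows]
    table = abundance_table(assign(peaks, zs, [p, q], tolerance=1.0), normalization="global")
    total = dict(zip(table["class"], table["abundance"]))
    assert total[p.label] == pytest.approx(3.0 / 8.0)
    assert total[q.label] == pytest.approx(5.0 / 8.0)


def test_normalization_sums_to_one(two_class_assignments):
    _, build = two_class_assignments
    table = abundance_table(build([1.0, 2.0, 3.0, 4.0]))
    sums = table.groupby("condition")["abundance"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    global_table = abundance_table(build([1.0, 2.0, 3.0, 4.0]), normalization="global")
    assert global_table["abundance"].sum() == pytest.approx(1.0, abs=1e-9)


def test_complex_apo_ratio_values(two_class_assignments):
    _, build = two_class_assignments
    table = abundance_table(build([1.0, 1.0, 2.0, 1.0]), normalization="global")
    ratios = {r.label: r.mean for r in complex_apo_ratio(table)}
    assert list(ratios.values()) == pytest.approx([2.0, 1.0])


def test_zero_apo_ratio_is_flagged():
    table = pd.DataFrame(
        {
            "class": ["a"] * 4,
            "condition": ["apo", "complex", "apo", "complex"],
            "replicate": [1, 1, 2, 2],
            "abundance": [0.0, 1.0, 2.0, 1.0],
        }
    )
    (result,) = complex_apo_ratio(table)
    assert result.flagged_replicates == (1,)
    assert result.n == 1 and result.mean == pytest.approx(0.5)


def test_ratio_sd_uses_n_minus_one():
    table = pd.DataFrame(
        {
            "class": ["a"] * 6,
            "condition": ["apo", "complex"] * 3,
            "replicate": [1, 1, 2, 2, 3, 3],
            "abundance": [1.0, 1.0, 1.0, 2.0, 1.0, 3.0],
        }
    )
    (result,) = complex_apo_ratio(table)
    assert result.mean == pytest.approx(2.0)
    assert result.sd == pytest.approx(np.std([1, 2, 3], ddof=1))


def test_t_test_identical_groups():
    result = compare_ratio_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert result.t == 0.0 and result.p == 1.0


def test_t_test_degenerate_separated_groups():
    result = compare_ratio_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    assert result.p == 0.0 and np.isinf(result.t)


def test_t_test_requires_two_replicates():
    with pytest.raises(ValueError):
        compare_ratio_groups([1.0], [1.0, 2.0])


def test_t_test_matches_scipy():
    from scipy import stats

    a, b = [1.0, 1.4, 0.9], [2.0, 1.8, 2.4]
    ours = compare_ratio_groups(a, b, variant="welch")
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert ours.t == pytest.approx(ref.statistic) and ours.p == pytest.approx(ref.pvalue)
    pooled = compare_ratio_groups(a, b, variant="pooled")
    ref_pooled = stats.ttest_ind(a, b, equal_var=True)
    assert pooled.p == pytest.approx(ref_pooled.pvalue)


def test_site_fucosylation_percentages():
    records = [
        GlycopeptideRecord(271, "HexNAc4Hex5Fuc1", "core", 9.0),
        GlycopeptideRecord(271, "HexNAc4Hex5Fuc1", "antennary", 1.0),
        GlycopeptideRecord(107, "HexNAc4Hex5", "none", 5.0),
    ]
    df = site_fucosylation_summary(records, known_sites=(70, 107, 271)).set_index("site")
    assert df.loc[271, "percent_core"] == pytest.approx(90.0)
    assert df.loc[271, "percent_antennary"] == pytest.approx(10.0)
    assert df.loc[107, "percent_nonfucosylated"] == pytest.approx(100.0)
    shares = df[["percent_core", "percent_antennary", "percent_nonfucosylated"]].sum(axis=1)
    assert np.allclose(shares, 100.0, atol=1e-6)


def test_site_summary_errors():
    with pytest.raises(ValueError):
        site_fucosylation_summary([])
    with pytest.raises(ValueError, match="99"):
        site_fucosylation_summary(
            [GlycopeptideRecord(99, "x", "core", 1.0)], known_sites=(70,)
        )


def test_site_summary_column_mapping():
    df = pd.DataFrame(
        {
            "GlycoSite": [70, 70],
            "FucType": ["core", "none"],
            "Area": [1.0, 3.0],
        }
    )
    out = site_fucosylation_summary(
        df, column_map={"GlycoSite": "site", "FucType": "placement", "Area": "intensity"}
    )
    assert out.loc[0, "percent_core"] == pytest.approx(25.0)


def test_feature_trend_geometric_series():
    trend = feature_trend({0: 4.0, 1: 2.0, 2: 1.0})
    assert trend.direction == "decreasing"
    assert trend.fold_per_step == pytest.approx(0.5)
    assert trend.rank_correlation == pytest.approx(-1.0)


def test_feature_trend_flat():
    trend = feature_trend({0: 1.5, 1: 1.5, 2: 1.5})
    assert trend.direction == "flat"
    assert trend.rank_correlation == 0.0
    assert trend.fold_per_step == pytest.approx(1.0)


def test_feature_trend_needs_three_levels():
    with pytest.raises(ValueError):
        feature_trend({0: 1.0, 1: 2.0})
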