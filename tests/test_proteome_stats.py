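import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmtopo.proteome_stats import (
    VENN_REGIONS,
    feature_correlation_curve,
    length_histogram,
    multiplicity_profile,
    quantile_profile,
    subset_proteome,
    venn_partition,
)
from ptmtopo.sequence_features import build_feature_table, features_to_frame
from ptmtopo.synthetic_data import SyntheticConfig, generate_proteome
from ptmtopo.types import FeatureKind

from .oracles import naive_venn_regions


def _rows(data: list[dict]) -> pd.DataFrame:
    base = {
        "accession": None,
        "length": 100,
        "n_tm": 0,
        "n_ss": 0,
        "n_glyc": 0,
        "n_cys": 0,
        "n_sequon": 0,
        "n_ss_cys": 0,
        "n_glyc_on_sequon": 0,
    }
    return pd.DataFrame([{**base, **d} for d in data])


# ---------------------------------------------------------------------------
# Length histogram
# ---------------------------------------------------------------------------


def test_length_histogram_small_example():
    hist = length_histogram([5, 5, 5, 100], bin_width=10)
    assert hist.mean_length == pytest.approx(28.75)
    assert hist.counts.sum() == hist.n == 4
    assert hist.peak_window[0] <= 5 <= hist.peak_window[1]
    assert hist.peak_window[1] - hist.peak_window[0] == 10


def test_length_histogram_earliest_peak_on_ties():
    hist = length_histogram([10, 300], bin_width=100)
    assert hist.peak_window == (10, 110)


def test_length_histogram_permutation_invariant():
    a = length_histogram([5, 9, 100, 42, 42], bin_width=10)
    b = length_histogram([42, 100, 5, 42, 9], bin_width=10)
    assert np.array_equal(a.counts, b.counts) and a.peak_window == b.peak_window


def test_length_histogram_empty_errors():
    with pytest.raises(ValueError):
        length_histogram([])


def test_length_histogram_mean_matches_lognormal_analytic():
    # lengths from the generator's length model (features disabled for speed):
    # analytic lognormal mean = median * exp(sigma^2 / 2)
    cfg = SyntheticConfig(
        n_proteins=10_000,
        seed=123,
        fraction_tm=0.0,
        p_signal=0.0,
        cys_density=0.0,
        sequon_density=0.0,
        interchain_rate=0.0,
    )
    proteome = generate_proteome(cfg)
    lengths = [r.length for r in proteome.records]
    hist = length_histogram(lengths)
    analytic_mean = cfg.length_median * math.exp(cfg.length_sigma**2 / 2)
    analytic_sd = analytic_mean * math.sqrt(math.exp(cfg.length_sigma**2) - 1)
    se = analytic_sd / math.sqrt(len(lengths))
    assert abs(hist.mean_length - analytic_mean) < 2 * se + 1.0  # +1 aa: min-length clamp


# ---------------------------------------------------------------------------
# Multiplicity profiles
# ---------------------------------------------------------------------------


def test_multiplicity_profile_trivial():
    frame = _rows(
        [
            {"accession": "A", "n_ss": 1},
            {"accession": "B", "n_ss": 1},
            {"accession": "C", "n_ss": 2},
            {"accession": "D", "n_ss": 0},  # excluded: no feature
        ]
    )
    table = multiplicity_profile(frame, FeatureKind.SS)
    assert dict(zip(table["multiplicity"], table["protein_count"])) == {"1": 2, "2": 1}
    assert table["protein_count"].sum() == 3


def test_multiplicity_binning_above_threshold():
    frame = _rows(
        [{"accession": f"P{i}", "n_glyc": c} for i, c in enumerate([1, 30, 31, 35, 40, 41, 102])]
    )
    table = multiplicity_profile(frame, FeatureKind.NGLYC)
    counts = dict(zip(table["multiplicity"], table["protein_count"]))
    assert counts == {"1": 1, "30": 1, "31-40": 3, "41-50": 1, "101-110": 1}


def test_multiplicity_recovers_geometric_frequencies():
    rng = np.random.default_rng(5)
    counts = rng.geometric(0.5, size=3000)
    frame = _rows([{"accession": f"P{i}", "n_ss": int(c)} for i, c in enumerate(counts)])
    table = multiplicity_profile(frame, FeatureKind.SS)
    observed = dict(zip(table["multiplicity"], table["protein_count"]))
    n = len(counts)
    for m in (1, 2, 3):
        expected = n * 0.5**m
        assert abs(observed[str(m)] - expected) < 4 * math.sqrt(expected)


def test_multiplicity_pooled_rate_bounded_by_per_protein_rates(study_frame):
    table = multiplicity_profile(study_frame, FeatureKind.SS)
    sub = study_frame[study_frame["n_ss"] >= 1].copy()
    sub["util"] = sub["n_ss_cys"] / sub["n_cys"]
    for mult, pooled in zip(table["multiplicity"], table["pooled_rate"]):
        if "-" in mult:
            continue
        grp = sub[sub["n_ss"] == int(mult)]
        assert grp["util"].min() - 1e-12 <= pooled <= grp["util"].max() + 1e-12


def test_multiplicity_exclusion_list():
    frame = _rows([{"accession": "A", "n_glyc": 5}, {"accession": "B", "n_glyc": 5}])
    table = multiplicity_profile(frame, FeatureKind.NGLYC, exclude=["B"])
    assert table["protein_count"].sum() == 1


# ---------------------------------------------------------------------------
# Correlation curves
# ---------------------------------------------------------------------------


def test_feature_correlation_curve_trivial():
    frame = _rows(
        [
            {"accession": "A", "n_ss": 1, "n_glyc": 2, "n_tm": 0},
            {"accession": "B", "n_ss": 1, "n_glyc": 4, "n_tm": 2},
        ]
    )
    curve = feature_correlation_curve(frame, FeatureKind.SS)
    row = curve[curve["n_ss"] == 1].iloc[0]
    assert row["mean_n_glyc"] == pytest.approx(3.0)
    assert row["mean_n_tm"] == pytest.approx(1.0)


def test_feature_correlation_recovers_planted_coupling():
    # rows built with glyc = ss + noise and TM decaying in ss: the curve
    # must show a ~unit slope for glyc and a decreasing TM trend
    rng = np.random.default_rng(3)
    ss = rng.integers(1, 20, size=4000)
    glyc = ss + rng.poisson(1.0, size=ss.size)
    tm = rng.poisson(8.0 * np.exp(-0.4 * ss))
    frame = _rows(
        [
            {"accession": f"P{i}", "n_ss": int(s), "n_glyc": int(g), "n_tm": int(t)}
            for i, (s, g, t) in enumerate(zip(ss, glyc, tm))
        ]
    )
    curve = feature_correlation_curve(frame, FeatureKind.SS)
    slope = np.polyfit(curve["n_ss"], curve["mean_n_glyc"], 1)[0]
    assert slope == pytest.approx(1.0, abs=0.05)
    low = curve[curve["n_ss"] <= 3]["mean_n_tm"].mean()
    high = curve[curve["n_ss"] >= 10]["mean_n_tm"].mean()
    assert low > high


def test_feature_correlation_swapped_axes_consistent(study_frame):
    sub = subset_proteome(study_frame, "ss_nglyco")
    a = feature_correlation_curve(sub, FeatureKind.SS, [FeatureKind.NGLYC])
    b = feature_correlation_curve(sub, FeatureKind.NGLYC, [FeatureKind.SS])
    # both views must reproduce the same grand total of (ss, glyc) mass
    total_a = (a["n_ss"] * a["n_proteins"]).sum()
    total_b = (b["mean_n_ss"] * b["n_proteins"]).sum()
    assert total_a == pytest.approx(total_b)


# ---------------------------------------------------------------------------
# Venn partitions
# ---------------------------------------------------------------------------


def test_venn_partition_trivial_assignment():
    frame = _rows(
        [
            {"accession": "A", "n_tm": 1, "n_ss": 0, "n_glyc": 1},
            {"accession": "B", "n_tm": 1, "n_ss": 1, "n_glyc": 1},
            {"accession": "C", "n_tm": 0, "n_ss": 1, "n_glyc": 0},
        ]
    )
    part = venn_partition(frame)
    assert part.regions[frozenset({"TM", "NGLYC"})] == {"A"}
    assert part.regions[frozenset({"TM", "NGLYC", "SS"})] == {"B"}
    assert part.regions[frozenset({"SS"})] == {"C"}
    assert part.total_unique == 3
    assert part.percentage("TM", "NGLYC", "SS") == pytest.approx(100 / 3)


def test_venn_partition_all_zero_rows_empty():
    frame = _rows([{"accession": "A"}, {"accession": "B"}])
    part = venn_partition(frame)
    assert part.total_unique == 0
    assert all(len(v) == 0 for v in part.regions.values())


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
        ),
        min_size=1,
        max_size=60,
    ),
    st.sampled_from([(1, 1), (1, 3), (11, math.inf), (2, 5)]),
)
def test_venn_partition_matches_brute_force(rows, rng_range):
    frame = _rows(
        [
            {"accession": f"P{i}", "n_tm": t, "n_glyc": g, "n_ss": s}
            for i, (t, g, s) in enumerate(rows)
        ]
    )
    part = venn_partition(
        frame, tm_range=rng_range, nglyc_range=rng_range, ss_range=rng_range
    )
    counts = {
        f"P{i}": {"TM": t, "NGLYC": g, "SS": s} for i, (t, g, s) in enumerate(rows)
    }
    expected = naive_venn_regions(
        counts, {"TM": rng_range, "NGLYC": rng_range, "SS": rng_range}
    )
    for region in VENN_REGIONS:
        assert set(part.regions[region]) == expected.get(region, set())
    # disjoint + exhaustive over the universe
    all_members = [m for v in part.regions.values() for m in v]
    assert len(all_members) == len(set(all_members)) == part.total_unique


# ---------------------------------------------------------------------------
# Quantile profiles
# ---------------------------------------------------------------------------


def _profile_frame(qdata: dict) -> pd.DataFrame:
    base = {
        f"q_{feat}_{q}": 0.0
        for feat in ("ss", "glyc", "glyc_on_sequon", "tm", "cys", "sequon")
        for q in (1, 2, 3, 4)
    }
    return pd.DataFrame([{**base, **qdata, "accession": "A"}])


def test_quantile_profile_single_site():
    frame = _profile_frame({"q_glyc_1": 1.0, "q_glyc_on_sequon_1": 1.0, "q_sequon_1": 1.0})
    profile = quantile_profile(frame)
    assert profile.counts[FeatureKind.NGLYC] == (1.0, 0.0, 0.0, 0.0)
    assert profile.sequon_occupancy[0] == pytest.approx(1.0)
    assert math.isnan(profile.sequon_occupancy[1])


def test_quantile_profile_directional_bias():
    # strongly type-I proteome: every protein a 7-TM receptor with a long
    # lumenal N-terminal ectodomain -> PTMs N-biased, TMs C-increasing
    cfg = SyntheticConfig(
        n_proteins=400,
        seed=21,
        fraction_tm=1.0,
        tm_count_dist={7: 1.0},
        orientation_bias=1.0,
        p_signal=0.0,
    )
    proteome = generate_proteome(cfg)
    frame = features_to_frame(
        build_feature_table(proteome.records, proteome.annotations, proteome.topologies)
    )
    profile = quantile_profile(frame)
    for kind in (FeatureKind.NGLYC, FeatureKind.SS, FeatureKind.CYS, FeatureKind.SEQUON):
        vec = profile.counts[kind]
        assert vec[0] > vec[3], kind
    tm = profile.counts[FeatureKind.TM]
    assert tm[0] < tm[3]


def test_quantile_utilization_uniform_null(study_frame):
    # engagement probability is position-independent in the generator, so
    # per-quantile utilization must match the global rate within noise
    profile = quantile_profile(study_frame)
    global_util = study_frame["n_ss_cys"].sum() / study_frame["n_cys"].sum()
    for q in range(4):
        n_q = profile.counts[FeatureKind.CYS][q]
        se = math.sqrt(global_util * (1 - global_util) / n_q)
        assert abs(profile.cys_utilization[q] - global_util) < 5 * se


def test_quantile_profile_sums_equal_feature_totals(study_frame):
    profile = quantile_profile(study_frame)
    assert sum(profile.counts[FeatureKind.NGLYC]) == study_frame["n_glyc"].sum()
    assert sum(profile.counts[FeatureKind.TM]) == study_frame["n_tm"].sum()
    assert sum(profile.counts[FeatureKind.SS]) == study_frame["n_ss_cys"].sum()


# ---------------------------------------------------------------------------
# Proteome subsets
# ---------------------------------------------------------------------------


def test_subset_proteome_definitions(study_frame):
    tm = subset_proteome(study_frame, "tm")
    non_tm = subset_proteome(study_frame, "non_tm")
    assert len(tm) + len(non_tm) == len(study_frame)
    both = subset_proteome(study_frame, "ss_nglyco")
    assert ((both["n_ss"] >= 1) & (both["n_glyc"] >= 1)).all()
    with pytest.raises(ValueError):
        subset_proteome(study_frame, "nope")
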