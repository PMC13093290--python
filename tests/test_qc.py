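"""Cleaning cascade: parsing, filters, transforms, imputation, normalization."""

import io

import numpy as np
import pandas as pd
import pytest

from coralstress.design import SampleDesign, generate_design
from coralstress.matrix import AbundanceMatrix, StateError
from coralstress.qc import (ForestImputer, apply_intensity_floor, clean_proteome,
                            drop_samples, filter_missingness,
                            filter_protein_groups, flag_outlier_samples,
                            impute_missing, log2_transform, median_normalize,
                            normalize_by_cell_density, read_protein_groups)
from tests.conftest import table_from_frame

FIXTURE_TSV = """Protein IDs\tFraction\tUnique peptides\tRazor + unique peptides\tQ-value\tPotential contaminant\tReverse\tIntensity s1\tIntensity s2
p1\thost\t3\t4\t0.001\t\t\t100\t200
p2\thost\t2\t2\t0.005\t+\t\t0\t50
p3\tsymbiont\t5\t6\t0.002\t\t\t300\t
"""


class TestReader:
    def test_parses_rows_and_flags(self):
        table = read_protein_groups(io.StringIO(FIXTURE_TSV))
        assert len(table) == 3
        assert table.meta["contaminant"].sum() == 1
        assert table.sample_ids == ["s1", "s2"]

    def test_zero_and_blank_intensities_become_absent(self):
        table = read_protein_groups(io.StringIO(FIXTURE_TSV))
        assert np.isnan(table.intensities.loc[1, "s1"])  # literal "0"
        assert np.isnan(table.intensities.loc[2, "s2"])  # empty cell

    def test_design_sample_missing_from_file_is_an_error(self):
        design = SampleDesign(pd.DataFrame(
            {"sample_id": ["s1", "sX"], "species": "A", "tank": 1,
             "treatment": ["ambient", "stress"], "timepoint": "TP0",
             "replicate": [1, 1]}
        ))
        with pytest.raises(ValueError, match="sX"):
            read_protein_groups(io.StringIO(FIXTURE_TSV), design=design)

    def test_missing_mandatory_column_named_in_error(self):
        broken = FIXTURE_TSV.replace("Q-value", "Qval")
        with pytest.raises(ValueError, match="Q-value"):
            read_protein_groups(io.StringIO(broken))


class TestIdentityFilters:
    def _one_row(self, unique, razor, q, fraction="host",
                 contaminant=False, reverse=False):
        frame = pd.DataFrame(
            {
                "Protein IDs": ["p"],
                "Fraction": [fraction],
                "Unique peptides": [unique],
                "Razor + unique peptides": [razor],
                "Q-value": [q],
                "Potential contaminant": ["+" if contaminant else ""],
                "Reverse": ["+" if reverse else ""],
                "Intensity s1": [10.0],
                "Intensity s2": [20.0],
            }
        )
        return table_from_frame(frame)

    @pytest.mark.parametrize(
        "unique, razor, q, kwargs, retained",
        [
            (2, 3, 0.005, {}, True),
            (1, 5, 0.001, {}, False),    # strict > 1 on unique peptides
            (4, 4, 0.01, {}, False),     # strict < 0.01 on q
            (2, 2, 0.0099, {}, True),
            (3, 3, 0.001, {"fraction": "symbiont"}, False),
            (3, 3, 0.001, {"contaminant": True}, False),
            (3, 3, 0.001, {"reverse": True}, False),
        ],
    )
    def test_row_predicates(self, unique, razor, q, kwargs, retained):
        table = self._one_row(unique, razor, q, **kwargs)
        out, tally = filter_protein_groups(table)
        assert (len(out) == 1) is retained
        assert tally["input"] == 1

    def test_filter_is_idempotent(self, small_proteome, design3):
        table = table_from_frame(small_proteome[0], design3)
        once, _ = filter_protein_groups(table)
        twice, _ = filter_protein_groups(once)
        pd.testing.assert_frame_equal(once.meta, twice.meta)
        assert set(once.meta["group_id"]) <= set(table.meta["group_id"])


class TestFloorAndLog2:
    def test_floor_masks_strictly_below(self):
        data = pd.DataFrame({"s1": [4.99, 5.0, 8.0]}, index=list("abc"))
        m = AbundanceMatrix(data)
        out = apply_intensity_floor(m, 5.0)
        assert np.isnan(out.data.loc["a", "s1"])
        assert out.data.loc["b", "s1"] == 5.0
        assert out.state == "floored"

    def test_floor_after_log2_is_a_state_error(self, log2_matrix):
        with pytest.raises(StateError):
            apply_intensity_floor(log2_matrix)

    def test_log2_values_and_absent_passthrough(self):
        data = pd.DataFrame({"s1": [8.0, 5.0, np.nan]}, index=list("abc"))
        out = log2_transform(apply_intensity_floor(AbundanceMatrix(data)))
        assert out.data.loc["a", "s1"] == pytest.approx(3.0)
        assert out.data.loc["b", "s1"] == pytest.approx(2.321928, abs=1e-6)
        assert np.isnan(out.data.loc["c", "s1"])

    def test_floor_then_log2_commutes_with_log2_threshold(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(np.exp2(rng.normal(3, 2, size=(40, 5))),
                           columns=[f"s{i}" for i in range(5)])
        a = log2_transform(apply_intensity_floor(AbundanceMatrix(raw.copy()), 5.0))
        b = np.log2(raw).where(np.log2(raw) >= np.log2(5.0))
        pd.testing.assert_frame_equal(a.data, b, check_names=False)


class TestPresenceFilter:
    def _matrix(self, present: int, total: int = 16):
        row = [20.0] * present + [np.nan] * (total - present)
        data = pd.DataFrame([row, [20.0] * total], index=["partial", "full"],
                            columns=[f"s{i}" for i in range(total)])
        return AbundanceMatrix(data, state="log2")

    def test_retains_at_80_percent(self):
        out = filter_missingness(self._matrix(13), 0.80)  # 81.25%
        assert "partial" in out.features

    def test_drops_below_80_percent(self):
        out = filter_missingness(self._matrix(12), 0.80)  # 75%
        assert out.features == ["full"]

    def test_zero_threshold_is_identity(self):
        m = self._matrix(1)
        out = filter_missingness(m, 0.0)
        assert out.features == m.features

    def test_idempotent(self):
        m = self._matrix(13)
        once = filter_missingness(m, 0.8)
        twice = filter_missingness(once, 0.8)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestImputer:
    def test_no_missing_is_identity(self, log2_matrix):
        out = impute_missing(log2_matrix)
        pd.testing.assert_frame_equal(out.data, log2_matrix.data)
        assert out.state == "imputed"

    def test_same_seed_reproduces_exactly(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(20, 1, size=(15, 8)),
                            columns=[f"s{i}" for i in range(8)])
        data.iloc[rng.random(data.shape) < 0.2] = np.nan
        m = AbundanceMatrix(data, state="log2")
        a = impute_missing(m, trees=20, seed=124)
        b = impute_missing(m, trees=20, seed=124)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_observed_entries_untouched_and_no_missing_left(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(20, 1, size=(20, 8)),
                            columns=[f"s{i}" for i in range(8)])
        mask = rng.random(data.shape) < 0.15
        data_missing = data.mask(mask)
        out = impute_missing(AbundanceMatrix(data_missing, state="log2"), trees=15)
        assert not out.data.isna().any().any()
        observed = ~mask
        np.testing.assert_array_equal(out.data.to_numpy()[observed],
                                      data_missing.to_numpy()[observed])

    def test_duplicate_features_imputed_from_their_donor(self):
        """Copies of one complete feature recover the donor's values closely.

        Tree ensembles interpolate on a grid of observed support points, so
        the donor spread (0.3 log2 units, a typical replicate sd) bounds the
        achievable resolution.
        """
        rng = np.random.default_rng(7)
        donor = rng.normal(20, 0.3, size=40)
        data = {"donor": donor}
        for i in range(6):
            data[f"copy{i}"] = donor.copy()
        df = pd.DataFrame(data, index=[f"s{i}" for i in range(40)]).T
        df.iloc[1, 0] = np.nan  # one missing cell in copy0
        df.iloc[2, 5] = np.nan
        out = impute_missing(AbundanceMatrix(df, state="log2"), trees=100)
        assert out.data.loc["copy0", "s0"] == pytest.approx(donor[0], abs=0.1)
        assert out.data.loc["copy1", "s5"] == pytest.approx(donor[5], abs=0.1)

    def test_feature_with_one_observation_is_an_error(self):
        data = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [np.nan, 1.0], "s3": [np.nan, 1.0]},
            index=["starved", "ok"],
        )
        with pytest.raises(ValueError, match="starved"):
            impute_missing(AbundanceMatrix(data, state="log2"))


class TestMedianNormalize:
    def _design(self, samples, treatment="ambient", timepoint="TP0"):
        return SampleDesign(pd.DataFrame(
            {"sample_id": samples, "species": "A", "tank": 1,
             "treatment": treatment, "timepoint": timepoint,
             "replicate": range(1, len(samples) + 1)}
        ))

    def test_two_sample_group_meets_at_midpoint(self):
        data = pd.DataFrame(
            {"s1": np.arange(10.0 - 2, 10.0 + 3), "s2": np.arange(12.0 - 2, 12.0 + 3)},
            index=[f"f{i}" for i in range(5)],
        )
        m = AbundanceMatrix(data, state="imputed")
        out = median_normalize(m, self._design(["s1", "s2"]))
        assert out.data["s1"].median() == pytest.approx(11.0)
        assert out.data["s2"].median() == pytest.approx(11.0)

    def test_equal_medians_identity(self, log2_matrix):
        m = AbundanceMatrix(log2_matrix.data - log2_matrix.data.median(),
                            state="imputed")
        out = median_normalize(m, self._design(m.samples))
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_constant_offset_removed_exactly(self, log2_matrix):
        base = AbundanceMatrix(log2_matrix.data.copy(), state="imputed")
        shifted_data = base.data.copy()
        shifted_data["s0"] = shifted_data["s0"] + 7.5
        shifted = AbundanceMatrix(shifted_data, state="imputed")
        design = self._design(base.samples)
        a = median_normalize(base, design)
        b = median_normalize(shifted, design)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_between_group_offsets_untouched(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(20, 1, (30, 4)),
                            columns=["a1", "a2", "b1", "b2"])
        data[["b1", "b2"]] += 5
        design = SampleDesign(pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"], "species": "A", "tank": 1,
             "treatment": ["ambient", "ambient", "stress", "stress"],
             "timepoint": "TP1", "replicate": [1, 2, 1, 2]}
        ))
        out = median_normalize(AbundanceMatrix(data, state="imputed"), design)
        gap = out.data[["b1", "b2"]].median().mean() - out.data[["a1", "a2"]].median().mean()
        assert gap == pytest.approx(5.0, abs=0.5)


class TestOutlierQc:
    def test_low_completeness_flagged_with_reason(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(20, 1, (20, 5)),
                            columns=[f"s{i}" for i in range(5)])
        data.loc[data.index[:12], "s0"] = np.nan  # 40% complete
        report = flag_outlier_samples(AbundanceMatrix(data, state="log2"),
                                      min_completeness=0.6)
        flagged = {f["sample"]: f["reason"] for f in report.flags}
        assert flagged.get("s0") == "completeness"

    def test_identical_samples_never_flagged(self):
        data = pd.DataFrame(np.tile(np.arange(10.0), (6, 1)).T,
                            columns=[f"s{i}" for i in range(6)])
        report = flag_outlier_samples(AbundanceMatrix(data, state="log2"))
        assert report.flags == []

    def test_shifted_clone_flagged_by_pca(self):
        rng = np.random.default_rng(4)
        base = rng.normal(20, 1, size=30)
        data = pd.DataFrame({f"s{i}": base for i in range(11)})
        outlier = base.copy()
        outlier[:15] += 10.0
        data["weird"] = outlier
        data.index = [f"f{i}" for i in range(30)]
        report = flag_outlier_samples(AbundanceMatrix(data, state="log2"))
        assert any(f["sample"] == "weird" and f["reason"] == "pca_distance"
                   for f in report.flags)
        assert report.flagged_samples == ["weird"]

    def test_completeness_matches_brute_force(self):
        data = pd.DataFrame(
            {"s1": [1.0, np.nan, 3.0, 4.0], "s2": [np.nan] * 3 + [1.0],
             "s3": [1.0, 2.0, 3.0, 4.0]}
        )
        report = flag_outlier_samples(AbundanceMatrix(data, state="log2"),
                                      min_completeness=0.0)
        assert report.completeness["s1"] == pytest.approx(3 / 4)
        assert report.completeness["s2"] == pytest.approx(1 / 4)
        assert report.completeness["s3"] == pytest.approx(1.0)

    def test_fewer_than_three_samples_rejected(self):
        data = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        with pytest.raises(ValueError):
            flag_outlier_samples(AbundanceMatrix(data, state="log2"))

    def test_flagging_is_advisory_dropping_is_explicit(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(20, 1, (10, 4)),
                            columns=[f"s{i}" for i in range(4)])
        m = AbundanceMatrix(data, state="log2")
        flag_outlier_samples(m)
        assert m.samples == [f"s{i}" for i in range(4)]
        dropped = drop_samples(m, ["s2"])
        assert dropped.samples == ["s0", "s1", "s3"]
        with pytest.raises(ValueError):
            drop_samples(m, ["nope"])


class TestCellDensityNormalization:
    def test_divides_raw_intensity_by_abundance(self):
        data = pd.DataFrame({"s1": [1000.0], "s2": [1000.0]}, index=["f"])
        out = normalize_by_cell_density(AbundanceMatrix(data),
                                        {"s1": 100.0, "s2": 50.0})
        assert out.data.loc["f", "s1"] == pytest.approx(10.0)
        assert out.data.loc["f", "s2"] == pytest.approx(20.0)  # halved abundance doubles

    def test_zero_abundance_sample_excluded_with_warning(self):
        data = pd.DataFrame({"s1": [1000.0], "s2": [1000.0]}, index=["f"])
        with pytest.warns(UserWarning, match="s2"):
            out = normalize_by_cell_density(AbundanceMatrix(data),
                                            {"s1": 100.0, "s2": 0.0})
        assert out.samples == ["s1"]


def test_full_cascade_on_synthetic_table(design_bailout):
    from coralstress.simulate import SimulationParams, simulate_proteome

    params = SimulationParams(n_proteins=60, seed=21)
    frame, _ = simulate_proteome(design_bailout, params)
    table = table_from_frame(frame, design_bailout)
    sub = design_bailout.subset(species="A")
    res = clean_proteome(table, sub, impute_trees=15, impute_rounds=2)
    m = res.matrix
    assert m.state == "normalized"
    assert not m.data.isna().any().any()
    assert [e["op"] for e in m.lineage][:3] == [
        "from_protein_groups", "intensity_floor", "log2_transform"
    ]
    assert res.tally["retained"] >= res.tally["final_features"]
    # within-group sample medians agree after normalization
    for (trt, tp), ids in sub.table.groupby(["treatment", "timepoint"])["sample_id"]:
        med = m.data[list(ids)].median()
        assert med.max() - med.min() < 1e-9
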