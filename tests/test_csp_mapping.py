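import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cspfret.binding_fit import bound_fraction
from cspfret.csp_mapping import (
    CLASS_ABOVE_2SIGMA,
    CLASS_ABOVE_SIGMA,
    CLASS_NOT_SIGNIFICANT,
    PeakList,
    TitrationSeries,
    classify_csp,
    compute_csp,
    compute_csp_profile,
    compute_thresholds,
    intensity_attenuation,
    read_peak_list,
    read_titration_manifest,
    write_peak_list,
)

finite_shifts = st.floats(-2.0, 2.0, allow_nan=False, allow_infinity=False)


def make_series(ref_records, end_records, conc=100.0, end_ratio=8.0):
    return TitrationSeries(
        labelled_protein_concentration=conc,
        points=[
            (0.0, PeakList.from_records(ref_records)),
            (end_ratio, PeakList.from_records(end_records)),
        ],
    )


class TestComputeCsp:
    @pytest.mark.parametrize(
        "dh, dn, convention, expected",
        [
            (0.0, 0.0, "scaled_squared", 0.0),
            (0.02, 0.1, "scaled_squared", np.sqrt(0.5 * (4e-4 + 1.96e-4))),
            (-0.02, -0.1, "scaled_squared", np.sqrt(0.5 * (4e-4 + 1.96e-4))),
            (0.02, 0.1, "literal", np.sqrt(0.5 * (4e-4 + 0.14 * 1e-2))),
        ],
    )
    def test_hand_arithmetic(self, dh, dn, convention, expected):
        assert compute_csp(dh, dn, 0.14, convention) == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=200, deadline=None)
    @given(dh=finite_shifts, dn=finite_shifts,
           convention=st.sampled_from(["scaled_squared", "literal"]))
    def test_non_negative_and_sign_invariant(self, dh, dn, convention):
        v = compute_csp(dh, dn, convention=convention)
        assert v >= 0
        assert compute_csp(-dh, dn, convention=convention) == v
        assert compute_csp(dh, -dn, convention=convention) == v
        assert compute_csp(-dh, -dn, convention=convention) == v

    @settings(max_examples=100, deadline=None)
    @given(dh=finite_shifts, dn=finite_shifts)
    def test_conventions_coincide_when_weight_is_one_or_dn_zero(self, dh, dn):
        assert compute_csp(dh, dn, 1.0, "scaled_squared") == pytest.approx(
            compute_csp(dh, dn, 1.0, "literal"), rel=1e-12, abs=1e-15
        )
        assert compute_csp(dh, 0.0, 0.14, "scaled_squared") == compute_csp(
            dh, 0.0, 0.14, "literal"
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            compute_csp(np.nan, 0.0)
        with pytest.raises(ValueError):
            compute_csp(0.1, 0.1, nitrogen_weight=-1)
        with pytest.raises(ValueError):
            compute_csp(0.1, 0.1, convention="other")


class TestThresholds:
    def test_hand_arithmetic_both_estimators(self):
        mu, sig, t1, t2 = compute_thresholds([0.01, 0.02, 0.03], "population")
        assert mu == pytest.approx(0.02)
        assert sig == pytest.approx(np.sqrt(2.0 / 3.0) * 0.01)
        assert (t1, t2) == (pytest.approx(mu + sig), pytest.approx(mu + 2 * sig))
        _, sig_s, _, _ = compute_thresholds([0.01, 0.02, 0.03], "sample")
        assert sig_s == pytest.approx(0.01)

    def test_degenerate_equal_values(self):
        mu, sig, t1, t2 = compute_thresholds([0.05, 0.05, 0.05])
        assert mu == pytest.approx(0.05)
        assert sig == pytest.approx(0.0, abs=1e-15)
        # "above" is strict, so the common value never clears mu + sigma
        assert classify_csp(mu, t1, t2) == CLASS_NOT_SIGNIFICANT

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            compute_thresholds([0.01])

    def test_boundary_strictness(self):
        # exactly at a threshold stays in the lower class
        assert classify_csp(1.0, 1.0, 2.0) == CLASS_NOT_SIGNIFICANT
        assert classify_csp(2.0, 1.0, 2.0) == CLASS_ABOVE_SIGMA
        assert classify_csp(2.0 + 1e-12, 1.0, 2.0) == CLASS_ABOVE_2SIGMA


class TestProfile:
    def test_identical_endpoint_gives_zero_csps(self):
        recs = [(1, "GLY", 8.0, 110.0), (2, "ALA", 8.5, 120.0), (3, "VAL", 7.9, 115.0)]
        profile = compute_csp_profile(make_series(recs, recs))
        assert (profile.table["csp"] == 0).all()
        assert (profile.table["csp_class"] == CLASS_NOT_SIGNIFICANT).all()

    def test_zero_noise_forward_model_matches_closed_form(self, noiseless_series):
        scenario, series = noiseless_series
        profile = compute_csp_profile(series)
        fb = bound_fraction(scenario.P, 8.0 * scenario.P, scenario.Kd)
        res = scenario.residues.set_index("residue_number")
        for _, row in profile.table.iterrows():
            expected = compute_csp(
                fb * res.loc[row["residue_number"], "ddH_max"],
                fb * res.loc[row["residue_number"], "ddN_max"],
            )
            assert row["csp"] == pytest.approx(expected, abs=1e-12)

    def test_lost_residue_recorded_as_excluded(self):
        ref = [(1, "GLY", 8.0, 110.0), (2, "ALA", 8.5, 120.0), (3, "VAL", 7.9, 115.0)]
        end = [(1, "GLY", 8.1, 110.4), (3, "VAL", 7.8, 114.5)]
        profile = compute_csp_profile(make_series(ref, end))
        assert profile.excluded == {2: "lost/overlapped"}
        assert 2 not in profile.table["residue_number"].values

    def test_user_exclusions_respected(self):
        recs = [(i, "GLY", 8.0 + i / 10, 110.0 + i) for i in range(1, 6)]
        profile = compute_csp_profile(make_series(recs, recs), exclusions=[3])
        assert profile.excluded[3] == "user_excluded"
        assert 3 not in profile.table["residue_number"].values

    def test_classification_counts_sum(self, forward_series):
        profile = compute_csp_profile(forward_series)
        counts = profile.table["csp_class"].value_counts()
        assert counts.sum() == len(profile.table)
        assert set(counts.index) <= {
            CLASS_NOT_SIGNIFICANT, CLASS_ABOVE_SIGMA, CLASS_ABOVE_2SIGMA
        }

    def test_missing_endpoint_ratio_raises(self, forward_series):
        with pytest.raises(ValueError):
            compute_csp_profile(forward_series, endpoint_ratio=9.5)

    def test_disjoint_residues_raise(self):
        ref = [(1, "GLY", 8.0, 110.0), (2, "ALA", 8.5, 120.0)]
        end = [(7, "GLY", 8.0, 110.0), (8, "ALA", 8.5, 120.0)]
        with pytest.raises(ValueError, match="no residues shared"):
            compute_csp_profile(make_series(ref, end))


class TestSeriesInvariants:
    def test_first_point_must_be_reference(self):
        peaks = PeakList.from_records([(1, "GLY", 8.0, 110.0), (2, "ALA", 8.1, 112.0)])
        with pytest.raises(ValueError):
            TitrationSeries(100.0, [(0.5, peaks), (1.0, peaks)])

    def test_ratios_strictly_increasing(self):
        peaks = PeakList.from_records([(1, "GLY", 8.0, 110.0)])
        with pytest.raises(ValueError):
            TitrationSeries(100.0, [(0.0, peaks), (1.0, peaks), (1.0, peaks)])

    def test_peaklist_rejects_duplicates_and_nonfinite(self):
        with pytest.raises(ValueError, match="duplicate"):
            PeakList.from_records([(1, "GLY", 8.0, 110.0), (1, "ALA", 8.1, 112.0)])
        with pytest.raises(ValueError):
            PeakList.from_records([(1, "GLY", np.inf, 110.0)])


class TestIntensityAttenuation:
    def test_identical_point_gives_unit_ratios(self):
        recs = [(1, "GLY", 8.0, 110.0, 1000.0), (2, "ALA", 8.5, 120.0, 800.0)]
        table, flagged = intensity_attenuation(make_series(recs, recs, end_ratio=1.0))
        assert np.allclose(table["ratio_1"], 1.0)
        assert flagged == []

    def test_generator_broadening_round_trip(self):
        from cspfret.synthetic_data import make_titration_scenario, simulate_titration

        scenario = make_titration_scenario(
            noise_sd=0.0, broadening_factor=0.5, ratios=(0.0, 0.5, 1.0)
        )
        series = simulate_titration(scenario, seed=0)
        table, _ = intensity_attenuation(series)
        assert np.allclose(table["ratio_1"], 0.5)
        assert np.allclose(table["ratio_0.5"], np.sqrt(0.5))

    def test_absent_residue_ratio_zero_and_zero_reference_flagged(self):
        ref = [(1, "GLY", 8.0, 110.0, 1000.0), (2, "ALA", 8.5, 120.0, 0.0)]
        end = [(2, "ALA", 8.5, 120.0, 400.0)]
        table, flagged = intensity_attenuation(make_series(ref, end, end_ratio=1.0))
        assert table.loc[1, "ratio_1"] == 0.0  # broadened beyond detection
        assert flagged == [2]
        assert np.isnan(table.loc[2, "ratio_1"])


class TestIO:
    def test_peak_list_round_trip(self, tmp_path):
        peaks = PeakList.from_records(
            [(1, "GLY", 8.01234, 110.04321, 900.0), (2, "ALA", 8.5, 120.0, 800.0)]
        )
        path = tmp_path / "peaks.tsv"
        write_peak_list(peaks, path)
        back = read_peak_list(path)
        pd.testing.assert_frame_equal(
            back.data, peaks.data, check_exact=False, atol=1e-5
        )

    def test_manifest_round_trip(self, tmp_path, forward_series):
        import yaml

        entries = []
        for ratio, peaks in forward_series.points:
            fname = f"r{ratio:g}.tsv"
            write_peak_list(peaks, tmp_path / fname)
            entries.append({"ratio": float(ratio), "file": fname})
        manifest = tmp_path / "manifest.yaml"
        manifest.write_text(
            yaml.safe_dump(
                {"labelled_protein_concentration_uM": 100.0, "points": entries}
            )
        )
        series = read_titration_manifest(manifest)
        assert series.labelled_protein_concentration == 100.0
        assert np.allclose(series.ratios, forward_series.ratios)
        assert len(series.reference) == len(forward_series.reference)
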