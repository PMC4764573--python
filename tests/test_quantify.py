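"""Filtering, proteoform merging, spike-in calibration, concentration and
partition-coefficient tests, including the paper-anchored worked examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import exportome as ex
from exportome import quantify
from exportome.config import RunConfig
from exportome.errors import CalibrationError

from conftest import make_intensity_rows


def concentrations_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "compartment", "replicate", "conc_mol_l"])


class TestFilters:
    def test_high_pep_removed_in_partition_mode(self, config):
        table = pd.concat(
            [
                make_intensity_rows(["P1"], [1e6], min_pep=0.02),
                make_intensity_rows(["P2"], [1e6], min_pep=0.005),
            ],
            ignore_index=True,
        )
        out, log = quantify.filter_records(table, config, mode="partition")
        assert set(out["protein_id"]) == {"P2"}
        assert log.to_dict("records") == [{"protein_id": "P1", "rule": "pep"}]

    def test_site_flag_single_compartment_rule(self, config):
        # site-flagged protein detected in both compartments is retained;
        # detected in one compartment it is excluded
        both = pd.concat(
            [
                make_intensity_rows(["P1"], [1e6], sample_id="nuc_r1", role="nuclear",
                                    only_by_site=True),
                make_intensity_rows(["P1"], [1e6], sample_id="cyt_r1", role="cytosolic",
                                    replicate=1, only_by_site=True),
            ],
            ignore_index=True,
        )
        out, _ = quantify.filter_records(both, config, mode="partition")
        assert set(out["protein_id"]) == {"P1"}

        single = pd.concat(
            [
                make_intensity_rows(["P1"], [1e6], sample_id="nuc_r1", role="nuclear",
                                    only_by_site=True),
                make_intensity_rows(["P1"], [None], sample_id="cyt_r1", role="cytosolic",
                                    only_by_site=True),
            ],
            ignore_index=True,
        )
        out, log = quantify.filter_records(single, config, mode="partition")
        assert out.empty
        assert ("P1", "site_single_compartment") in set(map(tuple, log.to_numpy()))

    def test_cargo_mode_site_flag_in_bound_sample(self, config):
        table = pd.concat(
            [
                make_intensity_rows(["P1"], [1e6], sample_id="bait_plus_ran",
                                    role="bait_plus_ran", only_by_site=True),
                make_intensity_rows(["P1"], [1e6], sample_id="input", role="input",
                                    only_by_site=True),
                make_intensity_rows(["P2"], [1e6], sample_id="bait_plus_ran",
                                    role="bait_plus_ran"),
            ],
            ignore_index=True,
        )
        out, log = quantify.filter_records(table, config, mode="cargo")
        assert set(out["protein_id"]) == {"P2"}
        assert ("P1", "site_in_bait_plus_ran") in set(map(tuple, log.to_numpy()))

    def test_cargo_mode_requires_two_unique_peptides(self, config):
        table = pd.concat(
            [
                make_intensity_rows(["P1"], [1e6], sample_id="input", role="input",
                                    unique_peptides=1),
                make_intensity_rows(["P2"], [1e6], sample_id="input", role="input",
                                    unique_peptides=2),
            ],
            ignore_index=True,
        )
        out, log = quantify.filter_records(table, config, mode="cargo")
        assert set(out["protein_id"]) == {"P2"}
        assert ("P1", "unique_peptides") in set(map(tuple, log.to_numpy()))


class TestMergeProteoforms:
    def test_intensities_add_and_metadata_combine(self):
        table = pd.concat(
            [
                make_intensity_rows(["P1.1", "P1.2"], [3e6, 7e6], min_pep=[0.002, 0.001],
                                    unique_peptides=[2, 3], only_by_site=[True, False]),
                make_intensity_rows(["P1.1", "P1.2"], [None, None], sample_id="cyt_r1",
                                    role="cytosolic", min_pep=[0.002, 0.001],
                                    unique_peptides=[2, 3], only_by_site=[True, False]),
            ],
            ignore_index=True,
        )
        pmap = pd.DataFrame({"proteoform_id": ["P1.1", "P1.2"], "protein_id": ["P1", "P1"]})
        merged = quantify.merge_proteoforms(table, pmap)
        nuc = merged[merged["sample_id"] == "nuc_r1"].iloc[0]
        assert nuc["intensity"] == 1e7
        assert nuc["min_pep"] == 0.001
        assert nuc["unique_peptides"] == 5
        assert not nuc["only_by_site"]  # survives only if all members carry it
        cyt = merged[merged["sample_id"] == "cyt_r1"].iloc[0]
        assert np.isnan(cyt["intensity"])  # all-missing stays missing

    def test_identity_map_is_noop(self):
        table = make_intensity_rows(["A", "B"], [1e6, 2e6])
        pmap = pd.DataFrame({"proteoform_id": [], "protein_id": []})
        merged = quantify.merge_proteoforms(table, pmap)
        pd.testing.assert_frame_equal(
            merged.sort_values("protein_id").reset_index(drop=True),
            table.sort_values("protein_id").reset_index(drop=True),
            check_dtype=False,
        )


class TestCalibration:
    def test_identity_data(self, spike):
        rows = make_intensity_rows(
            spike["standard_id"], spike["amount_fmol"], sample_id="nuc_r1"
        )
        curve = quantify.fit_calibration(spike, rows, 1)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.n_points == 48

    def test_constant_response_factor(self, spike):
        # intensity = 100 x amount  =>  slope 1, intercept -2 on log10 scale
        rows = make_intensity_rows(
            spike["standard_id"], 100.0 * spike["amount_fmol"], sample_id="nuc_r1"
        )
        curve = quantify.fit_calibration(spike, rows, 1)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(-2.0, abs=1e-10)

    def test_undetected_standards_are_excluded(self, spike):
        intensities = list(100.0 * spike["amount_fmol"])
        intensities[0] = None
        rows = make_intensity_rows(spike["standard_id"], intensities, sample_id="nuc_r1")
        curve = quantify.fit_calibration(spike, rows, 1)
        assert curve.n_points == 47

    def test_single_detected_standard_fails(self, spike):
        intensities = [None] * (len(spike) - 1) + [1e6]
        rows = make_intensity_rows(spike["standard_id"], intensities, sample_id="nuc_r1")
        with pytest.raises(CalibrationError):
            quantify.fit_calibration(spike, rows, 1)

    def test_noise_free_generator_inversion(self, truth, spike):
        """The fitted curve inverts the generator's intensity response:
        predicted amounts match spiked amounts to <1e-9 relative error."""
        p = ex.SimulationParams(seed=6, noise_sd_log10=0.0, detection_limit=0.0)
        table = ex.simulate_fraction_intensities(truth, spike, p, n_replicates=2)
        for rep in (1, 2):
            curve = quantify.fit_calibration(spike, table, rep)
            rows = table[
                (table["replicate"] == rep)
                & table["protein_id"].isin(spike["standard_id"])
                & (table["role"] == "nuclear")
            ]
            predicted = curve.predict_amount_fmol(rows["intensity"])
            known = spike.set_index("standard_id").loc[rows["protein_id"], "amount_fmol"]
            assert np.abs(predicted / known.to_numpy() - 1).max() < 1e-9


class TestConcentrations:
    def test_unit_conversion(self, config):
        # 50 fmol in 50 nl is 1 uM
        curve = quantify.CalibrationCurve(1, 1.0, 0.0, 1.0, 48)
        table = make_intensity_rows(["P1"], [50.0], sample_id="nuc_r1", role="nuclear")
        conc = quantify.estimate_concentrations(table, {1: curve}, config)
        assert conc["conc_mol_l"].iloc[0] == pytest.approx(1e-6)

    def test_identity_curve_returns_intensity_as_amount(self, config):
        curve = quantify.CalibrationCurve(1, 1.0, 0.0, 1.0, 48)
        table = make_intensity_rows(["P1"], [10.0], sample_id="cyt_r1", role="cytosolic")
        conc = quantify.estimate_concentrations(table, {1: curve}, config)
        assert conc["conc_mol_l"].iloc[0] == pytest.approx(10.0 / 500.0 * 1e-6)

    def test_doubling_volume_halves_concentration(self):
        curve = quantify.CalibrationCurve(1, 1.0, 0.0, 1.0, 48)
        table = make_intensity_rows(["P1"], [10.0], sample_id="nuc_r1", role="nuclear")
        base = quantify.estimate_concentrations(
            table, {1: curve}, RunConfig()
        )["conc_mol_l"].iloc[0]
        doubled = quantify.estimate_concentrations(
            table, {1: curve}, RunConfig(volumes={"nucleus": 100.0, "cytosol": 500.0})
        )["conc_mol_l"].iloc[0]
        assert doubled == pytest.approx(base / 2)

    def test_unknown_replicate_raises(self, config):
        curve = quantify.CalibrationCurve(1, 1.0, 0.0, 1.0, 48)
        table = make_intensity_rows(["P1"], [10.0], replicate=2)
        with pytest.raises(LookupError):
            quantify.estimate_concentrations(table, {1: curve}, config)


class TestPartition:
    def test_replicate_averaging(self, config):
        conc = concentrations_frame(
            [("P1", "nucleus", 1, 1e-6), ("P1", "nucleus", 2, 3e-6),
             ("P1", "cytosol", 1, 2e-6)]
        )
        rec = quantify.compute_partition(conc, config).iloc[0]
        assert rec["conc_nuc"] == pytest.approx(2e-6)
        assert rec["nc_ratio"] == pytest.approx(1.0)
        assert rec["log10_nc"] == pytest.approx(0.0)

    def test_censored_statuses(self, config):
        conc = concentrations_frame(
            [("P1", "nucleus", 1, 1e-6), ("P2", "cytosol", 1, 1e-6),
             ("P3", "nucleus", 1, 1e-6), ("P3", "cytosol", 1, 1e-6)]
        )
        rec = quantify.compute_partition(conc, config).set_index("protein_id")
        assert rec.loc["P1", "status"] == "nuc_only"
        assert rec.loc["P2", "status"] == "cyt_only"
        assert rec.loc["P3", "status"] == "both"
        assert np.isnan(rec.loc["P1", "nc_ratio"])

    def test_bookkeeping_identity(self, config):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            pattern = rng.integers(0, 3)
            if pattern in (0, 2):
                rows.append((f"P{i}", "nucleus", 1, 10.0 ** rng.uniform(-9, -5)))
            if pattern in (1, 2):
                rows.append((f"P{i}", "cytosol", 1, 10.0 ** rng.uniform(-9, -5)))
        rec = quantify.compute_partition(concentrations_frame(rows), config)
        counts = rec["status"].value_counts()
        assert counts.sum() == rec["protein_id"].nunique() == 200

    @given(
        nuc=st.floats(1e-9, 1e-4), cyt=st.floats(1e-9, 1e-4),
        scale=st.floats(0.1, 10.0),
    )
    def test_ratio_antisymmetry_and_volume_invariance(self, nuc, cyt, scale):
        config = RunConfig()
        fwd = quantify.compute_partition(
            concentrations_frame([("P", "nucleus", 1, nuc), ("P", "cytosol", 1, cyt)]),
            config,
        )["nc_ratio"].iloc[0]
        rev = quantify.compute_partition(
            concentrations_frame([("P", "nucleus", 1, cyt), ("P", "cytosol", 1, nuc)]),
            config,
        )["nc_ratio"].iloc[0]
        assert fwd == pytest.approx(1.0 / rev, rel=1e-12)
        # joint volume rescaling cancels out of the ratio
        curve = quantify.CalibrationCurve(1, 1.0, 0.0, 1.0, 48)
        table = pd.concat(
            [
                make_intensity_rows(["P"], [nuc * 1e9], sample_id="nuc_r1", role="nuclear"),
                make_intensity_rows(["P"], [cyt * 1e9], sample_id="cyt_r1", role="cytosolic"),
            ],
            ignore_index=True,
        )
        ratios = []
        for s in (1.0, scale):
            cfg = RunConfig(volumes={"nucleus": 50.0 * s, "cytosol": 500.0 * s})
            conc = quantify.estimate_concentrations(table, {1: curve}, cfg)
            ratios.append(quantify.compute_partition(conc, cfg)["nc_ratio"].iloc[0])
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-12)


class TestContaminantFlags:
    def test_set_algebra(self, config):
        records = quantify.compute_partition(
            concentrations_frame(
                [(p, "nucleus", 1, 1e-7) for p in ("a", "b", "c", "d")]
            ),
            config,
        )
        out, counts = quantify.apply_contaminant_flags(records, {"a", "b", "c"}, {"c"})
        assert set(out["protein_id"]) == {"c", "d"}
        assert counts["flagged"] == 3 and counts["removed"] == 2 and counts["kept"] == 1
        assert out.set_index("protein_id").loc["c", "kept_override"]

    def test_empty_flags(self, config):
        records = quantify.compute_partition(
            concentrations_frame([("a", "nucleus", 1, 1e-7)]), config
        )
        _, counts = quantify.apply_contaminant_flags(records, set(), set())
        assert counts == {"flagged": 0, "removed": 0, "kept": 0, "keep_not_flagged": 0}

    @given(st.data())
    def test_flagged_equals_removed_plus_kept(self, data):
        ids = [f"P{i}" for i in range(30)]
        flags = set(data.draw(st.lists(st.sampled_from(ids), unique=True)))
        keep = set(data.draw(st.lists(st.sampled_from(ids), unique=True)))
        records = quantify.compute_partition(
            concentrations_frame([(p, "nucleus", 1, 1e-7) for p in ids]), RunConfig()
        )
        _, counts = quantify.apply_contaminant_flags(records, flags, keep)
        assert counts["flagged"] == counts["removed"] + counts["kept"]


def test_format_ratio_significant_figures():
    assert quantify.format_ratio(287.5) == "300:1"
    assert quantify.format_ratio(0.0025) == "1:400"
    assert quantify.format_ratio(1.0) == "1:1"
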