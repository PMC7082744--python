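"""Plate normalization, Z-scoring, QC and hit calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirscreen import screenstats, synthgen
from mirscreen.screenstats import HitSet
from mirscreen.synthgen import EffectSize, SyntheticConfig

from conftest import make_measurements


def one_plate(neg_values, lib_values, plate="P01"):
    wells = []
    for i, v in enumerate(neg_values):
        wells.append((f"A{i+1:02d}", "neg_ctrl", "", v))
    for i, v in enumerate(lib_values):
        wells.append((f"B{i+1:02d}", "library", f"m{i}", v))
    return {plate: wells}


class TestNormalizePlates:
    def test_value_at_negative_control_median_maps_to_zero(self):
        meas, layout = make_measurements(one_plate([10, 9, 10, 12, 8], [10, 11]))
        out = screenstats.normalize_plates(meas, layout)
        x = out.loc[out["mir_name"] == "m0", "normalized"].iloc[0]
        assert x == 0.0

    def test_location_invariance_under_common_shift(self):
        meas, layout = make_measurements(one_plate([10, 9, 11, 12, 8], [10, 14, 7]))
        shifted = meas.copy()
        shifted["value"] += 100.0
        a = screenstats.normalize_plates(meas, layout)["normalized"]
        b = screenstats.normalize_plates(shifted, layout)["normalized"]
        assert np.allclose(a, b)

    def test_scale_invariance_under_positive_scaling(self):
        meas, layout = make_measurements(one_plate([10, 9, 11, 12, 8], [10, 14, 7]))
        scaled = meas.copy()
        scaled["value"] *= 3.0
        a = screenstats.normalize_plates(meas, layout)["normalized"]
        b = screenstats.normalize_plates(scaled, layout)["normalized"]
        assert np.allclose(a, b)

    def test_plate_offsets_removed_ks(self):
        # two plates with +/-5 offsets and identical planted well effects
        rng = np.random.default_rng(0)
        effects = rng.normal(0, 1, 80)
        plates = {}
        for plate, off in (("P01", 5.0), ("P02", -5.0)):
            wells = [(f"N{i:02d}", "neg_ctrl", "", off + rng.normal(0, 0.1)) for i in range(16)]
            wells += [
                (f"L{i:02d}", "library", f"m{i}", off + e + rng.normal(0, 0.1))
                for i, e in enumerate(effects)
            ]
            plates[plate] = wells
        meas, layout = make_measurements(plates)
        out = screenstats.normalize_plates(meas, layout)
        lib = out[out["content"] == "library"]
        a = lib.loc[lib["plate"] == "P01", "normalized"]
        b = lib.loc[lib["plate"] == "P02", "normalized"]
        assert stats.ks_2samp(a, b).statistic < 0.1

    def test_zero_mad_raises_with_plate_name(self):
        meas, layout = make_measurements(one_plate([10, 10, 10, 10], [1, 2]))
        with pytest.raises(ValueError, match="P01|replicate"):
            screenstats.normalize_plates(meas, layout)

    def test_too_few_negative_controls(self):
        meas, layout = make_measurements({"P09": [("A01", "neg_ctrl", "", 1.0),
                                                  ("B01", "library", "m0", 2.0)]})
        with pytest.raises(ValueError, match="P09"):
            screenstats.normalize_plates(meas, layout)


def _null_screen(n=1250, reps=1, seed=0):
    cfg = SyntheticConfig(
        n_mirs=n, n_replicates=reps, sigma_noise=0.01, baseline_sd=1.0,
        baseline_means={"migration": 0.0, "eccentricity": 0.0}, rng_seed=seed,
    )
    data = synthgen.gen_well_data(cfg)
    norm = screenstats.normalize_plates(data.measurements, data.layout)
    return screenstats.zscore_and_average(norm)


class TestZScore:
    def test_null_fraction_beyond_one_matches_gaussian_reference(self):
        scores, _ = _null_screen()
        mig = scores[scores["screen"] == "migration"]
        frac = (mig["z_avg"].abs() > 1).mean()
        assert frac == pytest.approx(2 * stats.norm.sf(1), abs=0.04)
        assert abs(mig["z_avg"].median()) < 0.1

    def test_single_replicate_flagged(self):
        scores, _ = _null_screen(n=200)
        assert "single_replicate" in scores.columns

    def test_constant_library_raises(self):
        meas, layout = make_measurements(one_plate([10, 9, 11, 12, 8], [5, 5, 5, 5]))
        norm = screenstats.normalize_plates(meas, layout)
        with pytest.raises(ValueError, match="library"):
            screenstats.zscore_and_average(norm)

    def test_planted_negative_effect_scores_below_minus_one(self):
        cfg = SyntheticConfig(
            n_mirs=300, rng_seed=4,
            effect_sizes={"syn-mir-010": EffectSize(-5.0, -5.0, 1.0)},
        )
        data = synthgen.gen_well_data(cfg)
        norm = screenstats.normalize_plates(data.measurements, data.layout)
        scores, _ = screenstats.zscore_and_average(norm)
        z = scores.set_index(["screen", "mir_name"]).loc[("migration", "syn-mir-010"), "z_avg"]
        assert z < -1


class TestCallHits:
    def test_strict_boundaries(self):
        scores = pd.DataFrame(
            {"screen": "migration", "mir_name": ["a", "b", "c", "d"],
             "z_avg": [-1.5, -1.0, 0.0, 1.2]}
        )
        low, high = screenstats.call_hits(scores, "migration")
        assert low.members == {"a"}  # -1.0 is excluded by the strict cutoff
        assert high.members == {"d"}

    def test_printed_integration_scores_are_hits(self):
        # the two miRs reported jointly by both screens, at their printed Z
        scores = pd.DataFrame(
            {
                "screen": ["migration"] * 2 + ["eccentricity"] * 2,
                "mir_name": ["hsa-mir-302d-3p", "hsa-mir-373-3p"] * 2,
                "z_avg": [-1.06, -1.56, -1.36, -1.98],
            }
        )
        for screen in ("migration", "eccentricity"):
            low, _ = screenstats.call_hits(scores, screen)
            assert low.members == {"hsa-mir-302d-3p", "hsa-mir-373-3p"}

    def test_empty_input(self):
        scores = pd.DataFrame({"screen": [], "mir_name": [], "z_avg": []})
        low, high = screenstats.call_hits(scores)
        assert low.members == set() and high.members == set()

    def test_null_screen_low_high_symmetry(self):
        scores, _ = _null_screen(seed=3)
        mig = scores[scores["screen"] == "migration"]
        low, high = screenstats.call_hits(mig)
        n, p = len(mig), 2 * stats.norm.sf(1)
        tol = 4 * np.sqrt(n * (p / 2) * (1 - p / 2))
        assert abs(len(low) - len(high)) < tol


class TestQC:
    def test_duplicated_replicate_has_unit_correlation(self):
        rng = np.random.default_rng(1)
        rows = []
        for rep in (1, 2):
            for i in range(20):
                rows.append(("P01", f"B{i:02d}", "library", f"m{i}", rep,
                             float(rng.normal() if rep == 1 else 0)))
        df = pd.DataFrame(rows, columns=["plate", "well", "content", "mir_name",
                                         "replicate", "z"])
        z1 = df.loc[df["replicate"] == 1, "z"].to_numpy()
        df.loc[df["replicate"] == 2, "z"] = z1  # exact duplicate
        df["screen"] = "migration"
        qc = screenstats.qc_report(df)
        assert qc.replicate_correlations[("migration", 1, 2)] == pytest.approx(1.0)

    def test_default_regime_correlations_exceed_085(self, small_screen):
        norm = screenstats.normalize_plates(small_screen.measurements, small_screen.layout)
        _, well_z = screenstats.zscore_and_average(norm)
        qc = screenstats.qc_report(well_z)
        assert all(r > 0.85 for r in qc.replicate_correlations.values())
        assert not any("edge" in f for f in qc.flags)

    def test_planted_edge_shift_raises_flag(self, small_screen):
        norm = screenstats.normalize_plates(small_screen.measurements, small_screen.layout)
        _, well_z = screenstats.zscore_and_average(norm)
        bumped = well_z.copy()
        edge = bumped["well"].isin(screenstats.EDGE_WELLS)
        bumped.loc[edge & (bumped["content"] == "library"), "z"] += 2.0
        qc = screenstats.qc_report(bumped)
        assert any("edge effect" in f for f in qc.flags)

    def test_control_class_means_reported(self, small_screen):
        norm = screenstats.normalize_plates(small_screen.measurements, small_screen.layout)
        _, well_z = screenstats.zscore_and_average(norm)
        qc = screenstats.qc_report(well_z)
        assert ("migration", "neg_ctrl") in qc.control_means
        assert qc.control_means[("migration", "pos_ctrl")] < -1
        assert qc.control_means[("migration", "neg_ctrl")] > 0


class TestViabilityFilter:
    def test_window_is_strict(self):
        hs = HitSet("migration", "low", -1, {"A", "B", "C", "D"})
        table = {"A": 0.9, "B": 0.5, "C": 1.3, "D": 0.8}
        filtered, missing = screenstats.viability_filter(hs, table)
        assert filtered.members == {"A"}  # 0.8 boundary excluded
        assert missing == []

    def test_missing_members_reported(self):
        hs = HitSet("migration", "low", -1, {"A", "X"})
        filtered, missing = screenstats.viability_filter(hs, {"A": 1.0})
        assert filtered.members == {"A"}
        assert missing == ["X"]

    def test_planted_lethal_hits_are_excluded(self, small_screen):
        norm = screenstats.normalize_plates(small_screen.measurements, small_screen.layout)
        scores, _ = screenstats.zscore_and_average(norm)
        low, _ = screenstats.call_hits(scores, "migration")
        assert {"syn-mir-007", "syn-mir-008"} <= low.members
        filtered, _ = screenstats.viability_filter(low, small_screen.viability)
        assert "syn-mir-007" in filtered.members   # healthy planted hit stays
        assert "syn-mir-008" not in filtered.members  # lethal planted hit removed
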