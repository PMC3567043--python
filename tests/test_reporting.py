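"""Region-level orchestration, cross-region summaries, scale correlation."""

import numpy as np
import pandas as pd
import pytest

import atlasthresh as at
from atlasthresh.cover import attach_neighborhood_cover
from atlasthresh.datasets import model_comparison_examples, regional_threshold_table
from atlasthresh.errors import UndefinedCorrelationError, ValidationError


def _region(seed=1, n=150):
    side = int(np.ceil(np.sqrt(n)))
    profile = at.RegionProfile("r", n, (side, side), 63.1, 3.5)
    blocks = at.generate_landscape(profile, seed)
    specs = [
        at.SpeciesResponseSpec("THRESH", 60.0, -2.0, 0.0, 0.5),
        at.SpeciesResponseSpec("PLAIN", 60.0, 0.5, 0.01, 0.0),
        at.SpeciesResponseSpec("EVERYWHERE", 60.0, 12.0, 0.0, 0.0),  # persists in all blocks
    ]
    records = []
    for spec in specs:
        records.extend(at.simulate_species_dynamics(blocks, spec, seed))
    return blocks, records


class TestRunRegionAnalysis:
    def test_bookkeeping_one_row_per_species_dynamic(self):
        blocks, records = _region()
        report = at.run_region_analysis(blocks, records)
        assert len(report.table) == 3 * 2
        assert set(report.table["dynamic"]) == {"persistence", "extinction"}

    def test_degenerate_species_flagged_not_dropped(self):
        blocks, records = _region()
        report = at.run_region_analysis(blocks, records)
        row = report.table.query("species == 'EVERYWHERE'").iloc[0]
        assert row["selected"] == "none"
        assert row["flags"] == "degenerate_response"

    def test_counts_match_rows(self):
        blocks, records = _region()
        report = at.run_region_analysis(blocks, records)
        for dyn, count in report.n_threshold_selected.items():
            sel = ((report.table["dynamic"] == dyn)
                   & (report.table["selected"] == "threshold")).sum()
            assert sel == count

    def test_deterministic(self):
        blocks, records = _region()
        a = at.run_region_analysis(blocks, records)
        b = at.run_region_analysis(blocks, records)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_config(self):
        with pytest.raises(ValidationError):
            at.AnalysisConfig(confidence_mode="sometimes")


class TestCrossRegionSummary:
    def test_published_shared_species_means(self):
        table = regional_threshold_table()
        ny = table[table["region"] == "new_york"]
        vt = table[table["region"] == "vermont"]
        out = at.cross_region_summary(ny, vt, "new_york", "vermont")
        get = lambda dyn, reg: out.query(
            "dynamic == @dyn and region == @reg"
        ).iloc[0]["mean_psi"]
        assert get("persistence", "vermont") == pytest.approx(51.08, abs=0.005)
        assert get("persistence", "new_york") == pytest.approx(61.41, abs=0.005)
        assert get("extinction", "vermont") == pytest.approx(73.67, abs=0.005)
        assert get("extinction", "new_york") == pytest.approx(66.45, abs=0.005)

    def test_all_equal_thresholds_zero_se(self):
        t = pd.DataFrame({"species": ["a", "b"], "dynamic": ["persistence"] * 2,
                          "psi": [42.0, 42.0]})
        out = at.cross_region_summary(t, t)
        assert (out["mean_psi"] == 42.0).all()
        assert (out["se"] == 0.0).all()

    def test_single_shared_species_undefined_se(self):
        t = pd.DataFrame({"species": ["a"], "dynamic": ["persistence"], "psi": [42.0]})
        out = at.cross_region_summary(t, t)
        assert out.iloc[0]["mean_psi"] == 42.0
        assert np.isnan(out.iloc[0]["se"])

    def test_no_shared_species_empty(self):
        a = pd.DataFrame({"species": ["a"], "dynamic": ["persistence"], "psi": [40.0]})
        b = pd.DataFrame({"species": ["z"], "dynamic": ["persistence"], "psi": [60.0]})
        assert at.cross_region_summary(a, b).empty


class TestCoverScaleCorrelation:
    def test_identical_covariates_perfect_rank_correlation(self):
        blocks = [
            at.AtlasBlock(f"b{i}", 0, i, float(10 + i * 7),
                          neighborhood_forest_pct=float(10 + i * 7))
            for i in range(8)
        ]
        rho, _ = at.cover_scale_correlation(blocks)
        assert rho == pytest.approx(1.0)

    def test_anti_ranked_covariates(self):
        blocks = [
            at.AtlasBlock(f"b{i}", 0, i, float(10 + i * 7),
                          neighborhood_forest_pct=float(90 - i * 7))
            for i in range(8)
        ]
        rho, _ = at.cover_scale_correlation(blocks)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(8)
        xs = rng.uniform(0, 100, 20)
        ws = rng.uniform(0, 100, 20)
        blocks = [
            at.AtlasBlock(f"b{i}", 0, i, float(xs[i]),
                          neighborhood_forest_pct=float(ws[i]))
            for i in range(20)
        ]
        rho, _ = at.cover_scale_correlation(blocks)
        # brute-force Spearman: Pearson correlation of the rank vectors
        rx = np.argsort(np.argsort(xs))
        rw = np.argsort(np.argsort(ws))
        expected = np.corrcoef(rx, rw)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_covariate_undefined(self):
        blocks = [
            at.AtlasBlock(f"b{i}", 0, i, 50.0, neighborhood_forest_pct=float(i))
            for i in range(5)
        ]
        with pytest.raises(UndefinedCorrelationError):
            at.cover_scale_correlation(blocks)

    def test_neighborhood_attachment_end_to_end(self):
        profile = at.RegionProfile("n", 36, (6, 6), 60.0, 4.0)
        blocks = attach_neighborhood_cover(at.generate_landscape(profile, 2))
        rho, p = at.cover_scale_correlation(blocks)
        assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0


class TestReferenceTables:
    def test_delta_aic_examples_consistent(self):
        ex = model_comparison_examples()
        row = ex.query("species == 'Yellow-bellied Sapsucker' and dynamic == 'persistence'").iloc[0]
        assert row["aic_nonthreshold"] - row["aic_threshold"] == pytest.approx(2.89)
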