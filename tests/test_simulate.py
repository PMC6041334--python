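"""Generator: stage mixture, marker gating, rendering conservation."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.stats

from qibc.simulate import (
    DrugEffects,
    FociModel,
    GroundTruthCell,
    RenderParams,
    RenderError,
    SimulationParams,
    render_field,
    sample_population,
    simulate_features,
)

STAGE_ORDER = ("G1", "S", "G2", "M_pro_meta", "M_ana_telo")


def _ellipse_cell(cell_id, c_units, area, stage="G1", markers=None, foci=None,
                  aspect=1.2):
    a = math.sqrt(area * aspect / math.pi)
    b = math.sqrt(area / (aspect * math.pi))
    return GroundTruthCell(
        cell_id=cell_id, true_stage=stage, s_progress=0.0,
        dna_content_C=c_units, marker_means=markers or {},
        foci_truth=foci or [], area_px=area, axes=(a, b), orientation=0.3,
    )


def _true_background(shape, render):
    lo, hi = render.background_range
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return lo + (hi - lo) * (yy + xx) / float(shape[0] + shape[1] - 2)


class TestSamplePopulation:
    def test_empty_population(self):
        assert sample_population(SimulationParams(n_cells=0)) == []

    def test_unnormalized_fractions_rejected(self):
        params = SimulationParams(stage_fractions=(0.5, 0.2, 0.1, 0.1, 0.05))
        with pytest.raises(ValueError, match="sum to 1"):
            params.validate()

    def test_s_phase_fold_gated_off_in_pure_g1(self):
        """The gamma-H2AX fold applies only to S cells: an all-G1 population
        is statistically indistinguishable from baseline."""
        base = SimulationParams(
            n_cells=3000, stage_fractions=(1, 0, 0, 0, 0), seed=11
        )
        drugged = dataclasses.replace(
            base, drug_effects=DrugEffects(s_phase_gh2ax_fold=10.0)
        )
        a = [c.marker_means["gh2ax"] for c in sample_population(base)]
        b = [c.marker_means["gh2ax"] for c in sample_population(drugged)]
        assert scipy.stats.mannwhitneyu(a, b).pvalue > 0.01

    def test_stage_counts_match_multinomial_oracle(self):
        """Empirical stage counts on 10,000 cells stay within 3 sigma of the
        multinomial expectation (direct tail computation as oracle)."""
        fractions = (0.4, 0.35, 0.15, 0.05, 0.05)
        params = SimulationParams(
            n_cells=10_000, stage_fractions=fractions, seed=7
        )
        cells = sample_population(params)
        stages = np.array([c.true_stage for c in cells])
        n = len(cells)
        for stage, p in zip(STAGE_ORDER, fractions):
            count = (stages == stage).sum()
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 3 * sigma, stage

    def test_stage_gated_markers(self):
        """EdU elevation only in S; H3pS10 elevation only in mitosis;
        Cyclin A mean is monotone along S progression."""
        cells = sample_population(SimulationParams(n_cells=5000, seed=3))
        edu_s = [c.marker_means["edu"] for c in cells if c.true_stage == "S"]
        edu_other = [c.marker_means["edu"] for c in cells if c.true_stage != "S"]
        assert np.median(edu_s) > 4 * np.median(edu_other)
        h3_m = [c.marker_means["h3ps10"] for c in cells if c.true_stage.startswith("M")]
        h3_other = [c.marker_means["h3ps10"] for c in cells
                    if not c.true_stage.startswith("M")]
        assert np.median(h3_m) > 4 * np.median(h3_other)
        s_cells = sorted(
            (c for c in cells if c.true_stage == "S"), key=lambda c: c.s_progress
        )
        tau = scipy.stats.kendalltau(
            [c.s_progress for c in s_cells],
            [c.marker_means["cyclin_a"] for c in s_cells],
        )
        assert tau.statistic > 0.5

    def test_dna_content_by_stage(self):
        cells = sample_population(SimulationParams(n_cells=2000, seed=9))
        for c in cells:
            assert 2.0 <= c.dna_content_C <= 4.0
            if c.true_stage == "G1" or c.true_stage == "M_ana_telo":
                assert c.dna_content_C == 2.0
            elif c.true_stage in ("G2", "M_pro_meta"):
                assert c.dna_content_C == 4.0
            else:
                assert c.dna_content_C == pytest.approx(2 + 2 * c.s_progress)

    def test_determinism(self):
        params = SimulationParams(n_cells=500, seed=42)
        a = sample_population(params)
        b = sample_population(params)
        assert a == b

    def test_trapping_requires_pre_extraction(self):
        drug = DrugEffects(trapping_fold=5.0)
        soluble = SimulationParams(
            n_cells=2000, markers=("parp1",), drug_effects=drug, seed=4
        )
        chromatin = dataclasses.replace(soluble, pre_extraction=True)
        m_sol = np.median([c.marker_means["parp1"]
                           for c in sample_population(soluble)])
        m_chr = np.median([c.marker_means["parp1"]
                           for c in sample_population(chromatin)])
        assert m_chr > 4 * m_sol

    def test_s_g2_accumulation_shift(self):
        arrested = SimulationParams(
            n_cells=8000, seed=6,
            drug_effects=DrugEffects(s_g2_accumulation_shift=0.3),
        )
        stages = np.array([c.true_stage for c in sample_population(arrested)])
        frac_g1 = (stages == "G1").mean()
        frac_sg2 = np.isin(stages, ("S", "G2")).mean()
        assert frac_g1 < 0.30  # down from 0.45
        assert frac_sg2 > 0.65  # up from 0.50


class TestRenderField:
    def test_empty_field_is_background_plus_noise(self):
        render = RenderParams(shape=(128, 128))
        fov = render_field([], render, seed=0)
        assert fov.truth_mask.max() == 0
        bg = _true_background((128, 128), render)
        assert abs(fov.channels["dapi"].mean() - bg.mean()) < 2.0

    def test_g2_g1_integrated_dapi_ratio(self):
        """Background-subtracted integrated DAPI, summed over the truth masks
        by a naive pixel loop, doubles from 2C to 4C (pixel-sum oracle)."""
        render = RenderParams(shape=(256, 256))
        cells = [
            _ellipse_cell(1, 2.0, 300.0),
            _ellipse_cell(2, 4.0, 300.0, stage="G2"),
        ]
        fov = render_field(cells, render, seed=1)
        bg = _true_background((256, 256), render)
        totals = {}
        for cell in fov.cells:
            acc = 0.0
            for r in range(256):
                for c in range(256):
                    if fov.truth_mask[r, c] == cell.cell_id:
                        acc += fov.channels["dapi"][r, c] - bg[r, c]
            totals[cell.cell_id] = acc
        expected = {1: 2 * render.dapi_total_per_c, 2: 4 * render.dapi_total_per_c}
        sigmas = {
            k: math.sqrt(expected[k] + 300 * (45 + render.read_noise_sd**2))
            for k in expected
        }
        ratio = totals[2] / totals[1]
        ratio_sigma = ratio * math.sqrt(
            (sigmas[1] / expected[1]) ** 2 + (sigmas[2] / expected[2]) ** 2
        )
        assert abs(ratio - 2.0) < 3 * ratio_sigma

    def test_dapi_conservation_per_nucleus(self):
        """Integrated DAPI over each truth mask recovers the cell's DNA
        content within 4 Poisson sigma of the calibration."""
        render = RenderParams(shape=(512, 512))
        cells = sample_population(SimulationParams(n_cells=40, seed=13, markers=()))
        fov = render_field(cells, render, seed=2)
        bg = _true_background((512, 512), render)
        for cell in fov.cells:
            mask = fov.truth_mask == cell.cell_id
            total = (fov.channels["dapi"][mask] - bg[mask]).sum()
            expected = cell.dna_content_C * render.dapi_total_per_c
            sigma = math.sqrt(
                expected + mask.sum() * (bg[mask].mean() + render.read_noise_sd**2)
            )
            assert abs(total - expected) < 4 * sigma

    def test_mitotic_mean_dapi_signature(self):
        """A condensed prophase nucleus (same 4C content, 0.4x area) shows
        higher mean DAPI than a G2 nucleus at equal total DAPI."""
        render = RenderParams(shape=(256, 256))
        cells = [
            _ellipse_cell(1, 4.0, 400.0, stage="G2"),
            _ellipse_cell(2, 4.0, 160.0, stage="M_pro_meta"),
        ]
        fov = render_field(cells, render, seed=3)
        bg = _true_background((256, 256), render)
        stats = {}
        for cell in fov.cells:
            mask = fov.truth_mask == cell.cell_id
            vals = fov.channels["dapi"][mask] - bg[mask]
            stats[cell.cell_id] = (vals.sum(), vals.mean())
        assert stats[2][1] > 1.5 * stats[1][1]
        assert stats[2][0] == pytest.approx(stats[1][0], rel=0.05)

    def test_overcrowded_field_rejected(self):
        cells = [_ellipse_cell(i, 2.0, 2000.0) for i in range(1, 60)]
        with pytest.raises(RenderError, match="place|fit"):
            render_field(cells, RenderParams(shape=(128, 128)), seed=0)

    def test_intensities_within_12bit_range(self):
        cells = sample_population(SimulationParams(n_cells=30, seed=1))
        fov = render_field(cells, RenderParams(shape=(512, 512)), seed=1)
        for img in fov.channels.values():
            assert img.min() >= 0.0 and img.max() <= 4095.0


class TestSimulateFeatures:
    def test_feature_table_matches_truth_calibration(self):
        feats = simulate_features(SimulationParams(n_cells=4000, seed=8))
        g1 = feats[feats["true_stage"] == "G1"]["total_dapi"]
        g2 = feats[feats["true_stage"] == "G2"]["total_dapi"]
        assert g2.mean() / g1.mean() == pytest.approx(2.0, abs=0.05)
        assert g1.median() == pytest.approx(1000.0, rel=0.05)

    def test_mean_times_area_equals_total(self):
        feats = simulate_features(SimulationParams(n_cells=500, seed=8))
        np.testing.assert_allclose(
            feats["mean_dapi"] * feats["area"], feats["total_dapi"], rtol=1e-12
        )

    def test_doublets_sum_content(self):
        feats = simulate_features(
            SimulationParams(n_cells=2000, doublet_fraction=0.05, seed=10)
        )
        doublets = feats[feats["true_stage"] == "doublet"]
        assert len(doublets) == 50
        assert (doublets["true_C"] >= 4.0).all()

    def test_rad51_foci_coupled_to_damaged_s_cells(self):
        """Foci-bearing cells carry more gamma-H2AX than focus-free S cells
        when foci rates couple to the damage marker."""
        params = SimulationParams(
            n_cells=4000,
            markers=("gh2ax", "edu"),
            drug_effects=DrugEffects(s_phase_gh2ax_fold=4.0),
            foci_models={"rad51": FociModel(rate_s=2.0, rate_other=0.05,
                                            couple_to_gh2ax=True)},
            seed=12,
        )
        feats = simulate_features(params)
        s = feats[feats["true_stage"] == "S"]
        with_foci = s[s["foci_count_rad51"] > 0]["mean_gh2ax"]
        without = s[s["foci_count_rad51"] == 0]["mean_gh2ax"]
        assert with_foci.mean() > without.mean()
        non_s = feats[feats["true_stage"] != "S"]
        assert non_s["foci_count_rad51"].mean() < 0.2
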