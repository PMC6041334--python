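"""Reference scenarios: end-to-end runs of the pipeline on generator output.

Each function builds a defined synthetic scenario, runs the relevant pipeline
stages on it and returns the measured quantities.  They are used both by the
validation suite and by the reproduction script, so the problem sizes here
are the package's documented study conditions, not ad-hoc test fixtures.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import imaging, quantify, screen, staging
from .simulate import (
    DrugEffects,
    FociModel,
    RenderParams,
    SimulationParams,
    GroundTruthCell,
    render_field,
    render_population,
    sample_population,
    simulate_features,
    simulate_plate_features,
    focus_pixel_positions,
)

__all__ = [
    "modal_c",
    "mitotic_scene",
    "mitotic_dna_anchors",
    "mann_whitney_null_calibration",
    "staging_recovery",
    "segmentation_recovery",
    "foci_recovery",
    "trapping_dissociation",
    "dynamic_range_check",
    "screen_recovery",
    "null_plate_zscores",
]


def modal_c(values: np.ndarray, bin_width: float = 0.5) -> float:
    """Mode of DNA content in C units, on a histogram of ``bin_width`` bins
    centered on multiples of the bin width (so 2C and 4C are bin centers)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return math.nan
    centers = np.round(vals / bin_width) * bin_width
    uniq, counts = np.unique(centers, return_counts=True)
    return float(uniq[np.argmax(counts)])


def mitotic_scene(seed: int = 1, n_cells: int = 5000) -> pd.DataFrame:
    """Default mitotic scene: render, segment, extract, normalize, stage.

    An asynchronous population (5% mitotic) is rendered as DAPI images,
    segmented, and staged from DNA content alone (1D staging: mitotic cells
    by the condensed-chromatin mean-DAPI signature).  Returns the staged
    per-nucleus table.
    """
    params = SimulationParams(n_cells=n_cells, markers=(), seed=seed)
    render = RenderParams(channels=())
    fields = render_population(params, render, cells_per_field=200)
    feats = []
    for i, fov in enumerate(fields):
        corrected = imaging.correct_background(fov.channels["dapi"])
        seg = imaging.segment_nuclei(corrected)
        feats.append(
            imaging.extract_features({"dapi": corrected}, seg, meta={"field": i})
        )
    features = pd.concat([f for f in feats if len(f)], ignore_index=True)
    staged = staging.stage_cells(features, available_markers=("dapi",))
    return staged


def mitotic_dna_anchors(seed: int = 1, n_cells: int = 5000) -> dict:
    """Modal C of the two mitotic sub-stages on the default scene.

    Prophase-to-metaphase chromosomes carry replicated (4C) DNA,
    anaphase/telophase figures segregated (2C) DNA; both stand out by
    elevated mean DAPI.  Returns the modal C (0.5-C bins) per sub-stage.
    """
    staged = mitotic_scene(seed=seed, n_cells=n_cells)
    pro_meta = staged.loc[staged["stage"] == "M_pro_meta", "C"]
    ana_telo = staged.loc[staged["stage"] == "M_ana_telo", "C"]
    return {
        "modal_C_pro_meta": modal_c(pro_meta.to_numpy()),
        "modal_C_ana_telo": modal_c(ana_telo.to_numpy()),
        "n_pro_meta": int(len(pro_meta)),
        "n_ana_telo": int(len(ana_telo)),
        "n_cells": int(len(staged)),
    }


def mann_whitney_null_calibration(
    seed: int = 1,
    n_replicates: int = 2000,
    n_per_group: int = 400,
    alpha: float = 0.05,
) -> dict:
    """Empirical false-positive rate of the per-condition comparison.

    Both groups of each replicate pair are drawn from one identical untreated
    gamma-H2AX distribution (the generator's asynchronous population), so any
    rejection at ``alpha`` is a false positive.  Returns the rejection
    fraction and its binomial standard error.
    """
    params = SimulationParams(
        n_cells=n_replicates * 2 * n_per_group, markers=("gh2ax",), seed=seed
    )
    feats = simulate_features(params)
    values = feats["mean_gh2ax"].to_numpy().reshape(n_replicates, 2, n_per_group)
    rejections = 0
    for i in range(n_replicates):
        res = quantify.compare_conditions(values[i, 0], values[i, 1])
        if res.p_two_sided < alpha:
            rejections += 1
    frac = rejections / n_replicates
    se = math.sqrt(alpha * (1 - alpha) / n_replicates)
    return {
        "false_positive_rate": frac,
        "n_replicates": n_replicates,
        "n_per_group": n_per_group,
        "alpha": alpha,
        "binomial_se": se,
    }


def staging_recovery(seed: int = 1, n_cells: int = 10_000) -> dict:
    """Staging accuracy against generator truth on the default scenario.

    4D staging (DAPI + EdU + Cyclin A + H3pS10) on the measured feature
    table; reports the overall accuracy, per-stage recall, and the
    G2/G1 total-DAPI ratio.
    """
    params = SimulationParams(n_cells=n_cells, seed=seed)
    feats = simulate_features(params)
    staged = staging.stage_cells(feats)
    truth = staged["true_stage"].to_numpy()
    predicted = staged["stage"].to_numpy()
    predicted = np.where(
        np.isin(predicted, ("S_early", "S_mid", "S_late")), "S", predicted
    )
    accuracy = float((predicted == truth).mean())
    recall = {}
    for st in ("G1", "S", "G2", "M_pro_meta", "M_ana_telo"):
        mask = truth == st
        recall[st] = float((predicted[mask] == st).mean()) if mask.any() else math.nan
    g1 = staged.loc[truth == "G1", "total_dapi"].mean()
    g2 = staged.loc[truth == "G2", "total_dapi"].mean()
    return {
        "accuracy": accuracy,
        "recall": recall,
        "g2_g1_total_dapi_ratio": float(g2 / g1),
        "n_cells": n_cells,
    }


def _match_labels(
    truth_mask: np.ndarray, labels: np.ndarray, iou_threshold: float = 0.5
) -> dict:
    """IoU>threshold matching between truth and segmentation labels.

    IoU > 0.5 matches are necessarily one-to-one, so recall/precision follow
    directly from the match count.
    """
    t = truth_mask.ravel().astype(np.int64)
    s = labels.ravel().astype(np.int64)
    both = (t > 0) & (s > 0)
    n_t, n_s = int(t.max()), int(s.max())
    pair_ids = t[both] * (n_s + 1) + s[both]
    uniq, counts = np.unique(pair_ids, return_counts=True)
    t_area = np.bincount(t, minlength=n_t + 1)
    s_area = np.bincount(s, minlength=n_s + 1)
    matched_t, matched_s = set(), set()
    n_match = 0
    for pid, inter in zip(uniq, counts):
        ti, si = int(pid // (n_s + 1)), int(pid % (n_s + 1))
        union = t_area[ti] + s_area[si] - inter
        if union > 0 and inter / union > iou_threshold:
            n_match += 1
            matched_t.add(ti)
            matched_s.add(si)
    bijective = n_match == len(matched_t) == len(matched_s)
    return {
        "n_truth": n_t,
        "n_segmented": n_s,
        "n_matched": n_match,
        "recall": n_match / n_t if n_t else math.nan,
        "precision": n_match / n_s if n_s else math.nan,
        "bijective": bijective,
    }


def segmentation_recovery(
    seed: int = 1, n_fields: int = 10, cells_per_field: int = 200
) -> dict:
    """Nucleus recovery on non-overlapping synthetic fields.

    Each field carries ``cells_per_field`` ground-truth nuclei at high SNR;
    reports aggregate counts, recall/precision under IoU>0.5 matching and
    whether the matching is a bijection in every field.
    """
    params = SimulationParams(
        n_cells=n_fields * cells_per_field, markers=(), seed=seed
    )
    render = RenderParams(channels=())
    fields = render_population(params, render, cells_per_field=cells_per_field)
    agg = {"n_truth": 0, "n_segmented": 0, "n_matched": 0}
    all_bijective = True
    exact_counts = True
    for fov in fields:
        corrected = imaging.correct_background(fov.channels["dapi"])
        seg = imaging.segment_nuclei(corrected)
        m = _match_labels(fov.truth_mask, seg.label_image)
        for k in agg:
            agg[k] += m[k]
        all_bijective &= m["bijective"]
        exact_counts &= m["n_segmented"] == m["n_truth"]
    agg["recall"] = agg["n_matched"] / agg["n_truth"]
    agg["precision"] = agg["n_matched"] / agg["n_segmented"]
    agg["bijective"] = all_bijective
    agg["exact_counts"] = exact_counts
    agg["n_fields"] = n_fields
    return agg


def _planted_focus_cells(
    n_nuclei: int, n_foci: int = 7, amplitude: float = 170.0, sigma: float = 1.5
) -> list[GroundTruthCell]:
    """Nuclei with ``n_foci`` planted Gaussian foci on a ring, spaced so that
    neighbouring foci are at least 4 sigma apart.

    Nuclei are sized as at high magnification (a few thousand px) so the
    foci occupy a small fraction of the nuclear area; the amplitude is about
    8x the in-nucleus shot-noise sigma (sqrt of ~450 counts)."""
    cells = []
    for i in range(n_nuclei):
        area = 2000.0
        aspect = 1.2
        a = math.sqrt(area * aspect / math.pi)
        b = math.sqrt(area / (aspect * math.pi))
        foci = []
        for k in range(n_foci):
            theta = 2 * math.pi * k / n_foci
            foci.append(
                ("rad51", 0.6 * math.cos(theta), 0.6 * math.sin(theta),
                 amplitude, sigma)
            )
        cells.append(
            GroundTruthCell(
                cell_id=i + 1, true_stage="S", s_progress=0.5,
                dna_content_C=3.0,
                marker_means={"rad51": 200.0},
                foci_truth=foci, area_px=area, axes=(a, b), orientation=0.0,
            )
        )
    return cells


def foci_recovery(
    seed: int = 1, n_nuclei: int = 30, n_foci: int = 7
) -> dict:
    """Planted-spot recovery: recall and false positives per nucleus.

    Foci are Gaussian bumps of amplitude ~8x the in-nucleus shot-noise sigma;
    a detection within 2 px of a planted focus counts as recovered.
    """
    cells = _planted_focus_cells(n_nuclei, n_foci=n_foci)
    fov = render_field(cells, RenderParams(shape=(768, 768)), seed=seed)
    # segment directly from the truth mask: this scenario probes foci
    # detection, not segmentation
    seg = imaging.SegmentationResult(
        fov.truth_mask.astype(np.int32),
        pd.DataFrame(
            {
                "label": [c.cell_id for c in fov.cells],
                "area": [c.area_px for c in fov.cells],
                "centroid_r": [c.centroid[0] for c in fov.cells],
                "centroid_c": [c.centroid[1] for c in fov.cells],
                "border_touching": False,
            }
        ),
    )
    corrected = imaging.correct_background(fov.channels["rad51"])
    result = imaging.detect_foci(corrected, seg)
    n_true = 0
    n_hit = 0
    n_false = 0
    for cell in fov.cells:
        truth_pos = focus_pixel_positions(cell)
        det = result.foci[result.foci["label"] == cell.cell_id]
        det_pos = det[["row", "col"]].to_numpy(dtype=float)
        n_true += len(truth_pos)
        used = np.zeros(len(det_pos), dtype=bool)
        for tp in truth_pos:
            if len(det_pos) == 0:
                continue
            d = np.sqrt(((det_pos - tp) ** 2).sum(axis=1))
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= 2.0:
                used[j] = True
                n_hit += 1
        n_false += int((~used).sum())
    return {
        "recall": n_hit / n_true,
        "false_positives_per_nucleus": n_false / len(fov.cells),
        "n_nuclei": len(fov.cells),
        "n_planted": n_true,
    }


def trapping_dissociation(
    seed: int = 1,
    n_cells: int = 10_000,
    trapping_fold: float = 3.0,
    gh2ax_fold: float = 6.0,
) -> dict:
    """Joint trapping/damage readout in one pre-extracted population.

    Chromatin-bound PARP1 rises uniformly across the cycle (trapping is
    cell-cycle independent) while the same cells' gamma-H2AX rises only in S
    (damage is replication-born).  Returns the trapping profile's
    independence statistics and the damage S/G1 fold.
    """
    params = SimulationParams(
        n_cells=n_cells,
        markers=("gh2ax", "edu", "parp1"),
        drug_effects=DrugEffects(
            s_phase_gh2ax_fold=gh2ax_fold, trapping_fold=trapping_fold
        ),
        pre_extraction=True,
        seed=seed,
    )
    feats = simulate_features(params, meta={"condition": "PARPi+MMS"})
    staged = staging.stage_cells(feats, available_markers=("dapi", "edu"))
    profile = quantify.trapping_profile(staged)
    dmg = profile.damage_per_stage.set_index("gate")["mean"]
    return {
        "max_pairwise_stage_fold": profile.max_pairwise_fold,
        "kruskal_p": profile.kruskal_p,
        "gh2ax_s_over_g1_fold": float(dmg["S"] / dmg["G1"]),
        "n_cells": n_cells,
    }


def dynamic_range_check(
    seed: int = 1, n_cells: int = 8000, gh2ax_fold: float = 4.0
) -> dict:
    """Subpopulation focusing vs the closed-form mixture oracle.

    For an effect restricted to S cells, the whole-population fold change is
    the mixture-diluted 1 + w_S (fold - 1), where w_S is the S share of the
    untreated signal; the mid-S gate measures the undiluted fold.  Returns
    both measured folds and the oracle prediction.
    """
    base = SimulationParams(n_cells=n_cells, markers=("gh2ax", "edu"), seed=seed)
    treated = dataclasses.replace(
        base, drug_effects=DrugEffects(s_phase_gh2ax_fold=gh2ax_fold),
        seed=seed + 1,
    )
    f_un = simulate_features(base, meta={"condition": "untreated"})
    f_tr = simulate_features(treated, meta={"condition": "treated"})
    both = pd.concat([f_un, f_tr], ignore_index=True)
    staged = staging.stage_cells(both, available_markers=("dapi", "edu"))
    staged = staging.bin_s_phase(staged)
    dr = quantify.dynamic_range(staged, "treated", "untreated", "gh2ax")
    folds = dr.set_index("gate")["fold_change"]
    # mixture oracle from the true stage mixture: marker means are equal
    # across stages untreated, so the S signal share equals the S fraction
    w_s = base.stage_fractions[1]
    oracle_whole = 1.0 + w_s * (gh2ax_fold - 1.0)
    return {
        "fold_all": float(folds["all"]),
        "fold_s": float(folds["S"]),
        "fold_mid_s": float(folds["mid_S"]),
        "oracle_whole_population": oracle_whole,
        "oracle_mid_s": gh2ax_fold,
        "n_cells": n_cells,
    }


def _screen_plate_spec(n_neutral: int = 20, n_sirna: int = 3) -> screen.PlateSpec:
    genes = ["RESCUE1", "SENS1"] + [f"NEUT{i:02d}" for i in range(n_neutral)]
    return screen.PlateSpec.grid(genes, n_sirna=n_sirna, arms=("treated",))


def screen_recovery(
    seed: int = 1,
    n_plates: int = 100,
    cells_per_well: int = 1000,
    rescue_factor: float = 0.3,
    sensitizer_factor: float = 3.0,
) -> dict:
    """Planted-effect recovery over repeated simulated screens.

    Each plate carries one rescue gene (effect factor < 1 on S-phase
    gamma-H2AX), one sensitizer (> 1) and neutral genes, three siRNA wells
    each.  Reports how often the rescue ranks first (most negative z) and the
    sensitizer last.
    """
    plate = _screen_plate_spec()
    effects = {"RESCUE1": rescue_factor, "SENS1": sensitizer_factor}
    base = SimulationParams(
        n_cells=cells_per_well,
        markers=("gh2ax", "edu"),
        drug_effects=DrugEffects(s_phase_gh2ax_fold=5.0),
        seed=0,
    )
    n_correct = 0
    for p in range(n_plates):
        plate_seed = int(
            np.random.SeedSequence(seed, spawn_key=(p,)).generate_state(1)[0]
            % (2**31)
        )
        feats = simulate_plate_features(plate, effects, base, seed=plate_seed)
        staged = staging.stage_cells(
            feats, available_markers=("dapi", "edu"), batch_col="arm"
        )
        wells = screen.analyze_wells(plate, staged)
        scores = screen.score_genes(wells, plate)
        first = scores.iloc[0]["gene"]
        last = scores.iloc[-1]["gene"]
        if first == "RESCUE1" and last == "SENS1":
            n_correct += 1
    return {
        "fraction_correct": n_correct / n_plates,
        "n_plates": n_plates,
        "cells_per_well": cells_per_well,
    }


def null_plate_zscores(
    seed: int = 1, n_neutral: int = 56, cells_per_well: int = 300
) -> dict:
    """z-score distribution of an all-neutral plate (standardization check)."""
    genes = [f"NEUT{i:02d}" for i in range(n_neutral)]
    plate = screen.PlateSpec.grid(genes, n_sirna=3, arms=("treated",))
    base = SimulationParams(
        n_cells=cells_per_well,
        markers=("gh2ax", "edu"),
        drug_effects=DrugEffects(s_phase_gh2ax_fold=5.0),
        seed=0,
    )
    feats = simulate_plate_features(plate, {}, base, seed=seed)
    staged = staging.stage_cells(
        feats, available_markers=("dapi", "edu"), batch_col="arm"
    )
    wells = screen.analyze_wells(plate, staged, min_cells=100)
    scores = screen.score_genes(wells, plate)
    z = scores["z"].to_numpy()
    return {
        "mean_z": float(z.mean()),
        "sd_z": float(z.std(ddof=1)),
        "n_genes": len(z),
    }
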