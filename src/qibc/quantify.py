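"""Condition-level, cell-cycle-resolved quantification.

Population summaries per stage gate, rank-based two-condition comparisons
(Mann-Whitney, the field's standard for immunofluorescence intensities),
subpopulation dynamic range, PARP-trapping cell-cycle-independence profiles,
and mitotic chromatin-condensation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "TrappingProfile",
    "gate_mask",
    "summarize_by_stage",
    "compare_conditions",
    "dynamic_range",
    "trapping_profile",
    "condensation_metrics",
    "adjust_pvalues",
    "jittered_column",
]

#: Built-in stage gates: name -> set of stage labels (None = all retained).
S_LABELS = ("S", "S_early", "S_mid", "S_late")
GATES: dict[str, tuple[str, ...] | None] = {
    "all": None,
    "G1": ("G1",),
    "S": S_LABELS,
    "mid_S": ("S_mid",),
    "G2": ("G2",),
    "M_pro_meta": ("M_pro_meta",),
    "M_ana_telo": ("M_ana_telo",),
    "mitotic": ("M_pro_meta", "M_ana_telo"),
}


def gate_mask(staged: pd.DataFrame, gate: str) -> np.ndarray:
    """Boolean mask of a named stage gate (excluded records never pass)."""
    if gate not in GATES:
        raise KeyError(f"unknown gate {gate!r}; known: {sorted(GATES)}")
    stages = staged["stage"]
    keep = (stages != "excluded").to_numpy()
    labels = GATES[gate]
    if labels is None:
        return keep
    return keep & stages.isin(labels).to_numpy()


def summarize_by_stage(
    staged: pd.DataFrame,
    marker: str,
    gates: tuple[str, ...] = ("all", "G1", "S", "mid_S", "G2"),
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Location/dispersion of a marker per (condition, gate).

    The location statistic is the mean (population averages, as QIBC bar
    charts report), with median, s.d. and MAD alongside.  Empty gates yield
    n=0 rows with NaN locations and ``flag='empty_gate'``.
    """
    col = f"mean_{marker}" if f"mean_{marker}" in staged else marker
    if col not in staged:
        raise ValueError(f"marker column {col!r} not found")
    conditions = (
        staged[condition_col].unique() if condition_col in staged else [None]
    )
    rows = []
    for cond in conditions:
        sub = staged if cond is None else staged[staged[condition_col] == cond]
        for gate in gates:
            vals = sub.loc[gate_mask(sub, gate), col].to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "condition": cond,
                    "gate": gate,
                    "n": n,
                    "mean": vals.mean() if n else np.nan,
                    "median": np.median(vals) if n else np.nan,
                    "sd": vals.std(ddof=1) if n > 1 else np.nan,
                    "mad": scipy.stats.median_abs_deviation(vals, scale="normal")
                    if n else np.nan,
                    "flag": "" if n else "empty_gate",
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Mann-Whitney comparison of one marker between two groups.

    ``effect_size`` is the rank-biserial correlation 1 - 2U/(n1*n2), positive
    when the first group tends to be smaller.
    """

    u: float
    p_two_sided: float
    n1: int
    n2: int
    effect_size: float
    gate: str = ""


def compare_conditions(
    group_a: np.ndarray | pd.Series,
    group_b: np.ndarray | pd.Series,
    gate: str = "",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between two samples of marker values.

    Exact null distribution for small tie-free samples (n1 + n2 <= 20), the
    tie-corrected normal approximation otherwise — matching how the test is
    applied to cohorts of hundreds of cells per condition.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)  # U of the first sample
    effect = 1.0 - 2.0 * u / (len(a) * len(b))
    return ComparisonResult(
        u=u,
        p_two_sided=float(min(res.pvalue, 1.0)),
        n1=len(a),
        n2=len(b),
        effect_size=effect,
        gate=gate,
    )


def dynamic_range(
    staged: pd.DataFrame,
    treated_condition: str,
    reference_condition: str,
    marker: str,
    gates: tuple[str, ...] = ("all", "S", "mid_S"),
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Treated/reference fold change of the marker mean, per stage gate.

    Restricting the gate to the responding subpopulation (S, and most of all
    mid-S) raises the fold change of an S-restricted effect above the
    whole-population readout.  Reference locations <= 0 flag the gate
    ``undefined_reference`` with NaN fold.
    """
    col = f"mean_{marker}" if f"mean_{marker}" in staged else marker
    treated = staged[staged[condition_col] == treated_condition]
    ref = staged[staged[condition_col] == reference_condition]
    rows = []
    for gate in gates:
        t_vals = treated.loc[gate_mask(treated, gate), col]
        r_vals = ref.loc[gate_mask(ref, gate), col]
        r_mean = r_vals.mean() if len(r_vals) else np.nan
        if not len(r_vals) or not np.isfinite(r_mean) or r_mean <= 0:
            rows.append({"gate": gate, "fold_change": np.nan,
                         "n_treated": len(t_vals), "n_reference": len(r_vals),
                         "flag": "undefined_reference"})
            continue
        rows.append(
            {
                "gate": gate,
                "fold_change": t_vals.mean() / r_mean if len(t_vals) else np.nan,
                "n_treated": len(t_vals),
                "n_reference": len(r_vals),
                "flag": "" if len(t_vals) else "empty_gate",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrappingProfile:
    """Cell-cycle profile of chromatin-bound PARP in pre-extracted cells.

    ``per_stage``: location/dispersion of the PARP channel per stage;
    ``damage_per_stage``: the same cells' gamma-H2AX summary (the joint
    readout: trapping flat across the cycle, damage concentrated in S).
    ``max_pairwise_fold`` and the Kruskal-Wallis test operationalize
    "cell-cycle independent": near-unity fold and a non-significant H.
    """

    per_stage: pd.DataFrame
    damage_per_stage: pd.DataFrame | None
    kruskal_h: float
    kruskal_p: float
    max_pairwise_fold: float


def trapping_profile(
    staged: pd.DataFrame,
    parp_marker: str = "parp1",
    damage_marker: str = "gh2ax",
    stages: tuple[str, ...] = ("G1", "S", "G2"),
) -> TrappingProfile:
    """Per-stage chromatin-bound PARP profile with an independence statistic.

    Requires pre-extracted input (``pre_extraction`` metadata True on every
    record): without the detergent wash the PARP channel measures total, not
    chromatin-bound, protein and trapping is undefined.
    """
    if "pre_extraction" not in staged.columns:
        raise ValueError("records carry no pre_extraction metadata; trapping "
                         "is undefined on non-pre-extracted fields")
    if not staged["pre_extraction"].astype(bool).all():
        raise ValueError("trapping requires pre-extracted fields only")
    col = f"mean_{parp_marker}"
    if col not in staged:
        raise ValueError(f"no {col!r} column")
    groups = []
    rows = []
    for st in stages:
        vals = staged.loc[gate_mask(staged, st), col].to_numpy(dtype=float)
        if len(vals):
            groups.append(vals)
        rows.append(
            {
                "stage": st,
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "median": np.median(vals) if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    per_stage = pd.DataFrame(rows)
    means = per_stage["mean"].dropna()
    max_fold = float(means.max() / means.min()) if len(means) >= 2 and means.min() > 0 else np.nan
    if len(groups) >= 2:
        h, p = scipy.stats.kruskal(*groups)
    else:
        h, p = np.nan, np.nan
    dmg_col = f"mean_{damage_marker}"
    damage = None
    if dmg_col in staged:
        damage = summarize_by_stage(
            staged.assign(condition="_"), damage_marker,
            gates=tuple(stages), condition_col="condition",
        ).drop(columns="condition")
    return TrappingProfile(
        per_stage=per_stage,
        damage_per_stage=damage,
        kruskal_h=float(h),
        kruskal_p=float(p),
        max_pairwise_fold=max_fold,
    )


def condensation_metrics(
    staged: pd.DataFrame, condition_col: str = "condition"
) -> pd.DataFrame:
    """Mitotic chromatin condensation: mean DAPI and chromosome area.

    Per condition, location +/- s.d. of mitotic mean DAPI (condensation
    raises it) and of the mitotic object area (condensed chromosomes occupy
    fewer pixels).  Conditions without mitotic cells are flagged.
    """
    conditions = (
        staged[condition_col].unique() if condition_col in staged else [None]
    )
    rows = []
    for cond in conditions:
        sub = staged if cond is None else staged[staged[condition_col] == cond]
        mit = sub[gate_mask(sub, "mitotic")]
        n = len(mit)
        rows.append(
            {
                "condition": cond,
                "n_mitotic": n,
                "mean_dapi_mean": mit["mean_dapi"].mean() if n else np.nan,
                "mean_dapi_sd": mit["mean_dapi"].std(ddof=1) if n > 1 else np.nan,
                "area_mean": mit["area"].mean() if n else np.nan,
                "area_sd": mit["area"].std(ddof=1) if n > 1 else np.nan,
                "flag": "" if n else "no_mitotic_cells",
            }
        )
    return pd.DataFrame(rows)


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR across a family of gate/timepoint comparisons."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def jittered_column(
    values, amount: float = 0.25, seed: int = 0
) -> np.ndarray:
    """Mildly jittered copy of a discrete column, for scatter plots only.

    Demerges overlapping points (e.g. foci counts) in visualizations; the
    jittered values must never enter statistics — keep them in a separate
    plotting column.
    """
    rng = np.random.default_rng(seed)
    vals = np.asarray(values, dtype=float)
    return vals + rng.uniform(-amount, amount, size=vals.shape)
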