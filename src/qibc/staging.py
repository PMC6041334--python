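"""Cell-cycle staging from per-nucleus features.

DNA content is normalized to C units by anchoring the G1 mode of the total
DAPI distribution at 2C (per batch, since staining intensity is in arbitrary,
batch-dependent units).  Stage labels are then assigned by a fixed priority:
mitotic classification (H3pS10 and/or the condensed-chromatin mean-DAPI
signature), EdU positivity (S), and DNA-content windows (G1/G2).  Without an
EdU channel, intermediate DNA content falls back to S (1D staging).

Marker positivity thresholds are resolved per batch from a two-component
Gaussian mixture on log intensity (equal-posterior crossing), with an Otsu
fallback when the mixture degenerates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

__all__ = [
    "StagingParams",
    "normalize_dna_content",
    "filter_2c_4c",
    "marker_positivity",
    "classify_mitotic",
    "stage_cells",
    "bin_s_phase",
]

#: Stage labels the staging partition can emit.
STAGE_LABELS = (
    "G1", "S", "S_early", "S_mid", "S_late", "G2",
    "M_pro_meta", "M_ana_telo", "excluded",
)


@dataclass(frozen=True)
class StagingParams:
    """Staging thresholds, all in C units unless noted.

    ``tol``: half-width of the retained 2C-4C window (records outside
    [2-tol, 4+tol] are excluded as debris/doublets).  ``delta``: width of the
    G1/G2 anchor windows.  ``mitotic_mean_dapi_factor``: a nucleus is called
    mitotic when its mean DAPI exceeds this multiple of the interphase median
    (chromatin condensation raises mean DAPI at conserved total DAPI).
    """

    tol: float = 0.4
    delta: float = 0.35
    mitotic_mean_dapi_factor: float = 1.8
    min_batch_records: int = 200


def _g1_mode(log_totals: np.ndarray) -> tuple[float, bool]:
    """Locate the G1 mode of log total DAPI by KDE; also report whether a
    secondary (G2) mode near twice the G1 intensity is visible."""
    kde = gaussian_kde(log_totals, bw_method="silverman")
    grid = np.linspace(log_totals.min(), log_totals.max(), 512)
    dens = kde(grid)
    peaks = argrelmax(dens)[0]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    med = np.median(log_totals)
    # G1 is the strongest mode at or below the median (S/G2 may dominate in
    # arrested populations); small tolerance covers near-pure-G1 batches
    below = peaks[grid[peaks] <= med + np.log(1.15)]
    chosen = below[np.argmax(dens[below])] if len(below) else peaks[np.argmax(dens[peaks])]
    g1_log = grid[chosen]
    has_g2 = bool(np.any(np.abs(grid[peaks] - (g1_log + np.log(2.0))) < 0.3))
    return float(np.exp(g1_log)), has_g2


def normalize_dna_content(
    records: pd.DataFrame,
    batch_col: str | None = None,
    params: StagingParams = StagingParams(),
) -> pd.DataFrame:
    """Add normalized DNA content ``C`` = 2 x total_dapi / (G1 mode).

    Normalization is per batch (``batch_col``; None = one batch).  A batch
    whose total-DAPI distribution shows no secondary mode near twice the G1
    mode is flagged in ``dna_qc_flag`` (C is still computed).  Fewer than
    ``min_batch_records`` records in a batch triggers a warning — the mode
    estimate becomes unstable.
    """
    if "total_dapi" not in records:
        raise ValueError("records must have a 'total_dapi' column")
    df = records.copy()
    df["C"] = np.nan
    df["dna_qc_flag"] = ""
    groups = [(None, df.index)] if batch_col is None else [
        (k, idx) for k, idx in df.groupby(batch_col).groups.items()
    ]
    for key, idx in groups:
        totals = df.loc[idx, "total_dapi"].to_numpy(dtype=float)
        valid = totals > 0
        if valid.sum() < 2:
            df.loc[idx, "dna_qc_flag"] = "degenerate_batch"
            continue
        if valid.sum() < params.min_batch_records:
            warnings.warn(
                f"batch {key!r}: only {int(valid.sum())} records; G1 mode "
                "estimate may be unstable",
                stacklevel=2,
            )
        g1, has_g2 = _g1_mode(np.log(totals[valid]))
        df.loc[idx, "C"] = 2.0 * totals / g1
        if not has_g2:
            df.loc[idx, "dna_qc_flag"] = "no_4c_shoulder"
    return df


def filter_2c_4c(records: pd.DataFrame, tol: float = 0.4) -> pd.DataFrame:
    """Flag records outside the 2C-4C window (plus tolerance) as excluded.

    Adds a boolean ``dna_excluded`` column; downstream staging labels those
    records ``excluded``.  Debris falls below 2C - tol, doublets above
    4C + tol.
    """
    if "C" not in records:
        raise ValueError("C must be computed first (normalize_dna_content)")
    df = records.copy()
    df["dna_excluded"] = (df["C"] < 2.0 - tol) | (df["C"] > 4.0 + tol)
    if "saturated" in df:
        df["dna_excluded"] |= df["saturated"].astype(bool)
    return df


def marker_positivity(
    values: np.ndarray, min_separation_sd: float = 0.5
) -> tuple[np.ndarray, float]:
    """Positive/negative split of a marker by 2-component GMM on log intensity.

    The threshold is the equal-posterior crossing between the two components;
    if the fit degenerates (components closer than ``min_separation_sd``
    pooled sd, or a vanishing weight), falls back to Otsu on log intensity.
    Returns (boolean flags, threshold on the original scale).
    """
    vals = np.asarray(values, dtype=float)
    logv = np.log(np.clip(vals, 1e-6, None)).reshape(-1, 1)
    thr_log = None
    if len(logv) >= 20 and np.ptp(logv) > 1e-6:
        gm = GaussianMixture(n_components=2, random_state=0, n_init=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(logv)
        mus = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        order = np.argsort(mus)
        mu_lo, mu_hi = mus[order]
        sd_pool = float(np.max(sds))
        if (mu_hi - mu_lo) > min_separation_sd * sd_pool and gm.weights_.min() > 0.01:
            grid = np.linspace(mu_lo, mu_hi, 512).reshape(-1, 1)
            post = gm.predict_proba(grid)[:, order[1]]
            cross = np.searchsorted(post > 0.5, True)
            thr_log = float(grid[min(cross, 511), 0])
    if thr_log is None:
        try:
            thr_log = float(threshold_otsu(logv.ravel()))
        except ValueError:
            thr_log = float(np.inf)  # constant marker: nobody positive
    return vals > np.exp(thr_log), float(np.exp(thr_log))


def classify_mitotic(
    records: pd.DataFrame, params: StagingParams = StagingParams()
) -> pd.DataFrame:
    """Flag mitotic cells and sub-stage them by DNA content.

    Mitotic = mean DAPI above ``mitotic_mean_dapi_factor`` times the median
    mean DAPI of 2C-4C cells (condensed chromatin), OR H3pS10-positive when
    that channel exists.  Sub-label: C >= 3 -> prophase-to-metaphase (4C),
    C < 3 -> anaphase/telophase (2C, chromatin still condensed).
    """
    if "C" not in records or "mean_dapi" not in records:
        raise ValueError("C and mean_dapi are required")
    df = records.copy()
    in_range = (df["C"] >= 2.0 - params.tol) & (df["C"] <= 4.0 + params.tol)
    ref = df.loc[in_range, "mean_dapi"].median()
    condensed = df["mean_dapi"] > params.mitotic_mean_dapi_factor * ref
    mitotic = condensed.to_numpy(copy=True)
    if "h3ps10_positive" in df:
        mitotic |= df["h3ps10_positive"].to_numpy(dtype=bool)
    df["mitotic"] = mitotic
    df["mitotic_sub"] = np.where(
        mitotic, np.where(df["C"] >= 3.0, "M_pro_meta", "M_ana_telo"), ""
    )
    return df


def stage_cells(
    records: pd.DataFrame,
    available_markers: tuple[str, ...] = ("dapi", "edu", "cyclin_a", "h3ps10"),
    params: StagingParams = StagingParams(),
    batch_col: str | None = None,
) -> pd.DataFrame:
    """Assign one cell-cycle stage label per record.

    Priority order: (1) 2C-4C exclusion; (2) mitotic classification;
    (3) EdU-positive -> S; (4) DNA-content anchors: C < 2 + delta -> G1,
    C > 4 - delta -> G2.  EdU-negative cells of intermediate C go to the
    nearer anchor with a QC flag when EdU is available, or to S for 1D
    staging without EdU.  Cyclin A never overrides DNA/EdU calls; a
    Cyclin-A-positive G1 call is QC-flagged instead.
    """
    if "dapi" not in available_markers:
        raise ValueError("DAPI is required for staging")
    if "total_dapi" not in records:
        raise ValueError("records must have a 'total_dapi' column")
    df = records.copy()
    if "C" not in df:
        df = normalize_dna_content(df, batch_col=batch_col, params=params)
    if "dna_excluded" not in df:
        df = filter_2c_4c(df, tol=params.tol)

    for marker in ("edu", "cyclin_a", "h3ps10"):
        col = f"mean_{marker}"
        flag = f"{marker.replace('cyclin_a', 'cyclina')}_positive"
        if marker in available_markers and col in df:
            flags = np.zeros(len(df), dtype=bool)
            groups = [(None, df.index)] if batch_col is None else [
                (k, idx) for k, idx in df.groupby(batch_col).groups.items()
            ]
            for _key, idx in groups:
                pos, _thr = marker_positivity(df.loc[idx, col].to_numpy())
                flags[df.index.get_indexer(idx)] = pos
            df[flag] = flags
        else:
            df[flag] = False
    df = classify_mitotic(df, params=params)  # reads 'h3ps10_positive'

    have_edu = "edu" in available_markers and "mean_edu" in records.columns
    c = df["C"].to_numpy()
    stage = np.empty(len(df), dtype=object)
    qc = np.array([""] * len(df), dtype=object)

    stage[:] = ""
    excluded = df["dna_excluded"].to_numpy(dtype=bool)
    mitotic = df["mitotic"].to_numpy(dtype=bool) & ~excluded
    stage[mitotic] = df.loc[df.index[mitotic], "mitotic_sub"].to_numpy()

    rest = ~excluded & ~mitotic
    if have_edu:
        edu_pos = df["edu_positive"].to_numpy(dtype=bool)
        s_sel = rest & edu_pos
        stage[s_sel] = "S"
        rest2 = rest & ~edu_pos
        g1_sel = rest2 & (c < 2.0 + params.delta)
        g2_sel = rest2 & (c > 4.0 - params.delta)
        stage[g1_sel] = "G1"
        stage[g2_sel] = "G2"
        inter = rest2 & ~g1_sel & ~g2_sel
        stage[inter & (c < 3.0)] = "G1"
        stage[inter & (c >= 3.0)] = "G2"
        qc[inter] = "intermediate_edu_negative"
    else:
        g1_sel = rest & (c < 2.0 + params.delta)
        g2_sel = rest & (c > 4.0 - params.delta)
        stage[g1_sel] = "G1"
        stage[g2_sel] = "G2"
        stage[rest & ~g1_sel & ~g2_sel] = "S"
    stage[excluded] = "excluded"

    cyc_conflict = df["cyclina_positive"].to_numpy(dtype=bool) & (stage == "G1")
    qc[cyc_conflict] = np.where(
        qc[cyc_conflict] == "", "cyclina_g1_conflict",
        qc[cyc_conflict] + ";cyclina_g1_conflict",
    )
    df["stage"] = stage
    df["stage_qc_flag"] = qc
    return df


def bin_s_phase(staged: pd.DataFrame) -> pd.DataFrame:
    """Split S cells into early/mid/late by DNA-content terciles.

    Boundaries: C <= 2.67 early, C <= 3.33 mid, else late (thirds of the
    2C->4C replication interval).  The mid-S gate is the subpopulation on
    which treated-vs-untreated dynamic range is maximal.  No S cells is not
    an error: the frame is returned unchanged.
    """
    if "stage" not in staged or "C" not in staged:
        raise ValueError("staged records with C are required")
    df = staged.copy()
    s_mask = df["stage"] == "S"
    c = df["C"]
    df.loc[s_mask & (c <= 2.67), "stage"] = "S_early"
    df.loc[s_mask & (c > 2.67) & (c <= 3.33), "stage"] = "S_mid"
    df.loc[s_mask & (c > 3.33), "stage"] = "S_late"
    return df
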