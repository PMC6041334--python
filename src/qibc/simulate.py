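"""Synthetic asynchronous cell populations and their rendering into images.

The generator emulates the statistical structure of an asynchronously growing
adherent cell population as seen by quantitative image-based cytometry (QIBC):
a cell-cycle stage mixture, 2C-4C DNA content, S-phase-restricted EdU
incorporation, Cyclin A accumulation through S/G2, H3pS10-marked mitosis with
chromatin condensation, S-phase-specific drug-induced gamma-H2AX and
cell-cycle-independent chromatin retention of PARP1 under trapping conditions
(inhibitor + genotoxin, read out after detergent pre-extraction).

Two output paths exist and share one sampling core:

* :func:`sample_population` + :func:`render_field` produce ground-truth cells
  and noisy multi-channel images (12-bit) with a label mask, exercising the
  full segmentation/feature-extraction pipeline.
* :func:`simulate_features` produces the measured per-cell feature table
  directly (total/mean DAPI, per-marker means, foci counts), emulating the
  measurement step with multiplicative staining/measurement noise.  This path
  scales to millions of cells and is what plate-scale simulations use.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import skimage.draw

__all__ = [
    "STAGES",
    "MITOTIC_STAGES",
    "DrugEffects",
    "MarkerModel",
    "FociModel",
    "SimulationParams",
    "RenderParams",
    "GroundTruthCell",
    "FieldOfView",
    "RenderError",
    "sample_population",
    "render_field",
    "render_population",
    "simulate_features",
    "truth_frame",
    "make_screen_plate",
    "simulate_plate_features",
    "focus_pixel_positions",
]

#: Cell-cycle stages, in the order stage_fractions refers to them.
STAGES = ("G1", "S", "G2", "M_pro_meta", "M_ana_telo")
MITOTIC_STAGES = ("M_pro_meta", "M_ana_telo")

#: Calibration of the feature-table path: total DAPI per C unit, so a G1 cell
#: (2C) measures ~1000 a.u.  Arbitrary units, as in real QIBC data.
DAPI_AU_PER_C = 500.0


@dataclass(frozen=True)
class DrugEffects:
    """Multiplicative per-condition effect sizes.

    s_phase_gh2ax_fold
        Fold increase of the gamma-H2AX mean in S-phase cells (>=1 for a
        genotoxic treatment; 1 = untreated).
    trapping_fold
        Fold increase of chromatin-bound PARP1 in *all* stages; only expressed
        when the population is pre-extracted (soluble PARP1 is washed out).
    edu_suppression
        Fraction (0-1) by which S-phase EdU incorporation is reduced
        (replication slow-down).
    mitotic_gh2ax_fold
        Fold increase of gamma-H2AX in mitotic cells (mitotic DNA damage).
    s_g2_accumulation_shift
        Probability mass moved from G1/M into S/G2 (cell-cycle arrest).
    par_suppression
        Fraction (0-1) by which cellular PAR is reduced (catalytic PARP
        inhibition).
    """

    s_phase_gh2ax_fold: float = 1.0
    trapping_fold: float = 1.0
    edu_suppression: float = 0.0
    mitotic_gh2ax_fold: float = 1.0
    s_g2_accumulation_shift: float = 0.0
    par_suppression: float = 0.0

    def validate(self) -> None:
        for name in ("s_phase_gh2ax_fold", "trapping_fold", "mitotic_gh2ax_fold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("edu_suppression", "par_suppression"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.s_g2_accumulation_shift < 1.0:
            raise ValueError("s_g2_accumulation_shift must be in [0, 1)")


@dataclass(frozen=True)
class MarkerModel:
    """Lognormal intensity model for one immunofluorescence marker.

    ``baseline_median``/``baseline_sigma`` parameterize the negative
    population; ``elevated_median``/``elevated_sigma`` the stage-gated
    positive population (EdU in S, Cyclin A in S/G2, H3pS10 in mitosis).
    Markers without a gated level (gamma-H2AX, PARP1, PAR) leave the elevated
    level unset; drug effects act multiplicatively on the baseline draw.
    """

    baseline_median: float
    baseline_sigma: float
    elevated_median: float | None = None
    elevated_sigma: float | None = None


@dataclass(frozen=True)
class FociModel:
    """Poisson model of discrete nuclear foci for one channel.

    ``rate_s``/``rate_other`` are expected foci per S / non-S cell.  With
    ``couple_to_gh2ax`` the per-cell S rate scales with that cell's
    gamma-H2AX mean relative to the marker baseline (RAD51 foci concentrate
    in the most damaged S cells), capped at 5x.
    """

    rate_s: float = 5.0
    rate_other: float = 0.2
    amplitude: float = 300.0
    sigma_px: float = 1.5
    couple_to_gh2ax: bool = False


DEFAULT_MARKERS: dict[str, MarkerModel] = {
    "gh2ax": MarkerModel(120.0, 0.40),
    "edu": MarkerModel(80.0, 0.45, 900.0, 0.35),
    "cyclin_a": MarkerModel(60.0, 0.40, 600.0, 0.25),
    "h3ps10": MarkerModel(50.0, 0.40, 1500.0, 0.30),
    "parp1": MarkerModel(250.0, 0.35),
    "par": MarkerModel(300.0, 0.35),
}

#: Asynchronous default: 45% G1, 35% S, 15% G2, 5% mitotic.
DEFAULT_STAGE_FRACTIONS = (0.45, 0.35, 0.15, 0.03, 0.02)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated condition (one population)."""

    n_cells: int = 5000
    stage_fractions: tuple[float, ...] = DEFAULT_STAGE_FRACTIONS
    dna_cv: float = 0.06
    marker_baselines: dict[str, MarkerModel] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    markers: tuple[str, ...] = ("gh2ax", "edu", "cyclin_a", "h3ps10")
    drug_effects: DrugEffects = field(default_factory=DrugEffects)
    pre_extraction: bool = False
    condensation_factor: float = 0.4
    mean_g1_area_px: float = 260.0
    area_sigma: float = 0.15
    measurement_cv: float = 0.05
    doublet_fraction: float = 0.0
    foci_models: dict[str, FociModel] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        fr = np.asarray(self.stage_fractions, dtype=float)
        if fr.shape != (5,):
            raise ValueError("stage_fractions must have 5 entries (G1, S, G2, "
                             "M_pro_meta, M_ana_telo)")
        if (fr < 0).any():
            raise ValueError("stage_fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"stage_fractions must sum to 1 (got {fr.sum():.12f}); "
                "normalize them explicitly"
            )
        if not 0.0 < self.condensation_factor < 1.0:
            raise ValueError("condensation_factor must be in (0, 1)")
        if self.dna_cv < 0:
            raise ValueError("dna_cv must be >= 0")
        if not 0.0 <= self.doublet_fraction < 0.5:
            raise ValueError("doublet_fraction must be in [0, 0.5)")
        for m in self.markers:
            if m not in self.marker_baselines:
                raise ValueError(f"no baseline model for marker {m!r}")
        self.drug_effects.validate()


@dataclass(frozen=True)
class RenderParams:
    """How a population is rendered into 12-bit camera images."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.32
    dapi_total_per_c: float = 45000.0
    background_range: tuple[float, float] = (30.0, 60.0)
    read_noise_sd: float = 3.0
    boundary_gap_px: float = 2.0
    max_retries: int = 1000
    full_range: float = 4095.0
    channels: tuple[str, ...] | None = None  # None = DAPI + all simulated


@dataclass
class GroundTruthCell:
    """Ground truth for one simulated cell.

    ``foci_truth`` holds (marker, u, v, amplitude, sigma) with (u, v) in the
    unit disc of the nucleus ellipse; absolute pixel positions exist once the
    cell is placed in a field (``centroid`` set) via
    :func:`focus_pixel_positions`.
    """

    cell_id: int
    true_stage: str
    s_progress: float
    dna_content_C: float
    marker_means: dict[str, float]
    foci_truth: list[tuple[str, float, float, float, float]]
    area_px: float
    axes: tuple[float, float]
    orientation: float
    centroid: tuple[float, float] | None = None


@dataclass
class FieldOfView:
    """Aligned multi-channel images of one acquisition field."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    meta: dict
    truth_mask: np.ndarray | None = None
    cells: list[GroundTruthCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")


class RenderError(RuntimeError):
    """Raised when a field cannot be rendered (e.g. placement fails)."""


# ---------------------------------------------------------------------------
# sampling


def _shifted_fractions(fractions: np.ndarray, shift: float) -> np.ndarray:
    """Move ``shift`` probability mass from G1/M into S/G2 proportionally."""
    if shift <= 0:
        return fractions
    out = fractions.copy()
    donors = np.array([0, 3, 4])  # G1, both M stages
    receivers = np.array([1, 2])  # S, G2
    donor_mass = out[donors].sum()
    take = min(shift, donor_mass)
    if donor_mass > 0:
        out[donors] -= take * out[donors] / donor_mass
    rec_mass = out[receivers].sum()
    if rec_mass > 0:
        out[receivers] += take * out[receivers] / rec_mass
    else:  # degenerate: dump into S
        out[1] += take
    return out / out.sum()


def _sample_arrays(params: SimulationParams, rng: np.random.Generator) -> dict:
    """Vectorized sampling core shared by both output paths.

    The order of rng draws is fixed, so identical params+seed give
    bit-identical populations.
    """
    n = params.n_cells
    eff = params.drug_effects
    fractions = _shifted_fractions(
        np.asarray(params.stage_fractions, float), eff.s_g2_accumulation_shift
    )
    stage_idx = rng.choice(5, size=n, p=fractions)
    stage = np.asarray(STAGES)[stage_idx]
    is_s = stage == "S"
    is_m = (stage == "M_pro_meta") | (stage == "M_ana_telo")

    u = np.zeros(n)
    u[is_s] = rng.uniform(0.0, 1.0, int(is_s.sum()))

    c = np.full(n, 2.0)
    c[is_s] = 2.0 + 2.0 * u[is_s]
    c[stage == "G2"] = 4.0
    c[stage == "M_pro_meta"] = 4.0
    c[stage == "M_ana_telo"] = 2.0

    # Interphase nuclear area grows proportionally with DNA content so mean
    # DAPI stays flat across interphase; mitotic chromatin condenses to a
    # fraction of the corresponding interphase area.
    base_area = rng.lognormal(math.log(params.mean_g1_area_px), params.area_sigma, n)
    area = base_area * (c / 2.0)
    area[is_m] *= params.condensation_factor

    aspect = rng.uniform(1.0, 1.4, n)
    orientation = rng.uniform(0.0, math.pi, n)

    means: dict[str, np.ndarray] = {}
    for marker in params.markers:
        model = params.marker_baselines[marker]
        base = rng.lognormal(math.log(model.baseline_median), model.baseline_sigma, n)
        if model.elevated_median is not None:
            elevated = rng.lognormal(
                math.log(model.elevated_median), model.elevated_sigma, n
            )
        else:
            elevated = None
        if marker == "gh2ax":
            fold = np.ones(n)
            fold[is_s] = eff.s_phase_gh2ax_fold
            fold[is_m] = eff.mitotic_gh2ax_fold
            means[marker] = base * fold
        elif marker == "edu":
            vals = base.copy()
            vals[is_s] = elevated[is_s] * (1.0 - eff.edu_suppression)
            means[marker] = vals
        elif marker == "cyclin_a":
            vals = base.copy()
            ramp = 0.2 + 0.8 * u  # linear accumulation through S
            vals[is_s] = elevated[is_s] * ramp[is_s]
            vals[stage == "G2"] = elevated[stage == "G2"]
            vals[stage == "M_pro_meta"] = 0.5 * elevated[stage == "M_pro_meta"]
            means[marker] = vals  # M_ana_telo stays at baseline (degraded)
        elif marker == "h3ps10":
            vals = base.copy()
            vals[is_m] = elevated[is_m]
            means[marker] = vals
        elif marker == "parp1":
            fold = eff.trapping_fold if params.pre_extraction else 1.0
            means[marker] = base * fold  # cell-cycle independent
        elif marker == "par":
            means[marker] = base * (1.0 - eff.par_suppression)
        else:
            means[marker] = base

    foci: dict[str, list] = {}
    for marker, fmodel in params.foci_models.items():
        rate = np.where(is_s, fmodel.rate_s, fmodel.rate_other).astype(float)
        if fmodel.couple_to_gh2ax and "gh2ax" in means:
            rel = means["gh2ax"] / params.marker_baselines["gh2ax"].baseline_median
            rate[is_s] *= np.minimum(rel[is_s], 5.0)
        counts = rng.poisson(rate)
        per_cell = []
        for k in counts:
            theta = rng.uniform(0, 2 * math.pi, k)
            r = 0.75 * np.sqrt(rng.uniform(0, 1, k))
            per_cell.append(
                [
                    (marker, r[j] * math.cos(theta[j]), r[j] * math.sin(theta[j]),
                     fmodel.amplitude, fmodel.sigma_px)
                    for j in range(k)
                ]
            )
        foci[marker] = per_cell

    return {
        "stage": stage,
        "s_progress": u,
        "dna_content_C": c,
        "area": area,
        "aspect": aspect,
        "orientation": orientation,
        "marker_means": means,
        "foci": foci,
    }


def sample_population(params: SimulationParams) -> list[GroundTruthCell]:
    """Draw a ground-truth population; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    arr = _sample_arrays(params, rng)
    n = params.n_cells
    cells = []
    marker_names = list(arr["marker_means"])
    for i in range(n):
        foci: list = []
        for marker, per_cell in arr["foci"].items():
            foci.extend(per_cell[i])
        area = arr["area"][i]
        aspect = arr["aspect"][i]
        a = math.sqrt(area * aspect / math.pi)
        b = math.sqrt(area / (aspect * math.pi))
        cells.append(
            GroundTruthCell(
                cell_id=i + 1,
                true_stage=str(arr["stage"][i]),
                s_progress=float(arr["s_progress"][i]),
                dna_content_C=float(arr["dna_content_C"][i]),
                marker_means={m: float(arr["marker_means"][m][i]) for m in marker_names},
                foci_truth=foci,
                area_px=float(area),
                axes=(a, b),
                orientation=float(arr["orientation"][i]),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# rendering


def focus_pixel_positions(cell: GroundTruthCell) -> np.ndarray:
    """Absolute (row, col) of each planted focus of a placed cell."""
    if cell.centroid is None:
        raise ValueError("cell has not been placed in a field")
    if not cell.foci_truth:
        return np.empty((0, 2))
    a, b = cell.axes
    phi = cell.orientation
    out = []
    for _marker, u, v, _amp, _sig in cell.foci_truth:
        dr = u * a * math.cos(phi) - v * b * math.sin(phi)
        dc = u * a * math.sin(phi) + v * b * math.cos(phi)
        out.append((cell.centroid[0] + dr, cell.centroid[1] + dc))
    return np.asarray(out)


def _place_cells(
    cells: list[GroundTruthCell],
    render: RenderParams,
    rng: np.random.Generator,
) -> list[GroundTruthCell]:
    """Uniform rejection placement with a minimum boundary gap."""
    h, w = render.shape
    gap = render.boundary_gap_px
    placed: list[GroundTruthCell] = []
    radii: list[float] = []
    centers: list[tuple[float, float]] = []
    for cell in cells:
        r_max = max(cell.axes)
        if 2 * (r_max + gap) >= min(h, w):
            raise RenderError(f"nucleus {cell.cell_id} does not fit the frame")
        for _attempt in range(render.max_retries):
            cy = rng.uniform(r_max + gap, h - r_max - gap)
            cx = rng.uniform(r_max + gap, w - r_max - gap)
            ok = True
            for (py, px), pr in zip(centers, radii):
                if (cy - py) ** 2 + (cx - px) ** 2 < (r_max + pr + gap) ** 2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RenderError(
                f"could not place nucleus {cell.cell_id} after "
                f"{render.max_retries} retries; reduce density"
            )
        c2 = copy.copy(cell)
        c2.centroid = (cy, cx)
        placed.append(c2)
        centers.append((cy, cx))
        radii.append(r_max)
    return placed


def render_field(
    cells: list[GroundTruthCell],
    render: RenderParams = RenderParams(),
    seed: int = 0,
    meta: dict | None = None,
) -> FieldOfView:
    """Render placed nuclei into noisy 12-bit multi-channel images.

    Each nucleus is a filled ellipse; its integrated DAPI (over the truth
    mask, before noise) equals ``dna_content_C * dapi_total_per_c`` exactly,
    so condensed mitotic nuclei have elevated mean DAPI at conserved total
    DAPI.  Foci are additive 2D Gaussian bumps.  Poisson shot noise, Gaussian
    read noise and a planar background gradient are applied, clipped to the
    12-bit range.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h, w = render.shape
    placed = _place_cells(cells, render, rng)

    marker_names: list[str] = []
    for cell in placed:
        for m in cell.marker_means:
            if m not in marker_names:
                marker_names.append(m)
    if render.channels is not None:
        marker_names = [m for m in marker_names if m in render.channels]
    channel_names = ["dapi"] + marker_names

    signal = {name: np.zeros((h, w)) for name in channel_names}
    mask = np.zeros((h, w), dtype=np.uint16)

    for cell in placed:
        cy, cx = cell.centroid
        a, b = cell.axes
        rr, cc = skimage.draw.ellipse(cy, cx, a, b, shape=(h, w),
                                      rotation=cell.orientation)
        npx = len(rr)
        if npx == 0:
            continue
        cell.area_px = float(npx)
        mask[rr, cc] = cell.cell_id
        signal["dapi"][rr, cc] += cell.dna_content_C * render.dapi_total_per_c / npx
        for m in marker_names:
            signal[m][rr, cc] += cell.marker_means.get(m, 0.0)
        for marker, u, v, amp, sig in cell.foci_truth:
            if marker not in signal:
                continue
            fr = cy + (u * a * math.cos(cell.orientation)
                       - v * b * math.sin(cell.orientation))
            fc = cx + (u * a * math.sin(cell.orientation)
                       + v * b * math.cos(cell.orientation))
            half = int(math.ceil(4 * sig))
            r0, r1 = max(0, int(fr) - half), min(h, int(fr) + half + 1)
            c0, c1 = max(0, int(fc) - half), min(w, int(fc) + half + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            signal[marker][r0:r1, c0:c1] += amp * np.exp(
                -((yy - fr) ** 2 + (xx - fc) ** 2) / (2.0 * sig**2)
            )

    lo, hi = render.background_range
    yy, xx = np.mgrid[0:h, 0:w]
    background = lo + (hi - lo) * (yy + xx) / float(h + w - 2)

    channels = {}
    for name in channel_names:
        img = rng.poisson(np.clip(signal[name] + background, 0, None)).astype(float)
        img += rng.normal(0.0, render.read_noise_sd, size=(h, w))
        channels[name] = np.clip(img, 0.0, render.full_range)

    meta = dict(meta or {})
    meta.setdefault("pre_extraction", False)
    return FieldOfView(
        channels=channels,
        pixel_size_um=render.pixel_size_um,
        meta=meta,
        truth_mask=mask,
        cells=placed,
    )


def render_population(
    params: SimulationParams,
    render: RenderParams = RenderParams(),
    cells_per_field: int = 200,
    meta: dict | None = None,
) -> list[FieldOfView]:
    """Sample a population and render it as multiple fields.

    Per-field rng streams are spawned from ``params.seed`` by field index, so
    the run is reproducible and fields are independent.
    """
    cells = sample_population(params)
    meta = dict(meta or {})
    meta.setdefault("pre_extraction", params.pre_extraction)
    fields = []
    n_fields = max(1, math.ceil(len(cells) / cells_per_field))
    seeds = np.random.SeedSequence(params.seed).spawn(n_fields + 1)
    for i in range(n_fields):
        chunk = cells[i * cells_per_field:(i + 1) * cells_per_field]
        field_cells = []
        for j, cell in enumerate(chunk):
            c2 = copy.copy(cell)
            c2.cell_id = j + 1  # labels are per-field
            field_cells.append(c2)
        field_seed = int(seeds[i + 1].generate_state(1)[0] % (2**31))
        fmeta = dict(meta)
        fmeta["field"] = i
        fields.append(render_field(field_cells, render, seed=field_seed, meta=fmeta))
    return fields


# ---------------------------------------------------------------------------
# feature-table path


def truth_frame(cells: list[GroundTruthCell]) -> pd.DataFrame:
    """Ground truth as a DataFrame keyed by cell_id."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "true_stage": [c.true_stage for c in cells],
            "s_progress": [c.s_progress for c in cells],
            "dna_content_C": [c.dna_content_C for c in cells],
            "area_px": [c.area_px for c in cells],
        }
    )


def simulate_features(
    params: SimulationParams,
    meta: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Measured per-cell feature table, bypassing image rendering.

    Total DAPI is ``C * DAPI_AU_PER_C`` with multiplicative lognormal noise of
    coefficient ``dna_cv`` (staining + measurement variability); marker means
    get lognormal measurement noise ``measurement_cv``.  A ``doublet_fraction``
    > 0 replaces that fraction of cells by merged random pairs (mimicking
    under-segmentation); truth columns mark them ``true_stage='doublet'``.

    Returns a DataFrame that carries both the measured columns the pipeline
    consumes and ``true_*`` columns for validation.
    """
    params.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed if seed is None else seed)
    )
    arr = _sample_arrays(params, rng)
    n = params.n_cells

    total_dapi = arr["dna_content_C"] * DAPI_AU_PER_C * np.exp(
        rng.normal(0.0, params.dna_cv, n)
    )
    area = np.maximum(np.rint(arr["area"]), 1.0)
    means = {
        m: vals * np.exp(rng.normal(0.0, params.measurement_cv, n))
        for m, vals in arr["marker_means"].items()
    }
    foci_counts = {
        m: np.array([len(per) for per in per_cell])
        for m, per_cell in arr["foci"].items()
    }

    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "area": area,
            "total_dapi": total_dapi,
            "mean_dapi": total_dapi / area,
            "true_stage": arr["stage"],
            "true_C": arr["dna_content_C"],
            "true_s_progress": arr["s_progress"],
        }
    )
    for m, vals in means.items():
        df[f"mean_{m}"] = vals
        df[f"total_{m}"] = vals * area
    for m, counts in foci_counts.items():
        df[f"foci_count_{m}"] = counts

    if params.doublet_fraction > 0 and n >= 4:
        n_pairs = int(round(params.doublet_fraction * n / 2.0))
        if n_pairs:
            idx = rng.choice(n, size=2 * n_pairs, replace=False)
            a_idx, b_idx = idx[:n_pairs], idx[n_pairs:]
            merged = df.iloc[a_idx].reset_index(drop=True).copy()
            other = df.iloc[b_idx].reset_index(drop=True)
            merged["area"] = merged["area"].to_numpy() + other["area"].to_numpy()
            merged["total_dapi"] = (
                merged["total_dapi"].to_numpy() + other["total_dapi"].to_numpy()
            )
            merged["mean_dapi"] = merged["total_dapi"] / merged["area"]
            for m in means:
                tot = merged[f"total_{m}"].to_numpy() + other[f"total_{m}"].to_numpy()
                merged[f"total_{m}"] = tot
                merged[f"mean_{m}"] = tot / merged["area"]
            merged["true_stage"] = "doublet"
            merged["true_C"] = merged["true_C"].to_numpy() + other["true_C"].to_numpy()
            keep = np.ones(n, dtype=bool)
            keep[idx] = False
            df = pd.concat([df[keep], merged], ignore_index=True)
            df["cell_id"] = np.arange(1, len(df) + 1)

    meta = dict(meta or {})
    meta.setdefault("pre_extraction", params.pre_extraction)
    for key, value in meta.items():
        df[key] = value
    return df


# ---------------------------------------------------------------------------
# plates


def _well_seed(root_seed: int, well_index: int) -> int:
    ss = np.random.SeedSequence(root_seed, spawn_key=(well_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _well_params(
    base: SimulationParams,
    gene_factor: float,
    arm: str,
    seed: int,
) -> SimulationParams:
    eff = base.drug_effects
    if arm == "treated":
        eff = replace(eff, s_phase_gh2ax_fold=eff.s_phase_gh2ax_fold * gene_factor)
    else:
        eff = DrugEffects()  # untreated arm: no drug effects at all
    return replace(base, drug_effects=eff, seed=seed)


def simulate_plate_features(
    plate,
    effects: dict[str, float],
    params: SimulationParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-well feature tables for a whole plate (fast, image-free path).

    ``effects`` maps gene -> multiplicative factor on the S-phase gamma-H2AX
    fold in the treated arm (rescue < 1, sensitizer > 1, neutral 1).  Genes
    absent from the map are neutral.  Per-well seeds derive from ``seed`` and
    the well index, so plates are reproducible.
    """
    frames = []
    wells = plate.wells.reset_index(drop=True)
    for i, row in wells.iterrows():
        factor = effects.get(row["gene"], 1.0)
        wp = _well_params(params, factor, row["arm"], _well_seed(seed, i))
        df = simulate_features(
            wp,
            meta={
                "well": row["well"],
                "gene": row["gene"],
                "sirna": int(row["sirna"]),
                "arm": row["arm"],
                "condition": f"{row['gene']}_si{row['sirna']}_{row['arm']}",
            },
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def make_screen_plate(
    plate,
    effects: dict[str, float],
    params: SimulationParams,
    render: RenderParams = RenderParams(),
    cells_per_field: int = 150,
    seed: int = 0,
):
    """Render every well of a plate as one or more fields.

    Yields ``(well_id, [FieldOfView, ...])``.  For plate-scale statistics use
    :func:`simulate_plate_features`; this path exists to exercise the full
    image pipeline on small plates.
    """
    wells = plate.wells.reset_index(drop=True)
    for i, row in wells.iterrows():
        factor = effects.get(row["gene"], 1.0)
        wp = _well_params(params, factor, row["arm"], _well_seed(seed, i))
        fields = render_population(
            wp,
            render,
            cells_per_field=cells_per_field,
            meta={"well": row["well"], "gene": row["gene"],
                  "sirna": int(row["sirna"]), "arm": row["arm"]},
        )
        yield row["well"], fields
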