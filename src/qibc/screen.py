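"""Plate-scale siRNA screen analysis.

Per-well staged summaries (cells, S-phase gamma-H2AX mean, cycle fractions),
per-gene aggregation over independent siRNA replicate wells, robust z-scores
over the treated arm, and hit ranking: the strongest rescue (e.g. loss of the
drug's own target) attains the most negative z, sensitizers (e.g. checkpoint
mediators) the most positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .quantify import gate_mask

__all__ = [
    "PlateSpec",
    "analyze_wells",
    "score_genes",
    "replicate_concordance",
]


@dataclass
class PlateSpec:
    """Well layout of one screening plate.

    ``wells``: DataFrame with columns well, gene, sirna (replicate index),
    arm ('untreated' or 'treated').  ``control_genes`` name the negative
    controls (non-targeting siRNA), which must be present in every arm.
    """

    wells: pd.DataFrame
    plate_id: str = "plate1"
    control_genes: tuple[str, ...] = ("siCon",)

    REQUIRED = ("well", "gene", "sirna", "arm")

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate spec lacks columns: {missing}")
        if self.wells["well"].duplicated().any():
            raise ValueError("duplicate well ids")
        if self.wells["gene"].isna().any() or (self.wells["gene"] == "").any():
            raise ValueError("every well needs a gene assignment")
        bad_arm = ~self.wells["arm"].isin(["untreated", "treated"])
        if bad_arm.any():
            raise ValueError(f"unknown arms: {self.wells.loc[bad_arm, 'arm'].unique()}")
        for arm in self.wells["arm"].unique():
            genes = set(self.wells.loc[self.wells["arm"] == arm, "gene"])
            if not genes & set(self.control_genes):
                raise ValueError(f"no control wells in arm {arm!r}")

    @classmethod
    def grid(
        cls,
        genes: list[str],
        n_sirna: int = 3,
        arms: tuple[str, ...] = ("untreated", "treated"),
        control_genes: tuple[str, ...] = ("siCon",),
        plate_id: str = "plate1",
    ) -> "PlateSpec":
        """Regular layout: every gene x siRNA replicate x arm gets a well."""
        rows = []
        i = 0
        for arm in arms:
            for gene in list(genes) + list(control_genes):
                for s in range(1, n_sirna + 1):
                    rows.append(
                        {"well": f"{arm[:2]}{i:03d}", "gene": gene,
                         "sirna": s, "arm": arm}
                    )
                    i += 1
        plate = cls(pd.DataFrame(rows), plate_id=plate_id,
                    control_genes=control_genes)
        plate.validate()
        return plate

    @classmethod
    def from_json(cls, path) -> "PlateSpec":
        payload = json.loads(Path(path).read_text())
        plate = cls(
            wells=pd.DataFrame(payload["wells"]),
            plate_id=payload.get("plate_id", "plate1"),
            control_genes=tuple(payload.get("control_genes", ("siCon",))),
        )
        plate.validate()
        return plate

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PlateSpec":
        plate = cls(wells=pd.read_csv(path), **kwargs)
        plate.validate()
        return plate

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "plate_id": self.plate_id,
                    "control_genes": list(self.control_genes),
                    "wells": self.wells.to_dict(orient="records"),
                },
                indent=1,
            )
        )


def analyze_wells(
    plate: PlateSpec,
    staged: pd.DataFrame,
    min_cells: int = 200,
    marker: str = "gh2ax",
) -> pd.DataFrame:
    """Per-well single-cell summaries from staged records.

    For every well: cell count, S-phase (EdU-positive) marker mean, G1/S/G2
    fractions and EdU mean.  Wells missing from the data, with fewer than
    ``min_cells`` cells, or without any S-phase cells are flagged; flagged
    wells are excluded from gene scoring.
    """
    plate.validate()
    col = f"mean_{marker}"
    rows = []
    by_well = dict(iter(staged.groupby("well"))) if "well" in staged else {}
    for _, spec_row in plate.wells.iterrows():
        well = spec_row["well"]
        rec = {
            "well": well,
            "gene": spec_row["gene"],
            "sirna": spec_row["sirna"],
            "arm": spec_row["arm"],
        }
        sub = by_well.get(well)
        if sub is None or len(sub) == 0:
            rec.update({"n_cells": 0, "s_phase_marker_mean": np.nan,
                        "frac_G1": np.nan, "frac_S": np.nan, "frac_G2": np.nan,
                        "edu_mean": np.nan, "flag": "missing_well"})
            rows.append(rec)
            continue
        retained = sub[sub["stage"] != "excluded"]
        n = len(retained)
        s_cells = retained[gate_mask(retained, "S")]
        flags = []
        if n < min_cells:
            flags.append("low_cell_count")
        if len(s_cells) == 0:
            flags.append("no_s_phase_cells")
        denom = max(n, 1)
        rec.update(
            {
                "n_cells": n,
                "s_phase_marker_mean": s_cells[col].mean() if len(s_cells) else np.nan,
                "frac_G1": (retained["stage"] == "G1").sum() / denom,
                "frac_S": gate_mask(retained, "S").sum() / denom,
                "frac_G2": (retained["stage"] == "G2").sum() / denom,
                "edu_mean": retained["mean_edu"].mean()
                if "mean_edu" in retained else np.nan,
                "flag": ";".join(flags),
            }
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def score_genes(
    well_summaries: pd.DataFrame,
    plate: PlateSpec,
    arm: str = "treated",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Robust per-gene z-scores of the S-phase marker signal, ranked ascending.

    Gene value = unweighted mean of its (unflagged) siRNA wells' S-phase
    marker means; z = (value - median) / (1.4826 * MAD) over all gene values
    in the ``arm``.  Median/MAD rather than mean/s.d. so the hits themselves
    cannot inflate the scale.  Negative z = rescue, positive = sensitization.
    Ties in z rank alphabetically by gene.
    """
    sub = well_summaries[
        (well_summaries["arm"] == arm) & (well_summaries["flag"] == "")
    ]
    if not include_controls:
        sub = sub[~sub["gene"].isin(plate.control_genes)]
    if sub.empty:
        raise ValueError(f"no scoreable wells in arm {arm!r}")
    gene_values = (
        sub.groupby("gene")["s_phase_marker_mean"].agg(["mean", "count"])
        .rename(columns={"mean": "gene_value", "count": "n_wells"})
        .reset_index()
    )
    center = gene_values["gene_value"].median()
    scale = 1.4826 * np.median(np.abs(gene_values["gene_value"] - center))
    if scale <= 0:
        raise ValueError(
            "plate MAD is zero: gene values are degenerate, z-scores undefined"
        )
    gene_values["z"] = (gene_values["gene_value"] - center) / scale
    gene_values = gene_values.sort_values(
        ["z", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    gene_values["rank"] = np.arange(1, len(gene_values) + 1)
    return gene_values


def replicate_concordance(
    well_summaries: pd.DataFrame,
    arm: str = "treated",
    cv_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Coefficient of variation of each gene's siRNA replicate wells.

    Genes whose wells disagree beyond ``cv_cutoff`` are flagged discordant
    (kept in scoring — the flag is a QC annotation, off-target effects of
    individual siRNAs being the usual culprit).  Single-replicate genes are
    flagged not-assessable.
    """
    sub = well_summaries[
        (well_summaries["arm"] == arm) & (well_summaries["flag"] == "")
    ]
    rows = []
    for gene, grp in sub.groupby("gene"):
        vals = grp["s_phase_marker_mean"].to_numpy(dtype=float)
        if len(vals) < 2:
            rows.append({"gene": gene, "n_wells": len(vals), "cv": np.nan,
                         "flag": "not_assessable"})
            continue
        mean = vals.mean()
        cv = vals.std(ddof=1) / mean if mean > 0 else np.nan
        rows.append(
            {
                "gene": gene,
                "n_wells": len(vals),
                "cv": cv,
                "flag": "discordant" if (np.isfinite(cv) and cv > cv_cutoff) else "",
            }
        )
    return pd.DataFrame(rows)
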