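"""Plate normalization, robust Z-scoring, QC and hit calling.

Both screens (migration, eccentricity) run through the same machinery:
each plate/replicate is normalized against its negative-control wells
with robust location/scale (median and 1.4826*MAD), library-wide robust
Z-scores are computed per replicate and averaged, and hits are called
at strict Z cutoffs.  A viability filter removes miRs whose phenotype
is confounded by cell death or over-proliferation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import CONTROL_CONTENTS, LIBRARY, NEG_CTRL, ROWS_96

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates Gaussian sigma

DIRECTION_LOW = "low"
DIRECTION_HIGH = "high"


def _robust_location_scale(values: np.ndarray, what: str) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad == 0:
        raise ValueError(f"zero MAD in {what}: cannot normalize")
    return med, MAD_SCALE * mad


def normalize_plates(
    measurements: pd.DataFrame, layout: pd.DataFrame, scale_scope: str = "pooled"
) -> pd.DataFrame:
    """Normalize against negative controls, per plate and replicate.

    x' = (x - median(neg ctrl of the plate)) / (1.4826 * MAD of neg-ctrl
    residuals).  The location is always the plate's own negative-control
    median (that is what removes plate and batch offsets).  The robust
    scale is, by default (``scale_scope="pooled"``), the scaled MAD of
    negative-control residuals pooled across plates within a screen and
    replicate: a plate carries only a handful of negative controls, and
    a per-plate MAD over so few wells is noisy enough to visibly
    decorrelate replicates.  ``scale_scope="plate"`` uses each plate's
    own MAD.  Raises when a plate has fewer than two negative controls
    or when the scale reference has zero spread, naming the offender.
    """
    if scale_scope not in ("pooled", "plate"):
        raise ValueError("scale_scope must be 'pooled' or 'plate'")
    df = measurements.copy()
    if "content" not in df.columns:
        df = df.merge(layout[["plate", "well", "content", "mir_name"]], on=["plate", "well"])
    out = []
    for (screen, rep), rep_grp in df.groupby(["screen", "replicate"], sort=True):
        centered = []
        for plate, grp in rep_grp.groupby("plate", sort=True):
            neg = grp.loc[grp["content"] == NEG_CTRL, "value"].to_numpy()
            if len(neg) < 2:
                raise ValueError(f"plate {plate}: need >= 2 negative-control wells")
            med = float(np.median(neg))
            g = grp.copy()
            g["normalized"] = g["value"] - med
            if scale_scope == "plate":
                _, scale = _robust_location_scale(neg, f"negative controls of plate {plate}")
                g["normalized"] /= scale
            centered.append(g)
        rep_df = pd.concat(centered, ignore_index=True)
        if scale_scope == "pooled":
            resid = rep_df.loc[rep_df["content"] == NEG_CTRL, "normalized"].to_numpy()
            _, scale = _robust_location_scale(
                resid, f"pooled negative controls ({screen}, replicate {rep})"
            )
            rep_df["normalized"] /= scale
        out.append(rep_df)
    return pd.concat(out, ignore_index=True)


def zscore_and_average(normalized: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Robust Z against the library distribution, then replicate averaging.

    Per screen and replicate, Z = (x' - median(library x')) /
    (1.4826 * MAD(library x')), with the reference distribution built
    from library wells only (controls are scored against it but do not
    shape it).  Returns ``(scores, well_z)``: per-miR averaged scores
    and the per-well long table (controls included) used for QC.
    """
    lib = normalized[normalized["content"] == LIBRARY]
    if lib["mir_name"].nunique() < 2:
        raise ValueError("need >= 2 library wells to build a Z reference")
    out = []
    for (screen, rep), grp in normalized.groupby(["screen", "replicate"], sort=True):
        ref = grp.loc[grp["content"] == LIBRARY, "normalized"].to_numpy()
        med, scale = _robust_location_scale(ref, f"library wells ({screen}, rep {rep})")
        g = grp.copy()
        g["z"] = (g["normalized"] - med) / scale
        out.append(g)
    well_z = pd.concat(out, ignore_index=True)

    lib_z = well_z[well_z["content"] == LIBRARY]
    wide = lib_z.pivot_table(
        index=["screen", "mir_name"], columns="replicate", values="z", aggfunc="mean"
    )
    wide.columns = [f"z_rep{int(c)}" for c in wide.columns]
    scores = wide.reset_index()
    rep_cols = [c for c in scores.columns if c.startswith("z_rep")]
    scores["z_avg"] = scores[rep_cols].mean(axis=1)
    if len(rep_cols) == 1:
        scores["single_replicate"] = True
    return scores, well_z


@dataclass
class HitSet:
    """Library miRs whose averaged Z lies strictly beyond a cutoff."""

    screen: str
    direction: str  # low / high
    cutoff: float
    members: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


def call_hits(
    scores: pd.DataFrame,
    screen: str | None = None,
    cutoff_low: float = -1.0,
    cutoff_high: float = 1.0,
) -> tuple[HitSet, HitSet]:
    """Call low/high hit sets at strict Z cutoffs (boundary values excluded)."""
    df = scores if screen is None else scores[scores["screen"] == screen]
    if not np.isfinite(df["z_avg"]).all():
        raise ValueError("non-finite averaged Z values")
    label = screen if screen is not None else "all"
    low = HitSet(label, DIRECTION_LOW, cutoff_low, set(df.loc[df["z_avg"] < cutoff_low, "mir_name"]))
    high = HitSet(
        label, DIRECTION_HIGH, cutoff_high, set(df.loc[df["z_avg"] > cutoff_high, "mir_name"])
    )
    return low, high


def _edge_wells() -> set[str]:
    edges = set()
    for row in ROWS_96:
        for col in range(1, 13):
            if row in ("A", "H") or col in (1, 12):
                edges.add(f"{row}{col:02d}")
    return edges


EDGE_WELLS = _edge_wells()


@dataclass
class QCReport:
    replicate_correlations: dict[tuple[str, int, int], float]
    control_means: dict[tuple[str, str], float]
    edge_pvalues: dict[tuple[str, str], float]
    flags: list[str] = field(default_factory=list)


def qc_report(
    well_z: pd.DataFrame,
    r_threshold: float = 0.85,
    edge_alpha: float = 0.01,
) -> QCReport:
    """Screen quality control.

    Pairwise replicate Pearson correlation over library wells, mean
    averaged Z per control class, and a per-plate edge-effect test
    (two-sided Wilcoxon rank-sum of edge vs interior library wells).
    Flags are raised for r <= ``r_threshold`` or edge p < ``edge_alpha``;
    plates without enough edge/interior wells get no entry.
    """
    lib = well_z[well_z["content"] == LIBRARY]
    flags: list[str] = []
    correlations: dict[tuple[str, int, int], float] = {}
    for screen, grp in lib.groupby("screen"):
        wide = grp.pivot_table(index=["plate", "well"], columns="replicate", values="z")
        reps = sorted(wide.columns)
        for i, j in itertools.combinations(reps, 2):
            r = float(wide[i].corr(wide[j]))
            correlations[(screen, int(i), int(j))] = r
            if not r > r_threshold:
                flags.append(f"{screen}: replicate correlation r({i},{j})={r:.3f} <= {r_threshold}")

    control_means: dict[tuple[str, str], float] = {}
    ctrl = well_z[well_z["content"].isin(CONTROL_CONTENTS)]
    per_well = ctrl.groupby(["screen", "content", "plate", "well"])["z"].mean().reset_index()
    for (screen, content), grp in per_well.groupby(["screen", "content"]):
        control_means[(screen, content)] = float(grp["z"].mean())

    edge_pvalues: dict[tuple[str, str], float] = {}
    lib_avg = lib.groupby(["screen", "plate", "well"])["z"].mean().reset_index()
    for (screen, plate), grp in lib_avg.groupby(["screen", "plate"]):
        is_edge = grp["well"].isin(EDGE_WELLS)
        edge, interior = grp.loc[is_edge, "z"], grp.loc[~is_edge, "z"]
        if len(edge) < 4 or len(interior) < 4:
            continue
        p = float(stats.ranksums(edge, interior).pvalue)
        edge_pvalues[(screen, plate)] = p
        if p < edge_alpha:
            flags.append(f"{screen}: edge effect on plate {plate} (p={p:.2e})")
    return QCReport(correlations, control_means, edge_pvalues, flags)


def viability_filter(
    hitset: HitSet,
    viability: pd.DataFrame | Mapping[str, float],
    low: float = 0.8,
    high: float = 1.2,
) -> tuple[HitSet, list[str]]:
    """Keep hits with control-normalized viability strictly inside (low, high).

    Members absent from the viability table are dropped and returned in
    the second element so the caller can report them.
    """
    if isinstance(viability, pd.DataFrame):
        table = dict(zip(viability["mir_name"], viability["viability"]))
    else:
        table = dict(viability)
    missing = sorted(m for m in hitset.members if m not in table)
    kept = {m for m in hitset.members if m in table and low < table[m] < high}
    filtered = HitSet(hitset.screen, hitset.direction, hitset.cutoff, kept)
    return filtered, missing
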