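"""Synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
a 96-well mimic-library screen with plate offsets and planted control /
hit effects; scratch-assay and morphology images built from
non-overlapping ellipses; negative-binomial miR counts for a 3-vs-3
two-cell-line comparison; and an exponential proportional-hazards
cohort with median-split planted hazards.  Every generated entity is
recorded in a :class:`PlantedTruth` so parameter recovery can be
tested without any external data.

All operations are deterministic given their ``rng_seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .integrate_seed import MiRNARecord, RNA_ALPHABET, normalize_rna

# content labels used in plate layouts
LIBRARY = "library"
NEG_CTRL = "neg_ctrl"
POS_CTRL = "pos_ctrl"
MOCK = "mock"
SIPTK6 = "siPTK6"
MICON = "miCon"
EMPTY = "empty"
CONTROL_CONTENTS = (NEG_CTRL, POS_CTRL, MOCK, SIPTK6, MICON)

SCREEN_MIGRATION = "migration"
SCREEN_ECCENTRICITY = "eccentricity"
SCREENS = (SCREEN_MIGRATION, SCREEN_ECCENTRICITY)

ROWS_96 = "ABCDEFGH"
COLS_96 = tuple(range(1, 13))

# Default screen regime.  Controls anchor the dynamic range: the
# positive control (a miR-373-like mimic) strongly suppresses migration
# and rounds cells up; the library baseline sits below the negative
# controls because a migratory, mesenchymal line leaves more room for
# inhibition than promotion, which reproduces the observed control
# Z-score separation (negative controls near +1, positives below -1).
DEFAULT_GLOBAL_MEAN = 10.0
DEFAULT_SIGMA_PLATE = 0.5
DEFAULT_SIGMA_NOISE = 0.3
BASELINE_EFFECT_MEAN = {SCREEN_MIGRATION: -1.0, SCREEN_ECCENTRICITY: -0.7}
BASELINE_EFFECT_SD = 1.0
CONTROL_EFFECTS = {
    NEG_CTRL: {SCREEN_MIGRATION: 0.0, SCREEN_ECCENTRICITY: 0.0},
    MOCK: {SCREEN_MIGRATION: 0.0, SCREEN_ECCENTRICITY: 0.0},
    POS_CTRL: {SCREEN_MIGRATION: -3.2, SCREEN_ECCENTRICITY: -3.0},
    SIPTK6: {SCREEN_MIGRATION: -1.6, SCREEN_ECCENTRICITY: -1.6},
    MICON: {SCREEN_MIGRATION: -1.6, SCREEN_ECCENTRICITY: -1.6},
}
DEFAULT_VIABILITY_SD = 0.05


class EffectSize(NamedTuple):
    """Planted per-miR effect: screen shifts (robust-σ units) and viability multiplier."""

    migration: float
    eccentricity: float
    viability: float = 1.0


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic screen."""

    n_mirs: int = 1253
    wells_per_plate: int = 96
    n_replicates: int = 3
    seed_motif: str = "AAGUGC"
    n_motif_carriers: int = 40
    effect_sizes: dict[str, EffectSize] = field(default_factory=dict)
    rng_seed: int = 0
    sigma_plate: float = DEFAULT_SIGMA_PLATE
    sigma_noise: float = DEFAULT_SIGMA_NOISE
    global_mean: float = DEFAULT_GLOBAL_MEAN
    baseline_sd: float = BASELINE_EFFECT_SD
    baseline_means: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_EFFECT_MEAN)
    )

    def __post_init__(self) -> None:
        if self.n_mirs <= 0 or self.wells_per_plate <= 0 or self.n_replicates <= 0:
            raise ValueError("n_mirs, wells_per_plate and n_replicates must be positive")
        if self.n_motif_carriers < 0 or self.n_motif_carriers > self.n_mirs:
            raise ValueError("need 0 <= n_motif_carriers <= n_mirs")
        motif = self.seed_motif.upper()
        if len(motif) != 6 or set(motif) - RNA_ALPHABET:
            raise ValueError(f"seed_motif must be an RNA 6-mer, got {self.seed_motif!r}")
        for name, eff in self.effect_sizes.items():
            if eff.viability <= 0:
                raise ValueError(f"viability multiplier for {name} must be > 0")


@dataclass
class PlantedTruth:
    """Ground truth for every generated entity; filled per generator."""

    migration_effect: dict[str, float] = field(default_factory=dict)
    eccentricity_effect: dict[str, float] = field(default_factory=dict)
    viability: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    log_hazard: dict[str, float] = field(default_factory=dict)
    met_shift: dict[str, float] = field(default_factory=dict)
    control_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    motif_carriers: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def gen_library(
    n_mirs: int,
    n_motif_carriers: int,
    motif: str = "AAGUGC",
    motif_position: int | str = 2,
    length_range: tuple[int, int] = (20, 23),
    rng_seed: int = 0,
    fixed_records: Sequence[tuple[str, str]] = (),
) -> tuple[list[MiRNARecord], PlantedTruth]:
    """Generate a mimic library with a planted number of motif carriers.

    Exactly ``n_motif_carriers`` records contain ``motif`` starting at
    ``motif_position`` (1-based; 2, 3 or ``"random"``); the remaining
    records are rejection-sampled until motif-free.  ``fixed_records``
    are included verbatim (counting toward both totals when they carry
    the motif at the requested position).
    """
    motif = normalize_rna(motif)
    if len(motif) != 6:
        raise ValueError("motif must be a 6-mer")
    if n_motif_carriers > n_mirs:
        raise ValueError("n_motif_carriers > n_mirs")
    if motif_position not in (2, 3, "random"):
        raise ValueError("motif_position must be 2, 3 or 'random'")
    lo, hi = length_range
    if not (7 <= lo <= hi):
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(rng_seed)

    records: list[MiRNARecord] = []
    n_fixed_carriers = 0
    for name, seq in fixed_records:
        rec = MiRNARecord(name, seq)
        pos = 2 if motif_position == "random" else motif_position
        if rec.sequence[pos - 1 : pos - 1 + 6] == motif:
            n_fixed_carriers += 1
        records.append(rec)
    if n_fixed_carriers > n_motif_carriers:
        raise ValueError("fixed_records contain more carriers than n_motif_carriers")

    n_random = n_mirs - len(records)
    n_random_carriers = n_motif_carriers - n_fixed_carriers
    width = len(str(n_mirs))
    for i in range(n_random):
        name = f"syn-mir-{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        if i < n_random_carriers:
            pos = motif_position
            if pos == "random":
                pos = int(rng.integers(1, length - 6 + 2))
            seq = _random_rna(rng, length)
            seq = seq[: pos - 1] + motif + seq[pos - 1 + 6 :]
        else:
            seq = _random_rna(rng, length)
            while motif in seq:
                seq = _random_rna(rng, length)
        records.append(MiRNARecord(name, seq))

    carriers = [r.name for r in records if motif in r.sequence]
    truth = PlantedTruth(motif_carriers=carriers)
    return records, truth


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def _place_ellipses(
    canvas: np.ndarray,
    allowed: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
    eccentricity: float,
    major_range: tuple[float, float] = (8.0, 13.0),
    gap: float = 2.0,
    max_tries: int = 4000,
) -> int:
    """Draw up to ``n_cells`` non-overlapping filled ellipses where allowed.

    Non-overlap is enforced by bounding-circle rejection sampling with a
    capped number of retries, which keeps segmentation ground truth
    exact.  Returns the number of ellipses actually drawn.
    """
    from skimage import draw

    h, w = canvas.shape
    centers: list[tuple[float, float, float]] = []  # (r, c, radius)
    placed = 0
    tries = 0
    while placed < n_cells and tries < max_tries:
        tries += 1
        a = rng.uniform(*major_range)  # semi-major
        b = a * np.sqrt(1.0 - eccentricity**2)  # semi-minor
        theta = rng.uniform(0, np.pi)
        r0 = rng.uniform(a + 1, h - a - 1)
        c0 = rng.uniform(a + 1, w - a - 1)
        if not allowed[int(r0), int(c0)]:
            continue
        if any((r0 - rr) ** 2 + (c0 - cc) ** 2 < (a + rad + gap) ** 2 for rr, cc, rad in centers):
            continue
        rr, cc = draw.ellipse(r0, c0, b, a, shape=canvas.shape, rotation=theta)
        if not allowed[rr, cc].all():
            continue
        intensity = np.clip(rng.normal(200, 8, size=rr.size), 120, 255)
        canvas[rr, cc] = intensity.astype(np.uint8)
        centers.append((r0, c0, a))
        placed += 1
    return placed


def _confluent_field(
    canvas: np.ndarray,
    band: tuple[int, int] | None,
    rng: np.random.Generator,
    cell_half: tuple[float, float] = (10.0, 6.0),
) -> None:
    """Fill the canvas with a confluent monolayer of ellipse cells.

    Cells sit on a jittered rectangular grid (guaranteeing non-overlap
    and only small inter-cell gaps, as in a confluent epithelial sheet);
    any cell intersecting the cell-free band columns ``band`` is
    skipped.
    """
    from skimage import draw

    h, w = canvas.shape
    a0, b0 = cell_half  # semi-axes along column / row directions
    col_pitch = 2 * a0 + 2
    row_pitch = 2 * b0 + 2
    for i, r0 in enumerate(np.arange(-b0, h + b0, row_pitch)):
        col_offset = (i % 2) * col_pitch / 2  # brick stagger narrows diagonal gaps
        for c0 in np.arange(-a0 + col_offset, w + a0, col_pitch):
            a = a0 * rng.uniform(0.9, 1.0)
            b = b0 * rng.uniform(0.9, 1.0)
            rr, cc = draw.ellipse(r0, c0, b, a, shape=canvas.shape,
                                  rotation=rng.uniform(-0.15, 0.15))
            if band is not None:
                outside = (cc < band[0]) | (cc >= band[1])  # the scratch wipes cells
                rr, cc = rr[outside], cc[outside]
            if rr.size == 0:
                continue
            intensity = np.clip(rng.normal(200, 8, size=rr.size), 120, 255)
            canvas[rr, cc] = intensity.astype(np.uint8)


def gen_images(
    mode: str,
    effect: Mapping[str, float] | None = None,
    timepoints: Sequence[float] = (0.0,),
    image_size: tuple[int, int] = (400, 400),
    rng_seed: int = 0,
    n_cells: int = 120,
) -> list[np.ndarray]:
    """Generate grayscale well images.

    ``scratch`` mode draws a confluent field of ellipse cells with a
    central cell-free vertical band whose width shrinks linearly at the
    planted closure rate (``effect``: ``band_width`` px at t=0,
    ``closure_rate`` px/h); one image per timepoint.  ``morphology``
    mode draws non-overlapping ellipses whose eccentricity follows the
    planted value (``effect``: ``eccentricity``); one image per call
    regardless of timepoints.  Background pixels are 0, cell pixels
    exceed any sensible threshold.
    """
    effect = dict(effect or {})
    h, w = image_size
    rng = np.random.default_rng(rng_seed)
    if any(t < 0 for t in timepoints):
        raise ValueError("negative timepoint")

    if mode == "scratch":
        band_width = float(effect.get("band_width", w // 4))
        rate = float(effect.get("closure_rate", 0.0))
        if band_width >= w - 40:
            raise ValueError("image too small to host the scratch band")
        images = []
        for t in timepoints:
            wt = max(0.0, band_width - rate * t)
            img = np.zeros((h, w), dtype=np.uint8)
            lo = int(round(w / 2 - wt / 2))
            hi = int(round(w / 2 + wt / 2))
            _confluent_field(img, (lo, hi) if hi > lo else None, rng)
            images.append(img)
        return images

    if mode == "morphology":
        ecc = float(effect.get("eccentricity", 0.0))
        if not 0.0 <= ecc < 1.0:
            raise ValueError("eccentricity must be in [0, 1)")
        img = np.zeros((h, w), dtype=np.uint8)
        allowed = np.ones((h, w), dtype=bool)
        _place_ellipses(img, allowed, n_cells, rng, eccentricity=ecc)
        return [img]

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# plate layout and well-level data (image-free fast path)
# ---------------------------------------------------------------------------

def make_layout(mirs: Sequence[str] | int) -> pd.DataFrame:
    """96-well layouts: controls in columns 1 and 12, library in columns 2-11.

    ``mirs`` is a list of miR names (or a count, in which case
    ``syn-mir-k`` names are minted).  Library miRs fill wells in order;
    surplus wells on the last plate are marked empty.
    """
    if isinstance(mirs, int):
        width = len(str(mirs))
        mirs = [f"syn-mir-{i + 1:0{width}d}" for i in range(mirs)]
    mirs = list(mirs)
    col1 = [NEG_CTRL, NEG_CTRL, NEG_CTRL, MOCK, POS_CTRL, POS_CTRL, SIPTK6, MICON]
    col12 = [MICON, SIPTK6, POS_CTRL, POS_CTRL, NEG_CTRL, NEG_CTRL, NEG_CTRL, MOCK]
    lib_per_plate = 8 * 10
    n_plates = max(1, int(np.ceil(len(mirs) / lib_per_plate)))
    rows = []
    k = 0
    for p in range(1, n_plates + 1):
        plate = f"P{p:02d}"
        for ri, row in enumerate(ROWS_96):
            for col in COLS_96:
                well = f"{row}{col:02d}"
                if col == 1:
                    rows.append((plate, well, col1[ri], ""))
                elif col == 12:
                    rows.append((plate, well, col12[ri], ""))
                elif k < len(mirs):
                    rows.append((plate, well, LIBRARY, mirs[k]))
                    k += 1
                else:
                    rows.append((plate, well, EMPTY, ""))
    return pd.DataFrame(rows, columns=["plate", "well", "content", "mir_name"])


@dataclass
class ScreenData:
    layout: pd.DataFrame
    measurements: pd.DataFrame  # plate, well, replicate, screen, value
    viability: pd.DataFrame     # mir_name, viability
    truth: PlantedTruth


def gen_well_data(
    config: SyntheticConfig,
    layout: pd.DataFrame | None = None,
) -> ScreenData:
    """Generate per-well screen measurements plus a viability table.

    Raw value = plate offset + global mean + planted effect + Gaussian
    noise, per screen and replicate.  Library miRs draw a baseline
    effect from a Gaussian whose negative mean reflects the migratory,
    mesenchymal baseline of the assayed cells; entries in
    ``config.effect_sizes`` override the baseline (the planted
    miR-373-like effect is wired to the positive-control wells via
    ``CONTROL_EFFECTS``).  Viability is the planted multiplier plus
    noise, clipped positive.
    """
    rng = np.random.default_rng(config.rng_seed)
    if layout is None:
        layout = make_layout(config.n_mirs)
    layout = layout.copy()
    lib_names = layout.loc[layout["content"] == LIBRARY, "mir_name"].unique()

    truth = PlantedTruth()
    for _, r in layout.iterrows():
        if r["content"] != LIBRARY:
            truth.control_labels[(r["plate"], r["well"])] = r["content"]

    effects: dict[str, dict[str, float]] = {}
    for name in lib_names:
        eff = {
            screen: rng.normal(config.baseline_means[screen], config.baseline_sd)
            for screen in SCREENS
        }
        via = float(np.clip(rng.normal(1.0, DEFAULT_VIABILITY_SD), 0.05, None))
        planted = config.effect_sizes.get(name)
        if planted is not None:
            eff[SCREEN_MIGRATION] = planted.migration
            eff[SCREEN_ECCENTRICITY] = planted.eccentricity
            via = float(np.clip(planted.viability + rng.normal(0, DEFAULT_VIABILITY_SD), 0.05, None))
        effects[name] = eff
        truth.migration_effect[name] = eff[SCREEN_MIGRATION]
        truth.eccentricity_effect[name] = eff[SCREEN_ECCENTRICITY]
        truth.viability[name] = via

    plates = layout["plate"].unique()
    offsets = {
        (screen, plate, rep): rng.normal(0.0, config.sigma_plate)
        for screen in SCREENS
        for plate in plates
        for rep in range(1, config.n_replicates + 1)
    }

    recs = []
    for screen in SCREENS:
        for rep in range(1, config.n_replicates + 1):
            for (plate, well, cont, mir) in layout.itertuples(index=False):
                if cont == EMPTY:
                    continue
                if cont == LIBRARY:
                    eff = effects[mir][screen]
                else:
                    eff = CONTROL_EFFECTS[cont][screen]
                value = (
                    offsets[(screen, plate, rep)]
                    + config.global_mean
                    + eff
                    + rng.normal(0.0, config.sigma_noise)
                )
                recs.append((plate, well, rep, screen, cont, mir, value))
    measurements = pd.DataFrame(
        recs, columns=["plate", "well", "replicate", "screen", "content", "mir_name", "value"]
    )
    viability = pd.DataFrame(
        {"mir_name": list(lib_names), "viability": [truth.viability[n] for n in lib_names]}
    )
    return ScreenData(layout=layout, measurements=measurements, viability=viability, truth=truth)


# seven LDA shape features, in fixed order
FEATURE_COLUMNS = (
    "Area",
    "Compactness",
    "Eccentricity",
    "EulerNumber",
    "Extent",
    "FormFactor",
    "Solidity",
)


def gen_well_features(
    layout: pd.DataFrame,
    truth: PlantedTruth,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-well aggregated shape-feature vectors for the image-free path.

    The latent morphology of a well is its planted eccentricity-screen
    effect (0 = mesenchymal baseline, strongly negative = rounded,
    epithelial).  Shape features are smooth functions of that latent
    value plus noise, so wells with strong planted rounding effects are
    separable by the LDA stage exactly as wells of rounded cells would
    be from real images.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for (plate, well, cont, mir) in layout.itertuples(index=False):
        if cont == EMPTY:
            continue
        if cont == LIBRARY:
            m = truth.eccentricity_effect[mir]
        else:
            m = CONTROL_EFFECTS[cont][SCREEN_ECCENTRICITY]
        ecc = float(np.clip(0.80 + 0.06 * m + rng.normal(0, 0.01), 0.05, 0.98))
        form = float(np.clip(0.95 - 0.25 * ecc + rng.normal(0, 0.02), 0.2, 1.0))
        rows.append(
            (
                plate,
                well,
                cont,
                mir,
                rng.normal(600.0, 60.0),                       # Area
                1.0 / form,                                     # Compactness
                ecc,                                            # Eccentricity
                1.0 - rng.binomial(1, 0.03),                    # EulerNumber
                float(np.clip(0.785 * (1 - 0.15 * ecc) + rng.normal(0, 0.02), 0.2, 1.0)),
                form,                                           # FormFactor
                float(np.clip(0.97 - 0.05 * ecc + rng.normal(0, 0.01), 0.5, 1.0)),
            )
        )
    return pd.DataFrame(
        rows, columns=["plate", "well", "content", "mir_name", *FEATURE_COLUMNS]
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def gen_counts(
    mir_names: Sequence[str] | int,
    n_reps_per_group: int = 3,
    depth: float = 1e6,
    dispersion: float = 0.05,
    planted_lfc_map: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    depth_jitter: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Negative-binomial miR counts for an E-vs-M two-group design.

    Sample mean for miR i in sample j is ``depth_j * q_i * 2**(lfc_i)``
    for M-group samples and ``depth_j * q_i`` for E-group samples, with
    relative abundances ``q_i`` lognormal and normalized to one, and NB
    dispersion ``alpha`` (variance mu + alpha*mu^2).  ``depth_jitter``
    scales each sample's depth by a lognormal factor of that sd.
    """
    if depth <= 0 or dispersion <= 0:
        raise ValueError("depth and dispersion must be positive")
    rng = np.random.default_rng(rng_seed)
    if isinstance(mir_names, int):
        width = len(str(mir_names))
        mir_names = [f"syn-mir-{i + 1:0{width}d}" for i in range(mir_names)]
    mir_names = list(mir_names)
    lfc = np.array([float((planted_lfc_map or {}).get(n, 0.0)) for n in mir_names])

    q = rng.lognormal(mean=0.0, sigma=2.0, size=len(mir_names))
    q /= q.sum()
    samples = [f"E{i+1}" for i in range(n_reps_per_group)] + [
        f"M{i+1}" for i in range(n_reps_per_group)
    ]
    groups = pd.Series(["E"] * n_reps_per_group + ["M"] * n_reps_per_group, index=samples)
    depths = depth * (
        rng.lognormal(0.0, depth_jitter, size=len(samples)) if depth_jitter > 0 else np.ones(len(samples))
    )
    counts = np.empty((len(mir_names), len(samples)), dtype=np.int64)
    size = 1.0 / dispersion
    for j, s in enumerate(samples):
        mu = depths[j] * q * np.where(groups[s] == "M", 2.0**lfc, 1.0)
        p = size / (size + mu)
        counts[:, j] = rng.negative_binomial(size, p)
    df = pd.DataFrame(counts, index=pd.Index(mir_names, name="mir_name"), columns=samples)
    truth = PlantedTruth(log2fc=dict(zip(mir_names, lfc)))
    return df, groups, truth


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

def gen_cohort(
    n_primary: int = 99,
    n_met: int = 14,
    mir_names: Sequence[str] | int = 30,
    planted_loghr_map: Mapping[str, float] | None = None,
    baseline_rate: float = 0.015,
    censor_rate: float = 0.01,
    planted_met_shift_map: Mapping[str, float] | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Exponential proportional-hazards cohort with median-split hazards.

    Expression is Gaussian on the log2 scale per miR; metastatic samples
    receive the planted shift (negative = down in mets).  Event times
    are exponential with hazard ``baseline_rate * exp(sum_i loghr_i *
    I[x_i > median_i])``; censoring is independent exponential.  Time is
    in months.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    if n_primary + n_met < 20:
        raise ValueError("cohort too small: need n_primary + n_met >= 20")
    rng = np.random.default_rng(rng_seed)
    if isinstance(mir_names, int):
        width = len(str(mir_names))
        mir_names = [f"syn-mir-{i + 1:0{width}d}" for i in range(mir_names)]
    mir_names = list(mir_names)
    loghr = {n: float((planted_loghr_map or {}).get(n, 0.0)) for n in mir_names}
    shift = {n: float((planted_met_shift_map or {}).get(n, 0.0)) for n in mir_names}

    n = n_primary + n_met
    tissue = np.array(["primary"] * n_primary + ["metastasis"] * n_met)
    expr = {}
    for name in mir_names:
        base = rng.normal(8.0, 1.5, size=n)
        base[tissue == "metastasis"] += shift[name]
        expr[name] = base
    expr_df = pd.DataFrame(expr)

    log_relative = np.zeros(n)
    for name in mir_names:
        if loghr[name] != 0.0:
            x = expr_df[name].to_numpy()
            log_relative += loghr[name] * (x > np.median(x))
    hazard = baseline_rate * np.exp(log_relative)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    truth = PlantedTruth(log_hazard=loghr, met_shift=shift)
    if event.sum() == 0:
        truth.flags.append("degenerate: all samples censored")
        warnings.warn("generated cohort has no observed events", stacklevel=2)

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i+1:03d}" for i in range(n)],
            "type": tissue,
            "time_months": time,
            "event": event,
        }
    )
    cohort = pd.concat([cohort, expr_df], axis=1)
    return cohort, truth
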