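"""Synthetic H&E-like tiles and survival cohorts with planted morphology effects.

The generator renders elliptical, hematoxylin-stained cells on an eosin-like
pink background through a fixed optical-density mixing matrix, so stain
deconvolution can be validated against a known ground truth.  Cohorts attach
exponential event times whose hazard depends on a latent high/low-risk class;
the class in turn shifts chosen morphology parameters (the "effect map"), so
the full imaging-to-survival pipeline can be exercised without real slides.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

# Optical-density unit vectors for hematoxylin and eosin (columns), the fixed
# mixing matrix every synthetic tile is rendered through.  Hematoxylin carries
# the larger blue-channel OD, matching its blue-purple appearance.
HE_STAIN_MATRIX = np.array(
    [[0.650, 0.072],
     [0.704, 0.990],
     [0.286, 0.105]]
)
HE_STAIN_MATRIX = HE_STAIN_MATRIX / np.linalg.norm(HE_STAIN_MATRIX, axis=0)

TILE_SIZE = 512
IO_REFERENCE = 255.0

#: Area (px^2) and axis-ratio bounds defining the small-hyperchromatic class.
SHC_AREA_RANGE = (120.0, 420.0)
SHC_RATIO_RANGE = (1.0, 1.8)
SHC_HEMATOXYLIN = (1.35, 0.10)  # mean, sd of H concentration: dark staining
NORMAL_HEMATOXYLIN = (0.75, 0.08)
BACKGROUND_EOSIN = 0.22  # baseline eosin concentration of stroma


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide.

    ``area_mu``/``area_sigma`` parameterize a lognormal cell-area distribution
    (px^2; median area = exp(area_mu)).  ``cell_density`` is the Poisson mean
    number of cells per 512x512 tile.  ``shc_fraction`` is the fraction of
    cells drawn from the small-hyperchromatic class (small, round, dark).
    """

    slide_id: str
    n_tiles: int = 4
    cell_density: float = 90.0
    area_mu: float = float(np.log(600.0))
    area_sigma: float = 0.35
    ecc_mean: float = 1.6
    shc_fraction: float = 0.12
    background_fraction: float = 0.0
    touch_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shc_fraction", "background_fraction", "touch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")


@dataclass
class TilePatch:
    """One 512x512 RGB tile with grid coordinates and provenance."""

    pixels: np.ndarray  # (512, 512, 3) uint8
    slide_id: str
    grid_row: int
    grid_col: int
    source_mpp: float = 0.25

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")


@dataclass
class CellTruth:
    area: float
    major_axis: float
    minor_axis: float
    is_shc: bool


@dataclass
class GroundTruth:
    """Instance mask plus the true geometry of every drawn cell."""

    mask: np.ndarray  # int32, 0 = background, instances 1..n consecutive
    cells: list[CellTruth]


def _tile_rng(seed: int, slide_id: str, tile_index: int) -> np.random.Generator:
    """Deterministic RNG for one tile; stable across processes and runs."""
    sid = zlib.crc32(slide_id.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([seed, sid, tile_index]))


def render_concentrations(h_conc: np.ndarray, e_conc: np.ndarray,
                          stain_matrix: np.ndarray = HE_STAIN_MATRIX,
                          io: float = IO_REFERENCE) -> np.ndarray:
    """Render per-pixel stain concentrations to an RGB uint8 image.

    The Beer-Lambert forward model: OD = S @ c, I = io * 10**(-OD).
    """
    conc = np.stack([h_conc.ravel(), e_conc.ravel()])  # (2, N)
    od = stain_matrix @ conc  # (3, N)
    img = io * np.power(10.0, -od)
    img = img.T.reshape(h_conc.shape + (3,))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_tile(spec: SlideSpec, tile_index: int) -> tuple[TilePatch, GroundTruth]:
    """Render one tile and its pixel-aligned ground truth.

    Deterministic for a given (spec.seed, spec.slide_id, tile_index).  Cell
    placement uses rejection sampling with bounded retries: at pathological
    densities the tile simply holds fewer cells than the Poisson draw.
    """
    rng = _tile_rng(spec.seed, spec.slide_id, tile_index)
    n = TILE_SIZE
    grid_row, grid_col = divmod(tile_index, 8)

    if rng.uniform() < spec.background_fraction:
        # White or black background tile (slide edge / scanner artifact).
        shade = 245 if rng.uniform() < 0.8 else 12
        pixels = np.full((n, n, 3), shade, dtype=np.uint8)
        pixels = np.clip(
            pixels.astype(np.int16) + rng.integers(-4, 5, size=pixels.shape), 0, 255
        ).astype(np.uint8)
        patch = TilePatch(pixels, spec.slide_id, grid_row, grid_col)
        return patch, GroundTruth(np.zeros((n, n), dtype=np.int32), [])

    n_cells = int(rng.poisson(spec.cell_density))
    mask = np.zeros((n, n), dtype=np.int32)
    centers: list[tuple[float, float, float]] = []  # (r, c, radius)
    placed: list[tuple[float, float, float, float, float, bool]] = []

    for _ in range(n_cells):
        is_shc = rng.uniform() < spec.shc_fraction
        if is_shc:
            area = rng.uniform(*SHC_AREA_RANGE)
            ratio = rng.uniform(*SHC_RATIO_RANGE)
        else:
            area = float(rng.lognormal(spec.area_mu, spec.area_sigma))
            ratio = max(1.0, rng.normal(spec.ecc_mean, 0.25))
        b = np.sqrt(area / (np.pi * ratio))  # minor semi-axis
        a = b * ratio
        theta = rng.uniform(0.0, np.pi)
        allow_touch = rng.uniform() < spec.touch_rate
        gap = 0.65 if allow_touch else 1.05
        for _retry in range(40):
            cy = rng.uniform(a, n - a)
            cx = rng.uniform(a, n - a)
            ok = True
            for (py, px, pr) in centers:
                if np.hypot(cy - py, cx - px) < gap * (a + pr):
                    ok = False
                    break
            if ok:
                centers.append((cy, cx, a))
                placed.append((cy, cx, a, b, theta, is_shc))
                break

    cells: list[CellTruth] = []
    label = 0
    for (cy, cx, a, b, theta, is_shc) in placed:
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(n, n), rotation=theta)
        if rr.size == 0:
            continue
        label += 1
        mask[rr, cc] = label
        cells.append(CellTruth(area=np.pi * a * b, major_axis=2 * a,
                               minor_axis=2 * b, is_shc=is_shc))

    # Drop instances fully overwritten by a touching later neighbor.
    present = np.unique(mask)
    present = present[present > 0]
    if len(present) != label:
        remap = np.zeros(label + 1, dtype=np.int32)
        remap[present] = np.arange(1, len(present) + 1)
        mask = remap[mask]
        cells = [cells[i - 1] for i in present]

    # Stain-concentration maps: smooth eosin stroma, per-cell hematoxylin,
    # and a strongly eosinophilic cytoplasm rim around each cell.  The rim
    # anchors the eosin direction for stain estimation the way eosin-rich
    # cytoplasm does in real tissue.
    e_conc = BACKGROUND_EOSIN + 0.04 * rng.standard_normal((n, n))
    e_conc = np.clip(e_conc, 0.05, None)
    h_conc = np.clip(0.02 + 0.01 * rng.standard_normal((n, n)), 0.0, None)
    rim = np.zeros((n, n), dtype=bool)
    for (cy, cx, a, b, theta, _shc) in placed:
        rr, cc = draw_ellipse(cy, cx, a + 4.0, b + 4.0, shape=(n, n),
                              rotation=theta)
        rim[rr, cc] = True
    rim &= mask == 0
    e_conc[rim] = rng.uniform(1.5, 1.9, int(rim.sum()))
    h_conc[rim] = rng.uniform(0.10, 0.16, int(rim.sum()))
    for lab in range(1, len(cells) + 1):
        mu, sd = SHC_HEMATOXYLIN if cells[lab - 1].is_shc else NORMAL_HEMATOXYLIN
        level = max(0.15, rng.normal(mu, sd))
        sel = mask == lab
        h_conc[sel] = level + 0.03 * rng.standard_normal(int(sel.sum()))
        e_conc[sel] *= 0.35

    pixels = render_concentrations(h_conc, e_conc)
    patch = TilePatch(pixels, spec.slide_id, grid_row, grid_col)
    return patch, GroundTruth(mask, cells)


def generate_slide(spec: SlideSpec) -> list[tuple[TilePatch, GroundTruth]]:
    """All tiles of one slide, in tile-index order."""
    return [generate_tile(spec, i) for i in range(spec.n_tiles)]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

DAYS_PER_YEAR = 365.25


@dataclass
class CohortConfig:
    """Synthetic patient cohort with morphology-linked hazards.

    ``effect_map`` maps SlideSpec field names to ``(low_value, high_value)``
    pairs applied according to the patient's latent risk class.  Event times
    are exponential with rate ``baseline_hazard`` (times ``hazard_ratio`` for
    the high-risk class); censoring is Uniform(0, censor_window) years.
    """

    n_patients: int = 40
    slides_per_patient: int | tuple[int, int] = 1
    baseline_hazard: float = 0.10
    hazard_ratio: float = 3.0
    censor_window: float = 12.0
    met_baseline_hazard: float | None = None
    met_hazard_ratio: float | None = None
    effect_map: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    high_risk_fraction: float = 0.5
    stage_iii_prob: tuple[float, float] = (0.2, 0.2)
    horizon_years: float = 5.0
    n_tiles: int = 4
    cell_density: float = 90.0
    background_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.censor_window <= 0:
            raise ValueError("censor_window must be > 0")
        valid = set(SlideSpec("x").__dict__)
        unknown = set(self.effect_map) - valid
        if unknown:
            raise ValueError(f"effect_map refers to unknown SlideSpec fields: {unknown}")


@dataclass
class Cohort:
    """Clinical table plus per-slide specs; tile images render on demand."""

    clinical: pd.DataFrame
    slide_specs: dict[str, SlideSpec]
    config: CohortConfig

    def slides_of(self, patient_id: str) -> list[str]:
        row = self.clinical.loc[self.clinical.patient_id == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        return row.iloc[0].slide_ids.split(";")

    def iter_tiles(self, slide_id: str) -> Iterator[tuple[TilePatch, GroundTruth]]:
        spec = self.slide_specs[slide_id]
        for i in range(spec.n_tiles):
            yield generate_tile(spec, i)


def _event_and_censor(rng: np.random.Generator, rate: float,
                      censor_window: float) -> tuple[float, int]:
    t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
    t_cens = rng.uniform(0.0, censor_window)
    if t_event <= t_cens:
        return float(t_event), 1
    return float(t_cens), 0


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw latent classes, clinical outcomes and per-slide morphology specs."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0C0]))
    met_base = (config.met_baseline_hazard
                if config.met_baseline_hazard is not None else config.baseline_hazard)
    met_hr = (config.met_hazard_ratio
              if config.met_hazard_ratio is not None else config.hazard_ratio)

    rows = []
    slide_specs: dict[str, SlideSpec] = {}
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        high = int(rng.uniform() < config.high_risk_fraction)

        rate = config.baseline_hazard * (config.hazard_ratio if high else 1.0)
        surv_t, surv_e = _event_and_censor(rng, rate, config.censor_window)
        met_rate = met_base * (met_hr if high else 1.0)
        met_t, met_e = _event_and_censor(rng, met_rate, config.censor_window)

        p3 = config.stage_iii_prob[high]
        u = rng.uniform()
        stage = "III" if u < p3 else ("II" if u < p3 + (1 - p3) / 2 else "I")

        if isinstance(config.slides_per_patient, int):
            n_slides = config.slides_per_patient
        else:
            lo, hi = config.slides_per_patient
            n_slides = int(rng.integers(lo, hi + 1))
        sids = []
        for s in range(n_slides):
            sid = f"{pid}_S{s}"
            kwargs = dict(
                n_tiles=config.n_tiles,
                cell_density=config.cell_density,
                background_fraction=config.background_fraction,
            )
            for name, (lo_v, hi_v) in config.effect_map.items():
                kwargs[name] = hi_v if high else lo_v
            slide_specs[sid] = SlideSpec(
                slide_id=sid, seed=config.seed, **kwargs
            )
            sids.append(sid)

        rows.append(dict(
            patient_id=pid,
            slide_ids=";".join(sids),
            stage=stage,
            surv_time_days=surv_t * DAYS_PER_YEAR,
            death_event=surv_e,
            met_time_days=met_t * DAYS_PER_YEAR,
            met_event=met_e,
            latent_class=("high" if high else "low"),
        ))

    clinical = pd.DataFrame(rows)
    return Cohort(clinical=clinical, slide_specs=slide_specs, config=config)


def simulate_feature_cohort(
    n_patients: int,
    n_noise: int = 10,
    hazard_ratio: float = 3.0,
    baseline_hazard: float = 0.10,
    censor_window: float | None = 12.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Tabular cohort: one planted prognostic feature among standard-normal noise.

    The planted column ``planted`` is a standardized score whose unit increase
    multiplies the hazard by ``hazard_ratio``.  Returns (X, time_years, event).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_patients)
    X = pd.DataFrame(
        rng.standard_normal((n_patients, n_noise)),
        columns=[f"noise_{j:02d}" for j in range(n_noise)],
    )
    X.insert(0, "planted", z)
    rate = baseline_hazard * np.power(hazard_ratio, z)
    t_event = rng.exponential(1.0 / rate)
    if censor_window is None:
        return X, t_event, np.ones(n_patients, dtype=int)
    t_cens = rng.uniform(0.0, censor_window, size=n_patients)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return X, time, event


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the clinical CSV, config JSON and all tiles/masks as PNG."""
    from pathlib import Path
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical.drop(columns=["latent_class"]).to_csv(
        out / "clinical.csv", index=False
    )
    cfg = asdict(cohort.config)
    cfg["effect_map"] = {k: list(v) for k, v in cohort.config.effect_map.items()}
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    for sid, spec in cohort.slide_specs.items():
        for i in range(spec.n_tiles):
            patch, truth = generate_tile(spec, i)
            stem = f"{sid}_r{patch.grid_row}_c{patch.grid_col}"
            Image.fromarray(patch.pixels).save(out / f"{stem}.png")
            Image.fromarray(truth.mask.astype(np.uint16)).save(
                out / f"{stem}_mask.png"
            )
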