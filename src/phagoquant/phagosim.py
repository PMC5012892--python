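"""Seeded stochastic simulator of plate-based pHrodo phagocytosis assays.

The simulator is a test harness, not a biological model: it produces
time-lapse image stacks with event-level ground truth so that every
stage of the analysis pipeline can be validated exactly.  The uptake
mechanism is the simplest one reproducing the qualitative behaviour of
the real assay:

* each adherent cell accrues engulfment events as a homogeneous Poisson
  process with rate ``rate_modifier * base_rate * conc / (conc + K)``
  (Michaelis-type saturation in the bioparticle concentration), capped
  at ``max_events_per_cell``;
* an engulfed particle only becomes fluorescent after an exponential
  acidification lag — the pH-switch property of pHrodo dyes, which emit
  only in the acidic phagolysosome;
* a visible event is rendered as an isotropic Gaussian spot on top of a
  smooth quadratic background vignette plus Gaussian sensor noise; the
  phase channel renders static textured cell footprints.

Identical seeds give bit-identical output.  Per-well random streams are
derived by stable hashing of the well id, so adding wells to a plate
never perturbs existing wells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phagoquant.plate_model import (
    Channel,
    Frame,
    PlateLayout,
    WellRole,
    write_frame,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PackingError",
    "simulate_well",
    "simulate_plate",
    "well_separated_well",
    "clumped_pair_frame",
]

TRUTH_COLUMNS = [
    "well", "image", "cell_id", "event_time_min", "onset_time_min",
    "row_px", "col_px", "amplitude",
]


class PackingError(RuntimeError):
    """Cells could not be placed at the requested density."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated well.

    Defaults emulate a typical run of the assay being modelled: a field
    of view at 2 um/px, a few tens of adherent macrophages, a 200 ug/ml
    bioparticle meal near the half-saturating dose, imaging every 10 min
    for 1 h, and spots bright enough (amplitude 10 corrected units vs a
    detection threshold of 2) and large enough (sigma 3 px) to survive
    the default 50 um^2 area filter.
    """

    field_px: tuple[int, int] = (192, 192)
    pixel_size_um: float = 2.0
    n_cells: int = 40
    cell_radius_um: float = 12.0
    particle_conc: float = 200.0
    base_rate_per_cell_per_min: float = 0.05
    half_sat_conc: float = 100.0
    max_events_per_cell: int = 30
    rate_modifier: float = 1.0
    acid_lag_mean_min: float = 15.0
    spot_sigma_px: float = 3.0
    spot_amplitude: float = 10.0
    background_amplitude: float = 5.0
    noise_sd: float = 0.3
    frame_interval_min: float = 10.0
    duration_min: float = 60.0
    seed: int = 0
    images_per_well: int = 2
    frame_times_min: tuple[float, ...] | None = None
    decay_halflife_min: float | None = None
    phase_background: float = 100.0
    phase_texture_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.cell_radius_um <= 0:
            raise ValueError("pixel_size_um and cell_radius_um must be positive")
        if min(self.field_px) < 1:
            raise ValueError("field_px must be a positive shape")
        for name in (
            "n_cells", "particle_conc", "base_rate_per_cell_per_min",
            "acid_lag_mean_min", "spot_amplitude", "background_amplitude",
            "noise_sd", "spot_sigma_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.half_sat_conc <= 0:
            raise ValueError("half_sat_conc must be positive")
        if self.rate_modifier < 0:
            raise ValueError("rate_modifier must be >= 0")
        if self.max_events_per_cell < 1 or self.images_per_well < 1:
            raise ValueError("max_events_per_cell and images_per_well must be >= 1")
        if self.frame_interval_min <= 0 or self.duration_min <= 0:
            raise ValueError("frame_interval_min and duration_min must be positive")

    @property
    def event_rate_per_min(self) -> float:
        """Effective per-cell engulfment rate lambda (events/cell/min)."""
        c = self.particle_conc
        return (
            self.rate_modifier
            * self.base_rate_per_cell_per_min
            * (c / (c + self.half_sat_conc))
        )

    @property
    def frame_times(self) -> np.ndarray:
        if self.frame_times_min is not None:
            return np.asarray(self.frame_times_min, dtype=float)
        n = int(np.floor(self.duration_min / self.frame_interval_min + 1e-9))
        return np.arange(n + 1) * self.frame_interval_min

    def replace(self, **changes) -> "SimConfig":
        return replace(self, **changes)


@dataclass
class GroundTruth:
    """Event log of one simulated well image.

    ``events`` has one row per engulfment (cell id, event and
    fluorescence-onset times, spot position and amplitude); ``cells``
    records the placed cell centres and radius.  Onset never precedes
    engulfment, and the visible-event list is monotone non-decreasing
    over frames (no photobleaching by default).
    """

    events: pd.DataFrame
    cells: pd.DataFrame
    config: SimConfig
    well_id: str = "A01"
    image_index: int = 1

    def visible_events(self, time_min: float) -> pd.DataFrame:
        return self.events[self.events["onset_time_min"] <= time_min]

    def visible_count(self, time_min: float) -> int:
        return int((self.events["onset_time_min"] <= time_min).sum())

    def cell_mask(self) -> np.ndarray:
        shape = self.config.field_px
        r_px = self.config.cell_radius_um / self.config.pixel_size_um
        mask = np.zeros(shape, dtype=bool)
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        for _, cell in self.cells.iterrows():
            mask |= (rr - cell.row_px) ** 2 + (cc - cell.col_px) ** 2 <= r_px**2
        return mask

    def to_frame(self) -> pd.DataFrame:
        df = self.events.copy()
        df.insert(0, "well", self.well_id)
        df.insert(1, "image", self.image_index)
        return df[TRUTH_COLUMNS]


def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform cell centres with minimum separation of one cell radius."""
    rows, cols = cfg.field_px
    r_px = cfg.cell_radius_um / cfg.pixel_size_um
    centres: list[tuple[float, float]] = []
    for _ in range(cfg.n_cells):
        for _attempt in range(1000):
            cand = (rng.uniform(0, rows), rng.uniform(0, cols))
            if all(
                (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= r_px**2
                for c in centres
            ):
                centres.append(cand)
                break
        else:
            raise PackingError(
                f"could not place cell {len(centres) + 1}/{cfg.n_cells} "
                f"within 1000 attempts (field {rows}x{cols}px, radius {r_px:.1f}px)"
            )
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(centres)),
            "row_px": [c[0] for c in centres],
            "col_px": [c[1] for c in centres],
            "radius_px": r_px,
        }
    )


def _draw_events(cfg: SimConfig, cells: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    lam = cfg.event_rate_per_min
    rows: dict[str, list] = {k: [] for k in (
        "cell_id", "event_time_min", "onset_time_min", "row_px", "col_px", "amplitude"
    )}
    r_px = cfg.cell_radius_um / cfg.pixel_size_um
    field = cfg.field_px
    for _, cell in cells.iterrows():
        n = int(rng.poisson(lam * cfg.duration_min))
        n = min(n, cfg.max_events_per_cell)
        times = np.sort(rng.uniform(0, cfg.duration_min, size=n))
        lags = rng.exponential(cfg.acid_lag_mean_min, size=n)
        # uniform position inside the cell footprint, clipped to the field
        radii = r_px * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        er = np.clip(cell.row_px + radii * np.sin(theta), 0, field[0] - 1)
        ec = np.clip(cell.col_px + radii * np.cos(theta), 0, field[1] - 1)
        rows["cell_id"].extend([int(cell.cell_id)] * n)
        rows["event_time_min"].extend(times)
        rows["onset_time_min"].extend(times + lags)
        rows["row_px"].extend(er)
        rows["col_px"].extend(ec)
        rows["amplitude"].extend([cfg.spot_amplitude] * n)
    return pd.DataFrame(rows)


def _background(cfg: SimConfig) -> np.ndarray:
    """Smooth quadratic vignette scaled to ``background_amplitude``."""
    rows, cols = cfg.field_px
    u = np.linspace(-1, 1, rows)[:, None]
    v = np.linspace(-1, 1, cols)[None, :]
    return cfg.background_amplitude * (0.4 + 0.6 * (1 - (u**2 + v**2) / 2))


def _add_spot(
    img: np.ndarray, row: float, col: float, amplitude: float, sigma: float
) -> None:
    """Add an isotropic Gaussian spot in place (local window, +-4 sigma)."""
    half = max(1, int(np.ceil(4 * sigma)))
    r0 = max(0, int(np.floor(row)) - half)
    r1 = min(img.shape[0], int(np.ceil(row)) + half + 1)
    c0 = max(0, int(np.floor(col)) - half)
    c1 = min(img.shape[1], int(np.ceil(col)) + half + 1)
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _render_green(
    cfg: SimConfig, truth: GroundTruth, time_min: float, rng: np.random.Generator
) -> np.ndarray:
    img = _background(cfg).copy()
    for _, ev in truth.visible_events(time_min).iterrows():
        amp = ev.amplitude
        if cfg.decay_halflife_min is not None:
            amp *= 0.5 ** ((time_min - ev.onset_time_min) / cfg.decay_halflife_min)
        _add_spot(img, ev.row_px, ev.col_px, amp, cfg.spot_sigma_px)
    if cfg.noise_sd > 0:
        img += rng.normal(0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0, None)


def _phase_texture(cfg: SimConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Static speckle texture confined to cell footprints."""
    from scipy.ndimage import gaussian_filter

    speckle = gaussian_filter(rng.normal(0, cfg.phase_texture_sd, size=cfg.field_px), 1.0)
    tex = np.zeros(cfg.field_px)
    tex[mask] = speckle[mask]
    return tex


def simulate_well(
    config: SimConfig, well_id: str = "A01", image_index: int = 1
) -> tuple[list[Frame], list[Frame], GroundTruth]:
    """Simulate one well image stack.

    Returns the green-channel frames, the phase-contrast frames and the
    ground-truth event log.  The config seed fully determines the output.
    """
    rng = np.random.default_rng(config.seed)
    cells = _place_cells(config, rng)
    events = _draw_events(config, cells, rng)
    truth = GroundTruth(events, cells, config, well_id, image_index)

    mask = truth.cell_mask() if config.n_cells else np.zeros(config.field_px, dtype=bool)
    texture = _phase_texture(config, mask, rng)

    green: list[Frame] = []
    phase: list[Frame] = []
    for t in config.frame_times:
        g = _render_green(config, truth, t, rng)
        p = config.phase_background + texture
        if config.noise_sd > 0:
            p = p + rng.normal(0, config.noise_sd, size=config.field_px)
        p = np.clip(p, 0, None)
        green.append(
            Frame(g, Channel.GREEN, float(t), well_id, image_index, config.pixel_size_um)
        )
        phase.append(
            Frame(p, Channel.PHASE, float(t), well_id, image_index, config.pixel_size_um)
        )
    return green, phase, truth


def derive_seed(root_seed: int, *tokens: str | int) -> int:
    """Stable sub-seed below 2**31 from a root seed and hashable tokens."""
    entropy = [int(root_seed) & 0x7FFFFFFF]
    for tok in tokens:
        if isinstance(tok, str):
            entropy.append(zlib.crc32(tok.encode()))
        else:
            entropy.append(int(tok))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def simulate_plate(
    layout: PlateLayout,
    configs: Mapping[str, SimConfig],
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[tuple[str, int], tuple[list[Frame], list[Frame], GroundTruth]]:
    """Simulate every well of a plate layout.

    ``configs`` maps each treatment label to its :class:`SimConfig`;
    vehicle wells must use ``rate_modifier`` 1 and blank wells are
    rendered with zero cells regardless of their condition's config.
    Per-image seeds are derived by stable hashing of the well id and
    image index from ``seed`` (default: the condition config's seed), so
    adding wells never perturbs existing ones.

    With ``out_dir`` set, frames are written as TIFFs under the standard
    naming convention together with ``layout.csv`` and ``truth.csv``, so
    the analysis pipeline consumes simulator output with no special
    casing.
    """
    results: dict[tuple[str, int], tuple[list[Frame], list[Frame], GroundTruth]] = {}
    truth_tables: list[pd.DataFrame] = []
    for well in layout.wells:
        cfg = configs.get(well.treatment)
        if cfg is None:
            raise KeyError(
                f"no SimConfig for condition {well.treatment!r} (well {well.well_id})"
            )
        if well.role is WellRole.VEHICLE and cfg.rate_modifier != 1.0:
            raise ValueError(
                f"vehicle well {well.well_id} must use rate_modifier 1, "
                f"got {cfg.rate_modifier}"
            )
        if well.role is WellRole.BLANK:
            cfg = cfg.replace(n_cells=0)
        root = seed if seed is not None else cfg.seed
        for img in range(1, cfg.images_per_well + 1):
            sub = cfg.replace(seed=derive_seed(root, well.well_id, img))
            green, phase, truth = simulate_well(sub, well.well_id, img)
            results[(well.well_id, img)] = (green, phase, truth)
            truth_tables.append(truth.to_frame())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for green, phase, _truth in results.values():
            for fr in (*green, *phase):
                write_frame(fr, out_dir)
        layout.to_frame().to_csv(out_dir / "layout.csv", index=False, lineterminator="\n")
        truth_all = (
            pd.concat(truth_tables, ignore_index=True)
            if truth_tables
            else pd.DataFrame(columns=TRUTH_COLUMNS)
        )
        truth_all.to_csv(
            out_dir / "truth.csv", index=False, lineterminator="\n", float_format="%.10g"
        )
    return results


def well_separated_well(
    seed: int,
    min_separation_px: float | None = None,
    border_margin_px: float = 12.0,
    max_attempts: int = 200,
    **overrides,
) -> tuple[list[Frame], list[Frame], GroundTruth]:
    """Simulate a sparse well whose visible spots are pairwise isolated.

    Validation scenario for exact object-count recovery: a low-density
    well is simulated; if any two spots visible in the final frame are
    closer than ``min_separation_px`` (default four spot sigmas), or any
    spot sits within ``border_margin_px`` of the field edge, the well is
    re-simulated from the next derived seed.  Deterministic given
    ``seed``.
    """
    base = SimConfig(
        n_cells=8,
        max_events_per_cell=1,
        cell_radius_um=20.0,
        acid_lag_mean_min=10.0,
        seed=0,
    ).replace(**overrides)
    sep = 4 * base.spot_sigma_px if min_separation_px is None else min_separation_px
    t_end = float(base.frame_times[-1])
    for attempt in range(max_attempts):
        cfg = base.replace(seed=derive_seed(seed, "sparse", attempt))
        try:
            green, phase, truth = simulate_well(cfg)
        except PackingError:
            continue
        vis = truth.visible_events(t_end)
        pos = vis[["row_px", "col_px"]].to_numpy()
        if len(pos) == 0:
            continue
        rows, cols = cfg.field_px
        if (
            (pos[:, 0] < border_margin_px).any()
            or (pos[:, 0] > rows - 1 - border_margin_px).any()
            or (pos[:, 1] < border_margin_px).any()
            or (pos[:, 1] > cols - 1 - border_margin_px).any()
        ):
            continue
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= sep:
            return green, phase, truth
    raise RuntimeError(f"no well-separated configuration found in {max_attempts} attempts")


def clumped_pair_frame(
    seed: int,
    separation_px: float = 8.0,
    sigma_px: float = 3.0,
    amplitude: float = 10.0,
    field_px: tuple[int, int] = (64, 64),
    pixel_size_um: float = 2.0,
    noise_sd: float = 0.2,
    background_amplitude: float = 3.0,
) -> tuple[Frame, np.ndarray]:
    """One frame with exactly two touching Gaussian blobs.

    The pair is placed at a random position and orientation near the
    field centre; the two spots merge into a single thresholded region,
    which is the declumping scenario the edge-split stage must resolve.
    Returns the frame and the two generating centres (row, col).
    """
    rng = np.random.default_rng(seed)
    rows, cols = field_px
    cfg = SimConfig(
        field_px=field_px,
        pixel_size_um=pixel_size_um,
        background_amplitude=background_amplitude,
        noise_sd=noise_sd,
    )
    img = _background(cfg).copy()
    margin = 6 * sigma_px
    centre = np.array(
        [
            rng.uniform(margin, rows - 1 - margin),
            rng.uniform(margin, cols - 1 - margin),
        ]
    )
    theta = rng.uniform(0, np.pi)
    offset = 0.5 * separation_px * np.array([np.sin(theta), np.cos(theta)])
    centres = np.stack([centre - offset, centre + offset])
    for r, c in centres:
        _add_spot(img, r, c, amplitude, sigma_px)
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, size=img.shape)
    frame = Frame(
        np.clip(img, 0, None), Channel.GREEN, 0.0, "A01", 1, pixel_size_um
    )
    return frame, centres
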