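"""Synthetic gas-challenge protocols, capillary populations and kymographs.

The study's intravital recordings are not deposited, so this module stands
in for them: it defines the nine timed gas-challenge regimes, draws
heterogeneous capillary populations whose per-second hemodynamics follow
delayed-exponential response kinetics around realistic baseline
distributions, and (optionally) renders the corresponding dual-wavelength
space-time images through a simple forward optical model.  Everything is
reproducible under a fixed root seed (per-capillary child streams).

Time convention: the 1 Hz grid runs t = 1..180 s for single-gas challenges
(1-min baseline, 2-min step) and t = 1..240 s for the combined challenge;
the step change lands at t = 60 s (and 120 s for the second combined step),
so fitted onset delays are referenced to the same clock as the published
fit windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import params as _params
from .kinetics import BiExpParams, MonoExpParams, eval_bi, eval_mono
from .sti_analysis import SO2Calibration, SpaceTimeImage, derive_hematocrit, derive_supply_rate

__all__ = [
    "GasChallengeProtocol",
    "PopulationSpec",
    "OpticsConfig",
    "GroundTruthSeries",
    "make_protocol",
    "simulate_population",
    "render_sti",
    "population_to_frame",
    "write_population",
    "read_population",
]

#: Physical bounds used for baseline truncation and post-noise clipping.
MEASURE_BOUNDS = {
    "velocity": (0.0, None),
    "lineal_density": (0.0, None),
    "so2": (0.0, 100.0),
}


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GasChallengeProtocol:
    """Timed gas-fraction segments defining a challenge (balance gas N2)."""

    name: str
    segments: tuple  # of (duration s, o2 %, co2 %)

    def __post_init__(self):
        segs = tuple((float(d), float(o), float(c)) for d, o, c in self.segments)
        object.__setattr__(self, "segments", segs)
        for d, o, c in segs:
            if d <= 0:
                raise ValueError("segment durations must be positive")
            if not (0 <= o <= 100 and 0 <= c <= 100 and o + c <= 100):
                raise ValueError(f"gas fractions out of range: O2={o}, CO2={c}")

    @property
    def duration(self) -> float:
        return sum(d for d, _, _ in self.segments)

    def gas_at(self, t: float) -> tuple[float, float]:
        """(O2 %, CO2 %) at time t (s); segments are left-closed."""
        acc = 0.0
        for d, o, c in self.segments:
            acc += d
            if t <= acc:
                return o, c
        return self.segments[-1][1], self.segments[-1][2]

    def to_dict(self) -> dict:
        return {"name": self.name,
                "segments": [list(s) for s in self.segments]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GasChallengeProtocol":
        return cls(d["name"], tuple(tuple(s) for s in d["segments"]))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GasChallengeProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_protocol(name, segments: Sequence | None = None) -> GasChallengeProtocol:
    """Build one of the nine reference challenge regimes, or a custom one.

    Reference names: O2_{7to12,12to7,7to2,2to7}, CO2_{5to0,0to5,5to10,10to5}
    and ``combined``.  With ``segments`` given, builds a user protocol under
    that name instead (validated against the gas-fraction invariants).
    """
    if segments is not None:
        return GasChallengeProtocol(name, tuple(tuple(s) for s in segments))
    try:
        segs = _params.PROTOCOL_SEGMENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; known: {sorted(_params.PROTOCOL_SEGMENTS)}"
        ) from None
    return GasChallengeProtocol(name, tuple(tuple(s) for s in segs))


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Population heterogeneity and noise for a simulated challenge.

    ``baseline`` maps the three simulated measures (velocity, lineal_density,
    so2) to (mean, SD) of the per-capillary baseline, truncated at physical
    bounds.  ``amplitude_sd`` is the per-capillary SD of the response
    amplitude (absolute units of the measure; the population-mean amplitude
    lives in the kinetic template).  ``noise_sd`` is the per-second
    observation noise.  Hematocrit and supply rate are derived, not drawn.
    """

    n_capillaries: int = 300
    baseline: dict = field(default_factory=lambda: {
        m: _params.BASELINES["O2_7to2"][m]
        for m in ("velocity", "lineal_density", "so2")})
    amplitude_sd: dict = field(default_factory=lambda: {
        "velocity": 0.0, "lineal_density": 0.0, "so2": 0.0})
    noise_sd: dict = field(default_factory=lambda: {
        "velocity": 0.0, "lineal_density": 0.0, "so2": 0.0})
    rbc_volume: float = 55.0
    capillary_diameter: float = 5.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_capillaries < 1:
            raise ValueError("n_capillaries must be >= 1")
        for m, (mu, sd) in self.baseline.items():
            if sd < 0:
                raise ValueError(f"baseline SD for {m} must be >= 0")
        for d in (self.amplitude_sd, self.noise_sd):
            for m, sd in d.items():
                if sd < 0:
                    raise ValueError(f"SD for {m} must be >= 0")
        if self.rbc_volume <= 0 or self.capillary_diameter <= 0:
            raise ValueError("rbc_volume and capillary_diameter must be positive")

    @classmethod
    def for_challenge(cls, challenge: str, **kw) -> "PopulationSpec":
        """Baselines from the challenge's published reference-window table."""
        base = {m: _params.BASELINES[challenge][m]
                for m in ("velocity", "lineal_density", "so2")}
        return cls(baseline=base, **kw)


@dataclass
class GroundTruthSeries:
    """Per-second hemodynamics of one simulated capillary with provenance."""

    capillary_id: int
    t: np.ndarray
    velocity: np.ndarray
    lineal_density: np.ndarray
    so2: np.ndarray
    hematocrit: np.ndarray
    supply_rate: np.ndarray
    kinetics: dict  # measure -> generating MonoExpParams/BiExpParams
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "capillary_id": self.capillary_id, "t": self.t,
            "velocity": self.velocity, "lineal_density": self.lineal_density,
            "hematocrit": self.hematocrit, "supply_rate": self.supply_rate,
            "so2": self.so2,
        })


def _truncnorm_draw(rng, mean, sd, bounds):
    lo, hi = bounds
    if sd == 0:
        return float(np.clip(mean, lo if lo is not None else -np.inf,
                             hi if hi is not None else np.inf))
    a = -np.inf if lo is None else (lo - mean) / sd
    b = np.inf if hi is None else (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _scaled_kinetics(template, yb, amp_delta):
    """Per-capillary kinetic parameters: its own baseline, amplitudes scaled
    by a shared factor so a capillary's components keep their proportion."""
    if isinstance(template, MonoExpParams):
        return MonoExpParams(yb, template.x0, template.y0 + amp_delta, template.tau)
    ref = template.y1 if template.y1 != 0 else (template.y2 or 1.0)
    f = (ref + amp_delta) / ref if ref != 0 else 1.0
    return BiExpParams(yb, template.x1, template.y1 * f, template.tau1,
                       template.x2, template.y2 * f, template.tau2)


def _eval_kinetics(t, p):
    return eval_mono(t, p) if isinstance(p, MonoExpParams) else eval_bi(t, p)


def simulate_population(protocol: GasChallengeProtocol, spec: PopulationSpec,
                        kinetics: Mapping, seed: int | None = None,
                        ) -> list[GroundTruthSeries]:
    """Draw a capillary population responding to a gas challenge.

    ``kinetics`` maps the simulated measures (velocity, lineal_density, so2)
    to MonoExpParams/BiExpParams templates whose amplitude is the population
    mean response (the template baseline is ignored; each capillary draws
    its own truncated-normal baseline).  Per-second Gaussian noise is added
    after evaluating the kinetic curve; hematocrit and supply rate are then
    derived from the noisy velocity and lineal density.  Responses that
    would leave physical bounds (SO2 outside [0, 100], density below 0) are
    clipped, with the clip count reported via a warning.
    """
    for m, p in kinetics.items():
        if p is None:
            continue
        delays = (p.x0,) if isinstance(p, MonoExpParams) else (p.x1, p.x2)
        for d in delays:
            if not 0 <= d <= protocol.duration:
                raise ValueError(
                    f"{m} delay {d} s outside protocol duration {protocol.duration} s")

    root = np.random.SeedSequence(seed if seed is not None else spec.seed)
    children = root.spawn(spec.n_capillaries)
    t = np.arange(1, int(round(protocol.duration)) + 1, dtype=float)

    out = []
    n_clipped = 0
    for cid, child in enumerate(children):
        rng = np.random.default_rng(child)
        series = {}
        gen = {}
        for m in ("velocity", "lineal_density", "so2"):
            template = kinetics.get(m)
            mu, sd = spec.baseline[m]
            yb = _truncnorm_draw(rng, mu, sd, MEASURE_BOUNDS[m])
            if template is None:
                p = MonoExpParams(yb, 0.0, 0.0, 1.0)  # flat: no reported response
            else:
                amp_delta = rng.normal(0.0, spec.amplitude_sd.get(m, 0.0)) \
                    if spec.amplitude_sd.get(m, 0.0) > 0 else 0.0
                p = _scaled_kinetics(template, yb, amp_delta)
            curve = _eval_kinetics(t, p)
            nsd = spec.noise_sd.get(m, 0.0)
            if nsd > 0:
                curve = curve + rng.normal(0.0, nsd, size=t.size)
            lo, hi = MEASURE_BOUNDS[m]
            lo = -np.inf if lo is None else lo
            hi = np.inf if hi is None else hi
            bad = (curve < lo) | (curve > hi)
            n_clipped += int(bad.sum())
            series[m] = np.clip(curve, lo, hi)
            gen[m] = p
        hct = derive_hematocrit(series["lineal_density"], spec.rbc_volume,
                                spec.capillary_diameter)
        sr = derive_supply_rate(series["velocity"], series["lineal_density"])
        out.append(GroundTruthSeries(cid, t, series["velocity"],
                                     series["lineal_density"], series["so2"],
                                     hct, sr, gen, seed=int(child.entropy)
                                     if isinstance(child.entropy, int) else None))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} out-of-bounds samples to physical "
                      "limits", stacklevel=2)
    return out


def population_to_frame(population: Sequence[GroundTruthSeries]) -> pd.DataFrame:
    """Long-format table: one row per capillary-second."""
    return pd.concat([s.to_frame() for s in population], ignore_index=True)


def write_population(population, csv_path, sidecar: dict | None = None) -> None:
    """CSV of capillary-seconds plus a JSON sidecar of generating parameters."""
    csv_path = Path(csv_path)
    population_to_frame(population).to_csv(csv_path, index=False,
                                           float_format="%.10g")
    meta = {"n_capillaries": len(population),
            "kinetics": {
                str(s.capillary_id): {m: p.as_dict() for m, p in s.kinetics.items()}
                for s in population}}
    if sidecar:
        meta.update(sidecar)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_population(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


# ---------------------------------------------------------------------------
# Space-time image rendering
# ---------------------------------------------------------------------------

@dataclass
class OpticsConfig:
    """Forward optical model for dual-wavelength kymograph rendering.

    At 420 nm (isosbestic) the RBC optical density is saturation-independent
    (``od420_deoxy == od420_oxy``); at 438 nm it interpolates linearly
    between the deoxy and oxy calibration values.  ``i0`` is the
    transmitted background intensity in counts.
    """

    um_per_px: float = 0.65
    fps: float = 60.0
    i0: float = 10_000.0
    od420: tuple[float, float] = (0.35, 0.35)  # (SO2=0, SO2=100)
    od438: tuple[float, float] = (0.50, 0.25)
    rbc_length_um: float = 6.0
    field_length_um: float = 200.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if min(self.um_per_px, self.fps, self.i0, self.rbc_length_um,
               self.field_length_um) <= 0:
            raise ValueError("optics scales and I0 must be positive")
        if self.od420[0] != self.od420[1]:
            raise ValueError("420 nm is isosbestic: calibration ODs must match")
        if self.od438[0] == self.od438[1]:
            raise ValueError("438 nm must be oxygen-sensitive (distinct ODs)")

    @property
    def calibration(self) -> SO2Calibration:
        return SO2Calibration(self.i0, self.od420[0], self.od438[0], self.od438[1])


def _cell_positions(series: GroundTruthSeries, optics: OpticsConfig, rng,
                    disp_frame: np.ndarray) -> np.ndarray:
    """Cell centres at t=0 on an extended line so advection fills the field.

    A single walk from the downstream end toward increasingly negative
    positions; the local spacing is 1000/LD of the second during which that
    stretch of cells occupies the field, so the rendered density tracks the
    ground truth as cells advect in.  Jitter is uniform within +-20% of the
    local spacing, which preserves single-file order (no overlap for
    spacings above ~1.7 cell lengths)."""
    field = optics.field_length_um
    margin = optics.rbc_length_um
    fps = int(round(optics.fps))
    T = len(series.t)
    ld = series.lineal_density
    disp_sec = np.concatenate([[0.0], disp_frame[fps - 1::fps]])

    lowest = -float(disp_sec[-1]) - margin
    centres = []
    x = field + margin
    while x >= lowest:
        if x > 0:
            idx = 0
        else:
            # second during which a cell starting at x reaches the field
            s = int(np.searchsorted(disp_sec, -x, side="left"))
            idx = min(max(s, 1), T) - 1
        if ld[idx] <= 0:
            # no cells during this stretch: jump to the next region boundary
            nxt = -float(disp_sec[min(idx + 1, T)]) - 1e-9
            if nxt >= x:
                break
            x = nxt
            continue
        spacing = 1000.0 / float(ld[idx])
        centres.append(x + rng.uniform(-0.2 * spacing, 0.2 * spacing))
        x -= spacing
    if not centres:
        return np.empty(0)
    return np.sort(np.asarray(centres))


def render_sti(series: GroundTruthSeries, optics: OpticsConfig,
               seed: int | None = None) -> tuple[SpaceTimeImage, SpaceTimeImage]:
    """Render the (420 nm, 438 nm) space-time image pair for one capillary.

    Cells advect at the per-second ground-truth velocity, tracing streaks of
    slope velocity / (um_per_px x fps) pixels per frame column; transmitted
    intensity is ``I0 * 10**(-OD)`` inside cells and ``I0`` outside, with
    the 438 nm OD interpolated by the cell's current SO2.  Additive Gaussian
    sensor noise is applied last and negative intensities clipped at zero.
    The 420 nm raster is SO2-independent by construction, and rendering is
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed if seed is not None else optics.seed)
    fps = int(round(optics.fps))
    T = len(series.t)
    n_cols = T * fps
    n_rows = int(round(optics.field_length_um / optics.um_per_px))

    v_sec = series.velocity
    if np.max(np.abs(v_sec)) / optics.fps > optics.field_length_um:
        warnings.warn("velocity high enough for a cell to cross the field in "
                      "one frame; streaks will alias", stacklevel=2)

    v_frame = np.repeat(v_sec, fps)
    disp = np.concatenate([[0.0], np.cumsum(v_frame / optics.fps)])[:-1]

    centres0 = _cell_positions(series, optics, rng, np.cumsum(v_frame / optics.fps))
    half = 0.5 * optics.rbc_length_um
    row_pos = (np.arange(n_rows) + 0.5) * optics.um_per_px

    od420 = optics.od420[0]
    d0, d100 = optics.od438
    img420 = np.full((n_rows, n_cols), optics.i0)
    img438 = np.full((n_rows, n_cols), optics.i0)
    cell420 = optics.i0 * 10.0 ** (-od420)

    for k in range(n_cols):
        sec = k // fps
        pos = centres0 + disp[k]
        j0 = np.searchsorted(pos, -half)
        j1 = np.searchsorted(pos, optics.field_length_um + half)
        if j1 <= j0:
            continue
        so2 = series.so2[sec]
        od438 = d0 + (so2 / 100.0) * (d100 - d0)
        cell438 = optics.i0 * 10.0 ** (-od438)
        for p in pos[j0:j1]:
            a = np.searchsorted(row_pos, p - half, side="left")
            b = np.searchsorted(row_pos, p + half, side="right")
            img420[a:b, k] = cell420
            img438[a:b, k] = cell438

    if optics.noise_sd > 0:
        img420 = img420 + rng.normal(0.0, optics.noise_sd, img420.shape)
        img438 = img438 + rng.normal(0.0, optics.noise_sd, img438.shape)
        np.clip(img420, 0.0, None, out=img420)
        np.clip(img438, 0.0, None, out=img438)

    s_per_col = 1.0 / optics.fps
    return (SpaceTimeImage(img420, optics.um_per_px, s_per_col, 420),
            SpaceTimeImage(img438, optics.um_per_px, s_per_col, 438))
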