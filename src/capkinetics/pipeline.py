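"""End-to-end orchestration: simulate -> (render -> analyze) -> fit -> summarize.

A run is driven by one YAML/JSON config and a root seed.  For every
requested challenge the pipeline simulates a ground-truth population,
optionally renders and re-analyzes dual-wavelength kymographs for a few
capillaries, fits the population mean trace of each measure with the
appropriate delayed-exponential model, runs the baseline-referenced
Dunnett onset statistics, and writes publication-schema tables, plots and
a manifest.  Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import params as _params
from .kinetics import BiExpParams, MonoExpParams, fit_bi, fit_mono
from .onset_stats import (MEASURE_COLUMNS, aggregate_means, dunnett_vs_baseline,
                          find_onset_and_peak)
from .synthetic import (GasChallengeProtocol, OpticsConfig, PopulationSpec,
                        make_protocol, population_to_frame, render_sti,
                        simulate_population, write_population)
from .sti_analysis import analyze_sti_pair, write_sti

log = logging.getLogger("capkinetics")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    protocols: list = field(default_factory=lambda: ["O2_7to2"])
    n_capillaries: int = 300
    amplitude_sd: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    baseline_override: dict = field(default_factory=dict)
    kinetics_override: dict = field(default_factory=dict)
    tabular_only: bool = True
    optics: dict = field(default_factory=dict)
    n_render: int = 2
    alpha: float = 0.05
    baseline_window: tuple = (51, 60)
    fit_windows: dict = field(default_factory=dict)
    outdir: str = "run_output"
    seed: int = 0
    make_plots: bool = True


_KNOWN_KEYS = {
    "protocols", "n_capillaries", "amplitude_sd", "noise_sd",
    "baseline_override", "kinetics_override", "tabular_only", "optics",
    "n_render", "alpha", "baseline_window", "fit_windows", "outdir", "seed",
    "make_plots",
}


def validate_config(source) -> tuple[RunConfig | None, list[str]]:
    """Schema-check a config mapping or YAML/JSON file path.

    Returns ``(config, [])`` on success or ``(None, errors)`` with
    human-readable field paths otherwise.  Cross-field rules include the
    window/protocol-duration consistency check.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]

    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key: {key}")

    cfg = RunConfig()
    protocols = raw.get("protocols", cfg.protocols)
    if protocols == "all":
        protocols = list(_params.PROTOCOL_SEGMENTS)
    if not isinstance(protocols, list) or not protocols:
        errors.append("protocols: must be a non-empty list or 'all'")
        protocols = []
    for p in protocols:
        if p not in _params.PROTOCOL_SEGMENTS:
            errors.append(f"protocols: unknown challenge {p!r}")

    n_cap = raw.get("n_capillaries", cfg.n_capillaries)
    if not isinstance(n_cap, int) or n_cap < 1:
        errors.append("n_capillaries: must be a positive integer")

    for key in ("amplitude_sd", "noise_sd"):
        for m, v in (raw.get(key) or {}).items():
            if m not in ("velocity", "lineal_density", "so2"):
                errors.append(f"{key}.{m}: unknown measure")
            elif not isinstance(v, (int, float)) or v < 0:
                errors.append(f"{key}.{m}: must be a non-negative number")

    for ch, meas in (raw.get("kinetics_override") or {}).items():
        for m, d in (meas or {}).items():
            for pname in ("tau", "tau1", "tau2"):
                if pname in (d or {}) and d[pname] <= 0:
                    errors.append(f"kinetics_override.{ch}.{m}.{pname}: "
                                  "time constant must be positive")

    alpha = raw.get("alpha", cfg.alpha)
    if not 0 < alpha < 1:
        errors.append("alpha: must lie in (0, 1)")

    fit_windows = raw.get("fit_windows") or {}
    for ch, win in fit_windows.items():
        if ch not in _params.PROTOCOL_SEGMENTS:
            errors.append(f"fit_windows.{ch}: unknown challenge")
            continue
        dur = _params.challenge_duration(ch)
        if not (isinstance(win, (list, tuple)) and len(win) == 2
                and win[0] < win[1]):
            errors.append(f"fit_windows.{ch}: must be [t_start, t_end]")
        elif win[1] > dur:
            errors.append(f"fit_windows.{ch}: window end {win[1]} s exceeds "
                          f"protocol duration {dur} s")
        elif ch == "combined" and win[1] < 240:
            errors.append(f"fit_windows.{ch}: combined challenge needs a "
                          f"window reaching 240 s, got {win}")

    if raw.get("optics"):
        try:
            OpticsConfig(**raw["optics"])
        except (TypeError, ValueError) as e:
            errors.append(f"optics: {e}")

    if errors:
        return None, errors
    return RunConfig(
        protocols=protocols, n_capillaries=n_cap,
        amplitude_sd=dict(raw.get("amplitude_sd") or {}),
        noise_sd=dict(raw.get("noise_sd") or {}),
        baseline_override=dict(raw.get("baseline_override") or {}),
        kinetics_override=dict(raw.get("kinetics_override") or {}),
        tabular_only=bool(raw.get("tabular_only", True)),
        optics=dict(raw.get("optics") or {}),
        n_render=int(raw.get("n_render", 2)),
        alpha=float(alpha),
        baseline_window=tuple(raw.get("baseline_window", (51, 60))),
        fit_windows={k: tuple(v) for k, v in fit_windows.items()},
        outdir=str(raw.get("outdir", "run_output")),
        seed=int(raw.get("seed", 0)),
        make_plots=bool(raw.get("make_plots", True)),
    ), []


def _challenge_kinetics(cfg: RunConfig, challenge: str) -> dict:
    kin = _params.default_kinetics(challenge)
    for m, over in (cfg.kinetics_override.get(challenge) or {}).items():
        p = kin.get(m)
        d = (p.as_dict() if p is not None else
             {"yb": 0.0, "x0": 60.0, "y0": 0.0, "tau": 1.0})
        d.update(over)
        kin[m] = BiExpParams(**d) if "tau2" in d else MonoExpParams(**d)
    return kin


def _fit_measure(challenge, measure, t, y, cfg):
    constraints = _params.default_constraints(challenge, measure)
    if constraints is None:
        return None, None
    if challenge in cfg.fit_windows:
        constraints.window = cfg.fit_windows[challenge]
    if challenge == "combined":
        return fit_bi(t, y, constraints), constraints
    return fit_mono(t, y, constraints), constraints


def _fit_row(challenge, measure, fit, constraints):
    row = {"challenge": challenge, "measurement": measure}
    if fit is None:
        return row  # no stable-fit configuration: blank row
    p = fit.params
    if p is None:
        row["converged"] = False
        return row
    row.update(p.as_dict())
    row.update({"r2": fit.r2, "ssr": fit.ssr, "converged": fit.converged,
                "identifiable": fit.identifiable,
                "window": f"{constraints.window[0]:g}-{constraints.window[1]:g}"})
    return row


def _onset_rows(challenge, cfg, pop_df, duration):
    """Single-step challenges: one summary row per measure (baseline 51-60).
    Combined challenge: two rows per measure, one per reference window."""
    phases = [(cfg.baseline_window, (cfg.baseline_window[1] + 1, duration), "")]
    if challenge == "combined":
        phases = [((51, 60), (61, 120), "post_low_o2"),
                  ((111, 120), (121, 240), "post_high_co2")]
    rows = []
    means = aggregate_means(pop_df)
    for m in MEASURE_COLUMNS:
        wide = pop_df.pivot_table(index="capillary_id", columns="t", values=m,
                                  dropna=False)
        for base_win, post_win, tag in phases:
            dn = dunnett_vs_baseline(wide, baseline_window=base_win,
                                     post_window=post_win, alpha=cfg.alpha)
            summ = find_onset_and_peak(means[means["measure"] == m], dn,
                                       step_time=base_win[1],
                                       baseline_window=base_win,
                                       alpha=cfg.alpha, measure=m,
                                       challenge=challenge)
            d = summ.to_dict()
            d["phase"] = tag
            rows.append(d)
    return rows


def _plot_challenge(challenge, means, fits, outpath, duration):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinetics import eval_bi, eval_mono

    fig, axes = plt.subplots(len(MEASURE_COLUMNS), 1, sharex=True,
                             figsize=(6, 2.0 * len(MEASURE_COLUMNS)))
    tt = np.linspace(1, duration, 4 * duration)
    for ax, m in zip(np.atleast_1d(axes), MEASURE_COLUMNS):
        sub = means[means["measure"] == m]
        ax.plot(sub["t"], sub["mean"], lw=0.8, color="k")
        ax.fill_between(sub["t"], sub["mean"] - sub["sem"],
                        sub["mean"] + sub["sem"], alpha=0.3, color="0.5",
                        label="mean ± SEM")
        fit = fits.get(m)
        if fit is not None and fit.params is not None and fit.identifiable:
            p = fit.raw_params
            curve = (eval_bi(tt, p) if isinstance(p, BiExpParams)
                     else eval_mono(tt, p))
            ax.plot(tt, curve, color="C3", lw=1.2, label="exponential fit")
        ax.set_ylabel(m, fontsize=8)
    np.atleast_1d(axes)[0].set_title(challenge)
    np.atleast_1d(axes)[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(outpath, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute a full run; returns a manifest dict (also written to disk).

    Per challenge the outputs are the ground-truth CSV (+ JSON generator
    sidecar), optional STI TIFF pairs and their re-analyzed hemodynamics
    CSV, a fit-parameter table, an onset-summary table and mean ± SEM plots
    with the fitted curves.  Failures are isolated per challenge; the run
    continues and the manifest records the error.
    """
    if not isinstance(config, RunConfig):
        config, errors = validate_config(config)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(cfg.seed)
    manifest = {
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "challenges": {}, "warnings": {}, "errors": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()[:16]

    fit_rows, onset_rows = [], []
    for challenge, child in zip(cfg.protocols, root_ss.spawn(len(cfg.protocols))):
        t0 = time.perf_counter()
        try:
            protocol = make_protocol(challenge)
            duration = int(protocol.duration)
            base = {m: _params.BASELINES[challenge][m]
                    for m in ("velocity", "lineal_density", "so2")}
            base.update(cfg.baseline_override.get(challenge, {}))
            spec = PopulationSpec(n_capillaries=cfg.n_capillaries,
                                  baseline=base,
                                  amplitude_sd={**{"velocity": 0.0,
                                                   "lineal_density": 0.0,
                                                   "so2": 0.0},
                                                **cfg.amplitude_sd},
                                  noise_sd={**{"velocity": 0.0,
                                               "lineal_density": 0.0,
                                               "so2": 0.0},
                                            **cfg.noise_sd})
            kin = _challenge_kinetics(cfg, challenge)
            sim_kin = {m: kin.get(m) for m in ("velocity", "lineal_density", "so2")}

            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                pop = simulate_population(protocol, spec, sim_kin,
                                          seed=int(child.generate_state(1)[0] >> 1))
            manifest["warnings"][challenge] = [str(w.message) for w in wlist]

            write_population(pop, outdir / f"ground_truth_{challenge}.csv",
                             sidecar={"challenge": challenge, "seed": cfg.seed})
            pop_df = population_to_frame(pop)

            if not cfg.tabular_only:
                optics = OpticsConfig(**cfg.optics)
                recovered = []
                for s in pop[:cfg.n_render]:
                    pair = render_sti(s, optics,
                                      seed=int(child.generate_state(2)[1] >> 1)
                                      + s.capillary_id)
                    for sti in pair:
                        write_sti(sti, outdir / f"sti_{challenge}_cap{s.capillary_id}"
                                               f"_{sti.wavelength}.tif")
                    recovered.append(analyze_sti_pair(
                        pair[0], pair[1], optics.calibration,
                        rbc_length_um=optics.rbc_length_um,
                        rbc_volume=spec.rbc_volume,
                        diameter=spec.capillary_diameter,
                        capillary_id=s.capillary_id))
                if recovered:
                    pd.concat(recovered, ignore_index=True).to_csv(
                        outdir / f"recovered_{challenge}.csv", index=False,
                        float_format=_FLOAT_FMT)

            means = aggregate_means(pop_df)
            fits = {}
            for m in MEASURE_COLUMNS:
                sub = means[means["measure"] == m]
                fit, constraints = _fit_measure(challenge, m,
                                                sub["t"].to_numpy(),
                                                sub["mean"].to_numpy(), cfg)
                fits[m] = fit
                fit_rows.append(_fit_row(challenge, m, fit, constraints))
            onset_rows.extend(_onset_rows(challenge, cfg, pop_df, duration))

            if cfg.make_plots:
                plots = outdir / "plots"
                plots.mkdir(exist_ok=True)
                _plot_challenge(challenge, means, fits,
                                plots / f"{challenge}.png", duration)

            manifest["challenges"][challenge] = {
                "n_capillaries": cfg.n_capillaries,
                "duration_s": duration,
                "runtime_s": round(time.perf_counter() - t0, 3),
                "non_converged": [m for m, f in fits.items()
                                  if f is not None and not f.converged],
            }
            log.info("challenge %s done in %.2fs", challenge,
                     time.perf_counter() - t0)
        except Exception as e:  # isolate per challenge
            log.exception("challenge %s failed", challenge)
            manifest["errors"][challenge] = f"{type(e).__name__}: {e}"

    pd.DataFrame(fit_rows).to_csv(outdir / "fit_table.csv", index=False,
                                  float_format=_FLOAT_FMT)
    pd.DataFrame(onset_rows).to_csv(outdir / "onset_table.csv", index=False,
                                    float_format=_FLOAT_FMT)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
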