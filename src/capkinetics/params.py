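"""Reference gas-challenge protocols, kinetic parameters and baselines.

These tables define the study conditions the synthetic generator emulates:
the nine gas-challenge regimes (four O2, four CO2, one combined), the
published delayed-exponential fit parameters for each measure x challenge
(with their fitting constraints), and the population baseline mean +- SD
over the 51-60 s reference window.  Measures are keyed ``velocity`` (um/s),
``lineal_density`` (cells/mm), ``hematocrit`` (%), ``supply_rate``
(cells/s) and ``so2`` (%).

Some responses required constraint variations to fit stably: a few delay
bounds differ from the standard "> 60 s", one delay is pinned at 60 s, and
several saturation fits use a narrower or unbounded window ("NSV" = no set
value).  The 10-5% CO2 lineal-density and hematocrit responses have no
stable exponential fit and carry ``None`` entries.
"""

from __future__ import annotations

from .kinetics import BiExpParams, FitConstraints, MonoExpParams, STRICT_EPS

__all__ = [
    "MEASURES",
    "PROTOCOL_SEGMENTS",
    "MONO_TABLE",
    "BI_TABLE",
    "BASELINES",
    "challenge_duration",
    "default_kinetics",
    "default_constraints",
]

MEASURES = ("velocity", "lineal_density", "hematocrit", "supply_rate", "so2")

#: (duration s, O2 %, CO2 %) segments; N2 is the balance gas.  O2 challenges
#: hold CO2 at 5%, CO2 challenges hold O2 at 7%.
PROTOCOL_SEGMENTS = {
    "O2_7to12": [(60, 7, 5), (120, 12, 5)],
    "O2_12to7": [(60, 12, 5), (120, 7, 5)],
    "O2_7to2": [(60, 7, 5), (120, 2, 5)],
    "O2_2to7": [(60, 2, 5), (120, 7, 5)],
    "CO2_5to0": [(60, 7, 5), (120, 7, 0)],
    "CO2_0to5": [(60, 7, 0), (120, 7, 5)],
    "CO2_5to10": [(60, 7, 5), (120, 7, 10)],
    "CO2_10to5": [(60, 7, 10), (120, 7, 5)],
    "combined": [(60, 7, 5), (60, 2, 5), (120, 2, 10)],
}

# Mono-exponential fits for the eight single-step challenges.
# Entries: (x0, y0, tau, r2, x0_rule, window); x0_rule is ">60"-style, "=60"
# for a pin or "NSV" for unbounded; window None means NSV (whole series).
MONO_TABLE = {
    "O2_7to12": {
        "velocity": (66.7, -29.4, 7.0, 0.8139, ">60", (51, 180)),
        "lineal_density": (64.9, -13.9, 24.0, 0.906, ">60", (51, 180)),
        "hematocrit": (65.7, -4.9, 27.2, 0.9372, ">60", (51, 180)),
        "supply_rate": (63.0, -4.3, 20.6, 0.9301, ">60", (51, 180)),
        "so2": (60.6, 18.7, 1.0, 0.9923, ">60", (0, 90)),
    },
    "O2_12to7": {
        "velocity": (60.0, 49.5, 38.5, 0.8468, ">60", (51, 180)),
        "lineal_density": (64.6, 12.1, 35.9, 0.9547, ">60", (51, 180)),
        "hematocrit": (64.7, 4.4, 35.2, 0.9475, ">60", (51, 180)),
        "supply_rate": (60.0, 5.2, 36.1, 0.9378, ">60", (51, 180)),
        "so2": (62.2, -18.4, 1.6, 0.9909, ">60", None),
    },
    "O2_7to2": {
        "velocity": (60.0, 116.5, 35.5, 0.9165, ">60", (51, 180)),
        "lineal_density": (64.7, 13.5, 26.9, 0.9415, ">60", (51, 180)),
        "hematocrit": (63.2, 5.4, 32.4, 0.9582, ">60", (51, 180)),
        "supply_rate": (60.0, 10.5, 41.9, 0.9591, ">60", (51, 180)),
        "so2": (62.3, -27.8, 1.4, 0.9952, ">60", (51, 90)),
    },
    "O2_2to7": {
        "velocity": (61.7, -66.3, 13.4, 0.8634, ">59", (51, 180)),
        "lineal_density": (64.7, -11.1, 68.2, 0.8729, ">60", (51, 180)),
        "hematocrit": (63.0, -4.1, 74.8, 0.88, ">60", (51, 180)),
        "supply_rate": (61.4, -6.0, 23.1, 0.8763, ">60", (51, 180)),
        "so2": (62.7, 24.5, 1.3, 0.9929, ">60", None),
    },
    "CO2_5to0": {
        "velocity": (60.7, -257.5, 18.88, 0.9902, ">60", (51, 180)),
        "lineal_density": (63.7, -41.8, 15.89, 0.9915, ">60", None),
        "hematocrit": (63.7, -13.7, 15.3, 0.9912, ">60", (51, 180)),
        "supply_rate": (61.6, -21.6, 13.8, 0.9966, ">60", (51, 180)),
        "so2": (62.4, 6.3, 0.84, 0.8509, ">60", (51, 100)),
    },
    "CO2_0to5": {
        "velocity": (66.5, 275.8, 21.79, 0.9951, ">60", (51, 180)),
        "lineal_density": (70.8, 41.6, 30.63, 0.9929, "NSV", None),
        "hematocrit": (70.9, 15.9, 38.5, 0.9920, ">60", (51, 180)),
        "supply_rate": (63.0, 17.1, 33.0, 0.9593, ">60", (51, 180)),
        "so2": (67.8, -5.9, 0.39, 0.5907, ">60", (51, 100)),
    },
    "CO2_5to10": {
        "velocity": (60.0, 182.2, 79.34, 0.9735, ">60", (51, 180)),
        "lineal_density": (60.0, 10.3, 30.31, 0.8855, ">60", None),
        "hematocrit": (60.0, 4.0, 65.9, 0.8757, ">60", (51, 180)),
        "supply_rate": (60.0, 14.4, 88.1, 0.9962, ">60", (51, 180)),
        "so2": (60.0, -5.7, 2.9, 0.9026, ">60", (51, 100)),
    },
    "CO2_10to5": {
        "velocity": (62.8, -94.3, 20.66, 0.9686, ">60", (51, 180)),
        "lineal_density": None,  # no stable exponential fit
        "hematocrit": None,  # no stable exponential fit
        "supply_rate": (65.9, -5.8, 20.2, 0.9479, ">60", (51, 180)),
        "so2": (60.0, 6.1, 5.4, 0.8792, "=60", (51, 180)),
    },
}

# Combined-challenge bi-exponential fits: (x1, y1, x2, y2, tau1, tau2, r2);
# constraints X1 > 60, X2 > 120, window 51-240 throughout.
BI_TABLE = {
    "velocity": (60.0, 76.4, 120.0, 213.6, 23.3, 85.78, 0.9843),
    "lineal_density": (64.4, 8.0, 120.0, 3.2, 22.38, 23.63, 0.9413),
    "hematocrit": (64.0, 2.9, 120.0, 1.4, 21.52, 20.73, 0.9486),
    "supply_rate": (62.0, 6.6, 120.0, 11.3, 20.94, 49.87, 0.9792),
    "so2": (63.2, -20.9, 120.0, 15.9, 0.6799, 92.32, 0.9561),
}

#: Baseline (mean, SD) over the 51-60 s reference window, per challenge.
BASELINES = {
    "O2_7to12": {"so2": (64.4, 14.7), "velocity": (238.6, 183.4),
                 "lineal_density": (56.5, 36.6), "hematocrit": (20.9, 10.9),
                 "supply_rate": (13.7, 15.3)},
    "O2_12to7": {"so2": (84.5, 13.9), "velocity": (230.6, 206.6),
                 "lineal_density": (46.3, 34.0), "hematocrit": (17.2, 11.2),
                 "supply_rate": (11.5, 14.9)},
    "O2_7to2": {"so2": (69.7, 13.1), "velocity": (228.5, 190.4),
                "lineal_density": (49.4, 34.2), "hematocrit": (19.0, 12.2),
                "supply_rate": (12.3, 15.9)},
    "O2_2to7": {"so2": (46.5, 19.6), "velocity": (337.2, 221.5),
                "lineal_density": (65.1, 35.3), "hematocrit": (24.0, 10.7),
                "supply_rate": (22.2, 20.6)},
    "CO2_5to0": {"so2": (68.7, 15.4), "velocity": (349.1, 245.8),
                 "lineal_density": (70.3, 50.1), "hematocrit": (23.4, 12.0),
                 "supply_rate": (23.4, 22.4)},
    "CO2_0to5": {"so2": (65.7, 28.4), "velocity": (71.4, 132.5),
                 "lineal_density": (25.0, 26.5), "hematocrit": (9.6, 10.2),
                 "supply_rate": (1.6, 6.0)},
    "CO2_5to10": {"so2": (69.5, 14.0), "velocity": (273.4, 218.1),
                  "lineal_density": (54.6, 35.0), "hematocrit": (22.4, 11.8),
                  "supply_rate": (15.9, 19.5)},
    "CO2_10to5": {"so2": (62.1, 17.3), "velocity": (420.4, 264.3),
                  "lineal_density": (60.8, 35.6), "hematocrit": (20.3, 11.3),
                  "supply_rate": (26.3, 24.3)},
    "combined": {"so2": (66.1, 16.4), "velocity": (259.2, 194.2),
                 "lineal_density": (58.6, 39.9), "hematocrit": (20.8, 13.1),
                 "supply_rate": (16.6, 19.5)},
}


def challenge_duration(name: str) -> int:
    return sum(d for d, _, _ in PROTOCOL_SEGMENTS[name])


def default_kinetics(challenge: str) -> dict:
    """Published kinetic parameter set for a challenge, keyed by measure.

    Baselines come from the reference-window means; entries are ``None``
    where no stable fit was reported.  Returns MonoExpParams for single-step
    challenges and BiExpParams for the combined challenge.
    """
    base = BASELINES[challenge]
    out = {}
    if challenge == "combined":
        for m, row in BI_TABLE.items():
            x1, y1, x2, y2, tau1, tau2, _ = row
            out[m] = BiExpParams(base[m][0], x1, y1, tau1, x2, y2, tau2)
        return out
    for m, row in MONO_TABLE[challenge].items():
        if row is None:
            out[m] = None
            continue
        x0, y0, tau, *_ = row
        out[m] = MonoExpParams(base[m][0], x0, y0, tau)
    return out


def _delay_bound(rule: str, default_gt: float):
    if rule == "NSV":
        return None, None
    if rule.startswith(">"):
        return float(rule[1:]) + STRICT_EPS, None
    if rule.startswith("="):
        return "pin", float(rule[1:])
    raise ValueError(f"unknown delay constraint {rule!r}")


def default_constraints(challenge: str, measure: str) -> FitConstraints | None:
    """Published fitting constraints for a measure x challenge.

    ``None`` where no stable fit exists.  An "NSV" window maps to the whole
    recorded series (1 s to the challenge duration).
    """
    dur = challenge_duration(challenge)
    if challenge == "combined":
        return FitConstraints.bi_default(window=(51.0, float(dur)))
    row = MONO_TABLE[challenge][measure]
    if row is None:
        return None
    _, _, _, _, rule, window = row
    window = (float(window[0]), float(window[1])) if window else (1.0, float(dur))
    b = _delay_bound(rule, 60.0)
    if b[0] == "pin":
        return FitConstraints(window=window, pins={"x0": b[1]})
    bounds = {} if b == (None, None) else {"x0": b}
    return FitConstraints(window=window, bounds=bounds)
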