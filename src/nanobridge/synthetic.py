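"""Seeded generators for every table the analysis pipelines consume.

Each generator emulates one family of measurements from a cancer-cell /
endothelium co-culture study:

* projection morphometry (lognormal short/long-axis populations),
* growth kinetics of the membrane bridges (logistic rise, mild post-peak
  decline),
* flow-cytometry event tables (lognormal intensity mixtures over DiI-Ac-LDL,
  PECAM-1 and CFSE channels, with ground-truth labels),
* actin-only vs actin+tubulin composition labels,
* qPCR threshold-cycle tables embedding known expression fold changes.

All generators take an explicit integer ``seed``; identical arguments produce
byte-identical tables.  Ground-truth columns (prefixed ``true_``) are carried
through so every downstream stage can be tested against the value it should
recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "PopulationParams",
    "ScenarioSpec",
    "NANOBRIDGE_SHORT_AXIS",
    "NANOBRIDGE_LONG_AXIS",
    "LAMELLIPODIUM_SHORT_AXIS",
    "LAMELLIPODIUM_LONG_AXIS",
    "gen_morphometry",
    "gen_kinetics",
    "gen_facs_events",
    "gen_composition_labels",
    "gen_ct_table",
    "gen_marker_table",
    "lognormal_params_from_moments",
]


@dataclass(frozen=True)
class PopulationParams:
    """Population location/spread as reported: mean ± s.e.m. with its n.

    The population s.d. is recovered as ``sem * sqrt(n_reported)``.
    ``distribution`` selects the positive-support family used to realize the
    population ('lognormal', matched by moments, or 'truncated-normal').
    """

    mean: float
    sem: float
    n_reported: int = 300
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sem < 0:
            raise InvalidInputError("mean must be > 0 and sem >= 0")
        if self.n_reported < 2:
            raise InvalidInputError("n_reported must be >= 2")
        if self.distribution not in ("lognormal", "truncated-normal"):
            raise InvalidInputError(f"unknown distribution {self.distribution!r}")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n_reported)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named generator scenario: family, parameters, size and seed."""

    family: str
    parameters: Mapping
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.family not in ("morphometry", "kinetics", "facs", "composition", "qpcr"):
            raise InvalidInputError(f"unknown scenario family {self.family!r}")
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")


# Published nanobridge / lamellipodium population moments (mean ± s.e.m., n>300).
NANOBRIDGE_SHORT_AXIS = PopulationParams(mean=290.0, sem=20.0, n_reported=300)
NANOBRIDGE_LONG_AXIS = PopulationParams(mean=30_690.0, sem=2_430.0, n_reported=300)
LAMELLIPODIUM_SHORT_AXIS = PopulationParams(mean=4_990.0, sem=230.0, n_reported=300)
LAMELLIPODIUM_LONG_AXIS = PopulationParams(mean=12_900.0, sem=1_790.0, n_reported=300)


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(μ_log, σ_log) of the lognormal with the given arithmetic mean and s.d.

    σ_log² = ln(1 + (sd/mean)²), μ_log = ln(mean) − σ_log²/2.  Raises when
    the implied σ_log is not finite.
    """
    if mean <= 0 or sd < 0:
        raise InvalidInputError("mean must be > 0 and sd >= 0")
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    if not math.isfinite(sigma2):
        raise InvalidInputError("moment match infeasible: CV overflows sigma_log")
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_population(params: PopulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.sd == 0:
        return np.full(n, params.mean)
    if params.distribution == "lognormal":
        mu, sigma = lognormal_params_from_moments(params.mean, params.sd)
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    # truncated normal on (0, inf), shifted moments not corrected: suitable
    # only for CV << 1 populations such as lamellipodia widths
    x = rng.normal(params.mean, params.sd, size=n)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(params.mean, params.sd, size=int(bad.sum()))
        bad = x <= 0
    return x


def gen_morphometry(
    short_axis: PopulationParams,
    long_axis: PopulationParams,
    kind_label: str,
    n: int,
    seed: int,
    condition: str = "co_culture",
) -> pd.DataFrame:
    """Projection-measurement table with lognormal axis populations.

    One row per measured projection with columns ``structure_id``,
    ``cell_id``, ``condition``, ``short_axis_nm``, ``long_axis_nm``,
    ``kind_label``.  Axes are drawn independently from the requested
    populations (matched by moments); all values are strictly positive.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    short = _draw_population(short_axis, n, rng)
    long = _draw_population(long_axis, n, rng)
    return pd.DataFrame(
        {
            "structure_id": np.arange(n),
            "cell_id": rng.integers(0, max(1, n // 3), size=n),
            "condition": condition,
            "short_axis_nm": short,
            "long_axis_nm": long,
            "kind_label": kind_label,
        }
    )


def kinetics_mean_curve(
    t,
    plateau_nm: float,
    t_peak_h: float,
    rate: float = 0.8,
    half_rise_offset_h: float = 5.0,
    decline_rate: float = 0.03,
) -> np.ndarray:
    """Noise-free mean bridge length at time ``t`` (hours).

    Logistic rise (half-rise at ``t_peak_h − half_rise_offset_h``) multiplied
    by a mild exponential decline after the peak, so the curve attains its
    maximum at ``t_peak_h`` and then slowly retracts.
    """
    t = np.asarray(t, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-rate * (t - (t_peak_h - half_rise_offset_h))))
    decline = np.exp(-decline_rate * np.clip(t - t_peak_h, 0.0, None))
    return plateau_nm * rise * decline


def gen_kinetics(
    plateau_nm: float,
    t_peak_h: float,
    rate: float,
    timepoints: Sequence[float],
    n_per_t: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Growth-kinetics table: per timepoint, mean measured length ± s.e.m.

    Columns: ``timepoint_h``, ``mean_length_nm``, ``sem_nm``, ``n``,
    ``true_mean_nm``.  ``n_per_t`` independent measurements with additive
    Gaussian noise are averaged per timepoint.
    """
    t = np.asarray(list(timepoints), dtype=float)
    if t.size < 3:
        raise InvalidInputError("need at least 3 timepoints")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("timepoints must be strictly increasing")
    if not (t[0] <= t_peak_h <= t[-1]):
        raise InvalidInputError("t_peak_h must lie within the timepoint range")
    rng = np.random.default_rng(seed)
    truth = kinetics_mean_curve(t, plateau_nm, t_peak_h, rate=rate)
    obs = truth[:, None] + rng.normal(0.0, noise_sd, size=(t.size, n_per_t))
    return pd.DataFrame(
        {
            "timepoint_h": t,
            "mean_length_nm": obs.mean(axis=1),
            "sem_nm": obs.std(axis=1, ddof=1) / math.sqrt(n_per_t),
            "n": n_per_t,
            "true_mean_nm": truth,
        }
    )


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

#: Default lognormal intensity populations per channel (linear scale).
#: Negative/positive medians are ≥10× apart across a ~4-decade range.
DEFAULT_CHANNEL_PARAMS: dict = {
    "negative_median": 100.0,
    "positive_median": 10_000.0,
    "sigma_log": 0.55,  # natural-log scale spread of each population
}

#: Preset true transfer fractions per experimental condition.
CONDITION_PRESETS: dict = {
    "co_culture": 0.30,
    "dual_culture": 0.04,
    "inhibitor": 0.04,
    "control": 0.0,
}


def gen_facs_events(
    condition: str,
    true_transfer_fraction: float | None = None,
    background_rate: float = 0.03,
    endo_fraction: float = 0.5,
    channel_params: Mapping | None = None,
    n_events: int = 50_000,
    seed: int = 0,
    unstained: bool = False,
) -> pd.DataFrame:
    """Per-event cytometry table over channels {diI, pecam, cfse}.

    Endothelial events (fraction ``endo_fraction``) are bright in DiI-Ac-LDL
    and PECAM-1; cancer-cell events are bright in CFSE (dye-loaded) but dim
    in the endothelial markers.  Among endothelial events, CFSE status is a
    three-way draw: truly transferred (``true_transfer_fraction``),
    spuriously positive background (``background_rate``, present in every
    condition), or negative.  With ``unstained=True`` every channel is drawn
    from the negative population — the sample used to place gate thresholds.

    Ground truth is kept in columns ``true_endothelial``, ``true_transfer``
    and ``true_background``.  A ``separation_warning`` attribute is set in
    ``DataFrame.attrs`` when the configured populations overlap badly.
    """
    if n_events < 1_000:
        raise InvalidInputError("need at least 1,000 events for quantification")
    if true_transfer_fraction is None:
        try:
            true_transfer_fraction = CONDITION_PRESETS[condition]
        except KeyError:
            raise InvalidInputError(
                f"no preset for condition {condition!r}; pass true_transfer_fraction"
            ) from None
    ttf, bg = float(true_transfer_fraction), float(background_rate)
    if not (0 <= ttf <= 1 and 0 <= bg <= 1 and 0 <= endo_fraction <= 1):
        raise InvalidInputError("fractions must be in [0, 1]")
    if ttf + bg > 1:
        raise InvalidInputError("true_transfer_fraction + background_rate must be <= 1")
    cp = dict(DEFAULT_CHANNEL_PARAMS)
    if channel_params:
        cp.update(channel_params)
    neg_med, pos_med, sig = cp["negative_median"], cp["positive_median"], cp["sigma_log"]
    if neg_med <= 0 or pos_med <= 0 or sig <= 0:
        raise InvalidInputError("channel parameters must be positive")

    rng = np.random.default_rng(seed)
    endo = rng.random(n_events) < endo_fraction

    def intensity(positive: np.ndarray) -> np.ndarray:
        med = np.where(positive, pos_med, neg_med)
        return med * rng.lognormal(0.0, sig, size=n_events)

    if unstained:
        stain_endo = np.zeros(n_events, dtype=bool)
        transfer = np.zeros(n_events, dtype=bool)
        spurious = np.zeros(n_events, dtype=bool)
        cfse_hi = np.zeros(n_events, dtype=bool)
    else:
        stain_endo = endo
        u = rng.random(n_events)
        transfer = endo & (u < ttf)
        spurious = endo & (u >= ttf) & (u < ttf + bg)
        # cancer cells are CFSE-loaded (95% labelling efficiency)
        cancer_loaded = (~endo) & (rng.random(n_events) < 0.95)
        cfse_hi = transfer | spurious | cancer_loaded

    out = pd.DataFrame(
        {
            "diI": intensity(stain_endo),
            "pecam": intensity(stain_endo),
            "cfse": intensity(cfse_hi),
            "condition": condition if not unstained else "unstained",
            "true_endothelial": endo,
            "true_transfer": transfer,
            "true_background": spurious,
        }
    )
    # flag configurations where the populations are no longer separable
    if pos_med / neg_med < math.exp(4.0 * sig):
        out.attrs["separation_warning"] = True
    return out


def gen_composition_labels(p_dual: float, n: int, seed: int) -> pd.DataFrame:
    """Independent composition draws: actin_only vs actin_plus_tubulin."""
    if not 0.0 <= p_dual <= 1.0:
        raise InvalidInputError("p_dual must be in [0, 1]")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dual = rng.random(n) < p_dual
    return pd.DataFrame(
        {
            "structure_id": np.arange(n),
            "composition": np.where(dual, "actin_plus_tubulin", "actin_only"),
        }
    )


def gen_ct_table(
    fold_changes: Mapping[str, float],
    base_ct_target: float = 28.0,
    base_ct_reference: float = 20.0,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table embedding known fold changes per condition.

    For each condition the target-gene Ct is shifted by −log2(fold) from
    ``base_ct_target`` (a doubling of expression removes one cycle); the
    reference gene stays at ``base_ct_reference``.  Gaussian Ct noise of
    s.d. ``noise_sd`` is added per replicate.  Columns: ``sample_id``,
    ``condition``, ``gene``, ``replicate``, ``ct``, ``true_fold``.
    """
    if replicates < 2:
        raise InvalidInputError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, fold in fold_changes.items():
        if fold <= 0:
            raise InvalidInputError(f"fold for {cond!r} must be > 0")
        ct_t = base_ct_target - math.log2(fold)
        for gene, base in (("target", ct_t), ("reference", base_ct_reference)):
            for rep in range(replicates):
                rows.append(
                    {
                        "sample_id": f"{cond}_s1",
                        "condition": cond,
                        "gene": gene,
                        "replicate": rep,
                        "ct": base + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                        "true_fold": fold,
                    }
                )
    return pd.DataFrame(rows)


def gen_marker_table(
    medians: Mapping[str, float],
    sigma_log: float = 0.5,
    n_per_population: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell marker-intensity table with lognormal populations.

    ``medians`` maps population name (recipient, non_recipient, naive,
    inhibitor, ...) to its true median intensity.  Columns: ``population``,
    ``intensity``, ``true_median``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for pop, med in medians.items():
        if med <= 0:
            raise InvalidInputError(f"median for {pop!r} must be > 0")
        vals = med * rng.lognormal(0.0, sigma_log, size=n_per_population)
        frames.append(
            pd.DataFrame({"population": pop, "intensity": vals, "true_median": med})
        )
    return pd.concat(frames, ignore_index=True)


def write_table(df: pd.DataFrame, path, scenario: ScenarioSpec | None = None) -> None:
    """Write a generated table as CSV with the scenario embedded as comments."""
    with open(path, "w") as fh:
        if scenario is not None:
            fh.write(f"# family: {scenario.family}\n")
            fh.write(f"# n: {scenario.n}\n# seed: {scenario.seed}\n")
            for k, v in dict(scenario.parameters).items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping comment headers."""
    return pd.read_csv(path, comment="#")
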