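"""Applications of the fitted decay models.

* short-/long-term rate recovery: evaluate the average-rate curve of an
  ensemble of fits at a stated timescale (presets: 10 years, 30 Myr);
* divergence-date inference: invert the cumulative curve at a node's
  substitutions s to get its age, per replicate, summarised to a median
  and central 95 % interval;
* three-node calibration-scheme experiments: fit the model to three
  calibrating nodes only and predict every other dated node's age, probing
  extrapolation vs interpolation behaviour of the calibration choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .dataset import CospeciationDataset, RateSampleSet, assemble_rate_sets
from .fitting import FitError, FitResult, fit_time_model
from .models import (
    RateModelKind,
    average_rate,
    ex_max_substitutions,
    invert_time,
)

__all__ = [
    "CalibrationScheme",
    "SCHEMES",
    "DateEstimate",
    "rate_at_timescale",
    "infer_dates",
    "run_calibration_scheme",
    "SHORT_TERM_YEARS",
    "LONG_TERM_YEARS",
]

#: preset rate-recovery timescales, in years
SHORT_TERM_YEARS = 10.0
LONG_TERM_YEARS = 30e6


@dataclass(frozen=True)
class CalibrationScheme:
    """Exactly three calibrating nodes; named scheme presets below."""

    name: str
    calibrating_nodes: tuple

    def __post_init__(self):
        if len(self.calibrating_nodes) != 3:
            raise ValueError("a calibration scheme names exactly 3 nodes")


#: aggregated (shallow/intermediate/deep) and dispersed three-node schemes;
#: the two nodes whose host assignment is ambiguous (7 and 9) never calibrate
SCHEMES: Dict[str, CalibrationScheme] = {
    s.name: s
    for s in (
        CalibrationScheme("shallow", ("1", "2", "3")),
        CalibrationScheme("intermediate", ("4", "5", "6")),
        CalibrationScheme("deep", ("8", "10", "11")),
        CalibrationScheme("dispersed-I", ("2", "5", "8")),
        CalibrationScheme("dispersed-II", ("1", "4", "10")),
        CalibrationScheme("dispersed-III", ("3", "6", "11")),
    )
}


@dataclass(frozen=True)
class DateEstimate:
    node_id: str
    median: float  # Myr
    lower: float
    upper: float
    n_replicates: int
    role: str = "predicted"  # or "calibrator"

    def __post_init__(self):
        if not self.lower <= self.median <= self.upper:
            raise ValueError("require lower <= median <= upper")


def _summary(node_id: str, vals: np.ndarray, role: str = "predicted") -> DateEstimate:
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"node {node_id}: no finite replicate estimates")
    return DateEstimate(
        node_id=node_id,
        median=float(np.median(vals)),
        lower=float(np.percentile(vals, 2.5)),
        upper=float(np.percentile(vals, 97.5)),
        n_replicates=int(vals.size),
        role=role,
    )


def rate_at_timescale(fits: Sequence[FitResult], t_years: float) -> Dict[str, float]:
    """Ensemble summary of the average rate at timescale ``t_years``.

    Returns median and central 2.5/97.5 percentiles in
    substitutions/site/year.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    if t_years <= 0:
        raise ValueError("t must be > 0")
    vals = np.array(
        [average_rate(f.params.to_unit("year"), t_years) for f in fits if f is not None]
    )
    return {
        "median": float(np.median(vals)),
        "q2.5": float(np.percentile(vals, 2.5)),
        "q97.5": float(np.percentile(vals, 97.5)),
        "n": int(vals.size),
    }


def infer_dates(
    fits: Sequence[Optional[FitResult]],
    s_draws: Dict[str, np.ndarray],
    diagnostics: Optional[dict] = None,
) -> List[DateEstimate]:
    """Infer node ages from substitutions via an ensemble of LSE_t fits.

    ``s_draws`` maps node_id -> one s value per replicate, co-indexed with
    ``fits`` (replicate i of the fit ensemble is paired with s draw i).
    Replicates where the fit is missing, or where s exceeds an EX fit's
    saturation bound, contribute no estimate and are counted in
    ``diagnostics`` if a dict is supplied.
    """
    for f in fits:
        if f is not None and f.criterion != "LSE_t":
            raise ValueError("date inference needs fits under the LSE_t criterion")
    out = []
    for nid, draws in s_draws.items():
        draws = np.asarray(draws, dtype=float)
        if draws.size != len(fits):
            raise ValueError(
                f"node {nid}: {draws.size} s draws for {len(fits)} fits "
                "(replicates are paired by index)"
            )
        if np.any(draws <= 0):
            raise ValueError(f"node {nid}: s draws must be positive")
        est = np.full(len(fits), np.nan)
        n_unreachable = 0
        for i, (f, s) in enumerate(zip(fits, draws)):
            if f is None:
                continue
            if s >= ex_max_substitutions(f.params):
                n_unreachable += 1
                continue
            est[i] = invert_time(f.params, s)
        if diagnostics is not None:
            diagnostics[nid] = {
                "n_missing_fit": sum(f is None for f in fits),
                "n_unreachable": n_unreachable,
            }
        out.append(_summary(nid, est))
    return out


def run_calibration_scheme(
    dataset: CospeciationDataset,
    scheme: Union[str, CalibrationScheme],
    kind: Union[str, RateModelKind] = RateModelKind.PL,
    n_sets: int = 1500,
    seed=0,
    n_starts: int = 6,
    allow_three_param: bool = False,
) -> List[DateEstimate]:
    """Fit the model to the scheme's three calibrating nodes only and
    predict every other dated node's age.

    The reference ages of non-calibrating nodes never enter the fit.  The
    three calibrating nodes are echoed in the output with role
    ``"calibrator"`` (their own resampled ages summarised, not predictions).
    Three-parameter kinds (VEX, VPL) interpolate 3 points exactly and are
    refused unless ``allow_three_param=True``.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    kind = RateModelKind(kind if isinstance(kind, RateModelKind) else str(kind).upper())
    if kind.has_offset and not allow_three_param:
        raise ValueError(
            f"{kind.value} has 3 free parameters and would interpolate 3 "
            "calibrating points exactly; pass allow_three_param=True to force"
        )
    dated = dataset.dated_ids
    missing = [n for n in scheme.calibrating_nodes if n not in dated]
    if missing:
        raise ValueError(f"scheme {scheme.name}: nodes {missing} are not dated")
    targets = [n for n in dated if n not in scheme.calibrating_nodes]

    sets = assemble_rate_sets(dataset, n_sets, seed)
    ss = np.random.SeedSequence(np.random.default_rng(seed).integers(0, 2**31 - 1))
    seeds = ss.generate_state(n_sets)
    pred = {nid: np.full(n_sets, np.nan) for nid in targets}
    calib = {nid: np.full(n_sets, np.nan) for nid in scheme.calibrating_nodes}
    n_failed = 0
    for m, pts in enumerate(sets):
        pos = {nid: j for j, nid in enumerate(pts.node_ids)}
        sub = RateSampleSet.from_ts(
            scheme.calibrating_nodes,
            [pts.t_myr[pos[n]] for n in scheme.calibrating_nodes],
            [pts.s[pos[n]] for n in scheme.calibrating_nodes],
        )
        try:
            fit = fit_time_model(
                sub, kind, n_starts=n_starts, seed=int(seeds[m]),
                allow_interpolating=True,
            )
        except FitError:
            n_failed += 1
            continue
        for nid in scheme.calibrating_nodes:
            calib[nid][m] = pts.t_myr[pos[nid]]
        for nid in targets:
            s = pts.s[pos[nid]]
            if s < ex_max_substitutions(fit.params):
                pred[nid][m] = invert_time(fit.params, s)
    out = [_summary(nid, calib[nid], role="calibrator") for nid in scheme.calibrating_nodes]
    out += [_summary(nid, pred[nid]) for nid in targets]
    return out
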