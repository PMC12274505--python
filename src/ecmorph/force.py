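"""Force-distance curve analysis: baseline fit, contact point, first-slope
cortical stiffness, and single-cell adhesion force / energy.

Conventions
-----------
Positions are in nm with larger values further from the surface; forces in
pN. Cortical stiffness is reported as the slope (pN/nm) of the first linear
segment of the approach curve past the contact point — an operational cortex
readout, deliberately not a Hertzian modulus. Adhesion metrics come from the
baseline-corrected retraction: the magnitude of the most negative force, and
the work of the negative-force region (1 pN·nm = 1e-21 J).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .containers import ForceCurve

__all__ = [
    "NoContactError",
    "BaselineFit",
    "StiffnessResult",
    "AdhesionResult",
    "fit_baseline",
    "find_contact_point",
    "first_slope_stiffness",
    "adhesion_metrics",
    "aggregate_cells",
]

PN_NM_TO_J = 1e-21
DEFAULT_K_SIGMA = 3.0
DEFAULT_RUN_LENGTH = 10
MIN_CURVES = {"stiffness": 6, "adhesion": 20}


class NoContactError(RuntimeError):
    """Raised when no sustained departure from the baseline is found
    (flat or failed curve)."""


@dataclass
class BaselineFit:
    intercept_pn: float
    slope_pn_per_nm: float
    noise_sd_pn: float

    def evaluate(self, position_nm: np.ndarray) -> np.ndarray:
        return self.intercept_pn + self.slope_pn_per_nm * np.asarray(position_nm)


@dataclass
class StiffnessResult:
    contact_point_nm: float
    slope_pn_per_nm: float
    fit_window_nm: tuple[float, float]
    residual_rms_pn: float
    baseline: BaselineFit
    n_samples: int


@dataclass
class AdhesionResult:
    max_pulling_force_pn: float
    adhesion_energy_J: float
    n_samples_in_event: int
    baseline: BaselineFit


def _off_contact_first(segment: np.ndarray) -> np.ndarray:
    """Reorder a segment so index 0 is the off-contact end (largest position)."""
    return segment if segment[0, 0] > segment[-1, 0] else segment[::-1]


def fit_baseline(
    curve: ForceCurve, segment: str = "approach", fraction: float = 0.3
) -> BaselineFit:
    """Least-squares line through the off-contact fraction of a segment.

    The off-contact end is the large-position end (probe far from the
    surface). ``noise_sd`` is the RMS residual about the fitted line; it
    scales the contact-detection threshold and the zero-adhesion band.
    """
    if not (0 < fraction <= 0.9):
        raise ValueError("fraction must be in (0, 0.9]")
    seg = _off_contact_first(curve.segment(segment))
    n = max(int(round(fraction * seg.shape[0])), 0)
    if n < 10:
        raise ValueError(f"baseline fit needs >= 10 samples, got {n}")
    x, y = seg[:n, 0], seg[:n, 1]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return BaselineFit(float(intercept), float(slope), float(np.sqrt(np.mean(resid**2))))


def _hinge_breakpoint(x: np.ndarray, f: np.ndarray) -> float:
    """Least-squares breakpoint of the hinge model f = max(0, k*(x0 - x)).

    For every candidate x0 = x_j the optimal non-negative slope and the
    resulting SSE follow in closed form from prefix/suffix sums; the
    returned x0 minimizes the SSE. Exact on noiseless piecewise-linear
    curves whose kink lies on the sample grid.
    """
    n = x.size
    sfx_f2 = np.cumsum((f**2)[::-1])[::-1]
    sfx_f = np.cumsum(f[::-1])[::-1]
    sfx_fx = np.cumsum((f * x)[::-1])[::-1]
    sfx_x = np.cumsum(x[::-1])[::-1]
    sfx_x2 = np.cumsum((x**2)[::-1])[::-1]
    sfx_n = np.arange(n, 0, -1)
    pre_f2 = np.concatenate([[0.0], np.cumsum(f**2)[:-1]])
    num = x * sfx_f - sfx_fx  # sum_i f_i * (x_j - x_i) over in-contact i
    den = sfx_x2 - 2 * x * sfx_x + sfx_n * x**2
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where((den > 0) & (num > 0), num**2 / den, 0.0)
    sse = pre_f2 + sfx_f2 - gain
    return float(x[int(np.argmin(sse))])


def find_contact_point(
    curve: ForceCurve,
    baseline: BaselineFit | None = None,
    k_sigma: float = DEFAULT_K_SIGMA,
    run_length: int = DEFAULT_RUN_LENGTH,
    baseline_fraction: float = 0.3,
    refine: Literal["hinge", "interpolate", "sample"] = "hinge",
) -> float:
    """Detect the contact point on the approach segment.

    Walking from the off-contact end toward the surface, contact is flagged
    where the baseline-corrected force first rises above
    ``k_sigma * noise_sd`` and stays above it for ``run_length`` consecutive
    samples; absence of such a run raises :class:`NoContactError` (flat or
    failed curve). Because the flagged sample sits where the force has
    already cleared the noise band — past the true contact — the position
    is then refined. The default ``refine="hinge"`` fits the piecewise
    model (zero baseline, then a linear rise) to the whole corrected
    approach and returns the least-squares breakpoint, which is exact on
    noiseless ramps and nearly unbiased under noise. ``"interpolate"``
    returns the sub-sample threshold crossing (biased deeper by roughly
    threshold/slope); ``"sample"`` the raw run-start sample position.
    """
    if baseline is None:
        baseline = fit_baseline(curve, "approach", baseline_fraction)
    seg = _off_contact_first(curve.approach)
    corrected = seg[:, 1] - baseline.evaluate(seg[:, 0])
    threshold = k_sigma * baseline.noise_sd_pn

    above = corrected > threshold
    run = 0
    start = -1
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= run_length:
            start = i - run_length + 1
            break
    if start < 0:
        raise NoContactError(
            f"no run of {run_length} samples above {threshold:.3g} pN; flat or failed curve"
        )
    if refine == "sample" or (refine == "interpolate" and start == 0):
        return float(seg[start, 0])
    if refine == "interpolate":
        x0, x1 = seg[start - 1, 0], seg[start, 0]
        f0, f1 = corrected[start - 1], corrected[start]
        t = 0.0 if f1 == f0 else (threshold - f0) / (f1 - f0)
        return float(x0 + t * (x1 - x0))
    return _hinge_breakpoint(seg[:, 0], corrected)


def first_slope_stiffness(
    curve: ForceCurve,
    window_nm: float = 200.0,
    contact_point_nm: float | None = None,
    baseline: BaselineFit | None = None,
    k_sigma: float = DEFAULT_K_SIGMA,
    run_length: int = DEFAULT_RUN_LENGTH,
    baseline_fraction: float = 0.3,
    min_samples: int = 10,
) -> StiffnessResult:
    """Cortical stiffness: least-squares slope of corrected force vs.
    indentation depth over the first ``window_nm`` past the contact point.

    The fit includes an intercept, which makes the slope estimate exactly
    invariant to the residual force offset at the detected contact point
    (and hence to modest contact-detection bias on linear-regime curves).
    ``contact_point_nm`` may be supplied externally (e.g. an instrument
    trigger); otherwise it is detected from the baseline.
    """
    if window_nm <= 0:
        raise ValueError("window_nm must be positive")
    if baseline is None:
        baseline = fit_baseline(curve, "approach", baseline_fraction)
    if contact_point_nm is None:
        contact_point_nm = find_contact_point(
            curve, baseline, k_sigma=k_sigma, run_length=run_length
        )
    seg = _off_contact_first(curve.approach)
    depth = contact_point_nm - seg[:, 0]  # indentation, increasing past contact
    corrected = seg[:, 1] - baseline.evaluate(seg[:, 0])
    sel = (depth >= 0) & (depth <= window_nm)
    if int(sel.sum()) < min_samples:
        raise ValueError(
            f"only {int(sel.sum())} samples in the {window_nm} nm fit window; "
            f">= {min_samples} required"
        )
    d, f = depth[sel], corrected[sel]
    slope, intercept = np.polyfit(d, f, 1)
    resid = f - (intercept + slope * d)
    return StiffnessResult(
        contact_point_nm=float(contact_point_nm),
        slope_pn_per_nm=float(slope),
        fit_window_nm=(float(contact_point_nm), float(contact_point_nm - window_nm)),
        residual_rms_pn=float(np.sqrt(np.mean(resid**2))),
        baseline=baseline,
        n_samples=int(sel.sum()),
    )


def adhesion_metrics(
    curve: ForceCurve,
    baseline: BaselineFit | None = None,
    k_sigma: float = DEFAULT_K_SIGMA,
    run_length: int = DEFAULT_RUN_LENGTH,
    baseline_fraction: float = 0.3,
) -> AdhesionResult:
    """Adhesion force and energy from the baseline-corrected retraction.

    ``max_pulling_force`` is the magnitude of the most negative corrected
    force; ``adhesion_energy`` the trapezoidal integral of the negative
    force over retraction distance, in joules. Samples inside the
    ±``k_sigma``·noise_sd baseline band contribute nothing, and an adhesion
    event is only recognized when at least ``run_length`` consecutive
    samples sit below the band — isolated noise excursions are never
    rectified into spurious adhesion, and any dip shallow enough to hide in
    the band yields exactly zero. On noiseless curves the band collapses
    and every true negative-force region counts.
    """
    if baseline is None:
        baseline = fit_baseline(curve, "retract", baseline_fraction)
    seg = _off_contact_first(curve.retract)[::-1]  # near -> far, positions increasing
    pos = seg[:, 0]
    corrected = seg[:, 1] - baseline.evaluate(pos)
    band = k_sigma * baseline.noise_sd_pn

    below = corrected < -band
    # sustained-run event criterion, mirroring contact detection
    run = 0
    sustained = False
    for flag in below:
        run = run + 1 if flag else 0
        if run >= run_length:
            sustained = True
            break
    if not sustained:
        return AdhesionResult(0.0, 0.0, 0, baseline)

    pulling = np.where(below, -corrected, 0.0)
    energy_pn_nm = float(np.trapezoid(pulling, pos))
    return AdhesionResult(
        max_pulling_force_pn=float(np.max(pulling)),
        adhesion_energy_J=energy_pn_nm * PN_NM_TO_J,
        n_samples_in_event=int(below.sum()),
        baseline=baseline,
    )


def aggregate_cells(
    results: pd.DataFrame | Iterable[dict],
    value_column: str,
    cell_column: str = "cell_id",
    min_curves: int = 6,
    group_labels: dict | None = None,
) -> pd.DataFrame:
    """Per-cell means of per-curve readouts.

    One row per cell with its mean, curve count, and an ``included`` flag;
    cells with fewer than ``min_curves`` curves are flagged and excluded
    from downstream statistics (6 curves/cell for stiffness, 20 for
    adhesion by convention). ``group_labels`` optionally maps cell ids to
    experimental groups; a cell id missing from it is an error. The
    returned table feeds directly into the group-comparison harness.
    """
    df = pd.DataFrame(results)
    if cell_column not in df.columns:
        raise KeyError(f"results have no '{cell_column}' column")
    if value_column not in df.columns:
        raise KeyError(f"results have no '{value_column}' column")
    if df[cell_column].isna().any():
        raise ValueError("every result must carry a cell id")
    grouped = df.groupby(cell_column, sort=True)[value_column]
    out = grouped.agg(mean="mean", n_curves="count").reset_index()
    out["included"] = out["n_curves"] >= min_curves
    if group_labels is not None:
        unknown = set(out[cell_column]) - set(group_labels)
        if unknown:
            raise KeyError(f"cells without a group label: {sorted(unknown)}")
        out["group"] = out[cell_column].map(group_labels)
    return out
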