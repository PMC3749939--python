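"""Fluorescence-recovery-after-photobleaching (FRAP) analysis.

A FRAP experiment bleaches a nuclear sub-region and follows the return of
fluorescence as unbleached molecules exchange into it.  After normalizing
each trace to its maximum pre-bleach intensity, the mobile fraction is

    MF = (I_sat - I_dip) / (1 - I_dip)

where I_dip is the intensity immediately after the bleach pulse and I_sat
the intensity at the end of the monitored recovery.  MF = 1 means full
exchange during the window; MF = 0 means the bleached pool is immobile on
that timescale.  An optional single-exponential fit
I(t) = I_dip + A (1 - exp(-k t)) provides a rate constant and a
plateau-extrapolated mobile fraction.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats


@dataclass
class FrapCurve:
    """One cell's intensity time course with the bleach frame index."""

    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray
    bleach_index: int  # index of the first post-bleach frame
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities differ in length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")
        if not 1 <= self.bleach_index < len(self.times):
            raise ValueError("bleach_index must leave >= 1 pre-bleach frame")

    @property
    def pre_bleach(self) -> np.ndarray:
        return self.intensities[: self.bleach_index]

    @property
    def post_bleach(self) -> np.ndarray:
        return self.intensities[self.bleach_index :]

    @property
    def post_times(self) -> np.ndarray:
        """Times of post-bleach frames, re-zeroed at the dip frame."""
        t = self.times[self.bleach_index :]
        return t - t[0]


@dataclass
class MobileFractionEstimate:
    mf: float
    i_dip: float
    i_sat: float
    cell_id: str = ""


@dataclass
class GroupComparison:
    """Unpaired equal-variance two-sample t comparison of mobile fractions."""

    labels: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    ns: tuple[int, int]
    t_stat: float
    p_value: float

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Mobile-fraction group comparison (unpaired t-test)\n")
        buf.write("=" * 50 + "\n")
        for lab, m, se, n in zip(self.labels, self.means, self.sems, self.ns):
            buf.write(f"{lab:>12s}: MF = {m:.4f} +/- {se:.4f} (SEM), n = {n}\n")
        buf.write(f"t = {self.t_stat:.4f}, two-sided p = {self.p_value:.3g}\n")
        return buf.getvalue()


def normalize_curve(raw: FrapCurve) -> FrapCurve:
    """Divide by the maximum pre-bleach intensity (background correction)."""
    peak = float(raw.pre_bleach.max())
    if peak <= 0:
        raise ValueError("non-positive pre-bleach maximum; cannot normalize")
    return replace(raw, intensities=raw.intensities / peak)


def mobile_fraction(curve: FrapCurve, tail_window: int = 1) -> MobileFractionEstimate:
    """Endpoint mobile-fraction estimator on a normalized curve.

    I_dip is the first post-bleach value; I_sat the mean of the last
    ``tail_window`` frames; MF = (I_sat - I_dip)/(1 - I_dip).
    """
    post = curve.post_bleach
    if tail_window < 1 or tail_window > len(post):
        raise ValueError("tail_window must lie in [1, number of post-bleach frames]")
    i_dip = float(post[0])
    i_sat = float(post[-tail_window:].mean())
    if i_dip >= 1.0:
        raise ValueError("I_dip >= 1: no bleach detected")
    mf = (i_sat - i_dip) / (1.0 - i_dip)
    return MobileFractionEstimate(mf=mf, i_dip=i_dip, i_sat=i_sat, cell_id=curve.cell_id)


def mean_recovery_curve(
    curves: list[FrapCurve],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average individual recovery curves aligned at the bleach frame.

    Pre-bleach frame counts may differ; the common grid spans the minimum
    pre- and post-bleach extent.  Returns (relative frame times, mean, SEM).
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 curves to average")
    n_pre = min(c.bleach_index for c in curves)
    n_post = min(len(c.post_bleach) for c in curves)
    ref = None
    rows = []
    for c in curves:
        sl = slice(c.bleach_index - n_pre, c.bleach_index + n_post)
        t = c.times[sl] - c.times[c.bleach_index]
        if ref is None:
            ref = t
        elif not np.allclose(t, ref):
            raise ValueError("curves do not share a common time grid")
        rows.append(c.intensities[sl])
    arr = np.vstack(rows)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return ref, mean, sem


def compare_mobile_fractions(
    group_a: list[float] | list[MobileFractionEstimate],
    group_b: list[float] | list[MobileFractionEstimate],
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Equal-variance unpaired two-sample t-test between MF groups."""
    a = np.asarray([m.mf if isinstance(m, MobileFractionEstimate) else m for m in group_a])
    b = np.asarray([m.mf if isinstance(m, MobileFractionEstimate) else m for m in group_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        # identical constant groups: t = 0, p = 1 by convention
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(p):
            raise ValueError("zero pooled variance; t-test undefined")
    return GroupComparison(
        labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sems=(
            float(a.std(ddof=1) / np.sqrt(len(a))),
            float(b.std(ddof=1) / np.sqrt(len(b))),
        ),
        ns=(len(a), len(b)),
        t_stat=float(t_stat),
        p_value=float(p),
    )


@dataclass
class RecoveryFitResults:
    """Single-exponential recovery fit for one cell."""

    mf: float
    rate_constant: float
    i_dip: float
    converged: bool
    message: str = ""
    stderr: dict[str, float] | None = None
    cell_id: str = ""

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Exponential recovery fit\n")
        buf.write("=" * 40 + "\n")
        buf.write(f"cell:       {self.cell_id or '(unlabelled)'}\n")
        buf.write(f"MF (fit):   {self.mf:.4f}\n")
        buf.write(f"k (1/s):    {self.rate_constant:.5f}\n")
        buf.write(f"I_dip:      {self.i_dip:.4f}\n")
        buf.write(f"converged:  {self.converged}  {self.message}\n")
        return buf.getvalue()


class RecoveryModel:
    """Single-exponential FRAP recovery model for one normalized curve.

    fit() least-squares fits I(t) = i_dip + A (1 - exp(-k t)) to the
    post-bleach segment and reports MF_fit = A / (1 - i_dip).
    """

    def __init__(self, curve: FrapCurve) -> None:
        if len(curve.post_bleach) < 5:
            raise ValueError("need >= 5 post-bleach frames to fit")
        self.curve = curve

    def fit(self) -> RecoveryFitResults:
        t = self.curve.post_times
        y = self.curve.post_bleach

        def model(tt, i_dip, amp, k):
            return i_dip + amp * (1.0 - np.exp(-k * tt))

        span = float(y[-1] - y[0])
        p0 = [float(y[0]), max(span, 1e-6), 1.0 / max(t[-1] / 3.0, 1e-9)]
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=10_000)
        except RuntimeError as exc:  # non-convergence
            est = mobile_fraction(self.curve, tail_window=1)
            return RecoveryFitResults(
                mf=est.mf, rate_constant=np.nan, i_dip=est.i_dip,
                converged=False, message=f"fit failed: {exc}",
                cell_id=self.curve.cell_id,
            )
        i_dip, amp, k = popt
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        mf = amp / (1.0 - i_dip)
        # a flat curve leaves k unidentifiable: flag rather than fail
        identifiable = abs(amp) > 5 * perr[1] if np.isfinite(perr[1]) else False
        return RecoveryFitResults(
            mf=float(mf),
            rate_constant=float(k),
            i_dip=float(i_dip),
            converged=bool(identifiable),
            message="" if identifiable else "recovery amplitude ~ 0; k unidentifiable",
            stderr={"i_dip": float(perr[0]), "amp": float(perr[1]), "k": float(perr[2])},
            cell_id=self.curve.cell_id,
        )


def fit_recovery(curve: FrapCurve) -> RecoveryFitResults:
    """Convenience wrapper around :class:`RecoveryModel`."""
    return RecoveryModel(curve).fit()
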