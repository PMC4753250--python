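"""dF/F quantification of calcium-imaging traces and water-baseline testing.

A measurement is a wash / stimulation / wash protocol (by default 100 + 200
+ 100 frames at 85 ms per frame).  The response measure is

    dF/F (%) = 100 * (F_peak - F0) / F0

with F0 the mean of five frames of the unstimulated (wash) period and
F_peak the maximum intensity during stimulation.  Because F_peak is a
maximum over a noisy window, even water-only applications yield a small
positive dF/F; responses to tastants are therefore tested against each
neuron class's *water baseline* — the distribution of dF/F values when only
water was applied — rather than against zero, which also absorbs
photobleaching drift.  Comparisons use the Wilcoxon signed-rank test when
tastant and water measurements are paired, falling back to the rank-sum
test otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import FluorescenceTrace
from .errors import DataError, InsufficientDataError, ParameterError

__all__ = [
    "DeltaFResult",
    "WaterBaseline",
    "ResponseTest",
    "compute_dff",
    "water_baseline",
    "test_response",
    "significance_stars",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaFResult:
    """dF/F summary for one trace."""

    roi_id: str
    f0: float
    f_peak: float
    dff_percent: float
    peak_frame: int


@dataclass(frozen=True)
class WaterBaseline:
    """The dF/F sample observed under water-only stimulation for one neuron
    class, kept as a distribution for downstream testing."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass(frozen=True)
class ResponseTest:
    """Outcome of a tastant-vs-water comparison."""

    statistic: float
    p_value: float
    stars: str
    method: str
    n: int


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional significance string:
    ``***`` for P<0.001, ``**`` for P<0.01, ``*`` for P<0.05, else empty."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compute_dff(
    trace: FluorescenceTrace,
    f0_frames: np.ndarray | None = None,
    smooth_frames: int = 1,
) -> DeltaFResult:
    """Compute dF/F (%) for one trace.

    F0 is the mean over five designated unstimulated frames — by default
    the five frames immediately preceding stimulation onset, the choice
    that minimizes bleaching bias between F0 and the response window.
    F_peak is the raw maximum over the stimulation window ``[n_pre, n_pre +
    n_stim)``; ``smooth_frames > 1`` applies a centered moving average
    before the maximum (off by default, since the protocol definition uses
    the raw peak).
    """
    n_pre = trace.n_pre_frames
    if f0_frames is None:
        f0_frames = np.arange(n_pre - 5, n_pre)
    f0_frames = np.asarray(f0_frames, dtype=np.int64)
    if f0_frames.min() < 0 or f0_frames.max() >= n_pre:
        raise ParameterError(
            "f0_frames must lie in the pre-stimulation window "
            f"[0, {n_pre}) for trace {trace.roi_id!r}"
        )
    f0 = float(trace.intensity[f0_frames].mean())
    if f0 <= 0:
        raise DataError(f"non-positive F0 ({f0:g}) in trace {trace.roi_id!r}")

    stim = trace.intensity[trace.stim_slice]
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        stim = np.convolve(stim, kernel, mode="same")
    peak_local = int(np.argmax(stim))
    f_peak = float(stim[peak_local])
    return DeltaFResult(
        roi_id=trace.roi_id,
        f0=f0,
        f_peak=f_peak,
        dff_percent=100.0 * (f_peak - f0) / f0,
        peak_frame=n_pre + peak_local,
    )


def water_baseline(responses: np.ndarray) -> WaterBaseline:
    """Collect water-only dF/F values into a baseline distribution.

    The sample is kept whole (not collapsed to a scalar) so response tests
    can compare full distributions; at least three water measurements are
    required.
    """
    values = np.asarray(responses, dtype=np.float64).ravel()
    if values.size == 0:
        raise DataError("empty water-baseline sample")
    if values.size < 3:
        raise InsufficientDataError(
            f"water baseline needs >= 3 measurements, got {values.size}"
        )
    if not np.isfinite(values).all():
        raise DataError("non-finite value in water-baseline sample")
    return WaterBaseline(values=values)


def test_response(
    tastant_dff: np.ndarray,
    water_dff: np.ndarray | WaterBaseline,
    paired: bool | None = None,
    alternative: str = "two-sided",
) -> ResponseTest:
    """Compare a tastant dF/F sample against the water baseline.

    When the samples are paired (same animals measured with water and with
    the tastant, matched by position) the Wilcoxon signed-rank test on the
    paired differences is used; otherwise the rank-sum (Mann-Whitney) test,
    with a logged notice.  ``paired=None`` infers pairing from equal sample
    sizes.  Exact p-values are used for small samples without ties, the
    normal approximation otherwise.
    """
    if isinstance(water_dff, WaterBaseline):
        water = water_dff.values
    else:
        water = np.asarray(water_dff, dtype=np.float64).ravel()
    tastant = np.asarray(tastant_dff, dtype=np.float64).ravel()
    if paired is None:
        paired = tastant.size == water.size
    if paired and tastant.size != water.size:
        raise ParameterError("paired test requires equal sample sizes")
    if min(tastant.size, water.size) < 3:
        raise InsufficientDataError("need >= 3 measurements per sample")

    if paired:
        diffs = tastant - water
        if np.all(diffs == 0):
            # degenerate: identical samples carry no evidence either way
            return ResponseTest(0.0, 1.0, "", "wilcoxon-signed-rank", tastant.size)
        mode = "exact" if tastant.size < 25 else "approx"
        res = stats.wilcoxon(tastant, water, alternative=alternative, method=mode,
                             zero_method="wilcox")
        method = "wilcoxon-signed-rank"
        n = tastant.size
    else:
        logger.info("unpaired samples (%d vs %d): falling back to rank-sum test",
                    tastant.size, water.size)
        has_ties = np.unique(np.concatenate([tastant, water])).size < tastant.size + water.size
        mode = "exact" if (min(tastant.size, water.size) < 25 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(tastant, water, alternative=alternative, method=mode)
        method = "wilcoxon-rank-sum"
        n = min(tastant.size, water.size)

    p = float(res.pvalue)
    return ResponseTest(float(res.statistic), p, significance_stars(p), method, n)
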