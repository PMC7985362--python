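"""Per-sample statistics: IPR spectra, Q-score, detection calls and curves.

The Q-score of a sample is the sum over the frequency panel of the
per-bead-averaged IPR — equivalently the mean over beads of each bead's
summed IPR (the two orders of summation are algebraically identical and
asserted on every call).  Samples are always interpreted relative to a
DNA-free bare-bead control measured in the same run: a sample is called
*detected* when its mean Q-score exceeds the control mean by more than two
control standard errors AND a Welch two-sample test on the per-bead Q
values is significant.

Standard curves are ordinary least squares of Q on log10(quantity, fmol)
over an automatically selected linear range; the bead binding capacity
saturates the response at high load, so the top of a dilution series is
excluded by the range search.  A full-range polynomial is retained for
descriptive plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect import EventTable


@dataclass(frozen=True)
class IPRSpectrum:
    """Per-frequency mean IPR and standard error over a sample's beads."""

    mean: np.ndarray
    sem: np.ndarray
    n_beads: int

    def __post_init__(self) -> None:
        if self.mean.shape != self.sem.shape:
            raise ValueError("mean and sem must have equal length")
        if np.any(self.sem < 0) or self.n_beads < 1:
            raise ValueError("sem must be >= 0 and n_beads >= 1")


@dataclass(frozen=True)
class QScoreResult:
    """Sample Q-score with dispersion and per-bead values."""

    q_mean: float
    q_se: float
    n_beads: int
    per_bead_q: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_beads != self.per_bead_q.size:
            raise ValueError("n_beads must equal per_bead_q length")


@dataclass(frozen=True)
class DetectionCall:
    """Control-calibrated detection decision for one sample."""

    detected: bool
    p_value: float
    margin: float  # q_mean(sample) - [q_mean(control) + 2 * q_se(control)]
    delta_q: float  # q_mean(sample) - q_mean(control)


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear standard curve ``Q = slope * log10(fmol) + intercept``."""

    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]  # fmol
    poly_coeffs: tuple[float, ...] = ()  # full-range descriptive fit
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.linear_range[0] < self.linear_range[1]:
            raise ValueError("linear_range must satisfy low < high")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, quantity_fmol: float) -> float:
        return self.slope * np.log10(quantity_fmol) + self.intercept


@dataclass(frozen=True)
class QuantityEstimate:
    """Inverted standard-curve estimate for an unknown sample."""

    quantity_fmol: float
    in_linear_range: bool


@dataclass(frozen=True)
class LengthFit:
    """Linear fit of Q-score against fragment length at equal molarity."""

    slope: float  # Q per bp
    intercept: float
    r_squared: float


def ipr_spectrum(events: EventTable) -> IPRSpectrum:
    """Per-frequency mean IPR and SEM over non-doublet events."""
    ipr = events.ipr_matrix()
    n = ipr.shape[0]
    if n < 1:
        raise ValueError("event table holds no accepted events")
    mean = ipr.mean(axis=0)
    if n == 1:
        warnings.warn("single-event sample: SEM set to 0", stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = ipr.std(axis=0, ddof=1) / np.sqrt(n)
    return IPRSpectrum(mean=mean, sem=sem, n_beads=n)


def q_score(events: EventTable, label: str = "") -> QScoreResult:
    """Sample Q-score: sum over the panel of per-bead-averaged IPR."""
    ipr = events.ipr_matrix()
    n = ipr.shape[0]
    if n < 1:
        raise ValueError("event table holds no accepted events")
    per_bead = ipr.sum(axis=1)
    q_mean = float(per_bead.mean())
    # identity: mean of per-bead sums == sum of per-frequency means
    q_alt = float(ipr.mean(axis=0).sum())
    assert abs(q_mean - q_alt) <= 1e-9 * max(1.0, abs(q_mean)), "Q-score identity violated"
    q_se = float(per_bead.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return QScoreResult(q_mean=q_mean, q_se=q_se, n_beads=n, per_bead_q=per_bead, label=label)


def detection_call(
    sample: QScoreResult, control: QScoreResult, alpha: float = 0.05
) -> DetectionCall:
    """Call a sample against its same-run bare-bead control.

    Detected requires both (i) the sample mean above the control mean by
    more than two control standard errors and (ii) a significant Welch
    unequal-variance two-sample test on per-bead Q values.
    """
    if sample.n_beads < 2 or control.n_beads < 2:
        raise ValueError("detection requires >= 2 beads in sample and control")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    margin = sample.q_mean - (control.q_mean + 2.0 * control.q_se)
    delta_q = sample.q_mean - control.q_mean
    res = stats.ttest_ind(sample.per_bead_q, control.per_bead_q, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # degenerate: zero variance in both groups
        p = 1.0 if sample.q_mean == control.q_mean else 0.0
    return DetectionCall(detected=bool(margin > 0 and p < alpha), p_value=p,
                         margin=float(margin), delta_q=float(delta_q))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return float(slope), float(intercept), float(r**2)


def fit_standard_curve(
    points: list[tuple[float, QScoreResult]],
    r2_min: float = 0.95,
    poly_degree: int = 3,
    fixed_range: tuple[float, float] | None = None,
) -> StandardCurve:
    """Fit Q vs log10(quantity) over an auto-selected linear range.

    ``points`` are (quantity in fmol, Q-score result) pairs; quantities
    must be positive and distinct (the zero-quantity control cannot enter
    a log fit).  The linear range is the longest contiguous run of at
    least three concentrations (in rank order) whose OLS fit reaches
    ``r2_min``; ties are broken by the higher r-squared.  A saturated
    plateau at the top of a dilution series therefore drops out of the
    range.  A degree-``poly_degree`` polynomial over the full series is
    stored for descriptive plotting.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs >= 3 points")
    q = np.array([float(p[0]) for p in points])
    y = np.array([p[1].q_mean for p in points])
    if np.any(q <= 0):
        raise ValueError("quantities must be > 0 for a log fit")
    if np.unique(q).size != q.size:
        raise ValueError("quantities must be distinct")
    order = np.argsort(q)
    q, y = q[order], y[order]
    logq = np.log10(q)

    if fixed_range is not None:
        mask = (q >= fixed_range[0]) & (q <= fixed_range[1])
        if mask.sum() < 3:
            raise ValueError("fixed_range must contain >= 3 points")
        slope, intercept, r2 = _ols(logq[mask], y[mask])
        lo, hi = float(q[mask].min()), float(q[mask].max())
        n_pts = int(mask.sum())
    else:
        best = None  # (count, r2, i, j)
        for i in range(len(q)):
            for j in range(i + 3, len(q) + 1):
                _, _, r2 = _ols(logq[i:j], y[i:j])
                if r2 >= r2_min:
                    cand = (j - i, r2, i, j)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        if best is None:
            raise ValueError(
                f"no contiguous run of >= 3 concentrations reaches r^2 >= {r2_min}"
            )
        _, _, i, j = best
        slope, intercept, r2 = _ols(logq[i:j], y[i:j])
        lo, hi = float(q[i]), float(q[j - 1])
        n_pts = j - i

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(logq, y, min(poly_degree, len(q) - 1))
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        linear_range=(lo, hi),
        poly_coeffs=tuple(float(c) for c in coeffs),
        n_points=n_pts,
    )


def quantify_unknown(q: QScoreResult, curve: StandardCurve) -> QuantityEstimate:
    """Invert the linear fit: ``10 ** ((q_mean - intercept) / slope)``."""
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve")
    est = 10.0 ** ((q.q_mean - curve.intercept) / curve.slope)
    in_range = curve.linear_range[0] <= est <= curve.linear_range[1]
    return QuantityEstimate(quantity_fmol=float(est), in_linear_range=bool(in_range))


def fit_length_response(
    points: list[tuple[float, float, QScoreResult]], rtol: float = 1e-6
) -> LengthFit:
    """OLS of Q-score on fragment length (bp) at equal molar quantity.

    ``points`` are (length_bp, quantity_fmol, Q-score result) triples; the
    quantities document the equal-molarity design and must agree to
    relative tolerance ``rtol``.
    """
    if len(points) < 3:
        raise ValueError("length response needs >= 3 lengths")
    lengths = np.array([p[0] for p in points], dtype=float)
    quants = np.array([p[1] for p in points], dtype=float)
    if np.unique(lengths).size != lengths.size:
        raise ValueError("lengths must be distinct")
    if np.any(np.abs(quants - quants[0]) > rtol * np.abs(quants[0])):
        raise ValueError("length response requires equal molar quantities")
    y = np.array([p[2].q_mean for p in points])
    slope, intercept, r2 = _ols(lengths, y)
    return LengthFit(slope=slope, intercept=intercept, r_squared=r2)


def subsample_power(
    sample: EventTable,
    control: EventTable,
    n_sub: int,
    reps: int = 200,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of random ``n_sub``-bead subsamples called detected.

    Repeats :func:`detection_call` on seeded random subsets of both the
    sample and the control, emulating runs that measure fewer beads.
    """
    if n_sub < 2:
        raise ValueError("n_sub must be >= 2")
    ipr_s = sample.ipr_matrix()
    ipr_c = control.ipr_matrix()
    if n_sub > min(ipr_s.shape[0], ipr_c.shape[0]):
        raise ValueError("n_sub exceeds available beads")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q_s = ipr_s.sum(axis=1)
    q_c = ipr_c.sum(axis=1)
    hits = 0
    for _ in range(reps):
        qs = q_s if n_sub == q_s.size else rng.choice(q_s, n_sub, replace=False)
        qc = q_c if n_sub == q_c.size else rng.choice(q_c, n_sub, replace=False)
        s = QScoreResult(float(qs.mean()), float(qs.std(ddof=1) / np.sqrt(n_sub)), n_sub, qs)
        c = QScoreResult(float(qc.mean()), float(qc.std(ddof=1) / np.sqrt(n_sub)), n_sub, qc)
        hits += detection_call(s, c, alpha).detected
    return hits / reps
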