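"""Fold-change and error computations for qRT-PCR and ELISA validation arms.

qRT-PCR relative expression is taken as already calibrator-normalized
(e.g. 2^-dCt against Gapdh); the fold change between two treatment groups is
the ratio of group means, with an error range obtained by quadrature
(delta-method) propagation of both groups' standard errors of the mean onto
the ratio scale.  ELISA standard curves are fit with a four-parameter
logistic (4-PL) model whose inverse maps optical densities to
concentrations; protein fold changes are ratios of mean replicate
concentrations flagged against a two-fold cutoff (strict inequality, applied
to both the ratio and its reciprocal).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# qRT-PCR
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QpcrFoldChange:
    fold_change: float
    error_range: float     # FC * sqrt((SEM_g/mean_g)^2 + (SEM_g'/mean_g')^2)
    mean_g: float
    mean_g2: float
    sem_g: float
    sem_g2: float


def relative_expression(ct_goi, ct_calibrator) -> np.ndarray:
    """2^-(Ct_GOI - Ct_calibrator) for paired Ct measurements."""
    a = np.asarray(ct_goi, dtype=float)
    b = np.asarray(ct_calibrator, dtype=float)
    if a.shape != b.shape:
        raise DataError("Ct arrays must have matching shapes")
    return 2.0 ** (-(a - b))


def qpcr_fold_change(group_g, group_g2) -> QpcrFoldChange:
    """Fold change between two groups of calibrator-relative expressions.

    FC = mean(g) / mean(g'); the error range propagates both groups' SEMs
    in quadrature onto the ratio.  With a single replicate the SEM (and the
    error range) is undefined and reported as NaN.
    """
    g = np.asarray(group_g, dtype=float)
    g2 = np.asarray(group_g2, dtype=float)
    if g.size == 0 or g2.size == 0:
        raise DataError("both groups must be nonempty")
    if (g <= 0).any() or (g2 <= 0).any():
        raise DataError("relative expressions must be positive")
    m1, m2 = float(g.mean()), float(g2.mean())
    if m2 == 0:
        raise DataError("zero mean in denominator group")
    sem1 = float(stats.sem(g)) if g.size > 1 else float("nan")
    sem2 = float(stats.sem(g2)) if g2.size > 1 else float("nan")
    fc = m1 / m2
    err = fc * float(np.sqrt((sem1 / m1) ** 2 + (sem2 / m2) ** 2))
    return QpcrFoldChange(fold_change=fc, error_range=err, mean_g=m1, mean_g2=m2,
                          sem_g=sem1, sem_g2=sem2)


# ---------------------------------------------------------------------------
# 4-PL ELISA standard curves
# ---------------------------------------------------------------------------

def four_pl(x, lower: float, upper: float, slope: float, ec50: float):
    """4-PL response: lower at x -> 0, upper at x -> inf (slope > 0).

    f(x) = upper + (lower - upper) / (1 + (x / ec50)^slope); the response at
    the inflection concentration ec50 is the midpoint of the asymptotes.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / ec50) ** slope, 0.0 if slope > 0 else np.inf)
    return upper + (lower - upper) / (1.0 + ratio)


@dataclasses.dataclass
class FourPLCurve:
    lower: float       # asymptote at zero concentration
    upper: float       # asymptote at saturating concentration
    slope: float
    ec50: float        # inflection concentration
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise DataError("4-PL upper asymptote must exceed the lower one")
        if self.ec50 <= 0:
            raise DataError("4-PL inflection concentration must be positive")

    def predict(self, conc):
        return four_pl(conc, self.lower, self.upper, self.slope, self.ec50)

    def inverse(self, od):
        """Concentration at a given OD; NaN outside the open asymptote range."""
        od = np.asarray(od, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = (self.lower - self.upper) / (od - self.upper) - 1.0
            out = self.ec50 * np.where(frac > 0, frac, np.nan) ** (1.0 / self.slope)
        inside = (od > min(self.lower, self.upper)) & (od < max(self.lower, self.upper))
        return np.where(inside, out, np.nan)


def elisa_fit_4pl(concentrations, ods) -> FourPLCurve:
    """Least-squares 4-PL fit of an ELISA standard series (>= 4 points)."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ods, dtype=float)
    if x.size != y.size:
        raise DataError("concentration and OD arrays must align")
    if x.size < 4:
        raise DataError("4-PL fit needs at least 4 standards")
    if (x < 0).any():
        raise DataError("standard concentrations must be non-negative")
    order = np.argsort(x)
    rho = stats.spearmanr(x[order], y[order]).statistic
    if not np.isfinite(rho) or abs(rho) < 1.0 - 1e-9:
        warnings.warn("standards are not strictly monotone in concentration; "
                      "4-PL fit may be unstable", stacklevel=2)
    increasing = y[order][-1] >= y[order][0]
    lo0, hi0 = (y.min(), y.max())
    pos = x[x > 0]
    c0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    p0 = [lo0, hi0, 1.0 if increasing else -1.0, c0]
    try:
        popt, _ = optimize.curve_fit(four_pl, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise DataError(f"4-PL fit failed to converge: {exc}") from exc
    lower, upper, slope, ec50 = popt
    if not np.isfinite(popt).all() or ec50 <= 0:
        raise DataError("singular 4-PL fit")
    if upper < lower:
        # reparametrize to the equivalent curve with upper > lower
        lower, upper, slope = upper, lower, -slope
    resid = y - four_pl(x, lower, upper, slope, ec50)
    return FourPLCurve(lower=float(lower), upper=float(upper), slope=float(slope),
                       ec50=float(ec50), residuals=resid)


def elisa_fold_change(conc_a, conc_b, cutoff: float = 2.0) -> tuple[float, bool]:
    """Ratio of mean replicate concentrations with a symmetric fold cutoff.

    Flagged iff FC > cutoff or FC < 1/cutoff (strict inequalities).
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    a = np.asarray(conc_a, dtype=float)
    b = np.asarray(conc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both replicate sets must be nonempty")
    if (a <= 0).any() or (b <= 0).any():
        raise DataError("concentrations must be positive")
    mb = float(b.mean())
    if mb == 0:
        raise DataError("zero mean denominator concentration")
    fc = float(a.mean()) / mb
    return fc, bool(fc > cutoff or fc < 1.0 / cutoff)
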