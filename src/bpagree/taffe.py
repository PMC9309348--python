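"""Differential/proportional bias and precision of a test device via BLUPs.

Method-comparison setting with repeated measurements: each patient *i*
carries a latent trait x_i ~ N(mu, tau2); the reference device measures
y1_ij = x_i + e1_ij and the test device y2_ij = alpha + beta * x_i + e2_ij.
``alpha`` is the differential bias, ``beta`` the proportional bias, and
the bias curve b(x) = alpha + (beta - 1) * x gives the expected
test-minus-truth error at true value x.

Estimation is two-stage and closed-form:

1. A one-way random-effects decomposition of the reference readings by
   method of moments yields mu, tau2 and the within-patient reference
   error variance sigma1_2; each patient's latent trait is predicted by
   its BLUP ``x_hat_i = mu + lambda_i * (ybar_i - mu)`` with shrinkage
   ``lambda_i = tau2 / (tau2 + sigma1_2 / n_i)``.
2. All test readings are regressed by OLS on the BLUP of their patient:
   intercept = alpha, slope = beta.  95% CIs come from a patient-level
   nonparametric bootstrap (patients are the resampling unit, percentile
   interval), which respects the within-patient clustering.

A third stage fits log-variance functions to squared residuals of each
device, giving smooth positive SD-vs-BLUP precision curves.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import digamma
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core_data import REFERENCE, TEST, CohortData

#: E[ln chi^2_1] = psi(1/2) + ln 2; added back when converting fitted
#: log-squared residuals to an SD so the curve is unbiased for normal errors.
_LN_CHI2_1_MEAN = float(digamma(0.5) + np.log(2.0))

DEFAULT_GRID_SIZE = 100
DEFAULT_N_BOOT = 500
RESIDUAL_FLOOR = 1e-6


def _frame(data) -> pd.DataFrame:
    return data.frame if isinstance(data, CohortData) else data


@dataclasses.dataclass(frozen=True)
class ReferenceModel:
    """Latent-trait model of the reference device.

    ``stats`` is indexed by patient with columns ``n_ref`` (reading
    count), ``mean_ref``, ``lam`` (shrinkage in [0, 1]) and ``blup``.
    """

    variable: str
    mu: float
    tau2: float
    sigma1_2: float
    stats: pd.DataFrame

    @property
    def blup(self) -> pd.Series:
        return self.stats["blup"]


@dataclasses.dataclass(frozen=True)
class BiasFit:
    """Fitted differential/proportional bias with bootstrap CIs."""

    variable: str
    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n_test: int
    blup_range: tuple[float, float]
    boot_alpha: np.ndarray
    boot_beta: np.ndarray
    n_boot_failed: int = 0

    def bias(self, x):
        """Bias curve b(x) = alpha + (beta - 1) x (positive = test overestimates)."""
        return self.alpha + (self.beta - 1.0) * np.asarray(x, dtype=float)

    @property
    def zero_bias_point(self) -> float:
        """The BLUP at which the bias crosses zero (alpha / (1 - beta))."""
        if self.beta == 1.0:
            return float("nan")
        return self.alpha / (1.0 - self.beta)


@dataclasses.dataclass(frozen=True)
class PrecisionFit:
    """Per-device SD-vs-BLUP variance functions sigma_d(x) = exp(c0 + c1 x)/2 scale.

    ``coef`` maps device -> (c0, c1) on the log-variance scale (after
    bias correction); ``grid`` tabulates the SD curves over the observed
    BLUP range.
    """

    variable: str
    coef: dict[str, tuple[float, float]]
    grid: pd.DataFrame

    def sd(self, device: str, x):
        c0, c1 = self.coef[device]
        return np.exp((c0 + c1 * np.asarray(x, dtype=float)) / 2.0)


def fit_reference_model(data, variable: str = "sbp") -> ReferenceModel:
    """Method-of-moments one-way random-effects fit of the reference readings.

    Requires at least two patients, at least two of which have repeated
    readings (otherwise the within-patient variance is unidentifiable).
    """
    df = _frame(data)
    ref = df[df["device"] == REFERENCE]
    if ref.empty:
        raise ValueError("no reference measurements")
    grp = ref.groupby("patient_id")[variable]
    n = grp.size()
    m = grp.mean()
    if len(n) < 2:
        raise ValueError("need reference readings from at least 2 patients")
    if int((n >= 2).sum()) < 1:
        raise ValueError(
            "within-patient reference variance unidentifiable: every patient "
            "has a single reference reading"
        )
    dev2 = (ref[variable] - ref["patient_id"].map(m)) ** 2
    ss = dev2.groupby(ref["patient_id"]).sum()
    dof = (n - 1).clip(lower=0)
    sigma1_2 = float(ss.sum() / dof.sum())
    tau2 = float(max(0.0, m.var(ddof=1) - sigma1_2 * float((1.0 / n).mean())))
    denom = tau2 + sigma1_2 / n
    if (denom > 0).all():
        w = 1.0 / denom
        mu = float((w * m).sum() / w.sum())
        lam = tau2 / denom
    else:  # fully degenerate: all readings identical
        mu = float(m.mean())
        lam = pd.Series(0.0, index=n.index)
    blup = mu + lam * (m - mu)
    stats = pd.DataFrame(
        {"n_ref": n, "mean_ref": m, "lam": lam, "blup": blup}
    ).sort_index()
    return ReferenceModel(
        variable=variable, mu=mu, tau2=tau2, sigma1_2=sigma1_2, stats=stats
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (intercept, slope) of y on x."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    d = sxx - sx * sx / n
    if d <= 0:
        raise ValueError("regressor is constant; slope unidentifiable")
    beta = (sxy - sx * sy / n) / d
    alpha = (sy - beta * sx) / n
    return float(alpha), float(beta)


def _bootstrap_bias(
    model: ReferenceModel,
    test_by_patient: pd.DataFrame,
    n_boot: int,
    seed,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Patient-level bootstrap of (alpha, beta), vectorised over draws.

    Both stages are recomputed on each resample from per-patient
    sufficient statistics (reference count/mean/SS, test count/sum).
    Degenerate draws yield NaN and are counted.
    """
    st = model.stats.join(test_by_patient, how="left").fillna({"n_test": 0, "sum_test": 0.0})
    n1 = st["n_ref"].to_numpy(float)
    m1 = st["mean_ref"].to_numpy(float)
    ss1 = st["ss_ref"].to_numpy(float)
    n2 = st["n_test"].to_numpy(float)
    s2 = st["sum_test"].to_numpy(float)
    n_pat = len(st)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_pat, size=(n_boot, n_pat))
    n1s, m1s, ss1s = n1[idx], m1[idx], ss1[idx]
    n2s, s2s = n2[idx], s2[idx]

    dof = np.clip(n1s - 1.0, 0.0, None).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = ss1s.sum(axis=1) / dof
        var_means = m1s.var(axis=1, ddof=1)
        tau2 = np.clip(var_means - sig * (1.0 / n1s).mean(axis=1), 0.0, None)
        den = tau2[:, None] + sig[:, None] / n1s
        w = 1.0 / np.maximum(den, 1e-12)
        mu = (w * m1s).sum(axis=1) / w.sum(axis=1)
        lam = np.where(den > 0, tau2[:, None] / np.maximum(den, 1e-12), 0.0)
        xb = mu[:, None] + lam * (m1s - mu[:, None])

        ntot = n2s.sum(axis=1)
        sx = (n2s * xb).sum(axis=1)
        sy = s2s.sum(axis=1)
        sxx = (n2s * xb * xb).sum(axis=1)
        sxy = (xb * s2s).sum(axis=1)
        d = sxx - sx * sx / np.maximum(ntot, 1.0)
        beta_b = (sxy - sx * sy / np.maximum(ntot, 1.0)) / d
        alpha_b = (sy - beta_b * sx) / np.maximum(ntot, 1.0)

    bad = ~np.isfinite(beta_b) | ~np.isfinite(alpha_b) | (d <= 1e-9) | (dof <= 0) | (ntot < 2)
    alpha_b[bad] = np.nan
    beta_b[bad] = np.nan
    return alpha_b, beta_b, int(bad.sum())


def estimate_bias(
    model: ReferenceModel,
    data,
    variable: str | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed=0,
) -> BiasFit:
    """OLS of all test readings on their patient's BLUP.

    Intercept = differential bias alpha; slope = proportional bias beta.
    With ``n_boot > 0``, percentile CIs from a seeded patient-level
    bootstrap are attached.
    """
    variable = variable or model.variable
    df = _frame(data)
    test = df[df["device"] == TEST][["patient_id", variable]]
    test = test[test["patient_id"].isin(model.stats.index)]
    if len(test) < 10 or test["patient_id"].nunique() < 2:
        raise ValueError("need >= 10 test readings spanning >= 2 patients")
    x = model.blup.loc[test["patient_id"]].to_numpy(float)
    y = test[variable].to_numpy(float)
    if np.ptp(x) <= 0:
        raise ValueError("all BLUPs equal; proportional bias unidentifiable")
    alpha, beta = _ols_line(x, y)

    if n_boot > 0:
        ref = df[df["device"] == REFERENCE]
        dev2 = (ref[variable] - ref["patient_id"].map(model.stats["mean_ref"])) ** 2
        ss_ref = dev2.groupby(ref["patient_id"]).sum().rename("ss_ref")
        tb = test.groupby("patient_id")[variable].agg(["size", "sum"])
        tb.columns = ["n_test", "sum_test"]
        stats_in = pd.concat([ss_ref, tb], axis=1).fillna(0.0)
        boot_alpha, boot_beta, n_failed = _bootstrap_bias(
            dataclasses.replace(
                model, stats=model.stats.join(stats_in[["ss_ref"]], how="left")
            ),
            stats_in[["n_test", "sum_test"]],
            n_boot,
            seed,
        )
        alpha_ci = tuple(np.nanpercentile(boot_alpha, [2.5, 97.5]).tolist())
        beta_ci = tuple(np.nanpercentile(boot_beta, [2.5, 97.5]).tolist())
    else:
        boot_alpha = np.empty(0)
        boot_beta = np.empty(0)
        n_failed = 0
        alpha_ci = (float("nan"), float("nan"))
        beta_ci = (float("nan"), float("nan"))

    return BiasFit(
        variable=variable,
        alpha=alpha,
        beta=beta,
        alpha_ci=alpha_ci,
        beta_ci=beta_ci,
        n_test=len(test),
        blup_range=(float(x.min()), float(x.max())),
        boot_alpha=boot_alpha,
        boot_beta=boot_beta,
        n_boot_failed=n_failed,
    )


def evaluate_bias(fit: BiasFit, x):
    """Bias b(x) = alpha + (beta - 1) x at a true value ``x`` (mmHg).

    Positive means the test device overestimates.  Evaluations more than
    20% of the observed span outside the BLUP range trigger an
    extrapolation warning.
    """
    lo, hi = fit.blup_range
    span = hi - lo
    xa = np.asarray(x, dtype=float)
    if span > 0 and (np.any(xa < lo - 0.2 * span) or np.any(xa > hi + 0.2 * span)):
        warnings.warn(
            "evaluating bias outside the observed BLUP range (extrapolation)",
            stacklevel=2,
        )
    out = fit.bias(xa)
    return float(out) if np.isscalar(x) else out


def estimate_precision(
    model: ReferenceModel,
    fit: BiasFit,
    data,
    variable: str | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    floor: float = RESIDUAL_FLOOR,
) -> PrecisionFit:
    """Per-device measurement-error SD as a smooth function of the BLUP.

    Residuals are y1 - x_hat for the reference and y2 - (alpha + beta *
    x_hat) for the test device; ``log(r^2 + floor)`` is regressed on the
    BLUP and converted back to an SD curve with the E[ln chi^2_1]
    correction, so a homoscedastic truth is recovered without bias.
    """
    variable = variable or model.variable
    df = _frame(data)
    coef: dict[str, tuple[float, float]] = {}
    for device in (REFERENCE, TEST):
        sub = df[df["device"] == device]
        sub = sub[sub["patient_id"].isin(model.stats.index)]
        xb = model.blup.loc[sub["patient_id"]].to_numpy(float)
        y = sub[variable].to_numpy(float)
        if device == REFERENCE:
            r = y - xb
        else:
            r = y - (fit.alpha + fit.beta * xb)
        if len(r) < 10:
            raise ValueError(f"need >= 10 {device} residuals for the variance function")
        logr2 = np.log(r * r + floor)
        c1, c0 = np.polyfit(xb, logr2, 1)
        coef[device] = (float(c0 - _LN_CHI2_1_MEAN), float(c1))
    lo, hi = model.blup.min(), model.blup.max()
    xs = np.linspace(lo, hi, grid_size)
    grid = pd.DataFrame(
        {
            "x_blup": xs,
            "sd_ref": np.exp((coef[REFERENCE][0] + coef[REFERENCE][1] * xs) / 2.0),
            "sd_test": np.exp((coef[TEST][0] + coef[TEST][1] * xs) / 2.0),
        }
    )
    return PrecisionFit(variable=variable, coef=coef, grid=grid)


def bias_plot_data(
    model: ReferenceModel, fit: BiasFit, grid_size: int = DEFAULT_GRID_SIZE
) -> pd.DataFrame:
    """Tidy bias-plot table over the BLUP grid.

    Columns: ``x_blup`` (monotone), ``identity``, ``fitted_test``
    (alpha + beta x), ``bias`` and its bootstrap percentile band
    ``bias_lo``/``bias_hi`` (NaN when the fit carries no bootstrap).
    """
    xs = np.linspace(model.blup.min(), model.blup.max(), grid_size)
    bias = fit.bias(xs)
    if fit.boot_alpha.size:
        curves = fit.boot_alpha[:, None] + (fit.boot_beta[:, None] - 1.0) * xs[None, :]
        lo = np.nanpercentile(curves, 2.5, axis=0)
        hi = np.nanpercentile(curves, 97.5, axis=0)
    else:
        lo = np.full_like(xs, np.nan)
        hi = np.full_like(xs, np.nan)
    return pd.DataFrame(
        {
            "x_blup": xs,
            "identity": xs,
            "fitted_test": fit.alpha + fit.beta * xs,
            "bias": bias,
            "bias_lo": lo,
            "bias_hi": hi,
        }
    )


class TaffeEstimator(BaseEstimator):
    """Latent-trait bias/precision estimator with an sklearn-style API.

    Parameters
    ----------
    variable:
        ``"sbp"`` or ``"dbp"``.
    n_boot:
        Bootstrap draws for the 95% CIs (0 disables them).
    random_state:
        Seed for the bootstrap resampling.
    grid_size:
        Points in the bias/precision plot tables.

    Attributes (after :meth:`fit`)
    ------------------------------
    mu_, tau2_, sigma1_2_ : floats of the reference random-effects model.
    alpha_, beta_ : differential / proportional bias point estimates.
    alpha_ci_, beta_ci_ : percentile 95% CIs.
    reference_model_, bias_fit_, precision_fit_ : full stage results.
    """

    def __init__(
        self,
        variable: str = "sbp",
        n_boot: int = DEFAULT_N_BOOT,
        random_state: int = 0,
        grid_size: int = DEFAULT_GRID_SIZE,
    ):
        self.variable = variable
        self.n_boot = n_boot
        self.random_state = random_state
        self.grid_size = grid_size

    def fit(self, X, y=None):
        """Fit all three stages on a cohort (CohortData or long frame)."""
        model = fit_reference_model(X, self.variable)
        bias = estimate_bias(
            model, X, self.variable, n_boot=self.n_boot, seed=self.random_state
        )
        precision = estimate_precision(
            model, bias, X, self.variable, grid_size=self.grid_size
        )
        self.reference_model_ = model
        self.bias_fit_ = bias
        self.precision_fit_ = precision
        self.mu_ = model.mu
        self.tau2_ = model.tau2
        self.sigma1_2_ = model.sigma1_2
        self.alpha_ = bias.alpha
        self.beta_ = bias.beta
        self.alpha_ci_ = bias.alpha_ci
        self.beta_ci_ = bias.beta_ci
        return self

    def predict(self, x):
        """Expected test-device reading alpha + beta * x at true value x."""
        check_is_fitted(self, "bias_fit_")
        return self.alpha_ + self.beta_ * np.asarray(x, dtype=float)

    def bias(self, x):
        """Bias curve at true value x (warns on extrapolation)."""
        check_is_fitted(self, "bias_fit_")
        return evaluate_bias(self.bias_fit_, x)

    def bias_table(self) -> pd.DataFrame:
        check_is_fitted(self, "bias_fit_")
        return bias_plot_data(self.reference_model_, self.bias_fit_, self.grid_size)

    def precision_table(self) -> pd.DataFrame:
        check_is_fitted(self, "precision_fit_")
        return self.precision_fit_.grid
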