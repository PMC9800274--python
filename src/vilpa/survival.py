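"""Spline dose-response survival models.

Statsmodels-style model/results pairs for the two regression routes used in
the analysis:

* :class:`CoxDoseResponse` — Cox proportional hazards on the all-cause (or
  cause-specific, censoring competing deaths) scale, with the exposure
  entering through a restricted cubic spline with knots at the 10th, 50th
  and 90th percentiles (linear tails, two basis columns for three knots);
* :class:`FineGrayDoseResponse` — the Fine-Gray subdistribution-hazard
  model for a specific cause of death: participants who die of a competing
  cause remain in later risk sets with inverse-probability-of-censoring
  weights from the Kaplan-Meier estimate of the censoring distribution.

Both ``fit()`` methods return a :class:`DoseResponseResults` carrying the
coefficient vector, its covariance (inverse observed information), the
log-likelihood, and diagnostic tests (Wald test for departure from
linearity, Schoenfeld-residual proportional-hazards test). Dose-response
curves, the minimal dose and E-values are derived from the results object
in :mod:`vilpa.dose_response`.

Partial-likelihood maximisation uses the Efron tie correction throughout
(delegated to lifelines); the Fine-Gray risk-set expansion and the
Grambsch-Therneau test statistics are implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .errors import FittingError, InputError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATE_FORMULA = "age + C(sex) + C(smoking) + confounder"
DEATH_CAUSES = ("cvd", "cancer", "other_death")

#: column names of the exposure basis in the design matrix
_EXPOSURE_LIN = "exposure_lin"
_EXPOSURE_RCS = "exposure_rcs1"


# --------------------------------------------------------------------------
# restricted cubic spline
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineSpec:
    """Three-knot restricted cubic spline specification.

    The spline is cubic between the knots, linear beyond the boundary knots,
    with continuous second derivative; with three knots this contributes one
    nonlinear basis column in addition to the linear term.
    """

    knots: tuple[float, float, float]

    def __post_init__(self):
        t1, t2, t3 = self.knots
        if not (t1 < t2 < t3):
            raise InputError(f"knots must be strictly increasing, got {self.knots}")

    @classmethod
    def from_percentiles(cls, x, percentiles=(10.0, 50.0, 90.0)) -> "SplineSpec":
        """Knots at percentiles of the (capped) analysis-sample exposure."""
        x = np.asarray(x, dtype=float)
        knots = tuple(float(np.percentile(x, p)) for p in percentiles)
        return cls(knots=knots)


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis.

    Returns an (n, 2) array: column 0 is x itself; column 1 is the
    restricted cubic term (Harrell's construction, scaled by the squared
    knot span so both columns share the scale of x). Column 1 is exactly
    zero at and below the first knot, which makes exposure 0 the natural
    referent when the first knot is non-negative.
    """
    x = np.asarray(x, dtype=float)
    t1, t2, t3 = spec.knots

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    nonlin = (
        pos3(x - t1)
        - pos3(x - t2) * (t3 - t1) / (t3 - t2)
        + pos3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, nonlin])


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------


def apply_exclusions(
    records: pd.DataFrame,
    landmark_years: float = 2.0,
    outcome: str = "all_cause",
) -> tuple[pd.DataFrame, dict]:
    """Landmark and prevalent-disease exclusions.

    Removes participants whose *death* (any cause) occurs strictly before
    ``landmark_years`` of follow-up — participants censored early are
    retained, their follow-up simply ends. For the cause-specific outcomes,
    additionally removes participants with the corresponding prevalent
    disease at baseline (columns ``prevalent_cvd`` / ``prevalent_cancer``
    must be present). Returns the filtered frame and a count log.
    """
    if outcome not in ("all_cause", "cvd", "cancer"):
        raise InputError(f"unknown outcome {outcome!r}")
    df = records
    n0 = len(df)
    died = df["cause"].isin(DEATH_CAUSES)
    early = died & (df["time_years"] < landmark_years)
    df = df[~early]
    n_landmark = int(early.sum())

    n_prevalent = 0
    if outcome in ("cvd", "cancer"):
        flag = f"prevalent_{outcome}"
        if flag not in df.columns:
            raise InputError(f"column {flag!r} required for the {outcome} analysis")
        prev = df[flag].astype(bool)
        n_prevalent = int(prev.sum())
        df = df[~prev]
    log = {
        "n_input": n0,
        "n_removed_landmark": n_landmark,
        "n_removed_prevalent": n_prevalent,
        "n_retained": len(df),
    }
    return df.reset_index(drop=True), log


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------


@dataclass
class WaldTest:
    statistic: float
    df: int
    p_value: float


@dataclass
class PHTest:
    """Schoenfeld-residual proportional-hazards test (Grambsch-Therneau)."""

    per_term: pd.DataFrame  # columns: statistic, p
    global_statistic: float
    global_df: int
    global_p: float
    transform: str = "rank"


@dataclass
class DoseResponseResults:
    """Fitted dose-response model.

    ``params``/``cov`` cover the exposure basis columns followed by the
    adjustment covariates; ``exposure_cols`` names the basis columns so the
    referent contrast (against exposure 0) can be formed. On the Fine-Gray
    route coefficients live on the subdistribution log-hazard-ratio scale.
    """

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n: int
    n_events: int
    model_kind: str  # "cox" | "fine_gray"
    spline: SplineSpec | None
    exposure_name: str
    exposure_cols: list[str]
    exposure_max: float
    _model: object = field(default=None, repr=False)
    _design: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        cov = self.cov.to_numpy()
        if cov.shape[0] != cov.shape[1] or cov.shape[0] != len(self.params):
            raise FittingError("covariance and coefficient dimensions disagree")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise FittingError("covariance must be symmetric")

    # -- exposure contrasts ------------------------------------------------

    def exposure_basis(self, x) -> np.ndarray:
        """Design columns of the exposure at values ``x`` (n, k)."""
        x = np.asarray(x, dtype=float)
        if self.spline is not None:
            return rcs_basis(x, self.spline)
        return x.reshape(-1, 1)

    def log_hr(self, x, reference: float = 0.0):
        """Adjusted log hazard ratio and its standard error at exposures
        ``x`` relative to ``reference``, by the delta method on the contrast
        ``basis(x) - basis(reference)``."""
        b = self.exposure_basis(np.atleast_1d(x))
        b0 = self.exposure_basis(np.atleast_1d(reference))
        contrast = b - b0
        beta = self.params[self.exposure_cols].to_numpy()
        V = self.cov.loc[self.exposure_cols, self.exposure_cols].to_numpy()
        eta = contrast @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, V, contrast))
        return eta, se

    def curve(self, grid_size: int = 512, x_max: float | None = None):
        """Dose-response curve over [0, exposure max]; see
        :func:`vilpa.dose_response.build_curve`."""
        from .dose_response import build_curve

        return build_curve(self, grid_size=grid_size, x_max=x_max)

    # -- diagnostics -------------------------------------------------------

    def wald_nonlinearity(self) -> WaldTest:
        """Wald chi-square test for departure from linearity: joint test of
        the nonlinear spline coefficient(s)."""
        nonlinear = self.exposure_cols[1:]
        if not nonlinear:
            raise InputError("fit has no nonlinear spline term")
        beta = self.params[nonlinear].to_numpy()
        V = self.cov.loc[nonlinear, nonlinear].to_numpy()
        stat = float(beta @ np.linalg.solve(V, beta))
        df = len(nonlinear)
        return WaldTest(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))

    def ph_test(self, transform: str = "rank") -> PHTest:
        """Schoenfeld-residual test of proportional hazards (Cox only)."""
        if self.model_kind != "cox":
            raise InputError("proportional-hazards test applies to the Cox fit")
        return _schoenfeld_ph_test(self._model, self._design, self.cov, transform)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, s.e., z, p, HR with 95% CI."""
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "z": z,
                "p": p,
                "hr": np.exp(self.params),
                "hr_lower_95": np.exp(self.params - 1.959963984540054 * se),
                "hr_upper_95": np.exp(self.params + 1.959963984540054 * se),
            }
        )

    def to_dict(self) -> dict:
        """JSON-serialisable representation (round-trips via from_dict)."""
        return {
            "params": self.params.to_dict(),
            "cov": {"index": list(self.cov.index), "values": self.cov.to_numpy().tolist()},
            "llf": self.llf,
            "n": self.n,
            "n_events": self.n_events,
            "model_kind": self.model_kind,
            "knots": list(self.spline.knots) if self.spline else None,
            "exposure_name": self.exposure_name,
            "exposure_cols": self.exposure_cols,
            "exposure_max": self.exposure_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoseResponseResults":
        idx = d["cov"]["index"]
        return cls(
            params=pd.Series(d["params"]).reindex(idx),
            cov=pd.DataFrame(np.array(d["cov"]["values"]), index=idx, columns=idx),
            llf=d["llf"],
            n=d["n"],
            n_events=d["n_events"],
            model_kind=d["model_kind"],
            spline=SplineSpec(knots=tuple(d["knots"])) if d["knots"] else None,
            exposure_name=d["exposure_name"],
            exposure_cols=list(d["exposure_cols"]),
            exposure_max=d["exposure_max"],
        )


# --------------------------------------------------------------------------
# model classes
# --------------------------------------------------------------------------


def _build_design(
    data: pd.DataFrame, exposure: str, covariate_formula: str | None, spline
) -> tuple[pd.DataFrame, SplineSpec | None, list[str]]:
    """Exposure basis + covariate design matrix (no intercept)."""
    if exposure not in data.columns:
        raise InputError(f"exposure column {exposure!r} not in data")
    x = data[exposure].to_numpy(dtype=float)
    if spline == "percentiles":
        spline = SplineSpec.from_percentiles(x)
    if spline is not None and not isinstance(spline, SplineSpec):
        raise InputError("spline must be a SplineSpec, 'percentiles' or None")

    if spline is not None:
        basis = rcs_basis(x, spline)
        design = pd.DataFrame(
            basis, columns=[_EXPOSURE_LIN, _EXPOSURE_RCS], index=data.index
        )
        exposure_cols = [_EXPOSURE_LIN, _EXPOSURE_RCS]
    else:
        design = pd.DataFrame({_EXPOSURE_LIN: x}, index=data.index)
        exposure_cols = [_EXPOSURE_LIN]

    if covariate_formula:
        Z = patsy.dmatrix(covariate_formula, data, return_type="dataframe")
        if "Intercept" in Z.columns:
            Z = Z.drop(columns="Intercept")
        Z.columns = [c.replace("[", "_").replace("]", "").replace("(", "_").replace(")", "") for c in Z.columns]
        const = Z.columns[Z.nunique() <= 1]
        if len(const):
            raise InputError(f"constant covariate columns: {list(const)}")
        design = pd.concat([design, Z], axis=1)
    return design, spline, exposure_cols


class CoxDoseResponse:
    """Cox proportional-hazards dose-response model.

    Parameters
    ----------
    data
        Analysis frame with the exposure column, ``time_years``, ``cause``
        (one of cvd / cancer / other_death / censored) and the covariates
        referenced by ``covariate_formula``.
    exposure
        Name of the exposure column (daily VILPA duration in min/day or
        length-standardized bouts/day).
    covariate_formula
        patsy formula for the adjustment covariates (no intercept is used;
        categorical terms expand to treatment contrasts).
    spline
        ``'percentiles'`` (default) places restricted-cubic-spline knots at
        the 10th/50th/90th percentiles of the exposure in ``data``; pass a
        :class:`SplineSpec` to fix the knots, or ``None`` for a purely
        linear exposure term.
    outcome
        ``'all_cause'`` treats any death as the event; a cause name fits a
        cause-specific Cox model censoring competing deaths.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str,
        covariate_formula: str | None = DEFAULT_COVARIATE_FORMULA,
        spline="percentiles",
        outcome: str = "all_cause",
        duration_col: str = "time_years",
        cause_col: str = "cause",
    ):
        self.data = data.reset_index(drop=True)
        self.exposure = exposure
        self.covariate_formula = covariate_formula
        self.outcome = outcome
        self.duration_col = duration_col
        self.cause_col = cause_col
        self.design, self.spline, self.exposure_cols = _build_design(
            self.data, exposure, covariate_formula, spline
        )
        if outcome == "all_cause":
            self.event = self.data[cause_col].isin(DEATH_CAUSES).to_numpy()
        elif outcome in DEATH_CAUSES or outcome in ("cvd", "cancer"):
            self.event = (self.data[cause_col] == outcome).to_numpy()
        else:
            raise InputError(f"unknown outcome {outcome!r}")
        if (self.data[duration_col] <= 0).any():
            raise InputError("time_years must be positive")
        if self.event.sum() < 2:
            raise InputError("need at least 2 events to fit")

    def fit(self, robust: bool = False) -> DoseResponseResults:
        frame = self.design.copy()
        frame["_T"] = self.data[self.duration_col].to_numpy(dtype=float)
        frame["_E"] = self.event.astype(int)
        cph = CoxPHFitter()
        try:
            cph.fit(
                frame,
                duration_col="_T",
                event_col="_E",
                robust=robust,
                fit_options={"precision": 1e-09},
            )
        except ConvergenceError as err:  # pragma: no cover - defensive
            raise FittingError(f"Cox fit failed to converge: {err}") from err
        params = cph.params_.copy()
        cov = cph.variance_matrix_.copy()
        return DoseResponseResults(
            params=params,
            cov=cov,
            llf=float(cph.log_likelihood_),
            n=len(frame),
            n_events=int(self.event.sum()),
            model_kind="cox",
            spline=self.spline,
            exposure_name=self.exposure,
            exposure_cols=self.exposure_cols,
            exposure_max=float(self.data[self.exposure].max()),
            _model=cph,
            _design=frame,
        )


class FineGrayDoseResponse:
    """Fine-Gray subdistribution-hazard dose-response model.

    Participants who die of a competing cause remain in the risk set for the
    target cause after their death, down-weighted over time by the ratio
    ``G(t-)/G(s-)`` of Kaplan-Meier estimates of the censoring distribution
    (s = competing death time). The expanded, weighted risk sets are fitted
    as a start-stop Cox model, yielding coefficients on the subdistribution
    log-hazard-ratio scale.
    """

    MIN_WEIGHT = 1e-8

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str,
        cause: str = "cvd",
        covariate_formula: str | None = DEFAULT_COVARIATE_FORMULA,
        spline="percentiles",
        duration_col: str = "time_years",
        cause_col: str = "cause",
    ):
        if cause not in DEATH_CAUSES:
            raise InputError(f"unknown cause {cause!r}")
        self.data = data.reset_index(drop=True)
        self.exposure = exposure
        self.cause = cause
        self.covariate_formula = covariate_formula
        self.duration_col = duration_col
        self.cause_col = cause_col
        self.design, self.spline, self.exposure_cols = _build_design(
            self.data, exposure, covariate_formula, spline
        )
        causes = self.data[cause_col]
        self.event = (causes == cause).to_numpy()
        self.competing = (causes.isin(DEATH_CAUSES) & (causes != cause)).to_numpy()
        if self.event.sum() < 2:
            raise InputError(f"need at least 2 events of cause {cause!r}")

    def _expand(self) -> pd.DataFrame:
        """Fine-Gray risk-set expansion with IPCW weights."""
        T = self.data[self.duration_col].to_numpy(dtype=float)
        censored = ~(self.event | self.competing)

        kmf = KaplanMeierFitter()
        kmf.fit(T, event_observed=censored.astype(int))
        # G(t): left-continuous evaluation via predict at t - 0 handled below
        km_times = kmf.survival_function_.index.to_numpy(dtype=float)
        km_surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)

        def G_minus(t):
            """P(C >= t) = G evaluated just before t."""
            idx = np.searchsorted(km_times, t, side="left") - 1
            return np.where(idx < 0, 1.0, km_surv[np.clip(idx, 0, None)])

        # weights change where G drops: at censoring times
        drop_times = km_times[np.concatenate([[False], np.diff(km_surv) < 0])]
        tau = float(T.max())

        rows = []
        n = len(T)
        for i in range(n):
            if not self.competing[i]:
                rows.append((i, 0.0, T[i], int(self.event[i]), 1.0))
                continue
            s = T[i]
            g_s = float(G_minus(np.array([s]))[0])
            if g_s <= 0:
                raise FittingError("degenerate censoring weights (G(s-) = 0)")
            # base interval up to the competing death, full weight
            rows.append((i, 0.0, s, 0, 1.0))
            cuts = drop_times[(drop_times > s) & (drop_times < tau)]
            bounds = np.concatenate([[s], cuts, [tau]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b <= a:
                    continue
                w = float(G_minus(np.array([(a + b) / 2.0]))[0]) / g_s
                rows.append((i, a, b, 0, max(w, self.MIN_WEIGHT)))
        long_df = pd.DataFrame(rows, columns=["_id", "_start", "_stop", "_event", "_w"])
        return long_df

    def fit(self) -> DoseResponseResults:
        if self.competing.sum() == 0:
            logger.info(
                "no competing events for cause %s: Fine-Gray reduces to Cox", self.cause
            )
        long_df = self._expand()
        design = self.design.copy()
        design["_id"] = np.arange(len(design))
        merged = long_df.merge(design, on="_id", how="left")

        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-integer weights notice
            try:
                ctv.fit(
                    merged,
                    id_col="_id",
                    event_col="_event",
                    start_col="_start",
                    stop_col="_stop",
                    weights_col="_w",
                )
            except ConvergenceError as err:  # pragma: no cover - defensive
                raise FittingError(f"Fine-Gray fit failed to converge: {err}") from err
        params = ctv.params_.copy()
        cov = ctv.variance_matrix_.copy()
        return DoseResponseResults(
            params=params,
            cov=cov,
            llf=float(ctv.log_likelihood_),
            n=len(self.data),
            n_events=int(self.event.sum()),
            model_kind="fine_gray",
            spline=self.spline,
            exposure_name=self.exposure,
            exposure_cols=self.exposure_cols,
            exposure_max=float(self.data[self.exposure].max()),
            _model=ctv,
            _design=merged,
        )


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def _schoenfeld_ph_test(cph, frame: pd.DataFrame, cov: pd.DataFrame, transform: str) -> PHTest:
    """Grambsch-Therneau test on (scaled) Schoenfeld residuals.

    Per-term statistic: squared covariance between the transformed event
    times and the scaled residuals over its variance; global statistic:
    ``(d / sum g*^2) * u' V u`` with ``u = sum_k g*_k s_k`` over the
    unscaled residual vectors. Both are chi-square under proportionality.
    """
    resid = cph.compute_residuals(frame, kind="schoenfeld")
    S = resid.to_numpy(dtype=float)  # d x p, unscaled Schoenfeld residuals
    d, p = S.shape
    if d < 2:
        raise InputError("need at least 2 events for the PH test")
    durations = pd.Series(cph.durations)  # indexed by original row labels
    if transform == "rank":
        # rank within the full sample (events + censored), then keep events
        g_full = pd.Series(stats.rankdata(durations), index=durations.index)
    elif transform == "log":
        g_full = np.log(durations)
    elif transform == "identity":
        g_full = durations.astype(float)
    else:
        raise InputError(f"unknown time transform {transform!r}")
    g = g_full.loc[resid.index].to_numpy(dtype=float)
    g = g - g.mean()
    gg = float((g**2).sum())

    V = cov.to_numpy()
    beta = cph.params_.to_numpy()
    scaled = d * (S @ V) + beta  # scaled Schoenfeld residuals

    stats_per_term = np.array(
        [
            (g @ scaled[:, j]) ** 2 / (d * V[j, j] * gg)
            for j in range(p)
        ]
    )
    p_per_term = stats.chi2.sf(stats_per_term, 1)
    per_term = pd.DataFrame(
        {"statistic": stats_per_term, "p": p_per_term}, index=cov.index
    )

    u = S.T @ g
    global_stat = float(d / gg * (u @ V @ u))
    global_p = float(stats.chi2.sf(global_stat, p))
    return PHTest(
        per_term=per_term,
        global_statistic=global_stat,
        global_df=p,
        global_p=global_p,
        transform=transform,
    )


# --------------------------------------------------------------------------
# thin functional interface
# --------------------------------------------------------------------------


def fit_cox(
    records: pd.DataFrame,
    exposure: str,
    covariate_formula: str | None = DEFAULT_COVARIATE_FORMULA,
    spline="percentiles",
    outcome: str = "all_cause",
) -> DoseResponseResults:
    """Fit the Cox spline dose-response model (see :class:`CoxDoseResponse`)."""
    return CoxDoseResponse(
        records, exposure, covariate_formula=covariate_formula, spline=spline, outcome=outcome
    ).fit()


def fit_fine_gray(
    records: pd.DataFrame,
    exposure: str,
    cause: str,
    covariate_formula: str | None = DEFAULT_COVARIATE_FORMULA,
    spline="percentiles",
) -> DoseResponseResults:
    """Fit the Fine-Gray subdistribution model (see :class:`FineGrayDoseResponse`)."""
    return FineGrayDoseResponse(
        records, exposure, cause=cause, covariate_formula=covariate_formula, spline=spline
    ).fit()


def test_nonlinearity(fit: DoseResponseResults) -> WaldTest:
    """Wald test for departure from linearity of the exposure effect."""
    return fit.wald_nonlinearity()


def test_proportional_hazards(fit: DoseResponseResults, transform: str = "rank") -> PHTest:
    """Schoenfeld-residual proportional-hazards test of a Cox fit."""
    return fit.ph_test(transform=transform)
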