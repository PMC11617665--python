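"""Enzyme-inhibition kinetics: percent inhibition, IC50, and Ki fitting.

The assay model is a chromogenic phosphatase read-out: percent inhibition
is computed from corrected absorbances, dose-response curves follow the
Hill form

    %Inh(I) = A100 / (1 + (IC50 / I)^s),

which is 0 at I = 0 (by continuity), A100/2 at I = IC50 and saturates at
A100; ``s`` is the cooperativity degree.  Rate data over a substrate x
inhibitor grid are fitted globally (all curves simultaneously) to one of
the classical reversible-inhibition laws:

    competitive     v = Vmax S / (Km (1 + I/Ki) + S)
    uncompetitive   v = Vmax S / (Km + S (1 + I/Ki))
    noncompetitive  v = Vmax S / ((Km + S)(1 + I/Ki))
    mixed           v = Vmax S / (Km (1 + I/Ki) + S (1 + I/Ki'))

All fits are unweighted least squares with positivity enforced by
log-parameterization; standard errors come from the Jacobian-based
covariance at the optimum (delta method back to the natural scale), and
models are compared by AICc.  The double-reciprocal (Lineweaver-Burk)
transform is provided as a diagnostic only; reported parameters always
come from the nonlinear fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DomainError, FitError, FlatDataError, ParameterError

MECHANISMS = ("competitive", "uncompetitive", "noncompetitive", "mixed")


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseDataset:
    """Inhibitor concentrations (mM) with observed percent inhibition."""

    inhibitor_conc: np.ndarray
    response: np.ndarray
    replicate: Optional[np.ndarray] = None

    def __post_init__(self):
        self.inhibitor_conc = np.asarray(self.inhibitor_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.inhibitor_conc.shape != self.response.shape:
            raise ParameterError("concentration and response lengths differ")
        if np.any(self.inhibitor_conc < 0):
            raise DomainError("negative inhibitor concentration")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseDataset":
        df = pd.read_csv(path)
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        return cls(df["inhibitor_mM"].to_numpy(), df["pct_inhibition"].to_numpy(), rep)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"inhibitor_mM": self.inhibitor_conc, "pct_inhibition": self.response}
        )
        if self.replicate is not None:
            df["replicate"] = self.replicate
        df.to_csv(path, index=False, float_format="%.8g")


@dataclass
class RateDataset:
    """(substrate, inhibitor, velocity) observations, all in mM / mM/min."""

    substrate_conc: np.ndarray
    inhibitor_conc: np.ndarray
    velocity: np.ndarray

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.inhibitor_conc = np.asarray(self.inhibitor_conc, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (
            self.substrate_conc.shape
            == self.inhibitor_conc.shape
            == self.velocity.shape
        ):
            raise ParameterError("substrate, inhibitor and velocity lengths differ")
        if np.any(self.substrate_conc <= 0):
            raise DomainError("substrate concentrations must be positive")
        if np.any(self.inhibitor_conc < 0):
            raise DomainError("negative inhibitor concentration")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateDataset":
        df = pd.read_csv(path)
        return cls(
            df["substrate_mM"].to_numpy(),
            df["inhibitor_mM"].to_numpy(),
            df["velocity"].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "substrate_mM": self.substrate_conc,
                "inhibitor_mM": self.inhibitor_conc,
                "velocity": self.velocity,
            }
        ).to_csv(path, index=False, float_format="%.8g")


@dataclass
class ParamEstimate:
    estimate: float
    stderr: Optional[float] = None


@dataclass
class FitResult:
    """Fitted parameters with uncertainties plus goodness-of-fit."""

    parameters: dict[str, ParamEstimate]
    model: str
    rss: float
    aicc: float
    n_obs: int

    def __getitem__(self, name: str) -> float:
        return self.parameters[name].estimate


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def percent_inhibition(A415t, A415c):
    """Percent inhibition from corrected absorbances: (1 - At/Ac) x 100."""
    A415t = np.asarray(A415t, dtype=float)
    A415c = np.asarray(A415c, dtype=float)
    if np.any(A415c <= 0):
        raise DomainError("blank absorbance must be positive")
    out = (1.0 - A415t / A415c) * 100.0
    return float(out) if out.ndim == 0 else out


def dose_response_model(I, A100: float, IC50: float, s: float):
    """Hill dose-response; 0 at I = 0, A100/2 at I = IC50, -> A100 as I -> inf."""
    if IC50 <= 0 or s <= 0:
        raise DomainError("IC50 and s must be positive")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise DomainError("negative inhibitor concentration")
    with np.errstate(divide="ignore"):
        out = np.where(I > 0, A100 / (1.0 + (IC50 / np.where(I > 0, I, 1.0)) ** s), 0.0)
    return float(out) if out.ndim == 0 else out


def _check_positive(**params):
    for name, value in params.items():
        if value <= 0:
            raise DomainError(f"{name} must be positive, got {value}")


def competitive_rate(S, I, Vmax: float, Km: float, Ki: float):
    """Competitive inhibition: raises apparent Km, Vmax unchanged."""
    _check_positive(Vmax=Vmax, Km=Km, Ki=Ki)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    out = Vmax * S / (Km * (1.0 + I / Ki) + S)
    return float(out) if out.ndim == 0 else out


def uncompetitive_rate(S, I, Vmax: float, Km: float, Ki: float):
    """Uncompetitive inhibition: inhibitor binds only the ES complex."""
    _check_positive(Vmax=Vmax, Km=Km, Ki=Ki)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    out = Vmax * S / (Km + S * (1.0 + I / Ki))
    return float(out) if out.ndim == 0 else out


def noncompetitive_rate(S, I, Vmax: float, Km: float, Ki: float):
    """Pure noncompetitive inhibition: lowers Vmax, Km unchanged."""
    _check_positive(Vmax=Vmax, Km=Km, Ki=Ki)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    out = Vmax * S / ((Km + S) * (1.0 + I / Ki))
    return float(out) if out.ndim == 0 else out


def mixed_rate(S, I, Vmax: float, Km: float, Ki: float, Ki_prime: float):
    """Mixed inhibition with distinct E and ES dissociation constants."""
    _check_positive(Vmax=Vmax, Km=Km, Ki=Ki, Ki_prime=Ki_prime)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    out = Vmax * S / (Km * (1.0 + I / Ki) + S * (1.0 + I / Ki_prime))
    return float(out) if out.ndim == 0 else out


def cheng_prusoff_ic50(Ki: float, S: float, Km: float) -> float:
    """IC50 implied by a competitive Ki at substrate concentration S."""
    _check_positive(Ki=Ki, S=S, Km=Km)
    return Ki * (1.0 + S / Km)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for least-squares fits."""
    if n <= k + 1:
        raise ParameterError(f"AICc undefined for n={n}, k={k}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _collect(result: lmfit.minimizer.MinimizerResult, names: Sequence[str]):
    """Natural-scale estimates and delta-method standard errors."""
    params = {}
    for name in names:
        p = result.params["log_" + name]
        est = math.exp(p.value)
        se = est * p.stderr if p.stderr is not None else None
        params[name] = ParamEstimate(est, se)
    return params


class DoseResponseIC50(BaseEstimator):
    """Hill dose-response fitter for IC50 estimation.

    Parameters
    ----------
    fix_a100 : float, optional
        Fix the maximal inhibition instead of estimating it.

    Attributes (after :meth:`fit`)
    ------------------------------
    a100_, ic50_, s_ : float
    stderr_ : dict of parameter name -> standard error (or None)
    rss_, aicc_ : float
    result_ : FitResult
    """

    def __init__(self, fix_a100: Optional[float] = None):
        self.fix_a100 = fix_a100

    def fit(self, I, y):
        I = np.asarray(I, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if I.shape != y.shape:
            raise ParameterError("concentration and response lengths differ")
        positive = I > 0
        if np.unique(I[positive]).size < 4:
            raise ParameterError("need >= 4 distinct positive concentrations")
        if np.all(np.abs(y) < 1e-12):
            raise FlatDataError("responses are all ~0; nothing to fit")
        rho = stats.spearmanr(I[positive], y[positive]).statistic
        if not np.isfinite(rho) or rho <= 0:
            raise FlatDataError(
                "responses do not increase with concentration (flat or inverted data)"
            )

        ymax = float(np.max(y))
        half_idx = int(np.argmin(np.abs(y - ymax / 2.0)))
        ic50_0 = float(I[half_idx]) if I[half_idx] > 0 else float(np.median(I[positive]))
        params = lmfit.Parameters()
        params.add("log_IC50", value=math.log(ic50_0))
        params.add("log_s", value=0.0)
        if self.fix_a100 is None:
            params.add("log_A100", value=math.log(max(ymax, 1e-6)))

        def residual(p):
            a100 = self.fix_a100 if self.fix_a100 is not None else math.exp(
                p["log_A100"].value
            )
            pred = dose_response_model(
                I, a100, math.exp(p["log_IC50"].value), math.exp(p["log_s"].value)
            )
            return pred - y

        out = lmfit.minimize(residual, params, method="leastsq")
        if not out.success:
            raise FitError("dose-response fit did not converge", diagnostics=out)
        names = ["IC50", "s"] + ([] if self.fix_a100 is not None else ["A100"])
        estimates = _collect(out, names)
        if self.fix_a100 is not None:
            estimates["A100"] = ParamEstimate(float(self.fix_a100), 0.0)
        rss = float(np.sum(out.residual**2))
        k = out.nvarys
        self.ic50_ = estimates["IC50"].estimate
        self.s_ = estimates["s"].estimate
        self.a100_ = estimates["A100"].estimate
        self.stderr_ = {n: p.stderr for n, p in estimates.items()}
        self.rss_ = rss
        self.aicc_ = aicc(rss, y.size, k)
        self.result_ = FitResult(estimates, "dose_response", rss, self.aicc_, y.size)
        return self

    def predict(self, I):
        return dose_response_model(I, self.a100_, self.ic50_, self.s_)


_RATE_LAWS = {
    "competitive": competitive_rate,
    "uncompetitive": uncompetitive_rate,
    "noncompetitive": noncompetitive_rate,
    "mixed": mixed_rate,
}


class InhibitionKinetics(BaseEstimator):
    """Global Michaelis-Menten inhibition fitter.

    All inhibitor levels are fitted simultaneously with shared Vmax, Km
    and Ki (plus Ki' for the mixed model).

    Parameters
    ----------
    model : {"competitive", "uncompetitive", "noncompetitive", "mixed"}

    Attributes (after :meth:`fit`)
    ------------------------------
    vmax_, km_, ki_ : float  (and ki_prime_ for the mixed model)
    stderr_ : dict, rss_, aicc_ : float, result_ : FitResult
    """

    def __init__(self, model: str = "competitive"):
        self.model = model

    def fit(self, X, y):
        if self.model not in _RATE_LAWS:
            raise ParameterError(
                f"unknown model {self.model!r}; choose from {sorted(_RATE_LAWS)}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ParameterError("X must be (n, 2): substrate and inhibitor columns")
        S, I = X[:, 0], X[:, 1]
        v = np.asarray(y, dtype=float).ravel()
        if v.shape != S.shape:
            raise ParameterError("X and y lengths differ")
        levels = np.unique(I)
        if levels.size < 2 or 0.0 not in levels:
            raise ParameterError("need >= 2 inhibitor levels including I = 0")
        if np.unique(S).size < 4:
            raise ParameterError("need >= 4 substrate levels")

        law = _RATE_LAWS[self.model]
        names = ["Vmax", "Km", "Ki"] + (["Ki_prime"] if self.model == "mixed" else [])
        init = {
            "Vmax": float(np.max(v)) * 1.2,
            "Km": float(np.median(S)),
            "Ki": float(np.min(levels[levels > 0])),
            "Ki_prime": float(np.min(levels[levels > 0])),
        }
        params = lmfit.Parameters()
        for name in names:
            params.add("log_" + name, value=math.log(init[name]))

        def residual(p):
            values = [math.exp(p["log_" + n].value) for n in names]
            return law(S, I, *values) - v

        out = lmfit.minimize(residual, params, method="leastsq", max_nfev=20000)
        if not out.success:
            raise FitError(f"{self.model} fit did not converge", diagnostics=out)
        estimates = _collect(out, names)
        rss = float(np.sum(out.residual**2))
        self.vmax_ = estimates["Vmax"].estimate
        self.km_ = estimates["Km"].estimate
        self.ki_ = estimates["Ki"].estimate
        if self.model == "mixed":
            self.ki_prime_ = estimates["Ki_prime"].estimate
        self.stderr_ = {n: p.stderr for n, p in estimates.items()}
        self.rss_ = rss
        self.aicc_ = aicc(rss, v.size, out.nvarys)
        self.result_ = FitResult(estimates, self.model, rss, self.aicc_, v.size)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        args = [self.vmax_, self.km_, self.ki_]
        if self.model == "mixed":
            args.append(self.ki_prime_)
        return _RATE_LAWS[self.model](X[:, 0], X[:, 1], *args)


def fit_ic50(
    data: DoseResponseDataset, fix_A100: Optional[float] = None
) -> FitResult:
    """Nonlinear least-squares IC50 estimation from a dose-response dataset."""
    est = DoseResponseIC50(fix_a100=fix_A100).fit(data.inhibitor_conc, data.response)
    return est.result_


def fit_inhibition(data: RateDataset, model: str = "competitive") -> FitResult:
    """Global inhibition-kinetics fit on a rate dataset."""
    X = np.column_stack([data.substrate_conc, data.inhibitor_conc])
    est = InhibitionKinetics(model=model).fit(X, data.velocity)
    return est.result_


def select_mechanism(
    data: RateDataset,
    candidates: Sequence[str] = ("competitive", "uncompetitive", "noncompetitive"),
) -> tuple[str, dict[str, FitResult]]:
    """Fit each candidate mechanism and pick the lowest AICc.

    The default candidate set holds the three pure mechanisms; the mixed
    model nests all of them and is only compared when explicitly listed.
    """
    fits = {m: fit_inhibition(data, m) for m in candidates}
    best = min(fits, key=lambda m: fits[m].aicc)
    return best, fits


# ---------------------------------------------------------------------------
# Lineweaver-Burk diagnostics
# ---------------------------------------------------------------------------

@dataclass
class LineFit:
    slope: float
    intercept: float


@dataclass
class LineweaverBurk:
    """Per-inhibitor-level double-reciprocal line fits plus a heuristic call."""

    lines: dict[float, LineFit]
    classification: str
    intercept_spread: float
    slope_spread: float

    def __getitem__(self, level: float) -> LineFit:
        return self.lines[level]


def _relative_spread(values: np.ndarray) -> float:
    scale = np.max(np.abs(values))
    if scale == 0:
        return 0.0
    return float(np.ptp(values) / scale)


def lineweaver_burk(data: RateDataset, rtol: float = 0.1) -> LineweaverBurk:
    """OLS of 1/v on 1/S per inhibitor level, plus a mechanism heuristic.

    Shared 1/v intercept -> competitive; parallel slopes -> uncompetitive;
    shared 1/S (abscissa) intercept -> noncompetitive; otherwise mixed.
    ``rtol`` is the relative spread below which quantities count as
    shared; the default suits assay-level noise, tighten it (e.g. 1e-6)
    for noise-free data.  Diagnostic only: reported parameters always
    come from the nonlinear fit.
    """
    if np.any(data.velocity <= 0):
        raise DomainError("all velocities must be positive for 1/v")
    lines: dict[float, LineFit] = {}
    for level in np.unique(data.inhibitor_conc):
        mask = data.inhibitor_conc == level
        inv_s = 1.0 / data.substrate_conc[mask]
        inv_v = 1.0 / data.velocity[mask]
        res = stats.linregress(inv_s, inv_v)
        lines[float(level)] = LineFit(float(res.slope), float(res.intercept))
    slopes = np.array([lf.slope for lf in lines.values()])
    intercepts = np.array([lf.intercept for lf in lines.values()])
    slope_spread = _relative_spread(slopes)
    intercept_spread = _relative_spread(intercepts)
    if len(lines) < 2:
        classification = "single_level"
    elif intercept_spread < rtol <= slope_spread:
        classification = "competitive"
    elif slope_spread < rtol <= intercept_spread:
        classification = "uncompetitive"
    else:
        x_intercepts = -intercepts / slopes
        if _relative_spread(x_intercepts) < rtol and slope_spread >= rtol:
            classification = "noncompetitive"
        elif slope_spread < rtol and intercept_spread < rtol:
            classification = "no_inhibition"
        else:
            classification = "mixed"
    return LineweaverBurk(lines, classification, intercept_spread, slope_spread)
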