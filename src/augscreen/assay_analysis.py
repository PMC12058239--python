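"""ATPase activity-table analysis and concentration-response modeling.

Activity is expressed as percent of the untreated control (100 %).  A
compound at a given concentration is called an *activator* when its mean
activity exceeds 100 + margin percentage points, an *inhibitor* below
100 - margin, and *marginal* otherwise (margin defaults to 5, the
conventional primary-screen cutoff).

Concentration-response curves are fitted by nonlinear least squares to

* a four-parameter logistic (4PL, Hill) model::

      y(c) = bottom + (top - bottom) / (1 + 10^(h * (log10 EC50 - log10 c)))

* a biphasic (bell-shaped) model — an activating Hill term multiplied by the
  complement of an inhibitory Hill term::

      y(c) = bottom + span * f(c; EC50, h1) * (1 - f(c; IC50, h2))

The preferred model is the one with the lower AICc; the nonmonotonic flag is
set when the biphasic model beats the 4PL by at least ``delta_aicc`` (default
4, the conventional "considerably less support" cutoff).  EC50/IC50 are
fitted on a log10 scale with the initial EC50 at the geometric mean of the
concentration range, Hill slopes initialized at 1 and plateaus from the data
extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

REQUIRED_COLUMNS = ("compound", "conc_uM", "mean_pct", "sem_pct", "n")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries last parameters and residuals."""

    def __init__(self, message: str, params: dict | None = None, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.params = params
        self.residuals = residuals


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

@dataclass
class ActivityTable:
    """Rows of (compound, concentration uM, mean % of control, SEM %, N)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"activity table missing columns: {missing}")
        for col in ("conc_uM", "mean_pct", "sem_pct"):
            if not np.issubdtype(self.data[col].dtype, np.number):
                raise ValueError(f"non-numeric values in column {col!r}")
        if (self.data["conc_uM"] <= 0).any():
            bad = self.data.loc[self.data["conc_uM"] <= 0]
            raise ValueError(f"nonpositive concentrations: {bad['conc_uM'].tolist()}")
        if (self.data["n"] < 1).any():
            raise ValueError("replicate count N must be >= 1")

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.data["compound"]))

    @property
    def concentrations(self) -> list[float]:
        return sorted(self.data["conc_uM"].unique())

    def at(self, concentration: float) -> pd.DataFrame:
        sub = self.data[np.isclose(self.data["conc_uM"], concentration)]
        if sub.empty:
            raise KeyError(f"concentration {concentration} uM not present in table")
        return sub

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def load_activity_table(path: str | Path) -> ActivityTable:
    """Read and validate an activity CSV (compound, conc_uM, mean_pct, sem_pct, n)."""
    df = pd.read_csv(path)
    return ActivityTable(data=df)


def load_atpase_reference_table() -> ActivityTable:
    """The packaged ten-compound ATPase fixture (activity at 1 and 10 uM)."""
    with resources.as_file(resources.files("augscreen.data").joinpath("atpase_reference.csv")) as p:
        return load_activity_table(p)


@dataclass(frozen=True)
class ModulationCall:
    compound: str
    concentration: float
    call: str  # activator | marginal | inhibitor
    mean_pct: float
    margin: float


def classify_modulation(tbl: ActivityTable, concentration: float, margin: float = 5.0) -> list[ModulationCall]:
    """One call per compound at the given concentration by the margin rule.

    activator iff mean > 100 + margin; inhibitor iff mean < 100 - margin;
    marginal otherwise.  The boundary is exact: a mean of precisely
    100 + margin is marginal.
    """
    sub = tbl.at(concentration)
    calls = []
    for row in sub.itertuples():
        if row.mean_pct > 100 + margin:
            call = "activator"
        elif row.mean_pct < 100 - margin:
            call = "inhibitor"
        else:
            call = "marginal"
        calls.append(
            ModulationCall(
                compound=row.compound,
                concentration=concentration,
                call=call,
                mean_pct=row.mean_pct,
                margin=margin,
            )
        )
    return calls


def modulation_summary(calls: Sequence[ModulationCall]) -> dict[str, int]:
    out = {"activator": 0, "marginal": 0, "inhibitor": 0}
    for c in calls:
        out[c.call] += 1
    return out


# ---------------------------------------------------------------------------
# Dose-response models
# ---------------------------------------------------------------------------

def four_param_logistic(c: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - np.log10(c))))


def biphasic_response(
    c: np.ndarray,
    bottom: float,
    span: float,
    log_ec50: float,
    hill1: float,
    log_ic50: float,
    hill2: float,
) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    logc = np.log10(c)
    f_act = 1.0 / (1.0 + 10.0 ** (hill1 * (log_ec50 - logc)))
    f_inh = 1.0 / (1.0 + 10.0 ** (hill2 * (log_ic50 - logc)))
    return bottom + span * f_act * (1.0 - f_inh)


def _aicc(rss: float, n: int, k: int) -> float:
    # k model parameters + 1 for the error variance
    k = k + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


@dataclass
class DoseResponseFit:
    model: str  # "4PL" | "biphasic"
    ec50: float
    hill: float
    top: float
    bottom: float
    ic50: float | None
    hill2: float | None
    rss: float
    aicc: float
    aicc_4pl: float
    aicc_biphasic: float | None
    nonmonotonic: bool

    def predict(self, c: np.ndarray) -> np.ndarray:
        if self.model == "4PL":
            return four_param_logistic(c, self.bottom, self.top, np.log10(self.ec50), self.hill)
        return biphasic_response(
            c, self.bottom, self.top - self.bottom, np.log10(self.ec50), self.hill,
            np.log10(self.ic50), self.hill2,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "ec50_uM": self.ec50,
            "hill": self.hill,
            "top_pct": self.top,
            "bottom_pct": self.bottom,
            "ic50_uM": self.ic50,
            "hill2": self.hill2,
            "rss": self.rss,
            "aicc": self.aicc,
            "nonmonotonic": self.nonmonotonic,
        }


_MAX_ITER = 2000
_TOL = 1e-10
_HILL_BOUNDS = (0.1, 5.0)  # physically plausible slope range
_MAX_RESTARTS = 4


def _least_squares_with_restarts(resid, x0, lo, hi):
    """Bounded least squares with warm restarts.

    The biphasic surface has flat valleys where the optimizer exhausts its
    evaluation budget without meeting the strict tolerances; a solution is
    accepted as converged when a warm restart improves the cost by less than
    1e-6 relative (parameters are stationary for practical purposes).
    """
    res = least_squares(resid, x0, bounds=(lo, hi), xtol=_TOL, ftol=_TOL, gtol=_TOL, max_nfev=_MAX_ITER)
    prev = res.cost
    for _ in range(_MAX_RESTARTS):
        if res.success:
            return res, True
        res = least_squares(resid, res.x, bounds=(lo, hi), xtol=_TOL, ftol=_TOL, gtol=_TOL, max_nfev=_MAX_ITER)
        if abs(prev - res.cost) <= 1e-6 * max(prev, 1e-12):
            return res, True
        prev = res.cost
    return res, bool(res.success)


def _fit_4pl(logc: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    bottom0, top0 = float(y[np.argmin(logc)]), float(y[np.argmax(np.abs(y - y[np.argmin(logc)]))])
    x0 = np.array([bottom0, top0, float(np.mean(logc)), 1.0])

    def resid(p):
        return four_param_logistic(10.0 ** logc, p[0], p[1], p[2], p[3]) - y

    lo = [-np.inf, -np.inf, logc.min() - 3, _HILL_BOUNDS[0]]
    hi = [np.inf, np.inf, logc.max() + 3, _HILL_BOUNDS[1]]
    x0 = np.clip(x0, lo, hi)
    res, ok = _least_squares_with_restarts(resid, x0, lo, hi)
    if not ok:
        raise FitError(
            "4PL fit did not converge",
            params={"bottom": res.x[0], "top": res.x[1], "log_ec50": res.x[2], "hill": res.x[3]},
            residuals=res.fun,
        )
    return res.x, float(np.sum(res.fun**2))


def _fit_biphasic(logc: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    bottom0 = float(y[np.argmin(logc)])
    span0 = max(2.0 * (float(y.max()) - bottom0), 1.0)
    lo_third = logc.min() + (logc.max() - logc.min()) / 3.0
    hi_third = logc.min() + 2.0 * (logc.max() - logc.min()) / 3.0
    x0 = np.array([bottom0, span0, lo_third, 1.0, hi_third, 1.0])

    def resid(p):
        return biphasic_response(10.0 ** logc, *p) - y

    lo = [-np.inf, 0.0, logc.min() - 3, _HILL_BOUNDS[0], logc.min() - 3, _HILL_BOUNDS[0]]
    hi = [np.inf, np.inf, logc.max() + 3, _HILL_BOUNDS[1], logc.max() + 3, _HILL_BOUNDS[1]]
    res, ok = _least_squares_with_restarts(resid, x0, lo, hi)
    if not ok:
        raise FitError("biphasic fit did not converge", params={"x": res.x.tolist()}, residuals=res.fun)
    return res.x, float(np.sum(res.fun**2))


def fit_dose_response(
    curve: Sequence[tuple[float, float]],
    models: Sequence[str] = ("4PL", "biphasic"),
    delta_aicc: float = 4.0,
) -> DoseResponseFit:
    """Fit the concentration-response models and return the AICc-preferred one.

    Requires >= 5 distinct concentrations for the 4PL and >= 7 for the
    biphasic model (which is otherwise skipped).  The nonmonotonic flag is
    set iff the biphasic model is preferred by at least ``delta_aicc``.

    ``curve`` may contain repeated concentrations (replicate-level points):
    all points enter the least-squares fit and the information criteria.
    On small designs (e.g. nine concentrations) model discrimination should
    use replicate-level data — AICc's small-sample correction at n = 9 is
    too severe for the six-parameter biphasic model to ever be preferred,
    whereas n = 27 (triplicates) discriminates reliably.
    """
    arr = np.asarray(sorted(curve), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("curve must be a sequence of (concentration, response) pairs")
    c, y = arr[:, 0], arr[:, 1]
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    n_distinct = len(np.unique(c))
    if "4PL" not in models:
        raise ValueError("the 4PL model is required as the monotone reference")
    if n_distinct < 5:
        raise ValueError(f"need >= 5 distinct concentrations for the 4PL fit (got {n_distinct})")
    logc = np.log10(c)
    n = len(y)

    fit4 = None
    fit4_error: FitError | None = None
    try:
        p4, rss4 = _fit_4pl(logc, y)
        fit4 = (p4, rss4, _aicc(rss4, n, 4))
    except FitError as exc:
        fit4_error = exc

    fit_bi = None
    if "biphasic" in models and n_distinct >= 7:
        try:
            pb, rssb = _fit_biphasic(logc, y)
            fit_bi = (pb, rssb, _aicc(rssb, n, 6))
        except FitError:
            fit_bi = None

    if fit4 is None and fit_bi is None:
        raise fit4_error if fit4_error is not None else FitError("no model converged")
    aicc4 = fit4[2] if fit4 is not None else np.inf
    # biphasic wins on AICc margin, or by default when the monotone
    # reference cannot describe the data at all
    use_biphasic = fit_bi is not None and (aicc4 - fit_bi[2]) >= delta_aicc
    if fit4 is None:
        use_biphasic = True
    if use_biphasic:
        pb, rssb, aiccb = fit_bi
        bottom, span, log_ec50, h1, log_ic50, h2 = pb
        return DoseResponseFit(
            model="biphasic",
            ec50=float(10.0 ** log_ec50),
            hill=float(h1),
            top=float(bottom + span),
            bottom=float(bottom),
            ic50=float(10.0 ** log_ic50),
            hill2=float(h2),
            rss=rssb,
            aicc=aiccb,
            aicc_4pl=aicc4,
            aicc_biphasic=aiccb,
            nonmonotonic=True,
        )
    bottom, top, log_ec50, hill = fit4[0]
    rss4 = fit4[1]
    return DoseResponseFit(
        model="4PL",
        ec50=float(10.0 ** log_ec50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        ic50=None,
        hill2=None,
        rss=rss4,
        aicc=aicc4,
        aicc_4pl=aicc4,
        aicc_biphasic=fit_bi[2] if fit_bi else None,
        nonmonotonic=False,
    )
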