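"""Dose-mortality statistics: Abbott correction, probit LC50, pLC50.

The bioassay design this supports is the classic topical/immersion assay:
five serial concentrations, a fixed number of organisms per dose (30 in the
study design), a solvent-only control, and dead/alive scoring after 24 h.
Observed mortalities are corrected for natural (control) mortality with
Abbott's formula, then a probit regression of corrected mortality on log10
concentration is fitted by maximum likelihood (IRLS, via statsmodels GLM);
the median lethal concentration follows as LC50 = 10**(-alpha/beta) and a
95% confidence interval comes from the delta method on log10 LC50.

Activities are summarized on the pLC50 scale, -log10 of the molar LC50;
with concentrations in mmol/L this is pLC50 = 3 - log10(LC50 mM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, SchemaError

__all__ = [
    "DoseResponseSeries",
    "ProbitFit",
    "ActivityRecord",
    "abbott_correct",
    "fit_probit",
    "to_plc50",
    "from_plc50",
    "summarize_activity",
    "records_from_table",
]


@dataclass
class DoseResponseSeries:
    """Raw dose-mortality counts for one compound/species pair."""

    compound: str
    species: str
    doses: np.ndarray  # mmol/L, strictly positive, sorted ascending
    n_exposed: np.ndarray
    n_dead: np.ndarray
    control_exposed: int = 0
    control_dead: int = 0

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n_exposed = np.asarray(self.n_exposed, dtype=int)
        self.n_dead = np.asarray(self.n_dead, dtype=int)
        if self.doses.ndim != 1 or len(set(map(len, (self.doses, self.n_exposed, self.n_dead)))) != 1:
            raise SchemaError("doses, n_exposed and n_dead must be equal-length vectors")
        if np.any(self.doses <= 0):
            raise SchemaError("doses must be strictly positive")
        if np.any(np.diff(self.doses) <= 0):
            raise SchemaError("doses must be sorted ascending and distinct")
        if len(np.unique(self.doses)) < 2:
            raise SchemaError("need at least 2 distinct doses")
        if np.any(self.n_dead < 0) or np.any(self.n_dead > self.n_exposed):
            raise SchemaError("0 <= n_dead <= n_exposed violated")

    @property
    def control_mortality(self) -> float:
        if self.control_exposed == 0:
            return 0.0
        return self.control_dead / self.control_exposed


@dataclass
class ProbitFit:
    """Maximum-likelihood probit fit on log10 dose."""

    compound: str
    species: str
    intercept: float  # alpha
    slope: float  # beta, probits per log10 dose unit
    lc50: float  # mmol/L
    lc50_ci: tuple[float, float] | None  # 95%, delta method; None if beta <= 0
    converged: bool
    loglik: float
    n_iterations: int = 0

    @property
    def plc50(self) -> float:
        return to_plc50(self.lc50)


@dataclass
class ActivityRecord:
    """One compound/species activity on both LC50 and pLC50 scales."""

    compound: str
    species: str
    lc50: float  # mmol/L
    role: str = "train"  # train / test / reference
    plc50: float = field(init=False)

    def __post_init__(self) -> None:
        self.plc50 = to_plc50(self.lc50)


# ---------------------------------------------------------------------------


def abbott_correct(p_obs: float, p_control: float) -> float:
    """Abbott's control-mortality correction (p_obs - p_c) / (1 - p_c).

    Negative corrected values (treatment mortality below control) are floored
    at zero.
    """
    if not 0 <= p_control < 1:
        raise FitError("control mortality must be in [0, 1)")
    if not 0 <= p_obs <= 1:
        raise FitError("observed mortality must be in [0, 1]")
    return max(0.0, (p_obs - p_control) / (1.0 - p_control))


def to_plc50(lc50_mM: float) -> float:
    """pLC50 = -log10(LC50 in mol/L) = 3 - log10(LC50 in mmol/L)."""
    if lc50_mM <= 0:
        raise ValueError("LC50 must be positive")
    return 3.0 - math.log10(lc50_mM)


def from_plc50(plc50: float) -> float:
    """Inverse of :func:`to_plc50`; returns LC50 in mmol/L."""
    return 10.0 ** (3.0 - plc50)


def fit_probit(
    series: DoseResponseSeries,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> ProbitFit:
    """Fit Phi^-1(p) = alpha + beta * log10(dose) to Abbott-corrected data.

    The corrected per-dose mortality proportions are treated as binomial
    with the exposed counts as weights (quasi-binomial treatment of the
    correction) and fitted by IRLS.  The 95% LC50 interval is obtained by
    the delta method on log10 LC50 = -alpha/beta; it is suppressed (None)
    when the fitted slope is non-positive.
    """
    p_obs = series.n_dead / series.n_exposed
    p_c = series.control_mortality
    p_corr = np.array([abbott_correct(p, p_c) for p in p_obs])
    if np.all(p_corr == 0.0) or np.all(p_corr == 1.0):
        raise FitError(
            f"complete separation for {series.compound!r}: all-alive or "
            "all-dead at every dose after correction"
        )
    x = np.log10(series.doses)
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            # non-integer corrected proportions are intentional here
            warnings.simplefilter("ignore")
            model = sm.GLM(
                p_corr,
                exog,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
                var_weights=series.n_exposed.astype(float),
            )
            res = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # perfect separation and friends
        raise FitError(f"probit fit failed for {series.compound!r}: {exc}") from exc
    alpha, beta = float(res.params[0]), float(res.params[1])
    converged = bool(res.converged)
    lc50 = 10.0 ** (-alpha / beta) if beta != 0 else float("nan")
    ci = None
    if beta > 0:
        # delta method on m = -alpha/beta
        cov = np.asarray(res.cov_params())
        grad = np.array([-1.0 / beta, alpha / beta**2])
        var_m = float(grad @ cov @ grad)
        if var_m >= 0:
            half = stats.norm.ppf(0.975) * math.sqrt(var_m)
            m = -alpha / beta
            ci = (10.0 ** (m - half), 10.0 ** (m + half))
    return ProbitFit(
        compound=series.compound,
        species=series.species,
        intercept=alpha,
        slope=beta,
        lc50=float(lc50),
        lc50_ci=ci,
        converged=converged,
        loglik=float(res.llf),
        n_iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
    )


# ---------------------------------------------------------------------------
# activity tables


def records_from_table(
    table: pd.DataFrame,
    roles: dict[str, str] | None = None,
    reference: str = "1",
) -> list[ActivityRecord]:
    """Build ActivityRecords from a long table (compound, species, lc50_mM)."""
    required = {"compound", "species", "lc50_mM"}
    if not required <= set(table.columns):
        raise SchemaError(f"activity table needs columns {sorted(required)}")
    out = []
    for _, row in table.iterrows():
        cid = str(row["compound"])
        if cid == reference:
            role = "reference"
        elif roles is not None:
            role = roles.get(cid, "train")
        else:
            role = "train"
        out.append(
            ActivityRecord(
                compound=cid,
                species=str(row["species"]),
                lc50=float(row["lc50_mM"]),
                role=role,
            )
        )
    return out


@dataclass
class ActivitySummary:
    species: str
    n_derivatives: int
    lc50_min: float
    lc50_max: float
    reference_lc50: float | None
    n_more_potent_than_reference: int | None


def summarize_activity(
    records: list[ActivityRecord], species: str, reference: str = "1"
) -> ActivitySummary:
    """Min/max LC50 over the derivatives and the count beating the reference.

    The reference compound (the parent natural product) is excluded from the
    min/max; "more potent" means a strictly smaller LC50 than the reference.
    """
    rows = [r for r in records if r.species == species]
    if not rows:
        raise SchemaError(f"no records for species {species!r}")
    deriv = [r for r in rows if r.compound != reference]
    ref = next((r for r in rows if r.compound == reference), None)
    lc = np.array([r.lc50 for r in deriv])
    n_better = None
    if ref is not None:
        n_better = int((lc < ref.lc50).sum())
    return ActivitySummary(
        species=species,
        n_derivatives=len(deriv),
        lc50_min=float(lc.min()),
        lc50_max=float(lc.max()),
        reference_lc50=None if ref is None else ref.lc50,
        n_more_potent_than_reference=n_better,
    )
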