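"""Stopped-flow FRET membrane-binding kinetics under a two-step scheme.

The model: unbound protein U binds accessible lipid L with rate constant
``k_on`` (mM^-1 s^-1) and leaves the membrane with ``k_off`` (s^-1); bound
protein B oligomerizes with ``k_oli`` and oligomers O disassemble with
``k_dis``.  Under pseudo-first-order conditions (lipid in large excess, L
constant) the state fractions obey a linear 3-state system

    dU/dt = -k_on*L*U + k_off*B
    dB/dt =  k_on*L*U - k_off*B - k_oli*B + k_dis*O
    dO/dt =  k_oli*B - k_dis*O

with U+B+O = 1 and U(0) = 1.  Observed traces are fit to a sum of up to
three exponentials; the fastest observed rate ``k_obs1`` grows linearly
with accessible lipid, ``k_obs1 = k_on*[accessible lipid] + k_off_app``,
and the apparent dissociation rate decomposes as
``k_off_app = k_off + k_oli + k_dis``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import statsmodels.api as sm
from scipy.integrate import solve_ivp


class FitError(RuntimeError):
    """Raised when a fit result is required but the fit did not converge."""


class PseudoFirstOrderWarning(UserWarning):
    """Accessible lipid is not in large excess over protein."""


def _require_nonneg_finite(name: str, value: float) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise ValueError(f"{name} must be finite and >= 0, got {value}")


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the two-step binding/oligomerization scheme.

    k_on in mM^-1 s^-1; k_off, k_oli, k_dis in s^-1.
    """

    k_on: float
    k_off: float
    k_oli: float = 0.0
    k_dis: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_oli", "k_dis"):
            _require_nonneg_finite(name, getattr(self, name))

    def rate_matrix(self, accessible_lipid: float) -> np.ndarray:
        """3x3 generator matrix of the (U, B, O) system at lipid L (mM)."""
        kl = self.k_on * accessible_lipid
        return np.array(
            [
                [-kl, self.k_off, 0.0],
                [kl, -(self.k_off + self.k_oli), self.k_dis],
                [0.0, self.k_oli, -self.k_dis],
            ]
        )


def koff_app_from_rates(params: RateParameters) -> float:
    """Apparent dissociation rate: k_off + k_oli + k_dis (s^-1)."""
    return params.k_off + params.k_oli + params.k_dis


def accessible_lipid(total_lipid: float, fraction: float = 0.6) -> float:
    """Accessible lipid concentration (mM).

    Only the outer-leaflet share of vesicle lipid is available to the
    protein; by convention 60% of total lipid is taken as accessible.
    """
    if not total_lipid >= 0:
        raise ValueError(f"total_lipid must be >= 0, got {total_lipid}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return total_lipid * fraction


@dataclass(frozen=True)
class LipidCondition:
    """Vesicle lipid condition of one mixing experiment."""

    total_lipid: float  # mM
    accessible_fraction: float = 0.6
    pip_mole_fraction: float = 0.01  # metadata only
    label: str = ""

    def __post_init__(self) -> None:
        if not self.total_lipid >= 0:
            raise ValueError("total_lipid must be >= 0")
        if not 0 < self.accessible_fraction <= 1:
            raise ValueError("accessible_fraction must be in (0, 1]")

    @property
    def accessible_lipid(self) -> float:
        return accessible_lipid(self.total_lipid, self.accessible_fraction)

    @classmethod
    def from_accessible(
        cls, accessible: float, accessible_fraction: float = 0.6, **kw
    ) -> "LipidCondition":
        """Build a condition from the accessible (not total) concentration."""
        return cls(
            total_lipid=accessible / accessible_fraction,
            accessible_fraction=accessible_fraction,
            **kw,
        )


@dataclass(frozen=True)
class ObservableModel:
    """Linear fluorescence readout over the (U, B, O) state fractions.

    FRET between labelled protein and labelled vesicles senses membrane
    proximity, so by default bound and oligomeric protein contribute
    equally (coeff_bound == coeff_oligomer) and unbound protein not at
    all.  ``drift_phases`` are additive slow exponentials (amplitude a.u.,
    rate s^-1) standing in for aggregation drift.
    """

    F_base: float = 0.0
    coeff_unbound: float = 0.0
    coeff_bound: float = 1.0
    coeff_oligomer: float = 1.0
    drift_phases: tuple = ()

    def __post_init__(self) -> None:
        for name in ("F_base", "coeff_unbound", "coeff_bound", "coeff_oligomer"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for amp, rate in self.drift_phases:
            if not rate >= 0:
                raise ValueError("drift rates must be >= 0")


@dataclass(frozen=True)
class StoppedFlowTrace:
    """A time-resolved fluorescence record with concentration metadata."""

    times: np.ndarray  # s, strictly increasing, first >= 0
    fluorescence: np.ndarray  # a.u.
    condition: LipidCondition
    protein_conc: float  # uM
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fluorescence", fluo)
        if times.ndim != 1 or len(times) != len(fluo):
            raise ValueError("times and fluorescence must be 1-D of equal length")
        if len(times) < 8:
            raise ValueError("a trace needs at least 8 points")
        if times[0] < 0:
            raise ValueError("times must start at >= 0")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")


def _simulate_states(
    params: RateParameters, lipid: float, times: np.ndarray
) -> np.ndarray:
    """Integrate the 3-state ODE; returns an (n, 3) array of (U, B, O)."""
    matrix = params.rate_matrix(lipid)
    sol = solve_ivp(
        lambda t, x: matrix @ x,
        (0.0, float(times[-1]) if times[-1] > 0 else 1e-12),
        [1.0, 0.0, 0.0],
        t_eval=times,
        method="LSODA",
        jac=lambda t, x: matrix,
        rtol=1e-10,
        atol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def simulate_trace(
    params: RateParameters,
    obs: ObservableModel,
    cond: LipidCondition,
    duration: float,
    n_points: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    protein_conc: float = 0.25,
    label: str = "",
) -> StoppedFlowTrace:
    """Simulate one stopped-flow trace (times on [0, duration], n_points).

    The trajectory is integrated numerically from the two-step rate
    equations; fluorescence is the ObservableModel readout plus drift
    exponentials and i.i.d. Gaussian noise of sd ``noise_sd``.  Identical
    seeds give bit-identical traces.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    if not noise_sd >= 0:
        raise ValueError("noise_sd must be >= 0")
    lipid = cond.accessible_lipid
    if protein_conc > 0 and lipid < 100 * (protein_conc * 1e-3):
        warnings.warn(
            f"accessible lipid {lipid} mM is not >= 100x protein "
            f"({protein_conc} uM); pseudo-first-order analysis may be biased",
            PseudoFirstOrderWarning,
            stacklevel=2,
        )
    times = np.linspace(0.0, duration, n_points)
    states = _simulate_states(params, lipid, times)
    coeffs = np.array([obs.coeff_unbound, obs.coeff_bound, obs.coeff_oligomer])
    fluo = obs.F_base + states @ coeffs
    for amp, rate in obs.drift_phases:
        fluo = fluo + amp * np.exp(-rate * times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fluo = fluo + rng.normal(0.0, noise_sd, size=fluo.shape)
    return StoppedFlowTrace(
        times=times,
        fluorescence=fluo,
        condition=cond,
        protein_conc=protein_conc,
        label=label,
        seed=seed,
    )


@dataclass(frozen=True)
class Phase:
    """One exponential phase A * exp(-k t) of a trace fit."""

    amplitude: float
    rate: float
    amplitude_se: float = float("nan")
    rate_se: float = float("nan")


@dataclass(frozen=True)
class ExpFit:
    """Result of fitting F(t) = F0 + sum_i A_i exp(-k_i t)."""

    f0: float
    phases: tuple  # Phase, sorted by descending rate
    rss: float
    converged: bool
    f0_se: float = float("nan")

    def __post_init__(self) -> None:
        if not 1 <= len(self.phases) <= 3:
            raise ValueError("an ExpFit carries 1-3 phases")
        rates = [p.rate for p in self.phases]
        if self.converged and any(not r > 0 for r in rates):
            raise ValueError("all rates of a converged fit must be > 0")
        if rates != sorted(rates, reverse=True):
            raise ValueError("phases must be sorted by descending rate")


def _multiexp(t: np.ndarray, f0: float, amps, rates) -> np.ndarray:
    out = np.full_like(t, f0, dtype=float)
    for a, k in zip(amps, rates):
        out += a * np.exp(-k * t)
    return out


def fit_multiexponential(
    trace: StoppedFlowTrace, n_phases: int, max_restarts: int = 5
) -> ExpFit:
    """Least-squares fit of a trace to a sum of 1-3 exponentials plus offset.

    Initial rate guesses are log-spaced across the resolvable band
    [1/duration, n_points/duration].  Single-phase fits are well
    conditioned and restart (up to ``max_restarts`` perturbed guesses)
    only on failure; multi-phase fits are ill-conditioned, so all
    restarts are evaluated and the lowest-RSS converged solution wins.
    A non-converged result (converged=False) is returned when every
    start fails.  Standard errors come from the local curvature of the
    objective.
    """
    if n_phases not in (1, 2, 3):
        raise ValueError("n_phases must be 1, 2 or 3")
    t = trace.times
    y = trace.fluorescence
    span = t[-1] - t[0]
    k_lo, k_hi = 1.0 / span, len(t) / span
    base_rates = np.geomspace(k_lo, k_hi, n_phases + 2)[1:-1]
    amp0 = (y[0] - y[-1]) / n_phases
    if amp0 == 0:
        amp0 = max(np.ptp(y), 1e-6) / n_phases
    rng = np.random.default_rng(20170)  # internal multistart jitter, fixed

    def attempt(rates0, amps0) -> lmfit.minimizer.MinimizerResult | None:
        params = lmfit.Parameters()
        params.add("f0", value=float(y[-1]))
        for i, (k0, a0) in enumerate(zip(rates0, amps0)):
            params.add(f"a{i}", value=float(a0))
            params.add(f"k{i}", value=float(k0), min=1e-12)

        def resid(p):
            amps = [p[f"a{i}"].value for i in range(n_phases)]
            rates = [p[f"k{i}"].value for i in range(n_phases)]
            return _multiexp(t, p["f0"].value, amps, rates) - y

        try:
            res = lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            return None
        return res if res.success else None

    def rss_of(res) -> float:
        return float(np.sum(np.asarray(res.residual) ** 2))

    result = attempt(base_rates, [amp0] * n_phases)
    exhaust_starts = n_phases > 1  # multi-phase objectives have local minima
    tries = 0
    while tries < max_restarts and (result is None or exhaust_starts):
        tries += 1
        jitter = rng.lognormal(0.0, 1.0, size=n_phases)
        rates0 = np.clip(base_rates * jitter, k_lo / 10, k_hi * 10)
        amps0 = amp0 * rng.lognormal(0.0, 0.5, size=n_phases)
        candidate = attempt(rates0, amps0)
        if candidate is not None and (result is None or rss_of(candidate) < rss_of(result)):
            result = candidate

    if result is None:
        return ExpFit(
            f0=float(y[-1]),
            phases=tuple(
                Phase(amplitude=float("nan"), rate=k) for k in sorted(base_rates)[::-1]
            )[:n_phases]
            or (Phase(float("nan"), k_hi),),
            rss=float("inf"),
            converged=False,
        )

    def se(name: str) -> float:
        err = result.params[name].stderr
        return float(err) if err is not None else float("nan")

    phases = [
        Phase(
            amplitude=result.params[f"a{i}"].value,
            rate=result.params[f"k{i}"].value,
            amplitude_se=se(f"a{i}"),
            rate_se=se(f"k{i}"),
        )
        for i in range(n_phases)
    ]
    phases.sort(key=lambda p: p.rate, reverse=True)
    return ExpFit(
        f0=result.params["f0"].value,
        f0_se=se("f0"),
        phases=tuple(phases),
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=all(p.rate > 0 for p in phases),
    )


@dataclass(frozen=True)
class KobsPoint:
    """Fastest observed rate at one accessible-lipid concentration."""

    accessible_lipid: float  # mM
    k_obs1: float  # s^-1
    se: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if not self.k_obs1 > 0:
            raise ValueError("k_obs1 must be > 0")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def select_kobs1(
    fit: ExpFit, cond: LipidCondition, rule: str = "fastest"
) -> KobsPoint:
    """Pick the binding-phase rate of a multi-exponential fit.

    Slower phases are discarded as aggregation artefacts.  ``rule`` is
    "fastest" (default) or "largest_amplitude".
    """
    if not fit.converged:
        raise FitError("cannot select k_obs1 from an unconverged fit")
    if rule == "fastest":
        phase = fit.phases[0]
    elif rule == "largest_amplitude":
        phase = max(fit.phases, key=lambda p: abs(p.amplitude))
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    se = phase.rate_se
    return KobsPoint(
        accessible_lipid=cond.accessible_lipid,
        k_obs1=phase.rate,
        se=se if math.isfinite(se) else 0.0,
    )


@dataclass(frozen=True)
class PfoFit:
    """Pseudo-first-order line k_obs1 = k_on * L + k_off_app."""

    k_on: float  # slope, mM^-1 s^-1
    k_on_se: float
    k_off_app: float  # intercept, s^-1
    k_off_app_se: float
    r_squared: float
    n_points: int
    weighted: bool
    negative_intercept: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a line fit needs >= 2 points")
        if self.k_on_se < 0 or self.k_off_app_se < 0:
            raise ValueError("standard errors must be >= 0")


def fit_pseudo_first_order(points: Sequence[KobsPoint]) -> PfoFit:
    """Weighted linear fit of k_obs1 against accessible lipid.

    Weights are 1/se^2; if any point carries a zero or non-finite SE
    (e.g. noiseless fixtures) the fit falls back to ordinary least
    squares.  A negative intercept is reported as-is with a flag, never
    clamped.
    """
    points = list(points)
    x = np.array([p.accessible_lipid for p in points])
    y = np.array([p.k_obs1 for p in points])
    ses = np.array([p.se for p in points])
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct accessible-lipid values")
    weighted = bool(np.all(np.isfinite(ses)) and np.all(ses > 0))
    weights = 1.0 / ses**2 if weighted else np.ones_like(y)
    res = sm.WLS(y, sm.add_constant(x), weights=weights).fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    if intercept < 0:
        warnings.warn(
            f"negative fitted intercept k_off_app = {intercept:.4g} s^-1",
            UserWarning,
            stacklevel=2,
        )
    return PfoFit(
        k_on=float(slope),
        k_on_se=float(slope_se),
        k_off_app=float(intercept),
        k_off_app_se=float(intercept_se),
        r_squared=float(res.rsquared),
        n_points=len(points),
        weighted=weighted,
        negative_intercept=bool(intercept < 0),
    )


def donor_quench(f_with_liposomes: float, f_without: float) -> float:
    """Normalized donor fluorescence change (F_with - F_without)/F_without.

    Negative values indicate quenching, i.e. proximity of the labelled
    residue to the acceptor-labelled membrane.
    """
    if not f_without > 0:
        raise ValueError("reference fluorescence must be > 0")
    return (f_with_liposomes - f_without) / f_without
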