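"""Fractal analysis of tau-beta trajectories of the GHz water process.

As water content decreases, the main dielectric relaxation of an aqueous
material slows down (``tau`` grows) and broadens (the Cole-Cole exponent
``beta`` drops).  Plotting ``beta`` against ``tau`` for a composition
series traces a hyperbola-like trajectory whose shape carries the fractal
dimension ``D`` of the set of relaxing units interacting with their
surroundings (the Ryabov relation):

    beta(tau) = (D/2) * ln(tau * omega_S) / ln(tau / tau0_s)

``tau0_s`` is the cutoff time of the time-domain scaling and ``omega_S``
the characteristic self-diffusion frequency,

    omega_S = 2 * d_E * G**(2/D) * D_s / R0**2

with Euclidean dimension ``d_E``, self-diffusion coefficient ``D_s``,
spatial scaling cutoff ``R0`` and geometric factor ``G ~ 1``.

Two distinct reference times appear in this analysis and are named
separately to avoid confusion:

* ``TAU_WATER_25C`` (8.3 ps): the pure-water relaxation time used to
  normalise the diagram's tau axis (``tau / tau_water``).
* ``tau0_s``: the scaling cutoff inside the Ryabov relation, a fitted or
  assumed microscopic time.

Trajectories with ``1 <= D <= 2`` indicate *solution*-like water (the
hydrogen-bond network and the solute network interpenetrate); ``0 <= D
<= 1`` indicates *dispersion*-like water (the network is fragmented by
dispersed particles).  The two classes overlap near ``D = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .relaxation_models import TAU_WATER_25C, TAU_WATER_25C_ALT, DomainError, ParameterError

__all__ = [
    "TauBetaPoint",
    "FractalFit",
    "SelfDiffusionScaling",
    "TrajectoryFitConfig",
    "ryabov_beta",
    "fit_trajectory",
    "omega_s_physical",
    "classify_water_structure",
    "normalize_by_bulk",
    "make_trajectory",
    "TAU_WATER_25C",
    "TAU_WATER_25C_ALT",
]


@dataclass(frozen=True)
class TauBetaPoint:
    """One (tau, beta) observation of the GHz process.

    ``tau_normalized`` is ``tau`` divided by the pure-water relaxation
    time (or by the bulk-solvent value after
    :func:`normalize_by_bulk`).  ``composition`` is an optional scalar
    coordinate (e.g. water weight fraction) used for bulk normalisation.
    """

    tau: float
    beta: float
    tau_err: float = 0.0
    beta_err: float = 0.0
    tau_normalized: float | None = None
    composition: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.beta <= 1:
            raise ParameterError(f"beta must be in (0, 1], got {self.beta}")

    def with_normalization(self, tau_ref: float) -> "TauBetaPoint":
        if tau_ref <= 0:
            raise DomainError("reference tau must be > 0")
        return TauBetaPoint(
            tau=self.tau,
            beta=self.beta,
            tau_err=self.tau_err,
            beta_err=self.beta_err,
            tau_normalized=self.tau / tau_ref,
            composition=self.composition,
            label=self.label,
        )


@dataclass(frozen=True)
class FractalFit:
    """Fitted Ryabov-relation parameters for one trajectory."""

    D: float
    omega_s: float
    tau0_s: float
    D_uncertainty: float = 0.0
    fit_residual: float = 0.0
    converged: bool = True
    n_points: int = 0
    tau_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ParameterError("D must be >= 0")
        if not self.omega_s > 0 or not self.tau0_s > 0:
            raise ParameterError("omega_s and tau0_s must be > 0")


@dataclass(frozen=True)
class SelfDiffusionScaling:
    """Physical inputs of the characteristic self-diffusion frequency."""

    d_E: int
    D_s: float
    R0: float
    G: float = 1.0

    def __post_init__(self) -> None:
        if self.d_E not in (1, 2, 3):
            raise ParameterError("d_E must be 1, 2 or 3")
        if not (self.D_s > 0 and self.R0 > 0 and self.G > 0):
            raise ParameterError("D_s, R0 and G must be > 0")


def ryabov_beta(tau, D: float, omega_s: float, tau0_s: float):
    """Evaluate beta(tau) = (D/2) ln(tau omega_S)/ln(tau/tau0_s).

    No clamping is applied: values outside (0, 1] are returned as-is,
    since selecting the physical branch is the caller's responsibility.
    ``tau = tau0_s`` is a singularity and raises.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0):
        raise DomainError("tau must be > 0")
    if not omega_s > 0:
        raise DomainError("omega_s must be > 0")
    if not tau0_s > 0:
        raise DomainError("tau0_s must be > 0")
    if np.any(tau_arr == tau0_s):
        raise DomainError("tau equals tau0_s: the relation is singular there")
    beta = (D / 2.0) * np.log(tau_arr * omega_s) / np.log(tau_arr / tau0_s)
    return beta if beta.ndim else float(beta)


def omega_s_physical(scaling: SelfDiffusionScaling, D: float) -> float:
    """omega_S = 2 d_E G^(2/D) D_s / R0^2 (rad/s)."""
    if not D > 0:
        raise DomainError("D must be > 0")
    return 2.0 * scaling.d_E * scaling.G ** (2.0 / D) * scaling.D_s / scaling.R0**2


@dataclass(frozen=True)
class TrajectoryFitConfig:
    """Bounds and starts for the three-parameter trajectory fit.

    The three parameters are weakly identifiable from short arcs, so the
    nuisance parameters are boxed: ``tau0_s`` within
    ``[tau0_lo, tau0_hi] * min(tau)`` and the product ``tau0_s * omega_s``
    (dimensionless, >= 1) within ``[1, exp(ln_product_hi)]``.
    Parameterising ``omega_s`` through this product keeps the search
    well-scaled for both solution- and dispersion-type arcs.
    """

    tau0_lo: float = 0.01
    tau0_hi: float = 1.0
    ln_product_hi: float = 14.0
    D_max: float = 4.0
    starts_D: tuple[float, ...] = (0.3, 0.9, 1.6)
    starts_tau0: tuple[float, ...] = (0.3, 0.7)


def fit_trajectory(
    points: list[TauBetaPoint] | tuple[TauBetaPoint, ...],
    config: TrajectoryFitConfig | None = None,
) -> FractalFit:
    """Least-squares fit of the Ryabov relation in (ln tau, beta) space.

    Requires at least 4 points with distinct ``tau``.  The fit is run
    from a small grid of starting values and the best optimum is kept;
    ``D_uncertainty`` is the one-sigma value from the local curvature
    (via the pseudo-inverse of J^T J, which behaves like a profile error
    when the nuisance parameters are poorly determined).
    """
    config = config or TrajectoryFitConfig()
    if len(points) < 4:
        raise DomainError(f"need >= 4 points, got {len(points)}")
    tau = np.array([p.tau for p in points], dtype=float)
    beta = np.array([p.beta for p in points], dtype=float)
    if np.unique(tau).size < 4:
        raise DomainError("need >= 4 distinct tau values")

    tmin = float(tau.min())
    ltau = np.log(tau)
    ltmin = np.log(tmin)

    # x = (D, L, u): L = ln(tau0_s * omega_s) >= 0, u = ln(tau0_s / tmin) < 0.
    def resid(x: np.ndarray) -> np.ndarray:
        D, L, u = x
        lt0 = ltmin + u
        denom = ltau - lt0
        return (D / 2.0) * (1.0 + L / denom) - beta

    lo = np.array([1e-9, 0.0, np.log(config.tau0_lo)])
    hi = np.array([config.D_max, config.ln_product_hi, np.log(config.tau0_hi) - 1e-9])
    best = None
    for D0 in config.starts_D:
        for r0 in config.starts_tau0:
            res = least_squares(
                resid, np.array([D0, 1.0, np.log(r0)]), bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            cost = float(res.fun @ res.fun)
            if best is None or cost < best[0]:
                best = (cost, res)
    cost, res = best
    D, L, u = res.x
    tau0_s = float(np.exp(ltmin + u))
    omega_s = float(np.exp(L) / tau0_s)

    dof = max(tau.size - 3, 1)
    s2 = cost / dof
    cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
    d_unc = float(np.sqrt(max(cov[0, 0], 0.0)))

    return FractalFit(
        D=float(D),
        omega_s=omega_s,
        tau0_s=tau0_s,
        D_uncertainty=d_unc,
        fit_residual=float(np.sqrt(cost)),
        converged=bool(res.status > 0),
        n_points=int(tau.size),
        tau_range=(float(tau.min()), float(tau.max())),
    )


def classify_water_structure(D: float, D_uncertainty: float = 0.0) -> str:
    """Classify a fitted fractal dimension.

    ``"solution"`` when the whole error interval lies above 1,
    ``"dispersion"`` when it lies below 1, ``"indeterminate"`` otherwise
    (the two regimes genuinely overlap around ``D = 1``).
    """
    if D < 0:
        raise DomainError("D must be >= 0")
    u = abs(D_uncertainty)
    if D - u > 1.0:
        return "solution"
    if D + u < 1.0:
        return "dispersion"
    return "indeterminate"


@dataclass(frozen=True)
class NormalizationResult:
    """Output of :func:`normalize_by_bulk`: points plus per-point errors."""

    points: tuple[TauBetaPoint, ...]
    errors: tuple[str, ...] = ()


def normalize_by_bulk(
    system_points: list[TauBetaPoint] | tuple[TauBetaPoint, ...],
    bulk_points: list[TauBetaPoint] | tuple[TauBetaPoint, ...],
) -> NormalizationResult:
    """Normalise gel/system relaxation times by the bulk-solvent value.

    For each system point with composition ``c``, ``tau_normalized =
    tau_system(c) / tau_bulk(c)`` with ``tau_bulk`` interpolated linearly
    in composition.  This removes the (possibly reentrant) composition
    dependence of the solvent mixture itself, leaving only the
    restriction imposed by the network.  ``beta`` passes through
    unchanged.  Compositions outside the bulk range are not extrapolated;
    they produce an error record instead.
    """
    bulk = [p for p in bulk_points if p.composition is not None]
    if not bulk:
        raise DomainError("bulk points need composition values")
    bulk.sort(key=lambda p: p.composition)
    cb = np.array([p.composition for p in bulk], dtype=float)
    tb = np.array([p.tau for p in bulk], dtype=float)
    if np.any(tb <= 0):
        raise DomainError("bulk tau must be > 0")

    out: list[TauBetaPoint] = []
    errors: list[str] = []
    for p in system_points:
        if p.composition is None:
            errors.append(f"point {p.label!r}: no composition, cannot normalise")
            continue
        if not cb.min() <= p.composition <= cb.max():
            errors.append(
                f"point {p.label!r}: composition {p.composition} outside bulk range "
                f"[{cb.min()}, {cb.max()}]"
            )
            continue
        tau_b = float(np.interp(p.composition, cb, tb))
        out.append(
            TauBetaPoint(
                tau=p.tau,
                beta=p.beta,
                tau_err=p.tau_err,
                beta_err=p.beta_err,
                tau_normalized=p.tau / tau_b,
                composition=p.composition,
                label=p.label,
            )
        )
    return NormalizationResult(points=tuple(out), errors=tuple(errors))


# ---------------------------------------------------------------------------
# Synthetic trajectory generator


#: Default scaling cutoff used by the generator: half the pure-water tau,
#: so that every generated trajectory passes through the pure-water anchor
#: (tau = 8.3 ps, beta = 1) -- see :func:`make_trajectory`.
TAU0_SCALING_DEFAULT = TAU_WATER_25C / 2.0


def make_trajectory(
    D: float,
    n_points: int = 12,
    noise: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    tau0_s: float = TAU0_SCALING_DEFAULT,
    beta_window: tuple[float, float] | None = None,
    label: str = "",
) -> list[TauBetaPoint]:
    """Generate a synthetic tau-beta trajectory with known fractal dimension.

    The generator emulates how composition series are actually observed:

    * every trajectory starts at the pure-water anchor -- ``omega_s`` is
      coupled to ``D`` through ``tau0_s * omega_s = 2**(2/D - 1)``, which
      makes ``beta(2 * tau0_s) = 1`` exactly (i.e. beta = 1 at
      tau = 8.3 ps with the default cutoff);
    * points are sampled on a fixed *beta* window rather than a fixed tau
      range, descending from ~0.95 toward the horizontal asymptote D/2.
      Solution-type trajectories (large D) therefore sweep several decades
      of tau, while dispersion-type ones (small D) cover only a short,
      nearly vertical arc -- which is why their fitted D carries a much
      larger uncertainty, as seen experimentally.

    Gaussian noise of standard deviation ``noise`` is added to beta
    (clipped into (0, 1]).
    """
    if not 0 < D < 2:
        raise DomainError("the generator supports 0 < D < 2")
    if n_points < 4:
        raise ParameterError("n_points must be >= 4")
    if noise < 0:
        raise ParameterError("noise must be >= 0")
    if beta_window is None:
        b_lo = max(0.40, D / 2.0 + 0.02)
        b_hi = min(max(0.95, b_lo + 0.02), 0.999)
    else:
        b_hi, b_lo = max(beta_window), min(beta_window)
        if b_lo <= D / 2.0:
            raise DomainError("beta window must lie above the asymptote D/2")
    L = np.log(2.0) * (2.0 / D - 1.0)
    beta_t = np.linspace(b_hi, b_lo, n_points)
    x = L / (2.0 * beta_t / D - 1.0)  # x = ln(tau / tau0_s)
    tau = tau0_s * np.exp(x)
    beta = beta_t.copy()
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        beta = np.clip(beta + rng.normal(0.0, noise, n_points), 1e-3, 1.0)
    return [
        TauBetaPoint(
            tau=float(t),
            beta=float(b),
            beta_err=noise,
            tau_normalized=float(t / TAU_WATER_25C),
            label=label,
        )
        for t, b in zip(tau, beta)
    ]
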