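"""Complex nonlinear least-squares fitting of relaxation spectra.

Estimates Havriliak-Negami parameters -- most importantly the relaxation
time ``tau`` and the symmetric broadening exponent ``beta`` of the GHz
water process -- from a measured or synthetic complex permittivity
spectrum.  The optimisation runs on ``log10(tau)`` and ``log10(delta_eps)``
with box bounds on the exponents, using ``scipy.optimize.least_squares``
(trust-region reflective), which handles active bounds such as the
Debye limit ``beta = 1`` cleanly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .relaxation_models import (
    TAU_WATER_25C,
    DielectricSpectrum,
    DomainError,
    ParameterError,
    RelaxationProcess,
    SpectrumModel,
    evaluate_model,
)

_TAU_LO, _TAU_HI = 1e-14, 1e-6
_EXP_LO = 1e-3  # lower bound for both shape exponents


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a spectrum fit.

    ``fix_alpha_to_one`` selects Cole-Cole mode (symmetric broadening
    only), ``fix_beta_to_one`` Cole-Davidson mode.  Fixing both gives a
    pure Debye fit.  ``weighting`` is ``"relative"`` (residuals divided by
    ``|eps*_data|``; appropriate for spectra whose loss spans decades) or
    ``"uniform"``.  ``diagram_exponent`` chooses which shape exponent
    :func:`extract_tau_beta` reports on the tau-beta diagram; asymmetric
    (Cole-Davidson) fits use the asymmetric exponent in that role.
    """

    n_processes: int = 1
    fix_alpha_to_one: bool = True
    fix_beta_to_one: bool = False
    include_conductivity: bool = False
    weighting: str = "relative"
    max_iterations: int = 2000
    tolerance: float = 1e-14
    diagram_exponent: str = "symmetric"

    def __post_init__(self) -> None:
        if self.n_processes < 1:
            raise ParameterError("n_processes must be >= 1")
        if self.weighting not in ("uniform", "relative"):
            raise ParameterError(f"unknown weighting {self.weighting!r}")
        if self.diagram_exponent not in ("symmetric", "asymmetric"):
            raise ParameterError(f"unknown diagram_exponent {self.diagram_exponent!r}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_spectrum`.

    ``parameter_uncertainties`` maps parameter names such as
    ``"process0.tau"`` to one-sigma uncertainties propagated from the
    local curvature (Jacobian) at the optimum.
    """

    model: SpectrumModel
    residual_norm: float
    parameter_uncertainties: dict = field(default_factory=dict)
    converged: bool = True
    config: FitConfig = field(default_factory=FitConfig)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ParameterError("residual_norm must be >= 0")


def _free_parameter_count(config: FitConfig) -> int:
    per_proc = 2 + (not config.fix_beta_to_one) + (not config.fix_alpha_to_one)
    return 1 + config.n_processes * per_proc + (1 if config.include_conductivity else 0)


def initial_guess(spectrum: DielectricSpectrum, config: FitConfig) -> SpectrumModel:
    """Heuristic starting model.

    ``tau`` comes from loss peaks (``tau = 1/(2 pi f_peak)``), ``delta_eps``
    from twice the peak loss (exact for a Debye process), ``eps_inf`` from
    the highest-frequency real permittivity.  With no interior loss
    maximum the band centre is used and a warning is emitted.
    """
    if len(spectrum) < 4 * _free_parameter_count(config):
        raise DomainError(
            "spectrum too short: need >= 4 points per free parameter "
            f"({4 * _free_parameter_count(config)}), got {len(spectrum)}"
        )
    f = spectrum.frequencies
    loss = spectrum.loss
    eps_inf = max(float(spectrum.eps_real[-1]), 1.0)
    delta_total = max(float(spectrum.eps_real[0] - spectrum.eps_real[-1]), 1e-3)

    peaks, props = find_peaks(loss, height=0.0)
    if peaks.size == 0:
        warnings.warn(
            "no interior loss maximum; initializing tau from the band centre",
            stacklevel=2,
        )
        f_centre = np.sqrt(f[0] * f[-1])
        peak_freqs = np.array([f_centre])
        peak_heights = np.array([max(loss.max(), delta_total / 2)])
    else:
        order = np.argsort(props["peak_heights"])[::-1]
        take = order[: config.n_processes]
        peak_freqs = f[peaks[take]]
        peak_heights = props["peak_heights"][take]

    # Pad with log-evenly placed extra guesses if fewer peaks than processes.
    while peak_freqs.size < config.n_processes:
        extra = np.sqrt(f[0] * peak_freqs.min())
        peak_freqs = np.append(peak_freqs, extra)
        peak_heights = np.append(peak_heights, peak_heights.min())

    order = np.argsort(peak_freqs)[::-1]  # high f first -> ascending tau
    peak_freqs, peak_heights = peak_freqs[order], peak_heights[order]

    strengths = 2.0 * peak_heights
    scale = delta_total / strengths.sum() if strengths.sum() > 0 else 1.0
    # Keep guesses within a sane factor of the eps' drop, but never zero.
    strengths = np.maximum(strengths * max(scale, 0.1), 1e-3)

    procs = tuple(
        RelaxationProcess(
            delta_eps=float(s),
            tau=float(np.clip(1.0 / (2 * np.pi * fp), _TAU_LO, _TAU_HI)),
            beta_sym=1.0,
            alpha_asym=1.0,
        )
        for fp, s in zip(peak_freqs, strengths)
    )
    return SpectrumModel(eps_inf=eps_inf, processes=procs)


def _pack(model: SpectrumModel, config: FitConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Flatten a model into the optimisation vector with bounds and names."""
    x, lo, hi, names = [], [], [], []
    x.append(model.eps_inf)
    lo.append(1.0)
    hi.append(1e4)
    names.append("eps_inf")
    for i, p in enumerate(model.processes):
        x += [np.log10(p.delta_eps), np.log10(p.tau)]
        lo += [-6.0, np.log10(_TAU_LO)]
        hi += [6.0, np.log10(_TAU_HI)]
        names += [f"process{i}.delta_eps", f"process{i}.tau"]
        if not config.fix_beta_to_one:
            x.append(p.beta_sym)
            lo.append(_EXP_LO)
            hi.append(1.0)
            names.append(f"process{i}.beta_sym")
        if not config.fix_alpha_to_one:
            x.append(p.alpha_asym)
            lo.append(_EXP_LO)
            hi.append(1.0)
            names.append(f"process{i}.alpha_asym")
    if config.include_conductivity:
        x.append(np.log10(max(model.sigma_dc, 1e-8)))
        lo.append(-8.0)
        hi.append(4.0)
        names.append("sigma_dc")
    return np.array(x), np.array(lo), np.array(hi), names


def _unpack(x: np.ndarray, config: FitConfig) -> SpectrumModel:
    k = 0
    eps_inf = float(x[k])
    k += 1
    procs = []
    for _ in range(config.n_processes):
        de = 10.0 ** float(x[k])
        tau = 10.0 ** float(x[k + 1])
        k += 2
        beta = 1.0
        alpha = 1.0
        if not config.fix_beta_to_one:
            beta = float(np.clip(x[k], _EXP_LO, 1.0))
            k += 1
        if not config.fix_alpha_to_one:
            alpha = float(np.clip(x[k], _EXP_LO, 1.0))
            k += 1
        procs.append(RelaxationProcess(de, tau, beta, alpha))
    sigma = 0.0
    if config.include_conductivity:
        sigma = 10.0 ** float(x[k])
    return SpectrumModel(eps_inf=eps_inf, processes=tuple(procs), sigma_dc=sigma)


def _sort_processes(model: SpectrumModel) -> SpectrumModel:
    """Report processes sorted by ascending tau; ties broken by larger delta_eps."""
    order = sorted(range(len(model.processes)), key=lambda i: (model.processes[i].tau, -model.processes[i].delta_eps))
    return replace(model, processes=tuple(model.processes[i] for i in order))


def fit_spectrum(
    spectrum: DielectricSpectrum,
    config: FitConfig | None = None,
    start: SpectrumModel | None = None,
) -> FitResult:
    """Weighted complex least-squares fit of the HN model family.

    Minimises ``sum_i w_i |eps*_model(f_i) - eps*_data(f_i)|^2``.  Never
    raises on non-convergence; the ``converged`` flag reflects the solver
    status.  NaN in the data is an input error.
    """
    config = config or FitConfig()
    if np.any(~np.isfinite(spectrum.eps_complex)):
        raise DomainError("spectrum contains NaN/inf values")
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        model0 = start if start is not None else initial_guess(spectrum, config)
        caught += [str(w.message) for w in rec]

    if config.fix_beta_to_one:
        model0 = replace(
            model0,
            processes=tuple(replace(p, beta_sym=1.0) for p in model0.processes),
        )
    # Broadened-exponent second start: the loss-peak tau guess is biased for
    # asymmetric processes and a start at the Debye corner can stall there.
    starts = [model0]
    if not (config.fix_alpha_to_one and config.fix_beta_to_one):
        broadened = tuple(
            replace(
                p,
                beta_sym=0.7 if not config.fix_beta_to_one else 1.0,
                alpha_asym=0.7 if not config.fix_alpha_to_one else 1.0,
            )
            for p in model0.processes
        )
        starts.append(replace(model0, processes=broadened))

    data = spectrum.eps_complex
    if config.weighting == "relative":
        w = 1.0 / np.abs(data)
    else:
        w = np.ones(len(spectrum))

    def residuals(x: np.ndarray) -> np.ndarray:
        m = _unpack(x, config)
        eps = evaluate_model(m, spectrum.frequencies).eps_complex
        r = (eps - data) * w
        return np.concatenate([r.real, r.imag])

    res = None
    for s_model in starts:
        x0, lo, hi, names = _pack(s_model, config)
        x0 = np.clip(x0, lo, hi)
        cand = least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=config.tolerance,
            ftol=config.tolerance,
            gtol=config.tolerance,
            max_nfev=config.max_iterations,
        )
        if res is None or cand.cost < res.cost:
            res = cand
    model = _unpack(res.x, config)
    residual_norm = float(np.linalg.norm(res.fun))

    # One-sigma uncertainties from the Jacobian at the optimum.
    dof = max(res.fun.size - res.x.size, 1)
    s2 = residual_norm**2 / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        sig = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - singular Jacobian
        sig = np.full(res.x.size, np.nan)

    unc: dict[str, float] = {}
    for name, xv, sv in zip(names, res.x, sig):
        if name.endswith((".delta_eps", ".tau")) or name == "sigma_dc":
            # d(10^x) = 10^x ln10 dx
            unc[name] = float(10.0**xv * np.log(10) * sv)
        else:
            unc[name] = float(sv)

    sorted_model = _sort_processes(model)
    # Remap uncertainty keys to the sorted process order.
    if sorted_model.processes != model.processes:
        perm = {j: model.processes.index(p) for j, p in enumerate(sorted_model.processes)}
        remapped = {}
        for k, v in unc.items():
            if k.startswith("process"):
                j, _, tail = k.partition(".")
                old = int(j[len("process"):])
                new = [a for a, b in perm.items() if b == old][0]
                remapped[f"process{new}.{tail}"] = v
            else:
                remapped[k] = v
        unc = remapped

    return FitResult(
        model=sorted_model,
        residual_norm=residual_norm,
        parameter_uncertainties=unc,
        converged=bool(res.status > 0),
        config=config,
        warnings=tuple(caught),
    )


def extract_tau_beta(
    result: FitResult, process_index: int | None = None
) -> tuple[float, float, tuple[float, float]]:
    """Return ``(tau, beta, (tau_err, beta_err))`` for one fitted process.

    With ``process_index=None`` the GHz water process is selected as the
    one whose relaxation time is closest (in log space) to the pure-water
    value of 8.3 ps.  The reported shape exponent follows
    ``config.diagram_exponent``.
    """
    procs = result.model.processes
    if process_index is None:
        process_index = int(
            np.argmin([abs(np.log(p.tau / TAU_WATER_25C)) for p in procs])
        )
    if not 0 <= process_index < len(procs):
        raise DomainError(f"process_index {process_index} out of range")
    if not result.converged:
        warnings.warn("extracting parameters from a non-converged fit", stacklevel=2)
    p = procs[process_index]
    if result.config.diagram_exponent == "asymmetric":
        beta = p.alpha_asym
        beta_err = result.parameter_uncertainties.get(f"process{process_index}.alpha_asym", 0.0)
    else:
        beta = p.beta_sym
        beta_err = result.parameter_uncertainties.get(f"process{process_index}.beta_sym", 0.0)
    tau_err = result.parameter_uncertainties.get(f"process{process_index}.tau", 0.0)
    return p.tau, beta, (tau_err, beta_err)
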