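"""Havriliak-Negami relaxation models and synthetic spectrum generation.

The complex relative permittivity of a material with one or more dipolar
relaxation processes is modelled as

    eps*(omega) = eps_inf + sum_k  delta_eps_k / [1 + (j omega tau_k)^beta_k]^alpha_k
                  + sigma_dc / (j omega eps_vac)

with the angular frequency omega = 2 pi f.  ``beta`` is the *symmetric*
relaxation-time-distribution exponent and ``alpha`` the *asymmetric* one;
the Debye process is ``alpha = beta = 1``, the Cole-Cole function is
``alpha = 1`` with ``beta`` free, and the Cole-Davidson function is
``beta = 1`` with ``alpha`` free.

.. warning::
   A large part of the dielectric literature writes the same function with
   the two exponent symbols swapped.  Everywhere in this package ``beta``
   is the symmetric exponent and ``alpha`` the asymmetric one; serialized
   output labels them ``symmetric_beta`` / ``asymmetric_alpha`` so files
   cannot be misread.

Sign convention: ``eps* = eps' - j eps''`` with the dielectric loss
``eps'' >= 0`` stored as a positive number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Vacuum permittivity in F/m.
EPS_VAC = 8.8541878128e-12

#: Relaxation time of the main (GHz) process of pure water at 25 C, in
#: seconds.  Two slightly different literature values are in circulation;
#: the 8.3 ps value is the one used as the tau-beta diagram anchor.
TAU_WATER_25C = 8.3e-12
TAU_WATER_25C_ALT = 8.2e-12


class ParameterError(ValueError):
    """A relaxation-model parameter is outside its admissible range."""


class DomainError(ValueError):
    """An input (frequency, time, ...) is outside the physical domain."""


@dataclass(frozen=True)
class RelaxationProcess:
    """One Havriliak-Negami relaxation process.

    Parameters
    ----------
    delta_eps
        Relaxation strength (dimensionless, > 0).
    tau
        Relaxation time in seconds (> 0).
    beta_sym
        Symmetric broadening exponent, 0 < beta <= 1.
    alpha_asym
        Asymmetric broadening exponent, 0 < alpha <= 1.
    """

    delta_eps: float
    tau: float
    beta_sym: float = 1.0
    alpha_asym: float = 1.0

    def __post_init__(self) -> None:
        if not self.delta_eps > 0:
            raise ParameterError(f"delta_eps must be > 0, got {self.delta_eps}")
        if not self.tau > 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        for name in ("beta_sym", "alpha_asym"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")

    @property
    def is_debye(self) -> bool:
        return self.beta_sym == 1.0 and self.alpha_asym == 1.0


@dataclass(frozen=True)
class SpectrumModel:
    """A full spectrum model: eps_inf, relaxation processes, dc conductivity.

    The static permittivity is ``eps_static = eps_inf + sum(delta_eps)``.
    ``sigma_dc`` (S/m, >= 0) adds the conductivity loss term; it defaults
    to zero and exists because low-frequency processes overlapping the GHz
    band often appear as an apparent conductivity tail.
    """

    eps_inf: float
    processes: tuple[RelaxationProcess, ...] = field(default_factory=tuple)
    sigma_dc: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps_inf >= 1:
            raise ParameterError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma_dc < 0:
            raise ParameterError(f"sigma_dc must be >= 0, got {self.sigma_dc}")
        object.__setattr__(self, "processes", tuple(self.processes))

    @property
    def eps_static(self) -> float:
        return self.eps_inf + sum(p.delta_eps for p in self.processes)


@dataclass(frozen=True)
class DielectricSpectrum:
    """Frequency grid plus complex permittivity values.

    ``eps_complex`` stores ``eps' - j eps''`` with a non-negative imaginary
    magnitude convention (``loss = -eps_complex.imag >= 0`` for passive
    materials).
    """

    frequencies: np.ndarray
    eps_complex: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        e = np.asarray(self.eps_complex, dtype=complex)
        if f.ndim != 1 or e.ndim != 1 or f.size != e.size:
            raise DomainError("frequencies and eps_complex must be 1-D and equal length")
        if f.size < 2:
            raise DomainError("a spectrum needs at least 2 points")
        if np.any(f <= 0):
            raise DomainError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise DomainError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "eps_complex", e)

    @property
    def eps_real(self) -> np.ndarray:
        return self.eps_complex.real

    @property
    def loss(self) -> np.ndarray:
        """Dielectric loss eps'' as a positive array."""
        return -self.eps_complex.imag

    def __len__(self) -> int:
        return int(self.frequencies.size)


def _hn_term(proc: RelaxationProcess, omega: np.ndarray) -> np.ndarray:
    """delta_eps / [1 + (j w tau)^beta]^alpha, principal complex branch."""
    jwt = 1j * omega * proc.tau
    return proc.delta_eps / (1.0 + jwt**proc.beta_sym) ** proc.alpha_asym


def evaluate_model(model: SpectrumModel, frequencies) -> DielectricSpectrum:
    """Evaluate a :class:`SpectrumModel` on a frequency grid (Hz).

    Returns the spectrum with the ``eps' - j eps''`` convention.  The HN
    term is evaluated with ``+j`` inside the bracket, which yields a
    negative imaginary part, i.e. a positive loss, for all admissible
    exponents.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequencies must be strictly positive")
    omega = 2 * np.pi * f
    eps = np.full(f.shape, model.eps_inf, dtype=complex)
    for proc in model.processes:
        eps = eps + _hn_term(proc, omega)
    if model.sigma_dc > 0:
        eps = eps + model.sigma_dc / (1j * omega * EPS_VAC)
    return DielectricSpectrum(f, eps)


def single_process_loss(proc: RelaxationProcess, frequencies) -> np.ndarray:
    """Loss eps''(f) of a single process (no eps_inf, no conductivity)."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequencies must be strictly positive")
    return -_hn_term(proc, 2 * np.pi * f).imag


def loss_peak_frequency(proc: RelaxationProcess) -> float:
    """Frequency (Hz) of the single-process loss maximum.

    For a symmetric process (``alpha_asym = 1``) the peak sits exactly at
    ``omega tau = 1``; asymmetric broadening skews the peak to higher
    frequency, in which case it is located numerically on a log grid and
    refined with a bounded scalar minimizer.
    """
    f0 = 1.0 / (2 * np.pi * proc.tau)
    if proc.alpha_asym == 1.0:
        return f0
    from scipy.optimize import minimize_scalar

    grid = f0 * np.logspace(-2, 3, 400)
    loss = single_process_loss(proc, grid)
    k = int(np.argmax(loss))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda lf: -single_process_loss(proc, np.array([10.0**lf]))[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(10.0**res.x)


def synthesize_spectrum(
    model: SpectrumModel,
    f_min: float,
    f_max: float,
    n_points: int = 100,
    noise_rel: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DielectricSpectrum:
    """Generate a log-spaced spectrum with optional Gaussian noise.

    Noise of standard deviation ``noise_rel * |eps*(f)|`` is added
    independently to the real and imaginary parts at each frequency.
    Reproducible given ``seed`` (or an explicit ``rng``).
    """
    if not f_min < f_max:
        raise DomainError("f_min must be < f_max")
    if f_min <= 0:
        raise DomainError("frequencies must be strictly positive")
    if n_points < 8:
        raise ParameterError("n_points must be >= 8")
    if noise_rel < 0:
        raise ParameterError("noise_rel must be >= 0")
    f = np.logspace(np.log10(f_min), np.log10(f_max), n_points)
    spec = evaluate_model(model, f)
    if noise_rel == 0:
        return spec
    if rng is None:
        rng = np.random.default_rng(seed)
    scale = noise_rel * np.abs(spec.eps_complex)
    noisy = (
        spec.eps_complex
        + rng.normal(0.0, scale)
        + 1j * rng.normal(0.0, scale)
    )
    return DielectricSpectrum(f, noisy)


def debye_water_model(
    delta_eps: float = 73.2, tau: float = TAU_WATER_25C, eps_inf: float = 5.2
) -> SpectrumModel:
    """Single-Debye model of pure water at 25 C (GHz process only)."""
    return SpectrumModel(eps_inf=eps_inf, processes=(RelaxationProcess(delta_eps, tau),))
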