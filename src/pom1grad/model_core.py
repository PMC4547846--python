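"""Closed-form results for cortical gradient models.

The central model describes a membrane-bound kinase (Pom1) that is deposited
at the cell pole at rate ``S``, diffuses laterally along the cortex with
coefficient ``D``, and detaches after intermolecular (trans)
auto-phosphorylation.  Because trans-phosphorylation is a bimolecular
encounter, the effective detachment term is quadratic in the local
concentration, giving the steady-state balance

    D P''(x) = alpha P(x)^2,      -D P'(0) = S,      P(inf) = 0,

whose solution is the power law

    P(x) = C / (x + x0)^2,   C = 6 D / alpha,   x0 = (12 D^2 / (alpha S))^(1/3).

The amplitude A = C/x0^2 then scales as S^(2/3) and the decay length as
A^(-1/2): both sub-linear responses constitute the gradient's buffering
against fluctuations in the source.  The competing cis-phosphorylation model
(linear decay term, -alpha P) gives the familiar exponential gradient
A exp(-x/lambda) with lambda = sqrt(D/alpha) independent of S, i.e. no
buffering.

Concentrations are in arbitrary fluorescence-intensity units throughout
(GFP intensity is linear in concentration); no molar units are attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SteadyStateSummary",
    "GradientProfile",
    "InvalidParameterError",
    "DegenerateSummaryError",
    "NoCrossingError",
    "analytic_steady_state",
    "steady_state_summary",
    "decay_length_from_x0",
    "threshold_shift",
    "cis_steady_state",
]

MODEL_KINDS = ("trans", "cis", "cluster", "combined", "detailed")

#: Default fraction of the amplitude defining the decay length (half-maximum).
#: All scaling exponents are independent of this choice.
DEFAULT_DECAY_FRACTION = 0.5


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateSummaryError(ValueError):
    """Steady-state summary requested for an all-zero (sourceless) gradient."""


class NoCrossingError(ValueError):
    """A threshold concentration is never reached by the profile."""


@dataclass
class ModelParams:
    """Physical constants of one gradient model.

    Parameters
    ----------
    D : float
        Lateral diffusion coefficient on the cortex (um^2/min).
    alpha : float
        Effective detachment coefficient of the simplified model
        (intensity^-1 min^-1 for the quadratic trans model; min^-1 for the
        linear cis model).
    gamma : float
        Effective decay exponent of the coarse-grained model, in (1, 2].
        gamma = 2 recovers the simplified trans model.
    beta : float
        Intermolecular phosphorylation rate of the detailed multi-state
        model (intensity^-1 min^-1).
    kappa : sequence of float
        Per-state detachment rates kappa_0..kappa_N (min^-1), non-decreasing;
        kappa_0 = 0 by default (fully dephosphorylated kinase does not
        detach).  Length N+1 where N is the number of phospho-states.
    source_strength : float
        Total influx at the pole, integral of S(x) (intensity um / min).
    source_width : float
        Spatial extent (um) of the half-Gaussian source band used by the
        numerical solver; the analytic forms treat the source as a point
        flux at x = 0.
    model_kind : str
        One of {trans, cis, cluster, combined, detailed}.
    cluster_D0, cluster_Pstar, cluster_h : float
        Parameters of the concentration-dependent diffusion law
        D(P) = D0 / (1 + (P/P*)^h) used by the cluster and combined models.
    """

    D: float = 1.0
    alpha: float = 6.0
    gamma: float = 2.0
    beta: float = 1.0
    kappa: Optional[Sequence[float]] = None
    source_strength: float = 2.0
    source_width: float = 0.3
    model_kind: str = "trans"
    cluster_D0: Optional[float] = None
    cluster_Pstar: float = 1.0
    cluster_h: float = 2.0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise InvalidParameterError(
                f"unknown model_kind {self.model_kind!r}; expected one of {MODEL_KINDS}"
            )
        if self.D <= 0:
            raise InvalidParameterError(f"D must be positive, got {self.D}")
        if self.model_kind in ("trans", "cis", "combined") and self.alpha <= 0:
            raise InvalidParameterError(
                f"alpha must be positive for {self.model_kind}, got {self.alpha}"
            )
        if not (1.0 < self.gamma <= 2.0):
            raise InvalidParameterError(f"gamma must lie in (1, 2], got {self.gamma}")
        if self.source_strength < 0:
            raise InvalidParameterError(
                f"source_strength must be non-negative, got {self.source_strength}"
            )
        if self.source_width <= 0:
            raise InvalidParameterError(
                f"source_width must be positive, got {self.source_width}"
            )
        if self.model_kind == "detailed":
            if self.kappa is None:
                # biological default: 6 phospho-states control membrane affinity
                self.kappa = tuple(0.5 * i for i in range(7))
            kap = np.asarray(self.kappa, dtype=float)
            if kap.size < 2:
                raise InvalidParameterError(
                    "detailed model needs kappa of length N+1 with N >= 1"
                )
            if kap[0] < 0:
                raise InvalidParameterError("kappa_0 must be non-negative")
            # ties allowed only at 0; strictly increasing for i >= 1
            if np.any(np.diff(kap) < 0) or np.any(np.diff(kap[kap > 0]) <= 0):
                raise InvalidParameterError(
                    "kappa must be non-decreasing, strictly increasing once positive"
                )
            if self.beta <= 0:
                raise InvalidParameterError("beta must be positive for detailed model")
        if self.cluster_D0 is None:
            self.cluster_D0 = self.D
        if self.model_kind in ("cluster", "combined"):
            if self.cluster_Pstar <= 0:
                raise InvalidParameterError("cluster_Pstar must be positive")
            if self.cluster_h < 0:
                raise InvalidParameterError("cluster_h must be non-negative")

    @property
    def n_states(self) -> int:
        """Number of phospho-states N (kappa has length N+1)."""
        if self.kappa is None:
            raise InvalidParameterError("kappa not set")
        return len(self.kappa) - 1

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["kappa"] is not None:
            d["kappa"] = list(d["kappa"])
        return d


@dataclass
class GradientProfile:
    """One concentration profile along the cortex.

    ``positions`` are arclength coordinates in um, ascending from 0 at the
    pole tip; ``values`` are intensities.  ``species_values``, when present,
    holds the per-phospho-state concentrations P_i(x) (shape (N+1, n)) whose
    sum equals ``values``.
    """

    positions: np.ndarray
    values: np.ndarray
    species_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be 1-D arrays of equal length")
        if self.positions[0] != 0 or np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing from 0")
        if self.species_values is not None:
            self.species_values = np.asarray(self.species_values, dtype=float)
            if self.species_values.shape[1] != self.positions.size:
                raise ValueError("species_values shape mismatch")

    @property
    def amplitude(self) -> float:
        """Concentration at the pole tip, P(0)."""
        return float(self.values[0])

    def total(self) -> float:
        """Trapezoidal integral of the profile (intensity * um)."""
        return float(np.trapezoid(self.values, self.positions))

    def to_csv(self, path) -> None:
        """Write as two-column CSV (position_um, value)."""
        arr = np.column_stack([self.positions, self.values])
        np.savetxt(path, arr, delimiter=",", header="position_um,value", comments="")

    @classmethod
    def from_csv(cls, path) -> "GradientProfile":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(positions=arr[:, 0], values=arr[:, 1])


@dataclass
class SteadyStateSummary:
    """Closed-form scalar summaries of the trans-model steady state.

    amplitude = C/x0^2, total_cortical = C/x0, hence
    total_cortical = sqrt(C * amplitude): the 1/2 power law between the
    pole amplitude and the overall cortical amount.
    """

    amplitude: float
    x0: float
    decay_length: float
    total_cortical: float
    C: float
    params: ModelParams = field(repr=False, default=None)

    def to_json(self, path=None) -> str:
        payload = {
            "amplitude": self.amplitude,
            "x0": self.x0,
            "decay_length": self.decay_length,
            "total_cortical": self.total_cortical,
            "C": self.C,
            "params": self.params.to_dict() if self.params is not None else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _require_trans(params: ModelParams) -> None:
    if params.model_kind != "trans":
        raise InvalidParameterError(
            f"operation requires model_kind='trans', got {params.model_kind!r}"
        )


def trans_x0(params: ModelParams) -> float:
    """Length scale x0 = (12 D^2 / (alpha S))^(1/3) from flux balance.

    The point-flux condition -D P'(0) = S applied to P = C/(x+x0)^2 gives
    2 D C / x0^3 = S with C = 6D/alpha.
    """
    _require_trans(params)
    if params.source_strength <= 0:
        raise DegenerateSummaryError("x0 undefined for zero source")
    C = 6.0 * params.D / params.alpha
    return float((2.0 * params.D * C / params.source_strength) ** (1.0 / 3.0))


def analytic_steady_state(params: ModelParams, grid) -> GradientProfile:
    """Steady state of the trans model, P(x) = C/(x + x0)^2, on ``grid``.

    The source is treated as a point flux at x = 0.  With S = 0 the only
    steady state of the decaying dynamics is the zero profile.
    """
    _require_trans(params)
    x = np.asarray(grid.positions, dtype=float)
    if params.source_strength == 0:
        return GradientProfile(positions=x, values=np.zeros_like(x))
    x0 = trans_x0(params)
    C = 6.0 * params.D / params.alpha
    return GradientProfile(positions=x, values=C / (x + x0) ** 2)


def steady_state_summary(
    params: ModelParams, fraction: float = DEFAULT_DECAY_FRACTION
) -> SteadyStateSummary:
    """Amplitude, length scale, decay length and cortical total of the
    trans-model steady state.

    A = C/x0^2 (so A scales as S^(2/3)); P_tot = int_0^inf P dx = C/x0
    (so P_tot = sqrt(C A)); lambda = x0 (fraction^(-1/2) - 1).
    """
    _require_trans(params)
    if params.source_strength <= 0:
        raise DegenerateSummaryError(
            "steady-state summary undefined: the zero profile has no amplitude"
        )
    C = 6.0 * params.D / params.alpha
    x0 = trans_x0(params)
    return SteadyStateSummary(
        amplitude=C / x0**2,
        x0=x0,
        decay_length=decay_length_from_x0(x0, fraction),
        total_cortical=C / x0,
        C=C,
        params=params,
    )


def decay_length_from_x0(x0: float, fraction: float = DEFAULT_DECAY_FRACTION) -> float:
    """Distance at which C/(x+x0)^2 falls to ``fraction`` of its amplitude.

    Solving C/(lambda+x0)^2 = fraction * C/x0^2 gives
    lambda = x0 (fraction^(-1/2) - 1), proportional to x0 for any fixed
    fraction; hence lambda scales as A^(-1/2) at fixed C.
    """
    if x0 <= 0:
        raise InvalidParameterError(f"x0 must be positive, got {x0}")
    if not (0.0 < fraction < 1.0):
        raise InvalidParameterError(f"fraction must lie in (0, 1), got {fraction}")
    return float(x0 * (fraction ** -0.5 - 1.0))


def threshold_shift(params: ModelParams, k: float, threshold: float) -> float:
    """Displacement of a fixed-threshold position after a k-fold source change.

    The position where P crosses ``threshold`` is x_T = sqrt(C/T) - x0.
    Scaling S -> k S rescales x0 by k^(-1/3), so the crossing moves by
    Delta x = x0 (1 - k^(-1/3)), which is bounded by x0 for every k > 1:
    positional information downstream of the gradient shifts by less than
    one length scale no matter how large the source fluctuation.
    """
    _require_trans(params)
    if k <= 0:
        raise InvalidParameterError(f"fold-change k must be positive, got {k}")
    summ = steady_state_summary(params)
    amp_low = min(summ.amplitude, summ.amplitude * k ** (2.0 / 3.0))
    if threshold >= amp_low:
        raise NoCrossingError(
            f"threshold {threshold} is not below both amplitudes (min {amp_low})"
        )
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    return float(summ.x0 * (1.0 - k ** (-1.0 / 3.0)))


def cis_steady_state(params: ModelParams, grid) -> GradientProfile:
    """Exponential steady state of the cis (linear-decay) model.

    D P'' = alpha P with point flux S at the pole gives
    P = A exp(-x/lambda), lambda = sqrt(D/alpha), A = S lambda / D.
    The decay length contains no S: amplitude fluctuations are not buffered.
    """
    if params.model_kind != "cis":
        raise InvalidParameterError(
            f"operation requires model_kind='cis', got {params.model_kind!r}"
        )
    x = np.asarray(grid.positions, dtype=float)
    if params.source_strength == 0:
        return GradientProfile(positions=x, values=np.zeros_like(x))
    lam = np.sqrt(params.D / params.alpha)
    A = params.source_strength * lam / params.D
    return GradientProfile(positions=x, values=A * np.exp(-x / lam))
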