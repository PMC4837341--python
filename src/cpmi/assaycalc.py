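"""Data reduction for the wet-lab validation assays.

Two computations: the percentage inhibition of TNF-alpha-mediated
cytotoxicity from plate optical densities, and the equilibrium
dissociation constant K_D from steady-state surface plasmon resonance
responses under a 1:1 Langmuir binding model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import BindingFit, ValidationError


@dataclass(frozen=True)
class InhibitionMeasurement:
    """Optical densities (450 nm) of the three plate conditions.

    od_component: actinomycin D + TNF-alpha + compound
    od_tnf:       actinomycin D + TNF-alpha (cytotoxicity control, 0%)
    od_actd:      actinomycin D only (full-protection control, 100%)
    """

    od_component: float
    od_tnf: float
    od_actd: float

    def __post_init__(self) -> None:
        for name in ("od_component", "od_tnf", "od_actd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.od_actd == self.od_tnf:
            raise ValidationError(
                "degenerate controls: od_actd equals od_tnf, inhibition undefined"
            )


def percent_inhibition(m: InhibitionMeasurement) -> float:
    """Percentage inhibition of cytotoxicity.

    (OD_compound - OD_TNF) / (OD_actD - OD_TNF) * 100 — the rescue of
    optical density normalized between the TNF-alpha-only control (0%)
    and the no-TNF-alpha control (100%).  Not clamped: values outside
    [0, 100] indicate responses beyond either control.
    """
    return (m.od_component - m.od_tnf) / (m.od_actd - m.od_tnf) * 100.0


def steady_state_response(conc: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """1:1 steady-state binding isotherm R(C) = rmax * C / (kd + C)."""
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (kd + conc)


def dilution_series(low: float = 6.25, high: float = 400.0, factor: float = 2.0) -> np.ndarray:
    """Geometric concentration series used in the SPR experiments
    (default 6.25-400 in 2-fold steps)."""
    n = int(round(np.log(high / low) / np.log(factor))) + 1
    return low * factor ** np.arange(n)


def fit_kd(concentrations, responses) -> BindingFit:
    """Least-squares fit of the 1:1 steady-state model to (C, R) data.

    Initialization: rmax0 = max response, kd0 = the concentration whose
    response is nearest half-maximal — robust for geometric dilution
    designs.  Replicates are fitted as individual points.  Convergence to
    relative parameter tolerance 1e-8 or better is enforced.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValidationError("concentrations and responses must be 1-D and equal length")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")
    if np.any(resp < 0):
        raise ValidationError("responses must be >= 0")
    if len(np.unique(conc)) < 3:
        raise ValidationError(
            f"underdetermined fit: need >= 3 distinct concentrations, "
            f"got {len(np.unique(conc))}"
        )
    rmax0 = float(resp.max())
    if rmax0 <= 0:
        raise ValidationError("all responses are zero: kd unidentifiable (rmax at boundary)")
    kd0 = float(conc[np.argmin(np.abs(resp - rmax0 / 2.0))])

    def residuals(theta):
        kd, rmax = theta
        return steady_state_response(conc, kd, rmax) - resp

    result = least_squares(
        residuals,
        x0=[kd0, rmax0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=10000,
    )
    if not result.success:
        raise ValidationError(
            f"1:1 binding fit failed to converge: {result.message}; "
            f"last iterate kd={result.x[0]:.6g}, rmax={result.x[1]:.6g}"
        )
    kd, rmax = map(float, result.x)
    sse = float(np.sum(result.fun ** 2))
    return BindingFit(kd=kd, rmax=rmax, residual_sse=sse, n_points=len(conc))


def average_replicates(concentrations, responses):
    """Mean response per distinct concentration (optional pre-averaging)."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    uniq = np.unique(conc)
    means = np.array([resp[conc == c].mean() for c in uniq])
    return uniq, means
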