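"""Directional-coupler error model.

A directional coupler with finite directivity D leaks a fraction 1/D of
the reflected voltage wave into the forward-wave measurement, so the
measured per-channel signal is ``a_meas = a_act + b/D``.  For an N-channel
array the reflected waves are ``y = (1/mu) e^{i phi} S x_act`` (phi is the
phase offset between the S-parameter reference plane and the coupler
plane, 1/mu the cable attenuation between them), which makes the measured
excitation vector a *linear* image of the actual one:

    x_meas = M x_act,    M = (1/mu) e^{i phi} (1/D) S + I

``M`` is the error matrix.  Measured SAR is then the quadratic form of the
congruence-transformed VOP ``M^H Q M``, so the whole measurement error is
captured by transforming the VOP set once per phase offset.

Conventions
-----------
* Directivity is specified in dB on the *voltage* convention,
  ``D_linear = 10**(dB/20)``: the leakage adds voltage phasors.
* Underestimation ratio ``r = actual / measured-bound >= 1`` is converted
  to percent of the *actual* SAR as ``(1 - 1/r) * 100`` by default; the
  alternative ``(r - 1) * 100`` convention is available everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .array_model import SMatrix, VOPSet, _as_square_complex

__all__ = [
    "CouplerModel",
    "ErrorMatrix",
    "linear_directivity",
    "build_error_matrix",
    "transform_vops",
    "custom_error_matrix",
    "single_channel_worst_case",
    "ratio_to_percent",
]


def linear_directivity(directivity_db) -> float | np.ndarray:
    """Convert directivity from dB to a linear voltage ratio, 10^(dB/20)."""
    d = np.asarray(directivity_db, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("directivity_db must be finite")
    out = 10.0 ** (d / 20.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CouplerModel:
    """Directional-coupler parameters for one measurement setup.

    Parameters
    ----------
    directivity_db
        Directivity in dB (voltage convention); either a scalar applied to
        every channel or a length-N vector of per-channel directivities.
    phase_rad
        Reference-plane phase offset phi between the S-parameter plane and
        the coupler plane; a single value for all channels (cable lengths
        are assumed matched).
    attenuation_linear
        The mu factor (>= 1): linear voltage attenuation of the cable
        between the two reference planes.  mu = 1 places the coupler at
        the S-parameter plane; cable loss is usually negligible next to
        the directivity, hence the default.
    """

    directivity_db: float | np.ndarray
    phase_rad: float = 0.0
    attenuation_linear: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.directivity_db, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("directivity_db must be finite")
        if d.ndim > 1:
            raise ValueError("directivity_db must be a scalar or a 1-D vector")
        if not np.isfinite(self.phase_rad):
            raise ValueError("phase_rad must be finite")
        if not self.attenuation_linear >= 1.0:
            raise ValueError("attenuation_linear must be >= 1 (mu >= 1)")
        object.__setattr__(
            self, "directivity_db", float(d) if d.ndim == 0 else d.copy()
        )

    def inverse_directivity(self, n_channels: int) -> np.ndarray:
        """Per-channel 1/D_linear as a length-N vector."""
        d = np.atleast_1d(np.asarray(self.directivity_db, dtype=float))
        if d.size == 1:
            d = np.full(n_channels, d[0])
        elif d.size != n_channels:
            raise ValueError(
                f"per-channel directivity vector has {d.size} entries for "
                f"{n_channels} channels"
            )
        return 1.0 / linear_directivity(d)

    def with_phase(self, phase_rad: float) -> "CouplerModel":
        return CouplerModel(self.directivity_db, phase_rad, self.attenuation_linear)


@dataclass(frozen=True)
class ErrorMatrix:
    """Complex N x N map from actual to measured excitation vectors."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_square_complex(self.values, "error matrix")
        object.__setattr__(self, "values", arr)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def build_error_matrix(S: SMatrix, coupler: CouplerModel) -> ErrorMatrix:
    """Error matrix ``M = (1/mu) e^{i phi} diag(1/D) S + I``.

    With an ideal coupler (1/D -> 0) or a perfectly matched and decoupled
    array (S = 0) this is the identity: measurement equals reality.
    """
    n = S.n_channels
    inv_d = coupler.inverse_directivity(n)
    phase = np.exp(1j * coupler.phase_rad)
    M = (phase / coupler.attenuation_linear) * (inv_d[:, None] * S.values) + np.eye(n)
    return ErrorMatrix(M)


def custom_error_matrix(values) -> ErrorMatrix:
    """Wrap an arbitrary square complex matrix as the error model.

    Covers measurement schemes beyond directional couplers — e.g. sniffer
    coils, where the diagonal is one and the off-diagonals hold the complex
    inter-coil correlation factors.  The matrix is used verbatim; a singular
    matrix is accepted here and surfaces downstream as an unbounded
    worst-case ratio (a direction with real SAR but zero measured SAR).
    """
    return ErrorMatrix(np.asarray(values, dtype=complex))


def transform_vops(vops: VOPSet, M: ErrorMatrix) -> VOPSet:
    """Congruence-transform every VOP: ``Q -> M^H Q M``, order preserved.

    The output is the "as-measured" VOP set: evaluating it on the actual
    excitation gives exactly the SAR the supervision system would compute
    from the coupler readings.  Hermiticity and positive semidefiniteness
    survive congruence, so the result is a valid VOP set.
    """
    if M.n_channels != vops.n_channels:
        raise ValueError(
            f"error matrix has {M.n_channels} channels, VOP set has {vops.n_channels}"
        )
    Mv = M.values
    transformed = np.einsum("ji,kjl,lm->kim", np.conj(Mv), vops.matrices, Mv)
    return VOPSet(transformed, labels=vops.labels)


def single_channel_worst_case(s11_magnitude: float, directivity_db: float) -> float:
    """Worst-case SAR underestimation ratio for a single transmit channel.

    With one channel, reflection coefficient magnitude ``|s11|`` and linear
    directivity D, the measured forward signal is smallest when the leaked
    reflection opposes the forward wave in phase: ``|a_meas| =
    (1 - |s11|/D) |a_act|``.  SAR goes with the square, so the
    actual-to-measured ratio maximized over the phase offset is

        r = (1 - |s11| / D)^(-2)  >=  1.

    Raises if ``|s11|/D >= 1``: the measured signal can then vanish
    entirely and the ratio is unbounded.
    """
    if not 0.0 <= s11_magnitude <= 1.0:
        raise ValueError("s11_magnitude must lie in [0, 1]")
    q = s11_magnitude / linear_directivity(directivity_db)
    if q >= 1.0:
        raise ValueError(
            "reflection leakage |s11|/D >= 1: the measured signal can vanish "
            "and the worst-case ratio is unbounded"
        )
    return (1.0 - q) ** -2


def ratio_to_percent(ratio, convention: str = "of-actual"):
    """Convert an underestimation ratio r to percent.

    ``"of-actual"`` (default): ``(1 - 1/r) * 100`` — the shortfall as a
    percentage of the actual SAR.  ``"ratio-minus-one"``: ``(r - 1) * 100``.
    """
    r = np.asarray(ratio, dtype=float)
    if convention == "of-actual":
        out = (1.0 - 1.0 / r) * 100.0
    elif convention == "ratio-minus-one":
        out = (r - 1.0) * 100.0
    else:
        raise ValueError(f"unknown percent convention: {convention!r}")
    return float(out) if out.ndim == 0 else out
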