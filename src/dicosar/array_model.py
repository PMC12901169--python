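"""Array-side data objects: scattering matrices and VOP sets.

The two inputs every downstream computation consumes are the complex
N x N scattering matrix ``S`` of the transmit array (50 Ohm reference,
measured or simulated at the coupler reference plane) and a set of
virtual-observation-point (VOP) matrices: Hermitian positive-semidefinite
N x N matrices ``Q_j`` such that ``max_j x^H Q_j x`` upper-bounds local
SAR for any complex excitation vector ``x``.

This module defines the containers, their validation, the reflected-power
eigenvalue spectrum of ``S^H S`` (the worst-case total reflected power per
orthogonal excitation mode), and plain quadratic-form SAR evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import DEFAULT, Tolerances

__all__ = [
    "SMatrix",
    "VOPSet",
    "PassivitySpectrum",
    "ValidationCheck",
    "ValidationReport",
    "validate_smatrix",
    "reflected_power_spectrum",
    "evaluate_sar",
]


def _as_square_complex(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=complex)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {arr.shape}")
    if arr.shape[0] < 1:
        raise ValueError(f"{name} must have at least one channel")
    if not np.all(np.isfinite(arr.real)) or not np.all(np.isfinite(arr.imag)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class SMatrix:
    """Complex scattering matrix of an N-channel transmit array.

    Entries are dimensionless voltage-wave ratios at a common reference
    impedance (50 Ohm by convention).  Reciprocity (symmetry) is *not*
    enforced: measured S-parameters may violate it slightly.
    """

    values: np.ndarray
    frequency_hz: float | None = None
    label: str | None = None

    def __post_init__(self):
        arr = _as_square_complex(self.values, "S-matrix")
        object.__setattr__(self, "values", arr)
        if self.frequency_hz is not None and not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_dict(self) -> dict:
        """Plain-structure serialization (complex split into real/imag)."""
        d = {
            "n_channels": self.n_channels,
            "real": self.values.real.tolist(),
            "imag": self.values.imag.tolist(),
        }
        if self.frequency_hz is not None:
            d["frequency_hz"] = self.frequency_hz
        if self.label is not None:
            d["label"] = self.label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SMatrix":
        values = np.asarray(d["real"], dtype=float) + 1j * np.asarray(d["imag"], dtype=float)
        return cls(values, frequency_hz=d.get("frequency_hz"), label=d.get("label"))


class VOPSet:
    """Ordered collection of Hermitian PSD SAR matrices sharing one channel count.

    Units: W/kg per unit squared excitation amplitude.  Matrices with a
    Hermiticity defect below the tolerance (relative to the largest
    absolute entry) are symmetrized as ``(Q + Q^H)/2`` on construction;
    larger defects are rejected — file round-trips introduce harmless
    asymmetry, genuinely non-Hermitian input is a data error.
    """

    def __init__(
        self,
        matrices: Sequence[np.ndarray] | np.ndarray,
        labels: Sequence[str] | None = None,
        tol: Tolerances = DEFAULT,
    ):
        mats = np.asarray(matrices, dtype=complex)
        if mats.ndim != 3:
            raise ValueError(f"expected a K x N x N stack of matrices, got shape {mats.shape}")
        if mats.shape[0] < 1:
            raise ValueError("empty VOP set")
        if mats.shape[1] != mats.shape[2]:
            raise ValueError(f"VOP matrices must be square, got shape {mats.shape[1:]}")
        if not (np.all(np.isfinite(mats.real)) and np.all(np.isfinite(mats.imag))):
            raise ValueError("VOP matrices contain non-finite entries")

        herm = 0.5 * (mats + np.conj(np.swapaxes(mats, 1, 2)))
        for k in range(mats.shape[0]):
            scale = np.abs(mats[k]).max()
            defect = np.abs(mats[k] - herm[k]).max()
            if scale > 0 and defect > tol.hermiticity * scale:
                raise ValueError(
                    f"VOP matrix {k} is not Hermitian: asymmetry {defect:.3e} "
                    f"exceeds tolerance {tol.hermiticity:.1e} x {scale:.3e}"
                )
            w = np.linalg.eigvalsh(herm[k])
            if w[0] < -tol.psd * max(w[-1], 0.0) - tol.psd:
                raise ValueError(
                    f"VOP matrix {k} is not positive semidefinite "
                    f"(min eigenvalue {w[0]:.3e}, max {w[-1]:.3e})"
                )
        if labels is not None:
            labels = list(labels)
            if len(labels) != mats.shape[0]:
                raise ValueError("label count does not match matrix count")
        self.matrices = herm
        self.labels = labels

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.matrices[k]

    def __iter__(self):
        return iter(self.matrices)

    def to_dict(self) -> dict:
        d = {
            "n_channels": self.n_channels,
            "real": self.matrices.real.tolist(),
            "imag": self.matrices.imag.tolist(),
        }
        if self.labels is not None:
            d["labels"] = list(self.labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VOPSet":
        mats = np.asarray(d["real"], dtype=float) + 1j * np.asarray(d["imag"], dtype=float)
        return cls(mats, labels=d.get("labels"))


@dataclass(frozen=True)
class PassivitySpectrum:
    """Eigenvalues of S^H S, sorted descending.

    Each value is the fraction of forward power returned by the array when
    driven along the corresponding orthogonal excitation mode; the first
    entry is the worst-case total reflected power fraction.
    """

    eigenvalues: np.ndarray

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def worst_case_reflected_power(self) -> float:
        return float(self.eigenvalues[0])


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    status: str  # "pass" | "warn" | "fail"
    detail: str = ""
    value: float | None = None


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.status != "fail" for c in self.checks)

    @property
    def warnings(self) -> list[ValidationCheck]:
        return [c for c in self.checks if c.status == "warn"]

    def __iter__(self):
        return iter(self.checks)

    def __getitem__(self, name: str) -> ValidationCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def validate_smatrix(S: SMatrix, tol: Tolerances = DEFAULT) -> ValidationReport:
    """Run named validation checks on a scattering matrix.

    Passivity violations are reported as warnings, not failures: measured
    S-parameters are routinely a hair non-passive.  ``S`` is never mutated.
    """
    report = ValidationReport()
    v = S.values
    report.checks.append(
        ValidationCheck("square", "pass", f"{S.n_channels} channels")
    )
    report.checks.append(ValidationCheck("finite", "pass"))
    max_abs = float(np.abs(v).max())
    report.checks.append(
        ValidationCheck("max_abs_entry", "pass", f"max |S_ij| = {max_abs:.6g}", max_abs)
    )
    lam_max = float(np.linalg.eigvalsh(v.conj().T @ v)[-1])
    status = "pass" if lam_max <= 1.0 + tol.passivity else "warn"
    report.checks.append(
        ValidationCheck(
            "passivity",
            status,
            f"max eigenvalue of S^H S = {lam_max:.6g} (tolerance 1 + {tol.passivity:.1e})",
            lam_max,
        )
    )
    return report


def reflected_power_spectrum(S: SMatrix) -> PassivitySpectrum:
    """Eigenvalues of ``S^H S`` sorted descending.

    Equal to the squared singular values of ``S``; the leading value is the
    worst-case total reflected power fraction of the array, a scalar quality
    measure of inter-element coupling plus mismatch.
    """
    v = S.values
    ev = np.linalg.eigvalsh(v.conj().T @ v)[::-1]
    return PassivitySpectrum(np.ascontiguousarray(ev))


def evaluate_sar(vops: VOPSet, x) -> np.ndarray:
    """Per-VOP SAR ``x^H Q_j x`` for a complex excitation vector ``x``.

    Returns a real vector with one entry per VOP matrix.  Invariant under a
    global phase of ``x`` and quadratic in its scale.
    """
    x = np.asarray(x, dtype=complex).ravel()
    if x.shape[0] != vops.n_channels:
        raise ValueError(
            f"excitation vector has {x.shape[0]} entries, VOP set has "
            f"{vops.n_channels} channels"
        )
    # einsum over the stack: real part only (Hermitian forms are real)
    vals = np.einsum("i,kij,j->k", np.conj(x), vops.matrices, x)
    return np.ascontiguousarray(vals.real)
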