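"""File formats, run configuration and end-to-end analysis reports.

Supported formats
-----------------
* Touchstone v1.1 ``.sNp`` files (RI/MA/DB formats, all option-line
  frequency units, 50 Ohm default reference).  Version 2.0 files are
  rejected outright rather than half-parsed.
* An HDF5 VOP container (group ``vops`` with ``real``/``imag`` float64
  stacks of shape K x N x N, channel count and labels as attributes);
  round-trips are bit-exact.
* MAT v7.3 compatibility: HDF5-based ``.mat`` files holding an
  N x N x K complex array load as a VOP set (MATLAB stores dimensions
  reversed and complex numbers as a real/imag compound, both of which are
  undone on read).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .array_model import SMatrix, VOPSet, reflected_power_spectrum, validate_smatrix
from .coupler import ratio_to_percent
from .worst_case import phase_sweep, power_error_sweep

__all__ = [
    "TouchstoneError",
    "read_touchstone",
    "write_touchstone",
    "read_vops",
    "write_vops",
    "write_vops_mat",
    "RunConfig",
    "run_analysis",
]


class TouchstoneError(ValueError):
    """Malformed Touchstone file; the message names the offending line."""


_FREQ_UNITS = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def _n_ports_from_suffix(path: Path) -> int:
    m = re.fullmatch(r"\.s(\d+)p", path.suffix.lower())
    if not m:
        raise TouchstoneError(
            f"{path.name}: cannot determine port count; expected an .sNp suffix"
        )
    return int(m.group(1))


def _pairs_to_complex(re_vals, im_vals, fmt: str) -> np.ndarray:
    re_vals = np.asarray(re_vals, dtype=float)
    im_vals = np.asarray(im_vals, dtype=float)
    if fmt == "RI":
        return re_vals + 1j * im_vals
    if fmt == "MA":
        return re_vals * np.exp(1j * np.deg2rad(im_vals))
    if fmt == "DB":
        return 10.0 ** (re_vals / 20.0) * np.exp(1j * np.deg2rad(im_vals))
    raise TouchstoneError(f"unknown data format {fmt!r}")


def read_touchstone(path, frequency_hz: float | None = None) -> SMatrix:
    """Parse a Touchstone v1.1 ``.sNp`` file into an :class:`SMatrix`.

    Single-frequency files load directly; multi-frequency files require a
    requested ``frequency_hz`` (the nearest stored point is selected) and
    otherwise fail listing the available frequencies.  The v1.1 2-port
    column order (S11 S21 S12 S22) is honored; for other port counts data
    is row-major.  The reference impedance from the option line is kept as
    metadata in the label.
    """
    path = Path(path)
    n = _n_ports_from_suffix(path)
    unit_scale = _FREQ_UNITS["GHZ"]
    fmt = "MA"
    z0 = 50.0
    saw_option = False

    tokens: list[tuple[float, int]] = []  # (value, line number)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                raise TouchstoneError(
                    f"{path.name}:{lineno}: Touchstone v2.0 keyword {line.split()[0]} "
                    "found; only v1.1 files are supported"
                )
            if line.startswith("#"):
                if saw_option:
                    # v1.1 allows repeated option lines only if identical; be strict
                    raise TouchstoneError(
                        f"{path.name}:{lineno}: multiple option lines"
                    )
                saw_option = True
                parts = line[1:].upper().split()
                i = 0
                while i < len(parts):
                    tok = parts[i]
                    if tok in _FREQ_UNITS:
                        unit_scale = _FREQ_UNITS[tok]
                    elif tok == "S":
                        pass
                    elif tok in ("RI", "MA", "DB"):
                        fmt = tok
                    elif tok == "R":
                        if i + 1 >= len(parts):
                            raise TouchstoneError(
                                f"{path.name}:{lineno}: option line 'R' without a value"
                            )
                        i += 1
                        z0 = float(parts[i])
                    elif tok in ("Y", "Z", "H", "G"):
                        raise TouchstoneError(
                            f"{path.name}:{lineno}: parameter type {tok} not supported "
                            "(S-parameters only)"
                        )
                    else:
                        raise TouchstoneError(
                            f"{path.name}:{lineno}: unrecognized option token {tok!r}"
                        )
                    i += 1
                continue
            for tok in line.split():
                try:
                    tokens.append((float(tok), lineno))
                except ValueError:
                    raise TouchstoneError(
                        f"{path.name}:{lineno}: non-numeric data token {tok!r}"
                    ) from None

    per_point = 1 + 2 * n * n
    if not tokens:
        raise TouchstoneError(f"{path.name}: no data found")
    if len(tokens) % per_point != 0:
        raise TouchstoneError(
            f"{path.name}:{tokens[-1][1]}: data count {len(tokens)} is not a "
            f"multiple of {per_point} values per frequency point for a "
            f"{n}-port file (inconsistent column count or port-count mismatch)"
        )
    values = np.array([t[0] for t in tokens])
    pts = values.reshape(-1, per_point)
    freqs_hz = pts[:, 0] * unit_scale

    if pts.shape[0] > 1:
        if frequency_hz is None:
            listing = ", ".join(f"{f:.6g}" for f in freqs_hz)
            raise TouchstoneError(
                f"{path.name}: {pts.shape[0]} frequency points present; request "
                f"one via frequency_hz. Available (Hz): {listing}"
            )
        idx = int(np.argmin(np.abs(freqs_hz - frequency_hz)))
    else:
        idx = 0

    row = pts[idx, 1:]
    cplx = _pairs_to_complex(row[0::2], row[1::2], fmt)
    if n == 2:
        # v1.1 2-port order: S11 S21 S12 S22
        S = np.array([[cplx[0], cplx[2]], [cplx[1], cplx[3]]])
    else:
        S = cplx.reshape(n, n)
    label = f"{path.stem} (Z0={z0:g} Ohm)"
    return SMatrix(S, frequency_hz=float(freqs_hz[idx]), label=label)


def write_touchstone(S: SMatrix, path) -> None:
    """Write a single-frequency Touchstone v1.1 file in RI format."""
    path = Path(path)
    n = _n_ports_from_suffix(path)
    if n != S.n_channels:
        raise ValueError(
            f"suffix {path.suffix} implies {n} ports but the matrix has "
            f"{S.n_channels} channels"
        )
    freq = S.frequency_hz if S.frequency_hz is not None else 1.0
    v = S.values
    if n == 2:
        seq = [v[0, 0], v[1, 0], v[0, 1], v[1, 1]]
    else:
        seq = list(v.ravel())
    with open(path, "w") as fh:
        if S.label:
            fh.write(f"! {S.label}\n")
        fh.write("# HZ S RI R 50\n")
        fields = [f"{freq:.10g}"]
        for i, c in enumerate(seq):
            fields.append(f"{c.real:.17g}")
            fields.append(f"{c.imag:.17g}")
            # at most 4 complex pairs per line per v1.1 convention
            if (i + 1) % 4 == 0 and i + 1 < len(seq):
                fh.write(" ".join(fields) + "\n")
                fields = []
        if fields:
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VOP containers
# ---------------------------------------------------------------------------


def write_vops(vops: VOPSet, path) -> None:
    """Write a VOP set to the native HDF5 schema (bit-exact round-trip)."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("vops")
        grp.create_dataset("real", data=vops.matrices.real)
        grp.create_dataset("imag", data=vops.matrices.imag)
        grp.attrs["n_channels"] = vops.n_channels
        if vops.labels is not None:
            grp.create_dataset(
                "labels", data=np.array(vops.labels, dtype=h5py.string_dtype())
            )


def write_vops_mat(vops: VOPSet, path, name: str = "VOPs") -> None:
    """Write a VOP set in a MAT v7.3-compatible layout.

    MATLAB stores an N x N x K array with reversed dimension order and
    complex values as a ('real', 'imag') compound; this writer mimics that
    layout so the compatibility reader exercises the same code path as
    genuine exports.
    """
    data = np.transpose(vops.matrices, (0, 2, 1))  # reversed-dims layout
    comp = np.empty(data.shape, dtype=[("real", "<f8"), ("imag", "<f8")])
    comp["real"] = data.real
    comp["imag"] = data.imag
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(name, data=comp)
        ds.attrs["MATLAB_class"] = np.bytes_(b"double")


def _read_vops_native(fh: h5py.File, path: Path) -> VOPSet:
    grp = fh["vops"]
    real = np.asarray(grp["real"])
    imag = np.asarray(grp["imag"])
    if real.shape != imag.shape:
        raise ValueError(
            f"{path.name}: real/imag shape mismatch {real.shape} vs {imag.shape}"
        )
    if real.ndim != 3:
        raise ValueError(f"{path.name}: expected K x N x N stacks, got {real.shape}")
    if real.shape[0] == 0:
        raise ValueError(f"{path.name}: empty VOP set")
    labels = None
    if "labels" in grp:
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in grp["labels"][...]
        ]
    return VOPSet(real + 1j * imag, labels=labels)


def _read_vops_mat(fh: h5py.File, path: Path) -> VOPSet:
    candidates = [
        k for k in fh.keys() if not k.startswith("#") and isinstance(fh[k], h5py.Dataset)
    ]
    if not candidates:
        raise ValueError(f"{path.name}: no array dataset found")
    ds = fh[candidates[0]]
    data = ds[...]
    if data.dtype.names and {"real", "imag"} <= set(data.dtype.names):
        arr = data["real"] + 1j * data["imag"]
    else:
        arr = np.asarray(data, dtype=complex)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError(
            f"{path.name}: expected an N x N x K array, got HDF5 shape {arr.shape}"
        )
    if arr.shape[0] == 0:
        raise ValueError(f"{path.name}: empty VOP set")
    # MATLAB dimension order is reversed on disk: undo the per-slice transpose
    return VOPSet(np.transpose(arr, (0, 2, 1)))


def read_vops(path) -> VOPSet:
    """Load a VOP set from the native HDF5 schema or a MAT v7.3 file."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as fh:
            if "vops" in fh:
                return _read_vops_native(fh, path)
            return _read_vops_mat(fh, path)
    except ValueError as exc:
        raise ValueError(f"failed to load VOP set: {exc}") from exc


# ---------------------------------------------------------------------------
# run configuration and report bundles
# ---------------------------------------------------------------------------

_ANALYSES = ("sar_error", "power_error", "reflected_power", "all")


@dataclass
class RunConfig:
    """Everything one end-to-end analysis run needs, YAML-loadable."""

    smatrix_path: str
    vops_path: str | None = None
    directivity_db: list[float] = field(default_factory=lambda: [25.0])
    n_phase_steps: int = 360
    attenuation: float = 1.0
    analysis: str = "all"
    output_dir: str = "dicosar-out"
    seed: int = 0
    percent_convention: str = "of-actual"
    frequency_hz: float | None = None
    make_plots: bool = False

    def __post_init__(self):
        if isinstance(self.directivity_db, (int, float)):
            self.directivity_db = [float(self.directivity_db)]
        self.directivity_db = [float(d) for d in self.directivity_db]
        if self.n_phase_steps < 1:
            raise ValueError("n_phase_steps must be >= 1")
        if self.analysis not in _ANALYSES:
            raise ValueError(f"analysis must be one of {_ANALYSES}")
        if not Path(self.smatrix_path).exists():
            raise FileNotFoundError(self.smatrix_path)
        needs_vops = self.analysis in ("sar_error", "all")
        if needs_vops and self.vops_path is None:
            raise ValueError(f"analysis {self.analysis!r} requires vops_path")
        if self.vops_path is not None and not Path(self.vops_path).exists():
            raise FileNotFoundError(self.vops_path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sweep_frame(sweep, convention: str) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "phase_rad": sweep.phases_rad,
            "ratio": sweep.ratios,
            "percent_of_actual": ratio_to_percent(sweep.ratios, "of-actual"),
            "percent_ratio_minus_one": ratio_to_percent(sweep.ratios, "ratio-minus-one"),
        }
    )
    if sweep.results:
        frame["argmax_vop_index"] = [r.argmax_vop_index for r in sweep.results]
        frame["certificate_gap"] = [r.certificate_gap for r in sweep.results]
    frame["percent"] = ratio_to_percent(sweep.ratios, convention)
    return frame


def run_analysis(config: RunConfig) -> dict:
    """Run the configured analyses and write the report bundle.

    Emits one CSV per analysis and directivity (phase, ratio, both percent
    conventions, argmax VOP, certificate gap), a ``summary.json`` with the
    peaks, the convention flag, software version and input digests, and —
    when requested and matplotlib is importable — error-vs-phase and
    reflected-power-spectrum plots.  Returns the summary dict.
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    S = read_touchstone(config.smatrix_path, frequency_hz=config.frequency_hz)
    digests = {"smatrix": _sha256(config.smatrix_path)}
    vops = None
    if config.vops_path is not None:
        vops = read_vops(config.vops_path)
        digests["vops"] = _sha256(config.vops_path)

    summary: dict = {
        "software_version": __version__,
        "inputs": {
            "smatrix_path": str(config.smatrix_path),
            "vops_path": str(config.vops_path) if config.vops_path else None,
            "digests": digests,
        },
        "n_phase_steps": config.n_phase_steps,
        "attenuation": config.attenuation,
        "percent_convention": config.percent_convention,
        "analyses": {},
        "solver_log": [],
    }
    timestamps = {"started_utc": datetime.now(timezone.utc).isoformat()}

    run_sar = config.analysis in ("sar_error", "all") and vops is not None
    run_power = config.analysis in ("power_error", "all")
    run_spectrum = config.analysis in ("reflected_power", "all")

    validation = validate_smatrix(S)
    summary["validation"] = [
        {"name": c.name, "status": c.status, "detail": c.detail} for c in validation
    ]

    if run_spectrum:
        spec = reflected_power_spectrum(S)
        pd.DataFrame(
            {
                "mode": np.arange(1, len(spec.eigenvalues) + 1),
                "reflected_power_fraction": spec.eigenvalues,
            }
        ).to_csv(out / "reflected_power_spectrum.csv", index=False)
        summary["analyses"]["reflected_power"] = {
            "worst_case_reflected_power": spec.worst_case_reflected_power,
            "eigenvalues": spec.eigenvalues.tolist(),
        }

    sar_entries = {}
    power_entries = {}
    curves = {"sar_error": {}, "power_error": {}}
    for d in config.directivity_db:
        tag = f"{d:g}dB"
        if run_sar:
            sw = phase_sweep(
                vops, S, d, n_steps=config.n_phase_steps, attenuation=config.attenuation
            )
            _sweep_frame(sw, config.percent_convention).to_csv(
                out / f"sar_error_{tag}.csv", index=False
            )
            gaps = [r.certificate_gap for r in sw.results]
            summary["solver_log"].append(
                {
                    "analysis": "sar_error",
                    "directivity_db": d,
                    "statuses": sorted({r.solver_status for r in sw.results}),
                    "max_certificate_gap": float(np.max(gaps)),
                }
            )
            sar_entries[tag] = {
                "directivity_db": d,
                "peak_ratio": sw.peak_ratio,
                "peak_percent": sw.peak_percent(config.percent_convention),
                "peak_phase_rad": sw.peak_phase_rad,
            }
            curves["sar_error"][tag] = sw
        if run_power:
            sw = power_error_sweep(
                S, d, n_steps=config.n_phase_steps, attenuation=config.attenuation
            )
            _sweep_frame(sw, config.percent_convention).to_csv(
                out / f"power_error_{tag}.csv", index=False
            )
            power_entries[tag] = {
                "directivity_db": d,
                "peak_ratio": sw.peak_ratio,
                "peak_percent": sw.peak_percent(config.percent_convention),
                "peak_phase_rad": sw.peak_phase_rad,
            }
            curves["power_error"][tag] = sw
    if run_sar:
        summary["analyses"]["sar_error"] = sar_entries
    if run_power:
        summary["analyses"]["power_error"] = power_entries

    if config.make_plots:
        _write_plots(out, S, curves, run_spectrum, config.percent_convention)

    timestamps["finished_utc"] = datetime.now(timezone.utc).isoformat()
    summary["timestamps"] = timestamps
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False)
    return summary


def _write_plots(out: Path, S: SMatrix, curves: dict, with_spectrum: bool, convention: str):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is an optional extra
        return
    for kind, by_tag in curves.items():
        if not by_tag:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        for tag, sw in by_tag.items():
            ax.plot(sw.phases_rad, sw.percent(convention), label=tag)
        ax.set_xlabel("reference-plane phase offset (rad)")
        ax.set_ylabel(f"underestimation ({convention}, %)")
        ax.set_title("local SAR" if kind == "sar_error" else "total forward power")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"{kind}_vs_phase.png", dpi=120)
        plt.close(fig)
    if with_spectrum:
        spec = reflected_power_spectrum(S)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(np.arange(1, len(spec.eigenvalues) + 1), spec.eigenvalues)
        ax.set_xlabel("mode")
        ax.set_ylabel("reflected power fraction")
        fig.tight_layout()
        fig.savefig(out / "reflected_power_spectrum.png", dpi=120)
        plt.close(fig)
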