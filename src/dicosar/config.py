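"""Package-level numerical tolerances.

All validation and solver tolerances live here so they can be adjusted in
one place; the defaults are what every public function uses unless an
explicit override is passed.
"""

from dataclasses import dataclass


@dataclass
class Tolerances:
    #: passivity slack on the largest eigenvalue of S^H S (measured data
    #: may be marginally non-passive)
    passivity: float = 1e-6
    #: relative Hermiticity tolerance for SAR matrices (relative to the
    #: largest absolute entry)
    hermiticity: float = 1e-9
    #: PSD slack: minimum eigenvalue >= -psd * maximum eigenvalue
    psd: float = 1e-10
    #: relative convergence tolerance of the worst-case solver
    solver: float = 1e-8


DEFAULT = Tolerances()
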