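"""Model parameters and YAML configuration handling.

The pacemaker is a Van der Pol-type limit-cycle oscillator driven by a
processed light signal (Process L) and a square-wave rest/activity signal.
The oscillator constants (``mu``, ``tau_c``, ``Lq``, ``Lk``, ``ls``,
``as_``) are the published values for the human circadian pacemaker; the
light-processor constants (``alpha0``, ``beta``, ``G``, ``p``, ``I0``) and
the non-photic magnitude ``rho`` follow the standard phototransduction
formulation from the same model lineage.  All are overridable through a
YAML config file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the pacemaker, light processor and non-photic drive.

    Attributes
    ----------
    mu : float
        Stiffness of the Van der Pol nonlinearity (dimensionless).
    tau_c : float
        Intrinsic circadian period, hours.
    Lq, Lk : float
        Light coupling constants in the complementary-variable equation.
    ls : float
        Light sensitivity of the state-dependent photic modulator.
    as_ : float
        Activity sensitivity of the non-photic modulator (tanh gain).
    alpha0 : float
        Photoreceptor activation rate at the reference illuminance, min^-1.
    beta : float
        Photoreceptor recovery rate, min^-1.
    G : float
        Photic drive gain (dimensionless).
    p : float
        Lux-compression exponent of the activation rate.
    I0 : float
        Reference illuminance, photopic lux.
    rho : float
        Magnitude of the square-wave non-photic drive.
    """

    mu: float = 0.13
    tau_c: float = 24.2
    Lq: float = 1.0 / 3.0
    Lk: float = 0.55
    ls: float = 0.4
    as_: float = 10.0
    alpha0: float = 0.05
    beta: float = 0.0075
    G: float = 33.75
    p: float = 0.5
    I0: float = 9500.0
    rho: float = 0.032

    # Fixed structural constants: the empirical period correction in the
    # restoring-force term and the base angular-velocity scale (rad/h).
    period_correction: float = field(default=0.99729, init=False, repr=False)
    omega_scale: float = field(default=math.pi / 12.0, init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError("tau_c must be positive")
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not 0 < self.ls < 1:
            raise ValueError("ls must lie in (0, 1)")
        if not self.as_ > 0:
            raise ValueError("as_ must be positive")
        for name in ("alpha0", "beta", "G", "I0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)


#: Config keys that map onto ModelParameters fields (``as`` is accepted as an
#: alias for ``as_`` since trailing underscores are awkward in YAML).
_PARAM_KEYS = {
    "mu", "tau_c", "Lq", "Lk", "ls", "as_", "as",
    "alpha0", "beta", "G", "p", "I0", "rho",
}


def load_config(path) -> tuple[ModelParameters, dict]:
    """Read a YAML config file.

    Returns the ModelParameters built from any recognised parameter keys,
    plus a dict of the remaining run options (mode, init, cbtmin_offset_h,
    integrator step, thresholds, ...).
    """
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    pkw, extras = {}, {}
    for key, value in raw.items():
        if key in _PARAM_KEYS:
            pkw["as_" if key == "as" else key] = float(value)
        else:
            extras[key] = value
    return ModelParameters(**pkw), extras
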