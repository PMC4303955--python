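"""Core model definitions for miRNA-mediated feed-forward loops (FFLs).

A feed-forward loop couples an upstream transcription factor (TF) to a
target gene through two routes: direct transcriptional regulation, and an
indirect route through a miRNA that represses the target
post-transcriptionally.  The system is described by five molecule counts:

    w : TF mRNA
    q : TF protein
    s : miRNA
    r : target mRNA
    p : target protein

TF mRNA and TF protein follow linear synthesis/degradation kinetics;
transcription of the miRNA and target genes is a Hill function of the TF
count, with the sign of each arm set by the loop topology.  The three
miRNA-action mechanisms differ only in how ``s`` feeds back on the target:

* **Stop** — miRNA represses translation: the target translation rate is a
  repressive Hill function of ``s``.
* **Target degradation** — miRNA accelerates target-mRNA decay: an
  activating Hill term in ``s`` is added to the basal degradation rate.
* **Dual degradation** — miRNA and target mRNA degrade together as a
  complex: a bilinear ``-krs*r*s`` loss appears in both the ``s`` and ``r``
  equations (the miRNA is consumed rather than re-used).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace as _dc_replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = [
    "ParameterSet",
    "Topology",
    "Mechanism",
    "State",
    "SPECIES",
    "default_parameters",
    "hill",
    "production_rates",
    "effective_mrna_degradation",
    "rhs",
    "DomainError",
    "ConfigurationError",
]


class DomainError(ValueError):
    """A quantity fell outside its physical domain (e.g. a negative count)."""


class ConfigurationError(ValueError):
    """An invalid mechanism/topology/settings combination was requested."""


SPECIES = ("w", "q", "s", "r", "p")


class State(NamedTuple):
    """Molecule counts of the five species at one time point."""

    w: float
    q: float
    s: float
    r: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @staticmethod
    def from_array(a: Iterable[float]) -> "State":
        w, q, s, r, p = (float(x) for x in a)
        return State(w, q, s, r, p)


@dataclass(frozen=True)
class ParameterSet:
    """All kinetic constants of the FFL models.

    Units: synthesis maxima (kw, ks, kr) in molecules/s; first-order rates
    (gw, gq, gs, gr, gp, kq, kp, gmax) in 1/s; half-saturation constants
    (hs, hr, hp, hg) in molecules; the complex-degradation constant krs in
    1/(molecule*s); c is the (even) Hill coefficient magnitude.
    """

    kw: float = 0.06      # TF-mRNA synthesis rate
    gw: float = 0.004     # TF-mRNA degradation rate
    kq: float = 0.04      # TF translation rate (per mRNA)
    gq: float = 0.002     # TF degradation rate
    ks: float = 0.5       # maximal miRNA transcription rate
    hs: float = 200.0     # TF half-saturation of the miRNA gene
    gs: float = 0.002     # miRNA degradation rate
    kr: float = 0.08      # maximal target transcription rate
    hr: float = 200.0     # TF half-saturation of the target gene
    gr: float = 0.004     # basal target-mRNA degradation rate
    kp: float = 0.8       # maximal target translation rate (per mRNA)
    gp: float = 0.002     # target-protein degradation rate
    hp: float = 60.0      # miRNA half-repression constant (Stop model)
    gmax: float = 0.004   # maximal extra mRNA degradation (Target-deg model)
    hg: float = 60.0      # miRNA half-saturation of the degradation term
    krs: float = 2e-5     # miRNA-mRNA complex degradation constant (Dual model)
    c: int = 2            # Hill coefficient magnitude

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "c":
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise DomainError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise DomainError(f"parameter {f.name} must be >= 0, got {v}")
        if not (isinstance(self.c, int) and self.c > 0 and self.c % 2 == 0):
            raise DomainError(f"Hill coefficient c must be a positive even integer, got {self.c!r}")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given coefficients replaced."""
        return _dc_replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_parameters() -> ParameterSet:
    """The reference coefficient set used throughout the analyses."""
    return ParameterSet()


class Topology(enum.Enum):
    """The four FFL wirings: sign of TF action on the miRNA and target genes.

    A loop is *coherent* when the direct arm and the overall sign of the
    indirect arm (TF -> miRNA -| target) agree, *incoherent* otherwise.
    """

    IN1 = ("1In", +1, +1)  # TF activates both miRNA and target genes
    C1 = ("1C", +1, -1)    # TF activates miRNA, represses target
    IN2 = ("2In", -1, -1)  # TF represses both
    C2 = ("2C", -1, +1)    # TF represses miRNA, activates target

    def __init__(self, label: str, sign_mirna: int, sign_target: int):
        self.label = label
        self.sign_mirna = sign_mirna
        self.sign_target = sign_target

    @classmethod
    def from_name(cls, name: str) -> "Topology":
        key = str(name).strip().lower()
        for t in cls:
            if key in (t.label.lower(), t.name.lower()):
                return t
        raise ConfigurationError(
            f"unknown topology {name!r}; expected one of {[t.label for t in cls]}"
        )


class Mechanism(enum.Enum):
    """How the miRNA acts on its target."""

    STOP = "stop"              # translational repression
    TARGET_DEG = "target_deg"  # miRNA-enhanced target-mRNA degradation
    DUAL_DEG = "dual_deg"      # joint miRNA + mRNA complex degradation

    @classmethod
    def from_name(cls, name: str) -> "Mechanism":
        key = str(name).strip().lower().replace("-", "_")
        aliases = {
            "stop": cls.STOP,
            "target": cls.TARGET_DEG,
            "target_deg": cls.TARGET_DEG,
            "target_degradation": cls.TARGET_DEG,
            "dual": cls.DUAL_DEG,
            "dual_deg": cls.DUAL_DEG,
            "dual_degradation": cls.DUAL_DEG,
        }
        if key in aliases:
            return aliases[key]
        raise ConfigurationError(
            f"unknown mechanism {name!r}; expected one of {sorted(set(aliases))}"
        )


def hill(x, kmax: float, h: float, sign: int, c: int = 2):
    """Hill regulation rate.

    ``sign=+1`` (activation) returns ``kmax * x**c / (h**c + x**c)``;
    ``sign=-1`` (repression) returns ``kmax * h**c / (h**c + x**c)``.
    The result always lies in ``[0, kmax]`` and the two signs sum to kmax.

    Accepts scalars or numpy arrays for ``x``.  The degenerate
    half-saturation ``h = 0`` is resolved by continuity in ``x > 0``:
    activation saturates immediately (``kmax`` everywhere, including the
    0/0 point at ``x = 0``); repression is 0 for ``x > 0`` and ``kmax`` at
    ``x = 0``.
    """
    if sign not in (+1, -1):
        raise ConfigurationError(f"sign must be +1 or -1, got {sign!r}")
    if kmax < 0 or h < 0:
        raise DomainError("kmax and h must be nonnegative")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise DomainError("regulator count x must be nonnegative")
    scalar = np.ndim(x) == 0
    if h == 0.0:
        if sign == +1:
            out = np.full_like(x_arr, kmax)
        else:
            out = np.where(x_arr == 0.0, kmax, 0.0)
        return float(out) if scalar else out
    xc = x_arr**c
    hc = h**c
    out = kmax * (xc if sign == +1 else hc) / (hc + xc)
    return float(out) if scalar else out


def production_rates(topology: Topology, params: ParameterSet, q):
    """Transcription rates (miRNA gene, target gene) at TF count ``q``.

    The sign of each Hill function is taken from the topology: e.g. the
    type 1 coherent loop activates the miRNA gene and represses the target.
    """
    ks_q = hill(q, params.ks, params.hs, topology.sign_mirna, params.c)
    kr_q = hill(q, params.kr, params.hr, topology.sign_target, params.c)
    return ks_q, kr_q


def effective_mrna_degradation(s, params: ParameterSet):
    """Target-mRNA degradation rate under the Target-degradation mechanism.

    The basal rate ``gr`` plus an activating Hill term in the miRNA count,
    saturating at ``gr + gmax``.
    """
    return params.gr + hill(s, params.gmax, params.hg, +1, params.c)


def rhs(
    mechanism: Mechanism,
    topology: Topology,
    params: ParameterSet,
    state: State,
    q_for_regulation: float | None = None,
) -> State:
    """Time derivatives of the five species at ``state``.

    ``q_for_regulation`` is the TF count seen by the miRNA and target
    promoters; it defaults to ``state.q`` and is overridden only by the
    TF-noise experiment (the TF's own dynamics are never perturbed).
    """
    if not isinstance(mechanism, Mechanism):
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    if not isinstance(topology, Topology):
        raise ConfigurationError(f"unknown topology {topology!r}")
    w, q, s, r, p = state
    for name, v in zip(SPECIES, state):
        if v < 0:
            raise DomainError(f"state component {name} must be >= 0, got {v}")
    q_reg = q if q_for_regulation is None else q_for_regulation
    ks_q, kr_q = production_rates(topology, params, q_reg)

    dw = params.kw - params.gw * w
    dq = params.kq * w - params.gq * q

    if mechanism is Mechanism.STOP:
        ds = ks_q - params.gs * s
        dr = kr_q - params.gr * r
        dp = hill(s, params.kp, params.hp, -1, params.c) * r - params.gp * p
    elif mechanism is Mechanism.TARGET_DEG:
        ds = ks_q - params.gs * s
        dr = kr_q - effective_mrna_degradation(s, params) * r
        dp = params.kp * r - params.gp * p
    else:  # DUAL_DEG
        ds = ks_q - params.gs * s - params.krs * r * s
        dr = kr_q - params.gr * r - params.krs * r * s
        dp = params.kp * r - params.gp * p

    return State(dw, dq, ds, dr, dp)
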