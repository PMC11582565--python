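"""Ligand-gated conformational state space of adenylate kinase and its CTMC generator.

The enzyme is modelled as a 10-state continuous-time Markov chain.  Observable
current levels correspond to the arrangement of the two mobile domains (LID,
NMP); asterisks mark bound ligands, which are *hidden* (they do not change the
emission level).  State roster, in the canonical row order used throughout::

    M0    anomalous shallow level (~ -180 pA), domains open, no ligand
    M1    NMP closed, apo
    M1*   NMP closed, one ligand
    M     fully open, apo
    M*    fully open, one ligand
    M2*   LID closed, one ligand
    M2**  LID closed, two ligands
    M**   fully open, two ligands
    M1**  NMP closed, two ligands
    M3**  LID and NMP closed, two ligands

For the ATP/AMP model the first ligand is ATP (association rate ``k1·|ATP|``)
and the second AMP (``k2·|AMP|``); the ADP model uses ADP for both.  Model
variants encode the two endosteric couplings:

* ``V3`` (full endosteric model): no direct M* <-> M** transition (ATP-induced
  effect) and LID rates r1/r_m1 distinct from r3/r_m3 (AMP-induced effect).
* ``V1``: LID dynamics independent of the second ligand — r3 tied to r1 and
  r_m3 tied to r_m1.
* ``V2``: second-ligand binding independent of LID status — M* <-> M**
  restored, re-using the M2* <-> M2** binding rates k2/k_m2.
* ``ADP``: V3 topology driven by a single ligand species.

Rates are stored in s^-1 (bimolecular rates in s^-1 mM^-1); concentrations in
mM.  Conversion to the ms time base happens only at discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "State",
    "StateSpace",
    "RateVector",
    "LigandConcentrations",
    "ModelVariant",
    "GeneratorMatrix",
    "EMISSION_GROUPS",
    "build_state_space",
    "build_generator",
    "apply_variant",
    "free_parameters",
    "transition_table",
]

EMISSION_GROUPS = ("M0", "M", "M1", "M2", "M3")

VARIANT_IDS = ("V1", "V2", "V3", "ADP")


@dataclass(frozen=True)
class State:
    name: str
    emission_group: str
    lid_status: str  # "open" | "closed"
    nmp_status: str  # "open" | "closed"
    n_bound_ligands: int


# Canonical 10-state roster (row order of the generator matrix).
_STATES = (
    State("M0", "M0", "open", "open", 0),
    State("M1", "M1", "open", "closed", 0),
    State("M1*", "M1", "open", "closed", 1),
    State("M", "M", "open", "open", 0),
    State("M*", "M", "open", "open", 1),
    State("M2*", "M2", "closed", "open", 1),
    State("M2**", "M2", "closed", "open", 2),
    State("M**", "M", "open", "open", 2),
    State("M1**", "M1", "open", "closed", 2),
    State("M3**", "M3", "closed", "closed", 2),
)


@dataclass(frozen=True)
class StateSpace:
    """Ordered conformational/ligation states with group annotations."""

    states: tuple[State, ...] = _STATES

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def emission_groups(self) -> list[str]:
        return [s.emission_group for s in self.states]

    def group_index(self, groups: Iterable[str] = EMISSION_GROUPS) -> np.ndarray:
        """Per-state index into the ordered emission-group list."""
        order = list(groups)
        return np.array([order.index(s.emission_group) for s in self.states])

    @property
    def lid_closed(self) -> np.ndarray:
        """Boolean mask of the LID-closed group {M2*, M2**, M3**}."""
        return np.array([s.lid_status == "closed" for s in self.states])

    @property
    def nmp_closed(self) -> np.ndarray:
        return np.array([s.nmp_status == "closed" for s in self.states])


@dataclass
class RateVector:
    """Elementary transition rates of the kinetic scheme.

    Units: s^-1, except k1/k2 which are bimolecular (s^-1 mM^-1).  r2/r_m2 are
    part of the declared rate vector but do not appear in the generator; they
    are carried for completeness and never fitted.
    """

    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    c_m1: float = 0.0
    c_m2: float = 0.0
    c_m3: float = 0.0
    c_m4: float = 0.0
    k1: float = 0.0
    k_m1: float = 0.0
    k2: float = 0.0
    k_m2: float = 0.0
    b1: float = 0.0
    b_m1: float = 0.0
    b2: float = 0.0
    b_m2: float = 0.0
    r1: float = 0.0
    r_m1: float = 0.0
    r2: float = 0.0  # declared but unused (absent from the generator)
    r_m2: float = 0.0  # declared but unused
    r3: float = 0.0
    r_m3: float = 0.0
    r4: float = 0.0
    r_m4: float = 0.0

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "RateVector":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RateVector":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class LigandConcentrations:
    """Ligand concentrations in mM.  Mg2+ presence is metadata only."""

    atp_mM: float = 0.0
    amp_mM: float = 0.0
    adp_mM: float = 0.0
    mg_present: bool = True

    def __post_init__(self) -> None:
        for name in ("atp_mM", "amp_mM", "adp_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def ligands_for(self, variant: "ModelVariant") -> tuple[float, float]:
        """(first-ligand, second-ligand) concentrations for a model variant."""
        if variant.variant_id == "ADP":
            return self.adp_mM, self.adp_mM
        return self.atp_mM, self.amp_mM

    def to_dict(self) -> dict:
        return {
            "atp_mM": self.atp_mM,
            "amp_mM": self.amp_mM,
            "adp_mM": self.adp_mM,
            "mg_present": self.mg_present,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LigandConcentrations":
        return cls(**d)


@dataclass(frozen=True)
class ModelVariant:
    """Structural rule set selecting which transitions exist / rates are tied."""

    variant_id: str

    def __post_init__(self) -> None:
        if self.variant_id not in VARIANT_IDS:
            raise ValueError(
                f"unknown variant {self.variant_id!r}; expected one of {VARIANT_IDS}"
            )

    @property
    def has_mstar_mdblstar(self) -> bool:
        """Whether the direct M* <-> M** transition exists (only in V2)."""
        return self.variant_id == "V2"

    @property
    def tied(self) -> dict[str, str]:
        """Mapping tied-parameter -> source parameter."""
        if self.variant_id == "V1":
            return {"r3": "r1", "r_m3": "r_m1"}
        return {}


# Base transition table of the full (V3) topology: (from, to, rate name,
# ligand multiplier: 0 none, 1 first ligand, 2 second ligand).
_BASE_TRANSITIONS: tuple[tuple[str, str, str, int], ...] = (
    ("M0", "M1", "c1", 0),
    ("M0", "M1*", "c2", 0),
    ("M0", "M", "c3", 0),
    ("M0", "M*", "c4", 0),
    ("M1", "M0", "c_m1", 0),
    ("M1", "M1*", "k1", 1),
    ("M1", "M", "b_m1", 0),
    ("M1*", "M0", "c_m2", 0),
    ("M1*", "M1", "k_m1", 0),
    ("M1*", "M*", "b_m1", 0),
    ("M", "M0", "c_m3", 0),
    ("M", "M1", "b1", 0),
    ("M", "M*", "k1", 1),
    ("M*", "M0", "c_m4", 0),
    ("M*", "M1*", "b1", 0),
    ("M*", "M", "k_m1", 0),
    ("M*", "M2*", "r1", 0),
    ("M2*", "M*", "r_m1", 0),
    ("M2*", "M2**", "k2", 2),
    ("M2**", "M2*", "k_m2", 0),
    ("M2**", "M**", "r_m3", 0),
    ("M2**", "M1**", "r_m4", 0),
    ("M2**", "M3**", "b2", 0),
    ("M**", "M2**", "r3", 0),
    ("M1**", "M2**", "r4", 0),
    ("M3**", "M2**", "b_m2", 0),
)

# V2 restores second-ligand exchange on the LID-open side, re-using k2/k_m2.
_V2_EXTRA: tuple[tuple[str, str, str, int], ...] = (
    ("M*", "M**", "k2", 2),
    ("M**", "M*", "k_m2", 0),
)


def transition_table(variant: ModelVariant) -> tuple[tuple[str, str, str, int], ...]:
    """All (from, to, rate, ligand-index) transitions present in a variant."""
    if variant.has_mstar_mdblstar:
        return _BASE_TRANSITIONS + _V2_EXTRA
    return _BASE_TRANSITIONS


def build_state_space(variant: ModelVariant | str) -> StateSpace:
    """State roster for a model variant (identical for all four variants)."""
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    return StateSpace()


def apply_variant(rates: RateVector, variant: ModelVariant) -> RateVector:
    """Overwrite tied parameters per the variant's rule set (V3/V2/ADP: identity)."""
    ties = variant.tied
    if not ties:
        return replace(rates)
    return replace(rates, **{t: getattr(rates, src) for t, src in ties.items()})


_FREE_ORDER = (
    "c1", "c2", "c3", "c4", "c_m1", "c_m2", "c_m3", "c_m4",
    "k1", "k_m1", "k2", "k_m2",
    "b1", "b_m1", "b2", "b_m2",
    "r1", "r_m1", "r3", "r_m3", "r4", "r_m4",
)


def free_parameters(variant: ModelVariant) -> list[str]:
    """Ordered free rate parameters of a variant (ties excluded)."""
    tied = set(variant.tied)
    return [p for p in _FREE_ORDER if p not in tied]


@dataclass
class GeneratorMatrix:
    """CTMC generator (Q-matrix, s^-1) at fixed ligand concentrations."""

    Q: np.ndarray
    state_space: StateSpace
    conc: LigandConcentrations
    variant: ModelVariant

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("generator must be square")
        self.Q = Q


def build_generator(
    rates: RateVector,
    conc: LigandConcentrations,
    variant: ModelVariant,
) -> GeneratorMatrix:
    """Assemble the concentration-dependent generator for a model variant.

    Off-diagonal entries are elementary rates, bimolecular ones scaled by the
    relevant ligand concentration; diagonals are negative row sums.
    """
    space = build_state_space(variant)
    rates = apply_variant(rates, variant)
    lig1, lig2 = conc.ligands_for(variant)
    mult = {0: 1.0, 1: lig1, 2: lig2}
    idx = {name: i for i, name in enumerate(space.names)}
    Q = np.zeros((space.n, space.n))
    for src, dst, rname, lig in transition_table(variant):
        val = getattr(rates, rname) * mult[lig]
        if val < 0:
            raise ValueError(f"rate {rname} gives negative entry {src}->{dst}")
        Q[idx[src], idx[dst]] = val
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GeneratorMatrix(Q, space, conc, variant)
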