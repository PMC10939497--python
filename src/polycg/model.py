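"""Core data structures shared across the package.

Internally all coordinates are in nm, charges in elementary charge e,
energies in kJ/mol. Beads sit at the alpha-carbon position, one per residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

AROMATIC_RESIDUES = frozenset("FYW")

#: Side-chain charge at pH 7.4. Histidine is treated as neutral; override by
#: passing a custom charge table to ``assign_bead_properties``.
DEFAULT_CHARGE_TABLE = {
    "D": -1.0,
    "E": -1.0,
    "K": +1.0,
    "R": +1.0,
}

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Consecutive-residue bead spacing used for disordered chains (nm).
BACKBONE_SPACING = 0.38


class ModelError(ValueError):
    """Raised on invalid model construction input."""


@dataclass
class CGModel:
    """One-bead-per-residue model of a single molecule.

    A molecule may contain several covalently independent chains (e.g. the
    two monomers of a homodimer) that are treated as one rigid-network unit;
    ``chain_ids`` records which chain each bead belongs to.
    """

    residue_names: np.ndarray  # (n,) unicode, one-letter codes
    positions: np.ndarray  # (n, 3) float, nm
    charges: np.ndarray | None = None  # (n,) float, e
    hydro_strengths: np.ndarray | None = None  # (n,) float in [0, 1]
    aromatic_flags: np.ndarray | None = None  # (n,) bool
    disorder_mask: np.ndarray | None = None  # (n,) bool, True = disordered
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    bond_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    chain_ids: np.ndarray | None = None  # (n,) unicode
    name: str = ""
    #: (chain_id, residue_number) pairs present in the source structure's
    #: numbering but absent from the coordinates (chain breaks).
    unresolved: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.n_beads
        if self.chain_ids is None:
            self.chain_ids = np.full(n, "A", dtype="U8")
        else:
            self.chain_ids = np.asarray(self.chain_ids, dtype="U8")
        if self.disorder_mask is None:
            self.disorder_mask = np.zeros(n, dtype=bool)
        else:
            self.disorder_mask = np.asarray(self.disorder_mask, dtype=bool)
        for attr in ("charges", "hydro_strengths"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))
        if self.aromatic_flags is not None:
            self.aromatic_flags = np.asarray(self.aromatic_flags, dtype=bool)
        self.bonds = np.asarray(self.bonds, dtype=np.intp).reshape(-1, 2)
        self.bond_lengths = np.asarray(self.bond_lengths, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.residue_names)

    @property
    def sequence(self) -> str:
        return "".join(self.residue_names)

    @property
    def net_charge(self) -> float:
        if self.charges is None:
            raise ModelError("bead charges not assigned yet")
        return float(self.charges.sum())

    @property
    def ncpr(self) -> float:
        """Net charge per residue (e)."""
        return self.net_charge / self.n_beads

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n_beads
        if self.positions.shape != (n, 3):
            raise ModelError(
                f"positions shape {self.positions.shape} does not match {n} beads"
            )
        for attr in ("charges", "hydro_strengths", "aromatic_flags"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ModelError(f"{attr} length {len(v)} != bead count {n}")
        if len(self.disorder_mask) != n or len(self.chain_ids) != n:
            raise ModelError("per-bead arrays must all have identical length")
        if self.charges is not None:
            bad = ~np.isin(self.charges, (-1.0, 0.0, 1.0))
            if bad.any():
                raise ModelError(f"charges must be in {{-1, 0, +1}} e; got {self.charges[bad]}")
        if len(self.bonds) != len(self.bond_lengths):
            raise ModelError("bonds and bond_lengths must have equal length")
        if len(self.bonds):
            if self.bonds.min() < 0 or self.bonds.max() >= n:
                raise ModelError("bond references an invalid bead index")
            if (self.bond_lengths <= 0).any() or (self.bond_lengths >= 1.4).any():
                raise ModelError("bond rest lengths must lie in (0, 1.4) nm")

    # ------------------------------------------------------------------
    def copy(self) -> "CGModel":
        return CGModel(
            residue_names=self.residue_names.copy(),
            positions=self.positions.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            hydro_strengths=None if self.hydro_strengths is None else self.hydro_strengths.copy(),
            aromatic_flags=None if self.aromatic_flags is None else self.aromatic_flags.copy(),
            disorder_mask=self.disorder_mask.copy(),
            bonds=self.bonds.copy(),
            bond_lengths=self.bond_lengths.copy(),
            chain_ids=self.chain_ids.copy(),
            name=self.name,
            unresolved=list(self.unresolved),
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "name": self.name,
            "residue_names": self.residue_names.tolist(),
            "positions": self.positions.tolist(),
            "charges": arr(self.charges),
            "hydro_strengths": arr(self.hydro_strengths),
            "aromatic_flags": arr(self.aromatic_flags),
            "disorder_mask": self.disorder_mask.tolist(),
            "bonds": self.bonds.tolist(),
            "bond_lengths": self.bond_lengths.tolist(),
            "chain_ids": self.chain_ids.tolist(),
            "unresolved": [list(u) for u in self.unresolved],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CGModel":
        return cls(
            residue_names=np.asarray(d["residue_names"]),
            positions=np.asarray(d["positions"], dtype=float),
            charges=None if d.get("charges") is None else np.asarray(d["charges"], dtype=float),
            hydro_strengths=(
                None
                if d.get("hydro_strengths") is None
                else np.asarray(d["hydro_strengths"], dtype=float)
            ),
            aromatic_flags=(
                None
                if d.get("aromatic_flags") is None
                else np.asarray(d["aromatic_flags"], dtype=bool)
            ),
            disorder_mask=np.asarray(d["disorder_mask"], dtype=bool),
            bonds=np.asarray(d["bonds"], dtype=np.intp).reshape(-1, 2),
            bond_lengths=np.asarray(d["bond_lengths"], dtype=float),
            chain_ids=np.asarray(d["chain_ids"]),
            name=d.get("name", ""),
            unresolved=[tuple(u) for u in d.get("unresolved", [])],
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CGModel":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                d = json.loads(s)
            else:
                with open(s) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class Descriptors:
    """Static/ensemble sequence-structure descriptors of one molecule."""

    ncpr: float  # e per residue
    dipole_M: float  # e.nm, time-averaged
    rg: float  # nm, time-averaged
    sequence_length: int
    from_single_conformation: bool = False

    def __post_init__(self) -> None:
        if abs(self.ncpr) > 1.0:
            raise ModelError("|NCPR| cannot exceed 1 e per residue")
        if self.rg <= 0:
            raise ModelError("radius of gyration must be positive")
        if self.dipole_M < 0:
            raise ModelError("dipole magnitude cannot be negative")
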