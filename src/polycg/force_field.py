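"""Interaction potentials, pair classification, and energy/force evaluation.

Every nonbonded pair belongs to exactly one class:

* ``HP`` — hydrophobic/hydrophilic 8–6 potential with geometric-mean mixing,
  plus screened electrostatics (disordered-chain pairs, intra-polyPR pairs).
* ``CATION_PI`` — 8–6 Lennard-Jones between a cationic bead (R/K) on the
  peptide and an aromatic bead (F/Y/W) on the folded partner, plus
  electrostatics.
* ``EXCLUDED`` — the HP form with the cross epsilon pinned at the repulsive
  value (vanishes at r = sigma), plus electrostatics; applies to all other
  peptide/partner pairs.
* ``NONE`` — no nonbonded term (structured pairs of one molecule, whose
  geometry is maintained by the elastic network).

Bonded pairs (``NETWORK`` for the elastic network, ``BACKBONE`` for
consecutive disordered beads) use a stiff harmonic potential and are excluded
from all nonbonded sums.

Units: nm, kJ/mol, elementary charge e, ps; masses in g/mol so that
kJ/mol = (g/mol)·nm²/ps² holds without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType

import numpy as np

from .model import CGModel

KB = 0.00831446261815324  # kJ/mol/K
#: 1/(4 pi eps0) in kJ·nm/(mol·e²), to 9 significant figures.
COULOMB_PREFACTOR = 138.935458

_EPS_CP_DEFAULT = MappingProxyType(
    {"RF": 4.30, "RY": 5.0, "RW": 6.7, "KF": 1.79, "KY": 3.13, "KW": 4.26}
)

_KAPPA_BY_SALT = {100.0: 1.0, 200.0: 1.5}  # mM -> nm^-1

NB_NONE, NB_HP, NB_CATION_PI, NB_EXCLUDED = 0, 1, 2, 3
_NB_NAMES = {NB_NONE: "NONE", NB_HP: "HP", NB_CATION_PI: "CATION_PI", NB_EXCLUDED: "EXCLUDED"}


class ForceFieldError(ValueError):
    pass


def kappa_for_salt(salt_mM: float) -> float:
    """Debye screening coefficient (nm⁻¹) for the supported salt conditions."""
    try:
        return _KAPPA_BY_SALT[float(salt_mM)]
    except KeyError:
        raise ForceFieldError(
            f"unsupported salt concentration {salt_mM} mM; supported: 100, 200"
        ) from None


@dataclass(frozen=True)
class ForceFieldParams:
    eps_hp: float = 13.0  # kJ/mol
    eps_rep: float = 10.0  # kJ/mol
    sigma: float = 0.6  # nm
    mixing_exponent: float = 0.27
    dielectric_s: float = 80.0  # bulk solvent dielectric
    dielectric_z: float = 0.25  # nm
    kappa: float = 1.0  # nm^-1 (100 mM monovalent salt)
    k_network: float = 8000.0  # kJ/mol/nm^2
    k_backbone: float = 8000.0  # kJ/mol/nm^2, disordered-chain stand-in
    rm_cp: float = 0.45  # nm
    eps_cp: MappingProxyType = field(default_factory=lambda: _EPS_CP_DEFAULT)
    eps_excl: float = 10.0  # kJ/mol cross excluded-volume eps_ij
    coulomb: float = COULOMB_PREFACTOR
    cutoff: float | None = 2.5  # nm; None disables truncation

    def __post_init__(self):
        if self.kappa <= 0 or self.sigma <= 0 or self.rm_cp <= 0:
            raise ForceFieldError("kappa, sigma and rm_cp must be positive")
        if min(self.eps_hp, self.eps_rep, self.eps_excl) < 0:
            raise ForceFieldError("energy parameters must be non-negative")
        if set(self.eps_cp) != set(_EPS_CP_DEFAULT):
            raise ForceFieldError(
                "eps_cp must cover exactly the six cation-aromatic pairs"
            )

    def with_salt(self, salt_mM: float) -> "ForceFieldParams":
        return replace(self, kappa=kappa_for_salt(salt_mM))


def paper_2024() -> ForceFieldParams:
    """The published parameter preset (all defaults, 100 mM salt)."""
    return ForceFieldParams()


# ----------------------------------------------------------------------
# scalar/vector potentials; each *_d variant also returns dphi/dr
# ----------------------------------------------------------------------
def mix_eps(eps_i, eps_j, params: ForceFieldParams | None = None):
    """Cross-interaction strength eps_ij = eps_hp (eps_i eps_j)^0.27."""
    p = params or ForceFieldParams()
    return p.eps_hp * (np.asarray(eps_i) * np.asarray(eps_j)) ** p.mixing_exponent


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ForceFieldError("inter-bead distance must be positive")
    return r


def phi_hp(r, eps_i=None, eps_j=None, *, eps_ij=None, params=None):
    """Two-branch 8–6 hydrophobic/hydrophilic potential (kJ/mol).

    Either pass per-bead strengths (mixed internally) or ``eps_ij`` directly;
    ``eps_ij = eps_rep`` gives the pure excluded-volume variant.
    """
    return _phi_hp_d(r, eps_i, eps_j, eps_ij=eps_ij, params=params)[0]


def _phi_hp_d(r, eps_i=None, eps_j=None, *, eps_ij=None, params=None):
    p = params or ForceFieldParams()
    r = _check_r(r)
    if eps_ij is None:
        if eps_i is None or eps_j is None:
            raise ForceFieldError("provide eps_i/eps_j or eps_ij")
        eps_ij = mix_eps(eps_i, eps_j, p)
    eps_ij = np.asarray(eps_ij, dtype=float)
    s6 = (p.sigma / r) ** 6
    s8 = s6 * (p.sigma / r) ** 2
    inner = p.eps_rep * s8 - eps_ij * (4.0 / 3.0 * s6 - 1.0 / 3.0)
    outer = (p.eps_rep - eps_ij) * s8
    d_inner = (-8.0 * p.eps_rep * s8 + 8.0 * eps_ij * s6) / r
    d_outer = -8.0 * (p.eps_rep - eps_ij) * s8 / r
    lo = r <= p.sigma
    return np.where(lo, inner, outer), np.where(lo, d_inner, d_outer)


def dielectric(r, params=None):
    """Distance-dependent solvent dielectric; → 0 as r → 0, → Ss as r → ∞."""
    return _dielectric_d(r, params)[0]


def _dielectric_d(r, params=None):
    p = params or ForceFieldParams()
    r = np.asarray(r, dtype=float)
    x = r / (2.0 * p.dielectric_z)
    # (x/sinh x)^2 and its derivative, with a series branch to avoid 0/0
    small = x < 1.0e-4
    xs = np.where(small, 1.0, x)  # dummy to silence overflow-free eval
    s = np.sinh(xs)
    c = np.cosh(xs)
    g = np.where(small, 1.0 - x**2 / 3.0 + x**4 / 15.0, (xs / s) ** 2)
    dg_dx = np.where(small, -2.0 * x / 3.0 + 4.0 * x**3 / 15.0, 2.0 * xs * (s - xs * c) / s**3)
    eps = p.dielectric_s * (1.0 - g)
    deps_dr = -p.dielectric_s * dg_dx / (2.0 * p.dielectric_z)
    return eps, deps_dr


def phi_elec(r, qi, qj, kappa=None, params=None):
    """Screened Coulomb energy with distance-dependent dielectric (kJ/mol)."""
    return _phi_elec_d(r, np.asarray(qi) * np.asarray(qj), kappa, params)[0]


def _phi_elec_d(r, qq, kappa=None, params=None):
    p = params or ForceFieldParams()
    r = _check_r(r)
    k = p.kappa if kappa is None else float(kappa)
    qq = np.asarray(qq, dtype=float)
    eps, deps = _dielectric_d(r, p)
    phi = p.coulomb * qq * np.exp(-k * r) / (eps * r)
    dphi = phi * (-k - 1.0 / r - deps / eps)
    zero = qq == 0.0
    return np.where(zero, 0.0, phi), np.where(zero, 0.0, dphi)


def phi_cp(r, pair_key=None, *, eps_cp=None, params=None):
    """8–6 cation–pi potential; minimum −eps_cp at exactly r = rm (kJ/mol)."""
    return _phi_cp_d(r, pair_key, eps_cp=eps_cp, params=params)[0]


def _phi_cp_d(r, pair_key=None, *, eps_cp=None, params=None):
    p = params or ForceFieldParams()
    r = _check_r(r)
    if eps_cp is None:
        if pair_key not in p.eps_cp:
            raise ForceFieldError(
                f"unknown cation-pi pair {pair_key!r}; expected one of {sorted(p.eps_cp)}"
            )
        eps_cp = p.eps_cp[pair_key]
    eps_cp = np.asarray(eps_cp, dtype=float)
    u6 = (p.rm_cp / r) ** 6
    u8 = u6 * (p.rm_cp / r) ** 2
    phi = eps_cp * (3.0 * u8 - 4.0 * u6)
    dphi = eps_cp * 24.0 * (u6 - u8) / r
    return phi, dphi


def phi_network(r, b, params=None):
    """Stiff harmonic tether K (r − b)² (kJ/mol)."""
    p = params or ForceFieldParams()
    r = np.asarray(r, dtype=float)
    if (np.asarray(b) <= 0).any():
        raise ForceFieldError("rest length must be positive")
    return p.k_network * (r - b) ** 2


# ----------------------------------------------------------------------
# system assembly and pair classification
# ----------------------------------------------------------------------
def infer_role(model: CGModel) -> str:
    """'polypr' if the molecule is a fully disordered P/R-only chain."""
    if model.disorder_mask.all() and set(model.sequence) <= {"P", "R"}:
        return "polypr"
    return "component"


@dataclass(frozen=True)
class PairRule:
    bonded: str | None  # NETWORK | BACKBONE | None
    nonbonded: str | None  # HP | CATION_PI | EXCLUDED | NONE; None if bonded


class System:
    """Concatenation of one or more molecules with per-bead metadata."""

    def __init__(self, models, roles=None):
        if isinstance(models, CGModel):
            models = [models]
        self.models = list(models)
        for m in self.models:
            if m.charges is None or m.hydro_strengths is None:
                raise ForceFieldError(
                    f"model {m.name!r} lacks bead properties; run assign_bead_properties"
                )
        if roles is None:
            roles = [infer_role(m) for m in self.models]
        if len(roles) != len(self.models):
            raise ForceFieldError("one role per model required")
        self.roles = list(roles)
        sizes = [m.n_beads for m in self.models]
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.n_beads = int(self.offsets[-1])
        self.molecule_index = np.repeat(np.arange(len(self.models)), sizes)
        self.charges = np.concatenate([m.charges for m in self.models])
        self.hydro = np.concatenate([m.hydro_strengths for m in self.models])
        self.aromatic = np.concatenate([m.aromatic_flags for m in self.models])
        self.disordered = np.concatenate([m.disorder_mask for m in self.models])
        self.residue_names = np.concatenate([m.residue_names for m in self.models])
        self.positions = np.concatenate([m.positions for m in self.models])
        self._build_bonds()

    def _build_bonds(self):
        from .model_builder import backbone_bonds

        bi, bj, bb, bk = [], [], [], []
        kinds = []
        for m, off in zip(self.models, self.offsets):
            if len(m.bonds):
                bi.append(m.bonds[:, 0] + off)
                bj.append(m.bonds[:, 1] + off)
                bb.append(m.bond_lengths)
                kinds += ["NETWORK"] * len(m.bonds)
            pairs, lengths = backbone_bonds(m)
            if len(pairs):
                # skip duplicates already present as network bonds
                existing = set()
                if len(m.bonds):
                    existing = {tuple(sorted(p)) for p in m.bonds.tolist()}
                keep = [
                    t for t, p in enumerate(pairs.tolist())
                    if tuple(sorted(p)) not in existing
                ]
                if keep:
                    pairs, lengths = pairs[keep], lengths[keep]
                    bi.append(pairs[:, 0] + off)
                    bj.append(pairs[:, 1] + off)
                    bb.append(lengths)
                    kinds += ["BACKBONE"] * len(pairs)
        if bi:
            self.bond_i = np.concatenate(bi).astype(np.intp)
            self.bond_j = np.concatenate(bj).astype(np.intp)
            self.bond_b = np.concatenate(bb).astype(float)
            self.bond_kind = np.asarray(kinds)
        else:
            self.bond_i = np.empty(0, dtype=np.intp)
            self.bond_j = np.empty(0, dtype=np.intp)
            self.bond_b = np.empty(0)
            self.bond_kind = np.empty(0, dtype="U8")
        self._bonded_lookup = {
            (int(min(i, j)), int(max(i, j))): k
            for i, j, k in zip(self.bond_i, self.bond_j, self.bond_kind)
        }


_CATION_RESIDUES = frozenset("RK")


def classify_pair(system: System, i: int, j: int) -> PairRule:
    """Deterministic, symmetric interaction class for one bead pair."""
    if not (0 <= i < system.n_beads and 0 <= j < system.n_beads) or i == j:
        raise ForceFieldError(f"invalid bead pair ({i}, {j})")
    key = (min(i, j), max(i, j))
    bonded = system._bonded_lookup.get(key)
    if bonded is not None:
        return PairRule(bonded=bonded, nonbonded=None)
    mi, mj = system.molecule_index[i], system.molecule_index[j]
    if mi == mj:
        if not system.disordered[i] and not system.disordered[j]:
            # structure held by the elastic network; no nonbonded term
            return PairRule(bonded=None, nonbonded="NONE")
        return PairRule(bonded=None, nonbonded="HP")
    ri, rj = system.roles[mi], system.roles[mj]
    if {ri, rj} == {"polypr", "component"}:
        pep, comp = (i, j) if ri == "polypr" else (j, i)
        if (
            system.residue_names[pep] in _CATION_RESIDUES
            and system.aromatic[comp]
        ):
            return PairRule(bonded=None, nonbonded="CATION_PI")
        return PairRule(bonded=None, nonbonded="EXCLUDED")
    if ri == rj == "polypr":
        return PairRule(bonded=None, nonbonded="HP")
    # component-component cross terms: plain excluded volume + electrostatics
    return PairRule(bonded=None, nonbonded="EXCLUDED")


# ----------------------------------------------------------------------
# evaluator
# ----------------------------------------------------------------------
def _min_image(dx, box):
    if box is not None:
        dx -= box * np.round(dx / box)
    return dx


class EnergyEvaluator:
    """Precomputes the pair table of a System for fast energy/force calls.

    Nonbonded potentials are shifted so that each term is zero at the cutoff
    (energies stay continuous under truncation); forces are the exact
    analytic negative gradient of the shifted energy.
    """

    def __init__(self, system: System, params: ForceFieldParams | None = None,
                 backend: str = "numba"):
        self.system = system
        self.params = params or ForceFieldParams()
        if backend == "numba":
            try:
                from . import _kernels  # noqa: F401
            except ImportError:  # pragma: no cover
                backend = "numpy"
        if backend not in ("numba", "numpy"):
            raise ForceFieldError(f"unknown backend {backend!r}")
        self.backend = backend
        self._build_pair_table()

    def _build_pair_table(self):
        sys_, p = self.system, self.params
        n = sys_.n_beads
        ii, jj = np.triu_indices(n, k=1)
        cls = np.full(len(ii), NB_NONE, dtype=np.int8)

        same_mol = sys_.molecule_index[ii] == sys_.molecule_index[jj]
        both_struct = ~sys_.disordered[ii] & ~sys_.disordered[jj]
        cls[same_mol & ~both_struct] = NB_HP

        roles = np.asarray(sys_.roles)
        role_i = roles[sys_.molecule_index[ii]]
        role_j = roles[sys_.molecule_index[jj]]
        cross_pc = ~same_mol & (role_i != role_j)
        pep_is_i = role_i == "polypr"
        pep = np.where(pep_is_i, ii, jj)
        comp = np.where(pep_is_i, jj, ii)
        cation = np.isin(sys_.residue_names, list(_CATION_RESIDUES))
        is_cp = cross_pc & cation[pep] & sys_.aromatic[comp]
        cls[cross_pc] = NB_EXCLUDED
        cls[is_cp] = NB_CATION_PI
        cross_pp = ~same_mol & (role_i == "polypr") & (role_j == "polypr")
        cls[cross_pp] = NB_HP
        cross_cc = ~same_mol & (role_i == "component") & (role_j == "component")
        cls[cross_cc] = NB_EXCLUDED

        # bonded pairs are excluded from the nonbonded table
        if len(sys_.bond_i):
            flat = np.minimum(sys_.bond_i, sys_.bond_j) * n + np.maximum(
                sys_.bond_i, sys_.bond_j
            )
            cls[np.isin(ii * n + jj, flat)] = NB_NONE

        keep = cls != NB_NONE
        self.nb_i = ii[keep]
        self.nb_j = jj[keep]
        self.nb_cls = cls[keep]
        qq = sys_.charges[self.nb_i] * sys_.charges[self.nb_j]
        self.nb_qq = qq
        eps_ij = np.where(
            self.nb_cls == NB_HP,
            mix_eps(sys_.hydro[self.nb_i], sys_.hydro[self.nb_j], p),
            p.eps_excl,
        )
        self.nb_eps_ij = eps_ij
        names = sys_.residue_names
        cp_keys = np.char.add(
            np.where(np.isin(names[self.nb_i], list(_CATION_RESIDUES)), names[self.nb_i], names[self.nb_j]),
            np.where(np.isin(names[self.nb_i], list(_CATION_RESIDUES)), names[self.nb_j], names[self.nb_i]),
        )
        self.nb_eps_cp = np.where(
            self.nb_cls == NB_CATION_PI,
            [p.eps_cp.get(k, 0.0) for k in cp_keys],
            0.0,
        ).astype(float)

        # energy shifts at the cutoff, per pair
        rc = p.cutoff
        if rc is not None:
            shift = np.zeros(len(self.nb_i))
            m86 = (self.nb_cls == NB_HP) | (self.nb_cls == NB_EXCLUDED)
            shift[m86] = _phi_hp_d(rc, eps_ij=eps_ij[m86], params=p)[0]
            mcp = self.nb_cls == NB_CATION_PI
            shift[mcp] = _phi_cp_d(rc, eps_cp=self.nb_eps_cp[mcp], params=p)[0]
            shift += _phi_elec_d(rc, qq, params=p)[0]
            self.nb_shift = shift
        else:
            self.nb_shift = np.zeros(len(self.nb_i))

        self._m86 = (self.nb_cls == NB_HP) | (self.nb_cls == NB_EXCLUDED)
        self._mcp = self.nb_cls == NB_CATION_PI
        self._mq = self.nb_qq != 0.0
        self._bond_k = np.where(
            self.system.bond_kind == "NETWORK", p.k_network, p.k_backbone
        ).astype(float)

    def energy_forces(self, positions, box=None, backend=None):
        """Total potential energy (kJ/mol) and per-bead forces (kJ/mol/nm)."""
        backend = backend or self.backend
        if backend == "numba":
            return self._energy_forces_numba(positions, box)
        return self._energy_forces_numpy(positions, box)

    def _energy_forces_numba(self, positions, box=None):
        from . import _kernels

        sys_, p = self.system, self.params
        pos = np.ascontiguousarray(positions, dtype=float)
        if not np.isfinite(pos).all():
            raise ForceFieldError("non-finite coordinates")
        forces = np.zeros_like(pos)
        box_val = -1.0 if box is None else float(box)
        energy = 0.0
        if len(sys_.bond_i):
            e_b, overlap = _kernels.bonded_kernel(
                pos, box_val, sys_.bond_i, sys_.bond_j, sys_.bond_b,
                self._bond_k, forces,
            )
            if overlap >= 0:
                raise ForceFieldError(
                    f"overlapping bonded beads {int(sys_.bond_i[overlap])} "
                    f"and {int(sys_.bond_j[overlap])}"
                )
            energy += e_b
        if len(self.nb_i):
            rc2 = -1.0 if p.cutoff is None else p.cutoff**2
            e_nb, overlap = _kernels.nonbonded_kernel(
                pos, box_val, self.nb_i, self.nb_j, self.nb_cls,
                self.nb_eps_ij, self.nb_eps_cp, self.nb_qq, self.nb_shift,
                p.sigma, p.eps_rep, p.rm_cp, p.coulomb, p.kappa,
                p.dielectric_s, p.dielectric_z, rc2, forces,
            )
            if overlap >= 0:
                raise ForceFieldError(
                    f"overlapping beads {int(self.nb_i[overlap])} "
                    f"and {int(self.nb_j[overlap])}"
                )
            energy += e_nb
        return float(energy), forces

    def _energy_forces_numpy(self, positions, box=None):
        sys_, p = self.system, self.params
        pos = np.asarray(positions, dtype=float)
        if not np.isfinite(pos).all():
            raise ForceFieldError("non-finite coordinates")
        n = sys_.n_beads
        energy = 0.0
        forces = np.zeros_like(pos)

        def accumulate(i_idx, j_idx, dx, r, dphi):
            # force on i is -dphi/dr * (dx/r)
            fvec = (-dphi / r)[:, None] * dx
            for d in range(3):
                forces[:, d] += np.bincount(i_idx, weights=fvec[:, d], minlength=n)
                forces[:, d] -= np.bincount(j_idx, weights=fvec[:, d], minlength=n)

        # bonded
        if len(sys_.bond_i):
            dx = _min_image(pos[sys_.bond_i] - pos[sys_.bond_j], box)
            r = np.linalg.norm(dx, axis=1)
            if (r < 1e-6).any():
                k = int(np.flatnonzero(r < 1e-6)[0])
                raise ForceFieldError(
                    f"overlapping bonded beads {int(sys_.bond_i[k])} "
                    f"and {int(sys_.bond_j[k])}"
                )
            k = np.where(sys_.bond_kind == "NETWORK", p.k_network, p.k_backbone)
            energy += float((k * (r - sys_.bond_b) ** 2).sum())
            accumulate(sys_.bond_i, sys_.bond_j, dx, r, 2.0 * k * (r - sys_.bond_b))

        # nonbonded
        if len(self.nb_i):
            dx = _min_image(pos[self.nb_i] - pos[self.nb_j], box)
            r2 = (dx**2).sum(axis=1)
            tiny = r2 < 1e-12
            if tiny.any():
                k = int(np.flatnonzero(tiny)[0])
                raise ForceFieldError(
                    f"overlapping beads {int(self.nb_i[k])} and {int(self.nb_j[k])}"
                )
            if p.cutoff is not None:
                within = r2 < p.cutoff**2
            else:
                within = np.ones(len(r2), dtype=bool)
            for mask, kind in ((self._m86 & within, "86"), (self._mcp & within, "cp")):
                if not mask.any():
                    continue
                sel = np.flatnonzero(mask)
                r = np.sqrt(r2[sel])
                if kind == "86":
                    e, de = _phi_hp_d(r, eps_ij=self.nb_eps_ij[sel], params=p)
                else:
                    e, de = _phi_cp_d(r, eps_cp=self.nb_eps_cp[sel], params=p)
                qsel = self._mq[sel]
                if qsel.any():
                    eq, deq = _phi_elec_d(r[qsel], self.nb_qq[sel[qsel]], params=p)
                    e[qsel] += eq
                    de[qsel] += deq
                energy += float(e.sum() - self.nb_shift[sel].sum())
                accumulate(self.nb_i[sel], self.nb_j[sel], dx[sel], r, de)
        return energy, forces


def total_energy_forces(models, positions=None, box=None, params=None, roles=None):
    """One-shot energy/forces for a set of models (convenience wrapper)."""
    system = models if isinstance(models, System) else System(models, roles)
    if positions is None:
        positions = system.positions
    return EnergyEvaluator(system, params).energy_forces(positions, box)
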