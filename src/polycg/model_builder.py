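"""Build one-bead-per-residue models from structures and sequences.

The pipeline is: :func:`parse_structure` (Cα extraction) →
:func:`place_unresolved` (grow beads for chain breaks) →
:func:`assign_bead_properties` (charges, hydrophobic strengths, aromatics) →
:func:`mark_disordered` → :func:`build_elastic_network`. Disordered chains
such as polyPR are built directly with :func:`build_polypr`.
"""

from __future__ import annotations

import io
from importlib import resources

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.sequence.io.fasta as fastaio
from biotite.sequence import ProteinSequence

from .model import (
    AMINO_ACIDS,
    AROMATIC_RESIDUES,
    BACKBONE_SPACING,
    DEFAULT_CHARGE_TABLE,
    CGModel,
    Descriptors,
    ModelError,
)

ANGSTROM_TO_NM = 0.1
PLDDT_DISORDER_THRESHOLD = 70.0
ELASTIC_NETWORK_CUTOFF = 1.4  # nm, strict upper bound on bonded pair distance


# ----------------------------------------------------------------------
# packaged data
# ----------------------------------------------------------------------
def load_hydropathy(path=None) -> dict[str, float]:
    """Load the per-residue hydrophobic strength table (residue -> eps_i)."""
    if path is None:
        text = resources.files("polycg.data").joinpath("hydropathy.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, value = line.split("\t")
        table[code] = float(value)
    return table


def load_fasta(source) -> dict[str, str]:
    """Read a FASTA file (path or text) into {header: sequence}."""
    if isinstance(source, str) and source.lstrip().startswith(">"):
        fasta = fastaio.FastaFile.read(io.StringIO(source))
    else:
        fasta = fastaio.FastaFile.read(str(source))
    return dict(fasta.items())


def ntf2_sequence() -> str:
    """Monomer sequence of human NTF2 shipped with the package."""
    path = resources.files("polycg.data").joinpath("ntf2_human.fasta")
    return next(iter(load_fasta(path.read_text()).values()))


# ----------------------------------------------------------------------
# structure parsing
# ----------------------------------------------------------------------
def parse_structure(pdb_text: str, chains=None, name: str = "") -> CGModel:
    """Extract a Cα bead model from PDB text (model 1, altloc "A" preferred).

    Residues missing from the coordinates (numbering gaps inside a chain)
    are recorded in ``model.unresolved`` as ``(chain_id, residue_number)``
    pairs for later placement; they get no bead here.

    Raises
    ------
    ModelError
        If no Cα atoms are found, if a resolved residue lacks a Cα atom, or
        if a residue code cannot be converted to a one-letter amino acid.
    """
    pdb_file = pdbio.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(model=1, altloc="first")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if chains is not None:
        atoms = atoms[np.isin(atoms.chain_id, list(chains))]
    if atoms.array_length() == 0:
        raise ModelError("no amino-acid atoms in the selected chains")

    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ModelError("input contains no C-alpha atoms")

    # a residue present in the coordinates but without a CA record is an error
    resolved = {
        (c, int(r)) for c, r in zip(atoms.chain_id, atoms.res_id)
    }
    with_ca = {(c, int(r)) for c, r in zip(ca.chain_id, ca.res_id)}
    missing_ca = sorted(resolved - with_ca)
    if missing_ca:
        raise ModelError(f"residues without a C-alpha atom: {missing_ca}")

    names, positions, chain_ids, res_nums = [], [], [], []
    seen = set()
    for i in range(ca.array_length()):
        key = (ca.chain_id[i], int(ca.res_id[i]))
        if key in seen:  # duplicate altlocs already filtered; guard anyway
            continue
        seen.add(key)
        three = ca.res_name[i]
        try:
            one = ProteinSequence.convert_letter_3to1(three)
        except KeyError as exc:
            raise ModelError(f"unknown residue code {three!r} at {key}") from exc
        if one not in AMINO_ACIDS:
            raise ModelError(f"non-standard residue code {three!r} at {key}")
        names.append(one)
        positions.append(ca.coord[i] * ANGSTROM_TO_NM)
        chain_ids.append(key[0])
        res_nums.append(key[1])

    unresolved = []
    chain_arr = np.asarray(chain_ids)
    num_arr = np.asarray(res_nums)
    for chain in dict.fromkeys(chain_ids):  # preserve order
        nums = np.sort(num_arr[chain_arr == chain])
        full = set(range(int(nums[0]), int(nums[-1]) + 1))
        for gap in sorted(full - set(int(x) for x in nums)):
            unresolved.append((chain, gap))

    model = CGModel(
        residue_names=np.asarray(names),
        positions=np.asarray(positions),
        chain_ids=chain_arr,
        name=name,
        unresolved=unresolved,
    )
    model.residue_numbers = num_arr  # numbering kept as metadata
    return model


def place_unresolved(model: CGModel, sequences: dict[str, str], seed: int = 0) -> CGModel:
    """Insert beads for unresolved residues by growing an ideal chain.

    ``sequences`` maps chain id to the full-length sequence with 1-based
    residue numbering. Interior gaps are interpolated between the flanking
    structured anchors; terminal gaps grow outward from the nearest anchor at
    0.38 nm spacing. Inserted beads are marked disordered and then relaxed by
    a few spacing-projection sweeps.
    """
    if not model.unresolved:
        return model.copy()
    rng = np.random.default_rng(seed)
    res_nums = getattr(model, "residue_numbers", None)
    if res_nums is None:
        raise ModelError("model lacks residue numbering metadata from parse_structure")

    records = []  # (chain, resnum, name, position, disordered)
    for i in range(model.n_beads):
        records.append(
            (model.chain_ids[i], int(res_nums[i]), model.residue_names[i],
             model.positions[i].copy(), bool(model.disorder_mask[i]))
        )
    centroid = model.positions.mean(axis=0)
    for chain, num in model.unresolved:
        seq = sequences.get(chain)
        if seq is None or num > len(seq):
            raise ModelError(f"no sequence entry for unresolved residue {(chain, num)}")
        records.append((chain, num, seq[num - 1], None, True))

    records.sort(key=lambda r: (r[0], r[1]))
    positions = [r[3] for r in records]

    # fill gaps chain by chain
    n = len(records)
    i = 0
    while i < n:
        if positions[i] is not None:
            i += 1
            continue
        j = i
        while j < n and positions[j] is None and records[j][0] == records[i][0]:
            j += 1
        prev_ok = i > 0 and records[i - 1][0] == records[i][0] and positions[i - 1] is not None
        next_ok = j < n and records[j][0] == records[i][0] and positions[j] is not None
        k = j - i
        if prev_ok and next_ok:
            a, b = positions[i - 1], positions[j]
            for m in range(k):
                t = (m + 1) / (k + 1)
                positions[i + m] = a + t * (b - a) + rng.normal(0, 0.05, 3)
        elif prev_ok or next_ok:
            anchor = positions[i - 1] if prev_ok else positions[j]
            direction = anchor - centroid
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            order = range(k) if prev_ok else range(k - 1, -1, -1)
            for step, m in enumerate(order, start=1):
                positions[i + m] = (
                    anchor + step * BACKBONE_SPACING * direction + rng.normal(0, 0.02, 3)
                )
        else:
            raise ModelError("cannot place a fully unresolved chain")
        i = j

    # relax inserted runs toward uniform backbone spacing
    pos = np.asarray(positions)
    inserted = np.asarray([r[3] is None for r in records])
    chains_arr = np.asarray([r[0] for r in records])
    for _ in range(30):
        for idx in np.flatnonzero(inserted):
            for nb in (idx - 1, idx + 1):
                if 0 <= nb < n and chains_arr[nb] == chains_arr[idx]:
                    d = pos[idx] - pos[nb]
                    r = np.linalg.norm(d)
                    if r > 1e-9:
                        pos[idx] -= 0.5 * (r - BACKBONE_SPACING) * d / r

    out = CGModel(
        residue_names=np.asarray([r[2] for r in records]),
        positions=pos,
        chain_ids=chains_arr,
        disorder_mask=np.asarray([r[4] for r in records]) | inserted,
        name=model.name,
        unresolved=[],
    )
    out.residue_numbers = np.asarray([r[1] for r in records])
    return out


def write_pdb(model: CGModel) -> str:
    """Serialize the bead model as PDB text (one CA atom per bead, Å)."""
    n = model.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = model.positions / ANGSTROM_TO_NM
    atoms.chain_id = model.chain_ids
    res_nums = getattr(model, "residue_numbers", None)
    if res_nums is None:
        res_nums = _default_numbering(model)
    atoms.res_id = np.asarray(res_nums, dtype=int)
    atoms.res_name = np.asarray(
        [ProteinSequence.convert_letter_1to3(c) for c in model.residue_names]
    )
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(atoms)
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


def _default_numbering(model: CGModel) -> np.ndarray:
    nums = np.empty(model.n_beads, dtype=int)
    for chain in np.unique(model.chain_ids):
        mask = model.chain_ids == chain
        nums[mask] = np.arange(1, mask.sum() + 1)
    return nums


# ----------------------------------------------------------------------
# property assignment
# ----------------------------------------------------------------------
def assign_bead_properties(
    model: CGModel,
    hydropathy_table: dict[str, float] | None = None,
    charge_table: dict[str, float] | None = None,
) -> CGModel:
    """Populate charges, hydrophobic strengths and aromatic flags.

    Charges follow the side-chain rule D/E → −1 e, K/R → +1 e, everything
    else (including histidine) 0 e; pass ``charge_table`` to override.
    """
    if hydropathy_table is None:
        hydropathy_table = load_hydropathy()
    if charge_table is None:
        charge_table = DEFAULT_CHARGE_TABLE
    missing = sorted({c for c in model.residue_names if c not in hydropathy_table})
    if missing:
        raise ModelError(f"residues missing from hydropathy table: {missing}")
    out = model.copy()
    out.charges = np.asarray([charge_table.get(c, 0.0) for c in model.residue_names])
    out.hydro_strengths = np.asarray([hydropathy_table[c] for c in model.residue_names])
    out.aromatic_flags = np.asarray([c in AROMATIC_RESIDUES for c in model.residue_names])
    out.validate()
    if hasattr(model, "residue_numbers"):
        out.residue_numbers = model.residue_numbers
    return out


def mark_disordered(
    model: CGModel,
    unresolved=(),
    confidence_scores=None,
    threshold: float = PLDDT_DISORDER_THRESHOLD,
) -> CGModel:
    """Set the disorder mask: unresolved beads or confidence < threshold.

    ``unresolved`` lists bead indices that were absent from the experimental
    coordinates; an unresolved bead is disordered regardless of its
    confidence score. ``confidence_scores``, when given, must cover every
    bead (e.g. per-residue pLDDT).
    """
    out = model.copy()
    mask = np.zeros(model.n_beads, dtype=bool)
    unresolved = np.asarray(list(unresolved), dtype=int)
    if unresolved.size:
        if unresolved.min() < 0 or unresolved.max() >= model.n_beads:
            raise ModelError("unresolved bead index out of range")
        mask[unresolved] = True
    if confidence_scores is not None:
        scores = np.asarray(confidence_scores, dtype=float)
        if len(scores) != model.n_beads:
            raise ModelError(
                f"confidence scores cover {len(scores)} residues, model has {model.n_beads}"
            )
        mask |= scores < threshold
    out.disorder_mask = out.disorder_mask | mask
    if hasattr(model, "residue_numbers"):
        out.residue_numbers = model.residue_numbers
    return out


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------
def build_elastic_network(model: CGModel, cutoff: float = ELASTIC_NETWORK_CUTOFF) -> CGModel:
    """Bond every pair of *structured* beads closer than ``cutoff`` (strict).

    Rest lengths are the reference-structure distances. Disordered beads get
    no network bonds; they are governed by the disordered-chain force field.
    Bonds may span chains of the same molecule (e.g. a homodimer interface).
    """
    structured = np.flatnonzero(~model.disorder_mask)
    pos = model.positions[structured]
    bonds, lengths = [], []
    if len(structured) > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        ii, jj = np.triu_indices(len(structured), k=1)
        keep = dist[ii, jj] < cutoff
        bonds = np.stack([structured[ii[keep]], structured[jj[keep]]], axis=1)
        lengths = dist[ii[keep], jj[keep]]
    out = model.copy()
    out.bonds = np.asarray(bonds, dtype=np.intp).reshape(-1, 2)
    out.bond_lengths = np.asarray(lengths, dtype=float)
    out.validate()
    if hasattr(model, "residue_numbers"):
        out.residue_numbers = model.residue_numbers
    return out


def backbone_bonds(model: CGModel) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive-bead bonds (at 0.38 nm rest length) for disordered runs.

    Returns pairs where at least one bead is disordered and both are
    consecutive within one chain, plus their rest lengths.
    """
    pairs, lengths = [], []
    for i in range(model.n_beads - 1):
        if model.chain_ids[i] != model.chain_ids[i + 1]:
            continue
        if model.disorder_mask[i] or model.disorder_mask[i + 1]:
            pairs.append((i, i + 1))
            lengths.append(BACKBONE_SPACING)
    return (
        np.asarray(pairs, dtype=np.intp).reshape(-1, 2),
        np.asarray(lengths, dtype=float),
    )


def build_polypr(n_repeats: int) -> CGModel:
    """Fully disordered (PR)ₙ chain: 2n beads alternating P, R, charge +n e."""
    if n_repeats < 1:
        raise ModelError("n_repeats must be >= 1")
    n = 2 * n_repeats
    names = np.asarray(["P", "R"] * n_repeats)
    # gentle helix-like backbone trace at 0.38 nm spacing as starting geometry
    t = np.arange(n)
    positions = np.stack(
        [0.30 * np.cos(1.8 * t), 0.30 * np.sin(1.8 * t), 0.23 * t], axis=1
    )
    # rescale consecutive spacing to exactly 0.38 nm
    deltas = np.diff(positions, axis=0)
    deltas *= BACKBONE_SPACING / np.linalg.norm(deltas, axis=1, keepdims=True)
    positions = np.vstack([np.zeros(3), np.cumsum(deltas, axis=0)])
    model = CGModel(
        residue_names=names,
        positions=positions,
        disorder_mask=np.ones(n, dtype=bool),
        name=f"PR{n_repeats}",
    )
    return assign_bead_properties(model)


def model_from_sequence(
    sequence: str, chain_ids: list[str] | None = None, name: str = ""
) -> CGModel:
    """Disordered extended-chain model from sequence(s), properties assigned.

    Pass one sequence per chain via repeated calls or a list of chain ids of
    the same length as ``sequence`` times chains; the homodimer convenience
    is ``model_from_sequence(seq * 2, ["A"] * len(seq) + ["B"] * len(seq))``.
    """
    n = len(sequence)
    positions = np.zeros((n, 3))
    positions[:, 2] = BACKBONE_SPACING * np.arange(n)
    model = CGModel(
        residue_names=np.asarray(list(sequence)),
        positions=positions,
        chain_ids=None if chain_ids is None else np.asarray(chain_ids),
        disorder_mask=np.ones(n, dtype=bool),
        name=name,
    )
    return assign_bead_properties(model)


def ntf2_dimer_model() -> CGModel:
    """Homodimer bead model of human NTF2 (sequence only, extended geometry)."""
    seq = ntf2_sequence()
    return model_from_sequence(
        seq * 2, ["A"] * len(seq) + ["B"] * len(seq), name="NTF2"
    )


# ----------------------------------------------------------------------
# descriptors
# ----------------------------------------------------------------------
def compute_descriptors(
    model: CGModel, trajectory=None, origin: str = "com"
) -> Descriptors:
    """NCPR, time-averaged dipole moment and radius of gyration.

    With no trajectory the model's single conformation is used and the result
    is flagged ``from_single_conformation``. The dipole origin for
    net-charged molecules is the uniform-mass center of mass (equal to the
    center of geometry at this resolution); both spellings are accepted.
    """
    if model.charges is None:
        raise ModelError("assign bead properties before computing descriptors")
    if origin not in ("com", "cog"):
        raise ModelError(f"unknown dipole origin convention {origin!r}")
    if trajectory is None:
        frames = model.positions[None, :, :]
        single = True
    else:
        frames = np.asarray(getattr(trajectory, "frames", trajectory), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.shape[0] == 0:
            raise ModelError("trajectory contains no frames")
        if frames.shape[1] != model.n_beads:
            raise ModelError("trajectory bead count does not match the model")
        single = False

    centers = frames.mean(axis=1, keepdims=True)  # uniform bead masses
    rel = frames - centers
    dipoles = np.linalg.norm(
        (model.charges[None, :, None] * rel).sum(axis=1), axis=1
    )
    rgs = np.sqrt((rel**2).sum(axis=2).mean(axis=1))
    return Descriptors(
        ncpr=model.ncpr,
        dipole_M=float(dipoles.mean()),
        rg=float(rgs.mean()),
        sequence_length=model.n_beads,
        from_single_conformation=single,
    )
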