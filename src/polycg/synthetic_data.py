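"""Deterministic generators for test inputs: toy folded components with
controlled net charge and dipole, binding-site annotations, and synthetic
correlation datasets with known ground truth.

Folds are geometric templates (compact lattice walks), not physical
predictions; they exist so the whole pipeline can run without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .charge_correlation import ComponentRecord, CorrelationDataset
from .contact_analysis import BindingSiteAnnotation, ContactError
from .model import CGModel, ModelError
from .model_builder import (
    assign_bead_properties,
    build_elastic_network,
    compute_descriptors,
)

NEUTRAL_FILLERS = np.array(list("GSATQN"))
LATTICE_SPACING = 0.55  # nm between neighbouring fold sites


@dataclass
class ToyComponentSpec:
    n_residues: int = 64
    net_charge: int = -10  # e
    target_dipole: float = 15.0  # e.nm, approximate; 0 disables segregation
    fraction_aromatic: float = 0.08
    fold: str = "lattice"
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 10:
            raise ModelError("toy components need at least 10 residues")
        if abs(self.net_charge) > self.n_residues:
            raise ModelError("net charge cannot exceed the residue count")
        if not 0.0 <= self.fraction_aromatic <= 1.0:
            raise ModelError("fraction_aromatic must be in [0, 1]")


@dataclass
class SyntheticCorrelationSpec:
    n_components: int = 9
    f_true: float = 0.0036
    slope_true: float = -0.25
    intercept_true: float = 0.002
    noise_sd: float = 0.002
    seed: int = 0
    series: tuple = ("PR20", "PR50")

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ModelError("noise sd must be >= 0")


# ----------------------------------------------------------------------
def _lattice_walk(n: int) -> np.ndarray:
    """Boustrophedon walk through a near-cubic lattice block (compact fold)."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    coords = []
    for z in range(side):
        for yy in range(side):
            y = yy if z % 2 == 0 else side - 1 - yy
            xs = range(side) if yy % 2 == 0 else range(side - 1, -1, -1)
            for x in xs:
                coords.append((x, y, z))
                if len(coords) == n:
                    return np.asarray(coords, dtype=float) * LATTICE_SPACING
    return np.asarray(coords[:n], dtype=float) * LATTICE_SPACING


def gen_toy_component(spec: ToyComponentSpec):
    """Compact folded toy molecule hitting the target net charge exactly.

    Returns ``(model, descriptors)``. Dipole control is spatial: with a
    nonzero ``target_dipole`` the negative charges are biased toward the
    low-x half of the fold and the positives toward the high-x half; with
    ``target_dipole = 0`` charge placement is uniform at random, giving a
    small residual dipole.
    """
    if spec.fold != "lattice":
        raise ModelError(f"unknown fold template {spec.fold!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    positions = _lattice_walk(n)
    positions += rng.normal(0.0, 0.02, positions.shape)  # break exact degeneracies

    # residue counts: net charge exact, plus a few balanced charge pairs
    extra_pairs = max(1, n // 20)
    n_pos = max(spec.net_charge, 0) + extra_pairs
    n_neg = max(-spec.net_charge, 0) + extra_pairs
    n_arom = int(round(spec.fraction_aromatic * n))
    if n_pos + n_neg + n_arom > n:
        raise ModelError("charge/aromatic composition infeasible for this length")

    names = np.array([""] * n, dtype="U1")
    order_by_x = np.argsort(positions[:, 0], kind="stable")
    if spec.target_dipole > 0:
        # maximally segregated placement, then relax toward the target
        neg_sites = list(order_by_x[:n_neg])
        pos_sites = list(order_by_x[n - n_pos:])
    else:
        perm = rng.permutation(n)
        neg_sites = list(perm[:n_neg])
        pos_sites = list(perm[n_neg:n_neg + n_pos])
    names[neg_sites] = "E"
    names[pos_sites] = "K"
    free = np.flatnonzero(names == "")
    arom_sites = rng.choice(free, size=n_arom, replace=False) if n_arom else []
    names[arom_sites] = "F"
    free = np.flatnonzero(names == "")
    names[free] = rng.choice(NEUTRAL_FILLERS, size=len(free))

    model = CGModel(
        residue_names=names,
        positions=positions,
        disorder_mask=np.zeros(n, dtype=bool),
        name=f"toy_q{spec.net_charge:+d}_s{spec.seed}",
    )
    model = assign_bead_properties(model)
    model = build_elastic_network(model)
    descriptors = compute_descriptors(model)
    return model, descriptors


# ----------------------------------------------------------------------
def gen_annotation(model: CGModel, rule: str, seed: int = 0, partner: str = "partner"):
    """Binding-site annotation fixture obeying a placement rule.

    Rules: ``"C-terminal quartile"``, ``"N-terminal quartile"``, or
    ``"random:<k>"`` for k seeded uniformly drawn sites.
    """
    n = model.n_beads
    if rule == "C-terminal quartile":
        residues = np.arange(3 * n // 4 + 1, n + 1)
    elif rule == "N-terminal quartile":
        residues = np.arange(1, n // 4 + 1)
    elif rule.startswith("random:"):
        k = int(rule.split(":", 1)[1])
        if k > n:
            raise ContactError("cannot draw more sites than residues")
        rng = np.random.default_rng(seed)
        residues = np.sort(rng.choice(np.arange(1, n + 1), size=k, replace=False))
    else:
        raise ContactError(f"unknown annotation rule {rule!r}")
    return BindingSiteAnnotation(partner=partner, residues=residues)


def gen_overlapping_annotations(
    model: CGModel, overlap: int, sizes=(10, 10), seed: int = 0,
    partners=("partner_a", "partner_b"),
):
    """Two annotations with exactly ``overlap`` shared residues."""
    n = model.n_beads
    if overlap > min(sizes):
        raise ContactError("overlap cannot exceed either annotation size")
    if sizes[0] + sizes[1] - overlap > n:
        raise ContactError("annotations do not fit in the sequence")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(np.arange(1, n + 1))
    shared = pool[:overlap]
    a_only = pool[overlap:sizes[0]]
    b_only = pool[sizes[0]:sizes[0] + sizes[1] - overlap]
    return (
        BindingSiteAnnotation(partner=partners[0], residues=np.concatenate([shared, a_only])),
        BindingSiteAnnotation(partner=partners[1], residues=np.concatenate([shared, b_only])),
    )


# ----------------------------------------------------------------------
#: Descriptor ranges loosely spanning the published spread: mostly negative
#: NCPR, dipole moments up to tens of e.nm, Rg of small folded domains.
NCPR_RANGE = (-0.25, 0.05)
DIPOLE_RANGE = (5.0, 60.0)
RG_RANGE = (2.0, 4.0)


def gen_correlation_dataset(spec: SyntheticCorrelationSpec) -> CorrelationDataset:
    """Synthetic dataset where y = slope·(NCPR − f_true·M/Rg) + intercept + noise."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_components):
        ncpr = rng.uniform(*NCPR_RANGE)
        dipole = rng.uniform(*DIPOLE_RANGE)
        rg = rng.uniform(*RG_RANGE)
        x = ncpr - spec.f_true * dipole / rg
        ys = {
            label: spec.slope_true * x
            + spec.intercept_true
            + rng.normal(0.0, spec.noise_sd)
            for label in spec.series
        }
        records.append(
            ComponentRecord(
                name=f"toy{i:02d}", ncpr=ncpr, dipole_M=dipole, rg=rg,
                ct_normalized=ys,
            )
        )
    return CorrelationDataset(
        records=records,
        ground_truth={
            "f_true": spec.f_true,
            "slope_true": spec.slope_true,
            "intercept_true": spec.intercept_true,
            "noise_sd": spec.noise_sd,
        },
    )
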