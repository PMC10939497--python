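"""Contact statistics between a peptide and a folded partner.

A contact is a peptide/component bead pair within the cutoff (default 1 nm,
closed interval) under the minimum-image convention. Residue indices in
annotations and contact-site sets are 1-based over the modeled construct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTACT_CUTOFF = 1.0  # nm
CONTACT_SITE_THRESHOLD = 0.10  # strictly-greater-than
N_BLOCKS = 3


class ContactError(ValueError):
    pass


@dataclass
class ContactResult:
    ct: float  # mean contacts per frame
    ct_normalized: float  # ct / (NTC * NPR)
    sem: float  # 3-block standard error of the mean
    per_residue_probability: np.ndarray  # (NTC,)
    contact_sites: np.ndarray  # 1-based residue indices, sorted

    def __post_init__(self):
        p = np.asarray(self.per_residue_probability, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ContactError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.ct_normalized <= 1.0:
            raise ContactError("normalized contact count must lie in [0, 1]")
        self.per_residue_probability = p
        self.contact_sites = np.asarray(self.contact_sites, dtype=int)


@dataclass
class BindingSiteAnnotation:
    partner: str
    residues: np.ndarray  # 1-based residue indices

    def __post_init__(self):
        self.residues = np.unique(np.asarray(self.residues, dtype=int))
        if len(self.residues) and self.residues.min() < 1:
            raise ContactError("annotation residue indices are 1-based (>= 1)")


# ----------------------------------------------------------------------
def _frames_of(trajectory):
    frames = getattr(trajectory, "production", None)
    if callable(frames):
        out = trajectory.production()
        box = trajectory.box
    else:
        out = np.asarray(trajectory, dtype=float)
        box = None
    if out.ndim == 2:
        out = out[None]
    return out, box


def _min_image(dx, box):
    if box is not None:
        dx -= box * np.round(dx / box)
    return dx


def _contact_matrix(frame, pep_idx, comp_idx, cutoff, box):
    """Boolean (NPR, NTC) matrix of pairs within the cutoff for one frame."""
    dx = frame[pep_idx][:, None, :] - frame[comp_idx][None, :, :]
    dx = _min_image(dx, box)
    return (dx**2).sum(axis=-1) <= cutoff**2


def _cell_contact_count(frame, pep_idx, comp_idx, cutoff, box):
    """Cell-list route for one frame's contact count (dual-route check)."""
    from .simulator import neighbor_list

    sub = np.concatenate([pep_idx, comp_idx])
    pairs = neighbor_list(frame[sub], box, cutoff)
    npep = len(pep_idx)
    lo, hi = pairs[:, 0], pairs[:, 1]
    return int(((lo < npep) & (hi >= npep)).sum())


def per_frame_contacts(
    trajectory, polypr_indices, component_indices, cutoff=CONTACT_CUTOFF,
    box=None, method="brute",
):
    """Number of peptide/component bead pairs within the cutoff, per frame."""
    frames, traj_box = _frames_of(trajectory)
    if box is None:
        box = traj_box
    pep = np.asarray(polypr_indices, dtype=int)
    comp = np.asarray(component_indices, dtype=int)
    if frames.shape[0] == 0:
        raise ContactError("trajectory has no production frames")
    if method == "brute":
        return np.asarray(
            [int(_contact_matrix(f, pep, comp, cutoff, box).sum()) for f in frames]
        )
    if method == "cell":
        if box is None:
            raise ContactError("cell-list counting requires a periodic box")
        return np.asarray(
            [_cell_contact_count(f, pep, comp, cutoff, box) for f in frames]
        )
    raise ContactError(f"unknown method {method!r}")


def block_sem(values, n_blocks: int = N_BLOCKS) -> float:
    """SEM from equal contiguous blocks; trailing partial frames dropped."""
    values = np.asarray(values, dtype=float)
    if len(values) < n_blocks:
        raise ContactError(f"need at least {n_blocks} frames for block averaging")
    size = len(values) // n_blocks
    means = values[: size * n_blocks].reshape(n_blocks, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def count_contacts(
    trajectory, polypr_indices, component_indices, cutoff=CONTACT_CUTOFF,
    box=None, method="brute", threshold=CONTACT_SITE_THRESHOLD,
) -> ContactResult:
    """Time-averaged contact count, its normalization, SEM and site calls."""
    counts = per_frame_contacts(
        trajectory, polypr_indices, component_indices, cutoff, box, method
    )
    npr = len(np.asarray(polypr_indices))
    ntc = len(np.asarray(component_indices))
    ct = float(counts.mean())
    probs = contact_probability(
        trajectory, component_indices, polypr_indices, cutoff, box
    )
    return ContactResult(
        ct=ct,
        ct_normalized=ct / (ntc * npr),
        sem=block_sem(counts),
        per_residue_probability=probs,
        contact_sites=call_contact_sites(probs, threshold),
    )


def contact_probability(
    trajectory, component_indices, polypr_indices, cutoff=CONTACT_CUTOFF, box=None
) -> np.ndarray:
    """Per component residue: fraction of frames with >= 1 peptide bead within the cutoff."""
    frames, traj_box = _frames_of(trajectory)
    if box is None:
        box = traj_box
    pep = np.asarray(polypr_indices, dtype=int)
    comp = np.asarray(component_indices, dtype=int)
    if frames.shape[0] == 0:
        raise ContactError("trajectory has no production frames")
    hits = np.zeros(len(comp))
    for f in frames:
        hits += _contact_matrix(f, pep, comp, cutoff, box).any(axis=0)
    return hits / frames.shape[0]


def call_contact_sites(probabilities, threshold=CONTACT_SITE_THRESHOLD) -> np.ndarray:
    """1-based residue indices with contact probability strictly above threshold."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ContactError("probabilities must lie in [0, 1]")
    return np.flatnonzero(p > threshold) + 1


def n_shared(contact_sites, annotation: BindingSiteAnnotation, sequence_length: int) -> int:
    """|contact sites ∩ annotated binding-site residues| on 1-based numbering."""
    sites = np.asarray(contact_sites, dtype=int)
    if len(annotation.residues) and annotation.residues.max() > sequence_length:
        raise ContactError(
            f"annotation for {annotation.partner!r} exceeds sequence length {sequence_length}"
        )
    return int(len(np.intersect1d(sites, annotation.residues)))


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_annotations_tsv(path) -> list[BindingSiteAnnotation]:
    """TSV with columns ``partner`` and ``residue_index`` (1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        BindingSiteAnnotation(partner=str(name), residues=grp["residue_index"].to_numpy())
        for name, grp in df.groupby("partner", sort=True)
    ]


def write_annotations_tsv(annotations, path) -> None:
    rows = [
        {"partner": a.partner, "residue_index": int(r)}
        for a in annotations
        for r in a.residues
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_probability_tsv(result: ContactResult, path) -> None:
    pd.DataFrame(
        {
            "residue_index": np.arange(1, len(result.per_residue_probability) + 1),
            "contact_probability": result.per_residue_probability,
        }
    ).to_csv(path, sep="\t", index=False)


def summary_dict(result: ContactResult, annotations=(), sequence_length=None) -> dict:
    out = {
        "ct": result.ct,
        "ct_normalized": result.ct_normalized,
        "sem": result.sem,
        "n_contact_sites": int(len(result.contact_sites)),
    }
    if sequence_length is not None:
        out["n_shared"] = {
            a.partner: n_shared(result.contact_sites, a, sequence_length)
            for a in annotations
        }
    return out
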