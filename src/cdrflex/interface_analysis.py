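"""Protein-protein interface analysis and docking-model selection.

Residue-by-residue minimum-distance contact maps between two chains,
the CDR-versus-hinge contact-fraction filter used to pick a docked
model (fraction of CDR residues with any heavy atom within 4.0 Å of the
partner's hinge span), model ranking with artifact exclusions, and
overlap of observed interface residues against literature binding-assay
residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import RegionScheme, Residue, Structure, select_region

__all__ = [
    "ContactMap",
    "DockModelScore",
    "residue_min_distance_map",
    "contacts",
    "cdr_hinge_fraction",
    "rank_dock_models",
    "residue_set_overlap",
    "CDR_REGION_NAMES",
    "HINGE_FILTER_REGION",
]

CDR_REGION_NAMES = ("CDR1", "CDR2", "CDR3")
HINGE_FILTER_REGION = "hinge_full"  # combined canonical + extended hinge span


@dataclass(frozen=True)
class ContactMap:
    """Minimum inter-residue distances between two residue selections."""

    rows: tuple[tuple[str, int], ...]  # residues of protein A
    cols: tuple[tuple[str, int], ...]  # residues of protein B
    values: np.ndarray                 # Å, shape (len(rows), len(cols))

    def __post_init__(self):
        values = np.asarray(self.values, float)
        if values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("values shape must be (rows, cols)")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", values)

    def transpose(self) -> "ContactMap":
        return ContactMap(self.cols, self.rows, self.values.T)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: res_a, res_b, min_dist_A."""
        rows = []
        for i, ra in enumerate(self.rows):
            for j, rb in enumerate(self.cols):
                rows.append((f"{ra[0]}{ra[1]}", f"{rb[0]}{rb[1]}", self.values[i, j]))
        return pd.DataFrame(rows, columns=["res_a", "res_b", "min_dist_A"])


@dataclass(frozen=True)
class DockModelScore:
    """Contact-fraction score of one docked model."""

    model_id: str
    cdr_residues_total: int
    cdr_residues_in_contact: int
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if not 0 <= self.cdr_residues_in_contact <= self.cdr_residues_total:
            raise ValueError("in-contact count must be within [0, total]")

    @property
    def fraction(self) -> float:
        return self.cdr_residues_in_contact / self.cdr_residues_total


def _residue_coords(res: Residue, atom_mode: str) -> np.ndarray:
    if atom_mode == "heavy":
        return res.heavy_atom_coords()
    if atom_mode == "ca":
        return res.atom("CA").xyz[None, :]
    if atom_mode == "all":
        return np.asarray([a.xyz for a in res.atoms])
    raise ValueError(f"unknown atom_mode {atom_mode!r}; use 'heavy', 'ca' or 'all'")


def residue_min_distance_map(
    struct_a: Structure,
    sel_a: Sequence[Residue],
    struct_b: Structure,
    sel_b: Sequence[Residue],
    atom_mode: str = "heavy",
) -> ContactMap:
    """Minimum atom-pair distance for every residue pair across two selections.

    ``atom_mode`` picks the atom set per residue: ``"heavy"`` (default,
    matching the usual any-heavy-atom "within" semantics), ``"ca"`` or
    ``"all"``.
    """
    if not sel_a or not sel_b:
        raise ValueError("selections must be non-empty")
    coords_a = [_residue_coords(r, atom_mode) for r in sel_a]
    coords_b = [_residue_coords(r, atom_mode) for r in sel_b]
    values = np.empty((len(sel_a), len(sel_b)))
    for i, ca_ in enumerate(coords_a):
        for j, cb in enumerate(coords_b):
            values[i, j] = cdist(ca_, cb).min()
    return ContactMap(
        rows=tuple(r.key for r in sel_a),
        cols=tuple(r.key for r in sel_b),
        values=values,
    )


def contacts(
    cmap: ContactMap, cutoff: float
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs at or within the distance cutoff (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ii, jj = np.nonzero(cmap.values <= cutoff)
    return {(cmap.rows[i], cmap.cols[j]) for i, j in zip(ii, jj)}


def cdr_hinge_fraction(
    complex_pair: tuple[Structure, Structure],
    scheme: RegionScheme,
    cutoff: float = 4.0,
    model_id: str = "model",
    atom_mode: str = "heavy",
) -> DockModelScore:
    """Fraction of CDR residues in contact with the partner hinge span.

    The numerator counts distinct CDR residues (CDR1+CDR2+CDR3) of the
    receptor chain having at least one heavy atom within ``cutoff`` of
    any heavy atom of a hinge-span residue (canonical + extended,
    aa167-231) on the partner; the denominator is the number of CDR
    residues present in the structure (26 when all three loops are
    complete).
    """
    receptor, partner = complex_pair
    cdr_residues: list[Residue] = []
    missing: list[str] = []
    for name in CDR_REGION_NAMES:
        sel = select_region(receptor, scheme, name)
        if not sel.residues:
            missing.append(name)
        cdr_residues.extend(sel.residues)
    hinge_sel = select_region(partner, scheme, HINGE_FILTER_REGION)
    if missing or not hinge_sel.residues:
        absent = missing + ([] if hinge_sel.residues else [HINGE_FILTER_REGION])
        raise ValueError(f"regions unresolvable in complex: {absent}")

    cmap = residue_min_distance_map(
        receptor, cdr_residues, partner, list(hinge_sel.residues), atom_mode=atom_mode
    )
    in_contact = int(np.sum(cmap.values.min(axis=1) <= cutoff))
    return DockModelScore(
        model_id=model_id,
        cdr_residues_total=len(cdr_residues),
        cdr_residues_in_contact=in_contact,
    )


def rank_dock_models(
    models: Sequence[DockModelScore],
    exclusions: Mapping[str, str] | None = None,
) -> tuple[list[DockModelScore], DockModelScore]:
    """Rank scored models by contact fraction and pick the top valid one.

    Stable descending sort by fraction with ties broken by model id;
    ``exclusions`` maps model id to a reason (visual-artifact flags are
    an input, not detected here).  Returns the ordered list and the
    first non-excluded model; raises if every model is excluded.
    """
    if not models:
        raise ValueError("no models to rank")
    exclusions = dict(exclusions or {})
    annotated = [
        DockModelScore(
            m.model_id,
            m.cdr_residues_total,
            m.cdr_residues_in_contact,
            excluded=m.model_id in exclusions or m.excluded,
            exclusion_reason=exclusions.get(m.model_id, m.exclusion_reason),
        )
        for m in models
    ]
    ordered = sorted(annotated, key=lambda m: (-m.fraction, m.model_id))
    for m in ordered:
        if not m.excluded:
            return ordered, m
    raise ValueError("all models are excluded; no valid model to select")


def residue_set_overlap(
    observed: set, literature: set
) -> tuple[int, float]:
    """Intersection size and Jaccard index of two residue sets."""
    if not observed and not literature:
        raise ValueError("Jaccard undefined: both sets empty")
    inter = observed & literature
    union = observed | literature
    return len(inter), len(inter) / len(union)
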