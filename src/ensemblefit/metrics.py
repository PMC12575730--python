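"""Validation metrics against a ground-truth structure: Cα RMSD over
configurable regions and per-residue deviation.

These are *assessment* quantities only — model selection never sees them;
they quantify, after the fact, how close a refined model came to a known
target conformation. Residue ranges are inclusive, in author numbering,
per chain. The default convention superposes on all matched Cα and then
reports RMSD over the region of interest (the "local deviation" reading);
alignment on the region itself or on a custom subset (e.g. a rigid scaffold
domain) is available through :class:`RegionSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import superpose
from .structures import StructureModel

__all__ = ["RegionSpec", "ca_rmsd", "per_residue_deviation"]


@dataclass(frozen=True)
class RegionSpec:
    """Residue ranges (chain, first, last), inclusive, author numbering."""

    ranges: tuple[tuple[str, int, int], ...]
    align_on: str = "all_ca"  # "all_ca" | "region" | "custom"
    custom_align: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("RegionSpec needs at least one range")
        for chain, start, end in self.ranges:
            if start > end:
                raise ValueError(f"range {chain}:{start}-{end} has start > end")
        if self.align_on not in ("all_ca", "region", "custom"):
            raise ValueError(f"unknown align_on: {self.align_on}")

    def contains(self, chain: str, resi: int) -> bool:
        return any(c == chain and a <= resi <= b for c, a, b in self.ranges)

    def in_align_set(self, chain: str, resi: int) -> bool:
        if self.align_on == "all_ca":
            return True
        if self.align_on == "region":
            return self.contains(chain, resi)
        return any(c == chain and a <= resi <= b for c, a, b in self.custom_align)


def _matched_ca(model_a: StructureModel, model_b: StructureModel):
    """Cα pairs matched on (chain, residue_index, icode)."""
    keys_a = model_a.residue_keys_ca()
    keys_b = model_b.residue_keys_ca()
    pos_a = {k: p for k, p in zip(keys_a, model_a.positions[model_a.ca_mask])}
    pos_b = {k: p for k, p in zip(keys_b, model_b.positions[model_b.ca_mask])}
    common = [k for k in keys_a if k in pos_b]
    if not common:
        missing = sorted(set(keys_a) ^ set(keys_b))[:10]
        raise ValueError(f"no residue correspondence between models; "
                         f"unmatched examples: {missing}")
    A = np.array([pos_a[k] for k in common])
    B = np.array([pos_b[k] for k in common])
    return common, A, B


def _region_masks(common, region: RegionSpec | None):
    if region is None:
        n = len(common)
        return np.ones(n, bool), np.ones(n, bool)
    eval_mask = np.array([region.contains(c, r) for c, r, _ in common])
    align_mask = np.array([region.in_align_set(c, r) for c, r, _ in common])
    if not eval_mask.any():
        raise ValueError("region matches no residues common to both models")
    return eval_mask, align_mask


def ca_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    region: RegionSpec | None = None,
    align: bool = True,
) -> float:
    """Cα RMSD (Å) between two models over a region.

    With ``align`` the models are first superposed on the region's alignment
    subset (default: all matched Cα); without it, raw coordinates are
    compared. Residues are matched by (chain, residue number, insertion
    code).
    """
    common, A, B = _matched_ca(model_a, model_b)
    eval_mask, align_mask = _region_masks(common, region)
    if align:
        tf, _ = superpose(A, B, subset=np.flatnonzero(align_mask))
        A = tf.apply(A)
    diff = A[eval_mask] - B[eval_mask]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def per_residue_deviation(
    model_a: StructureModel,
    model_b: StructureModel,
    region: RegionSpec | None = None,
) -> dict[tuple[str, int, str], float]:
    """|Cα_a − Cα_b| per matched residue after one global superposition.

    The superposition uses the region's alignment subset (all matched Cα by
    default); deviations are reported for every matched residue.
    """
    common, A, B = _matched_ca(model_a, model_b)
    _, align_mask = _region_masks(common, region)
    tf, _ = superpose(A, B, subset=np.flatnonzero(align_mask))
    A = tf.apply(A)
    dev = np.linalg.norm(A - B, axis=1)
    return {k: float(d) for k, d in zip(common, dev)}
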