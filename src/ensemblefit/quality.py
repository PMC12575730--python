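"""Model geometry quality: scaled scores, clash counting, ensemble filtering.

Two score sources exist and are never mixed within one run:

* ``external_goap`` — totals computed by an external statistical-potential
  program (e.g. GOAP) and imported from a table; more negative = better.
* ``internal_fallback`` — a built-in geometry score from clash density and
  backbone bond-length strain, calibrated so that well-formed models score
  below the filtering threshold and coordinate-scrambled decoys above it.

Both are length-scaled (total / n_residues) before filtering, so one
threshold applies across proteins of different size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._chem import bond_graph_exclusions, bonded_pairs, vdw_radius
from .structures import Ensemble, StructureModel

__all__ = [
    "GeometryScore",
    "FilterConfig",
    "FallbackScoreConfig",
    "scaled_score",
    "read_external_scores",
    "write_scores",
    "clash_score",
    "fallback_geometry_score",
    "score_ensemble",
    "filter_models",
]


@dataclass(frozen=True)
class GeometryScore:
    raw_total: float
    n_residues: int
    source: str  # "external_goap" | "internal_fallback"

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.source not in ("external_goap", "internal_fallback"):
            raise ValueError(f"unknown score source: {self.source}")

    @property
    def scaled(self) -> float:
        return self.raw_total / self.n_residues


@dataclass(frozen=True)
class FilterConfig:
    """Keep models whose scaled score is at or below ``threshold``.

    The default of −100 is a round, admittedly arbitrary cutoff that in
    practice separates grossly misfolded models from plausible ones; models
    *above* the threshold are discarded, so a score exactly at −100 is kept.
    """

    threshold: float = -100.0


def scaled_score(raw_total: float, n_residues: int) -> float:
    """Length-scaled geometry score: total divided by residue count."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return raw_total / n_residues


def read_external_scores(path: str, ensemble: Ensemble) -> list[GeometryScore]:
    """Read an external score table (CSV) and align it to ensemble order.

    The table needs columns ``raw_total`` and optionally ``model_label``;
    labelled rows are joined on the ensemble's labels, unlabelled tables are
    taken in file order and must match the ensemble length.
    """
    df = pd.read_csv(path)
    if "raw_total" not in df.columns:
        raise ValueError(f"{path}: score table needs a 'raw_total' column")
    if "model_label" in df.columns:
        order = {lab: i for i, lab in enumerate(ensemble.labels())}
        unknown = set(df["model_label"]) - set(order)
        if unknown or len(df) != len(ensemble):
            raise ValueError(
                f"{path}: score labels do not align with the ensemble "
                f"({len(df)} rows for {len(ensemble)} models; "
                f"unmatched: {sorted(unknown)[:5]})"
            )
        df = df.sort_values("model_label", key=lambda s: s.map(order))
    elif len(df) != len(ensemble):
        raise ValueError(
            f"{path}: {len(df)} scores for {len(ensemble)} models"
        )
    return [
        GeometryScore(float(raw), m.n_residues, "external_goap")
        for raw, m in zip(df["raw_total"], ensemble.models)
    ]


def write_scores(scores: list[GeometryScore], labels: list[str], path: str) -> None:
    pd.DataFrame(
        {
            "model_label": labels,
            "raw_total": [s.raw_total for s in scores],
            "n_residues": [s.n_residues for s in scores],
            "scaled": [s.scaled for s in scores],
            "source": [s.source for s in scores],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clash counting


def clash_score(model: StructureModel, overlap_cutoff: float = 0.4) -> float:
    """Steric clashes per 1000 heavy atoms (MolProbity-style approximation).

    Counts unordered heavy-atom pairs whose distance is below the sum of
    vdW radii minus ``overlap_cutoff``, excluding same-residue pairs and
    1-2/1-3 bonded neighbours from standard connectivity.
    """
    heavy = model.heavy_mask & ~model.hetero_flags
    idx = np.flatnonzero(heavy)
    if len(idx) < 2:
        raise ValueError("clash_score needs at least 2 heavy atoms")
    pos = model.positions[idx]
    radii = np.array([vdw_radius(model.elements[i]) for i in idx])
    res_keys = [model.residue_key(i) for i in idx]
    excluded = bond_graph_exclusions(model, max_separation=2)

    tree = cKDTree(pos)
    max_touch = 2 * radii.max() - overlap_cutoff
    count = 0
    for a, b in tree.query_pairs(max_touch):
        if res_keys[a] == res_keys[b]:
            continue
        i, j = int(idx[a]), int(idx[b])
        if (min(i, j), max(i, j)) in excluded:
            continue
        if np.linalg.norm(pos[a] - pos[b]) < radii[a] + radii[b] - overlap_cutoff:
            count += 1
    return 1000.0 * count / len(idx)


# ---------------------------------------------------------------------------
# internal fallback geometry score


@dataclass(frozen=True)
class FallbackScoreConfig:
    """Weights of the internal geometry score.

    scaled = −(base − w_clash·clashscore − w_bond·⟨(d−d_ideal)²⟩)

    ``base`` sets the score of a strain-free clash-free model (−150,
    comfortably below the −100 filter threshold); the penalty weights are
    calibrated so that per-atom coordinate noise at the Å scale keeps a
    model below −100 while coordinate-scrambled models — whose
    template-bonded atom pairs end up several Å apart — land far above it.
    Bond-length strain is the dominant discriminator because scrambling
    permutes a point cloud without changing its pairwise-distance multiset,
    leaving clash density almost unchanged.
    """

    base: float = 150.0
    w_clash: float = 0.02        # per clash-per-1000-atoms
    w_bond: float = 25.0         # per Å² of mean squared bond-length strain

    # idealized reference bond lengths by sorted atom-name pair
    @staticmethod
    def ideal_length(name_a: str, name_b: str) -> float:
        key = tuple(sorted((name_a, name_b)))
        return {
            ("CA", "N"): 1.458,
            ("C", "CA"): 1.525,
            ("C", "O"): 1.231,
            ("C", "OXT"): 1.231,
            ("CA", "CB"): 1.530,
            ("C", "N"): 1.329,   # peptide bond
        }.get(key, 1.50)


def fallback_geometry_score(
    model: StructureModel, config: FallbackScoreConfig | None = None
) -> GeometryScore:
    """Internal geometry score from clash density and bond-length strain.

    Depends only on internal distances, hence rigid-transform invariant.
    The sign convention matches statistical potentials: more negative is
    better, and the score is length-scaled by construction.
    """
    config = config or FallbackScoreConfig()
    bonds = bonded_pairs(model)
    if bonds:
        dev2 = []
        for i, j in bonds:
            d = float(np.linalg.norm(model.positions[i] - model.positions[j]))
            d0 = config.ideal_length(model.names[i], model.names[j])
            dev2.append((d - d0) ** 2)
        bond_msd = float(np.mean(dev2))
    else:
        bond_msd = 0.0
    clash = clash_score(model)
    scaled = -(config.base - config.w_clash * clash - config.w_bond * bond_msd)
    n_res = model.n_residues
    return GeometryScore(scaled * n_res, n_res, "internal_fallback")


def score_ensemble(
    ensemble: Ensemble, config: FallbackScoreConfig | None = None
) -> list[GeometryScore]:
    """Fallback geometry scores for every model of an ensemble."""
    return [fallback_geometry_score(m, config) for m in ensemble.models]


# ---------------------------------------------------------------------------
# filtering


def filter_models(
    ensemble: Ensemble,
    scores: list[GeometryScore],
    config: FilterConfig | None = None,
) -> list[int]:
    """Indices of models whose scaled score is ≤ threshold, in input order.

    Mixing external and fallback scores in one call is an error: scores are
    only comparable within a single source.
    """
    config = config or FilterConfig()
    if len(scores) != len(ensemble):
        raise ValueError(
            f"{len(scores)} scores for {len(ensemble)} models"
        )
    if len({s.source for s in scores}) > 1:
        raise ValueError("cannot filter on a mixture of score sources")
    kept = [i for i, s in enumerate(scores) if s.scaled <= config.threshold]
    if not kept:
        warnings.warn(
            f"no models pass the scaled-score threshold {config.threshold}",
            stacklevel=2,
        )
    return kept
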