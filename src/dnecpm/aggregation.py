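"""Aggregation of per-fold regression weights into interpretable summaries.

Cross-validation selects slightly different connections in every fold, so
feature importance is summarised by (1) averaging each feature's regression
weight across all folds (unselected = 0, preserving selection frequency),
(2) pooling node-pair weights into a macro-region by macro-region
contribution matrix (signed mean, so positively and negatively predictive
connection classes stay distinguishable), and (3) a per-node prediction
efficacy: the sum of absolute incident mean weights, min-max normalised to
[0, 1].

The packaged lookup groups the 246 Brainnetome parcels (210 cortical + 36
subcortical, 123 per hemisphere) into the atlas's 24 gyral/subcortical
macro-regions; any lookup with the same four-column schema may be
substituted for other parcellations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

# (macro label, full name, number of subregions per hemisphere);
# cortical gyri first (210 nodes), then subcortical nuclei (36 nodes),
# following the atlas ordering with left/right alternation within each
# subregion.
_BRAINNETOME_24 = [
    ("SFG", "Superior Frontal Gyrus", 7),
    ("MFG", "Middle Frontal Gyrus", 7),
    ("IFG", "Inferior Frontal Gyrus", 6),
    ("OrG", "Orbital Gyrus", 6),
    ("PrG", "Precentral Gyrus", 6),
    ("PCL", "Paracentral Lobule", 2),
    ("STG", "Superior Temporal Gyrus", 6),
    ("MTG", "Middle Temporal Gyrus", 4),
    ("ITG", "Inferior Temporal Gyrus", 7),
    ("FuG", "Fusiform Gyrus", 3),
    ("PhG", "Parahippocampal Gyrus", 6),
    ("pSTS", "posterior Superior Temporal Sulcus", 2),
    ("SPL", "Superior Parietal Lobule", 5),
    ("IPL", "Inferior Parietal Lobule", 6),
    ("Pcun", "Precuneus", 4),
    ("PoG", "Postcentral Gyrus", 4),
    ("INS", "Insular Gyrus", 6),
    ("CG", "Cingulate Gyrus", 7),
    ("MVOcC", "MedioVentral Occipital Cortex", 5),
    ("LOcC", "lateral Occipital Cortex", 6),
    ("Amyg", "Amygdala", 2),
    ("Hipp", "Hippocampus", 2),
    ("BG", "Basal Ganglia", 6),
    ("Tha", "Thalamus", 8),
]

_MAP_COLUMNS = ["node_id", "node_name", "macro_region", "hemisphere"]


@dataclass
class MacroRegionMap:
    """Node-to-macro-region lookup with one row per node.

    ``table`` columns: node_id (0-based, matching dnE row order), node_name,
    macro_region, hemisphere.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"macro map missing column(s): {missing}")
        if self.table["node_id"].duplicated().any():
            dup = self.table.loc[self.table["node_id"].duplicated(), "node_id"]
            raise InputError(f"macro map has duplicate node_id(s): {dup.tolist()}")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.table["macro_region"]:
            seen.setdefault(r, None)
        return list(seen)

    def region_of(self) -> dict[int, str]:
        return dict(zip(self.table["node_id"].astype(int),
                        self.table["macro_region"]))


def brainnetome_map() -> MacroRegionMap:
    """The packaged 246-node / 24-macro-region Brainnetome lookup."""
    rows = []
    node = 0
    for label, full_name, n_sub in _BRAINNETOME_24:
        for sub in range(1, n_sub + 1):
            for hemi in ("L", "R"):
                rows.append({
                    "node_id": node,
                    "node_name": f"{label}_{hemi}_{n_sub}_{sub}",
                    "macro_region": label,
                    "hemisphere": hemi,
                })
                node += 1
    return MacroRegionMap(pd.DataFrame(rows))


def load_macro_map(path: str | Path) -> MacroRegionMap:
    """Read a lookup TSV with the four named columns."""
    return MacroRegionMap(pd.read_csv(path, sep="\t"))


def write_macro_map(path: str | Path, macro_map: MacroRegionMap) -> None:
    macro_map.table.to_csv(path, sep="\t", index=False)


@dataclass
class AggregatedWeights:
    """Region-level contribution matrix and per-node prediction efficacy."""

    region_matrix: pd.DataFrame
    pair_counts: pd.DataFrame
    node_efficacy: pd.Series


def mean_fold_weights(per_fold_beta: np.ndarray) -> np.ndarray:
    """Arithmetic mean of regression weights across folds (unselected = 0)."""
    beta = np.asarray(per_fold_beta, dtype=float)
    if beta.ndim == 1:
        beta = beta[None, :]
    if beta.ndim != 2 or beta.shape[0] < 1:
        raise InputError("per_fold_beta must be a fold-by-feature table")
    return beta.mean(axis=0)


def aggregate_macro(
    mean_weights: np.ndarray,
    pair_index: list[tuple[int, int]],
    macro_map: MacroRegionMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool node-pair weights into a symmetric macro-region matrix.

    Cell (A, B) is the signed mean of mean weights over all node pairs with
    one node in A and the other in B (within-region pairs for A = B).
    Region pairs with no connecting features are 0; the companion count
    matrix (returned second) flags them with a 0 count.
    """
    region_of = macro_map.region_of()
    regions = macro_map.regions
    pos = {r: k for k, r in enumerate(regions)}
    sums = np.zeros((len(regions), len(regions)))
    counts = np.zeros((len(regions), len(regions)), dtype=int)
    for w, (p, q) in zip(np.asarray(mean_weights, dtype=float), pair_index):
        for node in (p, q):
            if node not in region_of:
                raise InputError(f"node {node} missing from the macro-region map")
        a, b = pos[region_of[p]], pos[region_of[q]]
        sums[a, b] += w
        counts[a, b] += 1
        if a != b:
            sums[b, a] += w
            counts[b, a] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return (
        pd.DataFrame(means, index=regions, columns=regions),
        pd.DataFrame(counts, index=regions, columns=regions),
    )


def node_efficacy(
    mean_weights: np.ndarray,
    pair_index: list[tuple[int, int]],
    n_nodes: int,
) -> np.ndarray:
    """Per-node prediction efficacy, normalised to [0, 1].

    The raw score of a node is the sum of absolute mean weights over its
    incident features.  Raw scores are non-negative, so normalisation
    divides by the maximum with the floor anchored at zero (a node with no
    selected incident connection scores exactly 0); an all-zero weight
    vector yields all zeros.
    """
    raw = np.zeros(n_nodes)
    for w, (p, q) in zip(np.asarray(mean_weights, dtype=float), pair_index):
        if not (0 <= p < n_nodes and 0 <= q < n_nodes):
            raise InputError(f"pair ({p}, {q}) outside 0..{n_nodes - 1}")
        raw[p] += abs(w)
        raw[q] += abs(w)
    hi = raw.max()
    if hi == 0:
        return np.zeros(n_nodes)
    return raw / hi


def aggregate(per_fold_beta: np.ndarray, pair_index: list[tuple[int, int]],
              macro_map: MacroRegionMap, n_nodes: int) -> AggregatedWeights:
    """Full aggregation: fold-mean weights, region matrix, node efficacy."""
    mw = mean_fold_weights(per_fold_beta)
    region_matrix, pair_counts = aggregate_macro(mw, pair_index, macro_map)
    eff = node_efficacy(mw, pair_index, n_nodes)
    node_ids = macro_map.table.set_index("node_id").loc[
        np.arange(n_nodes), "node_name"
    ] if set(range(n_nodes)) <= set(macro_map.table["node_id"]) else pd.Series(
        [f"n{i}" for i in range(n_nodes)]
    )
    return AggregatedWeights(
        region_matrix=region_matrix,
        pair_counts=pair_counts,
        node_efficacy=pd.Series(eff, index=list(node_ids), name="efficacy"),
    )
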