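"""Cross-species concordance of differential-expression profiles.

Human and mouse DE tables are joined through 1:1 orthologs; each gene gets a
per-species stage profile (direction at the compensated stage and at
moderate failure, called at |log2FC| > 1 and FDR < 0.05 by default), and
genes whose profiles agree across species form the conserved set rendered
as a log2FC heatmap matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ConservedGeneSet",
    "join_orthologs",
    "classify_profile",
    "classify_profiles",
    "conserved_set",
    "export_heatmap_matrix",
    "HEATMAP_COLUMNS",
]

log = logging.getLogger(__name__)

#: contrasts shown in the heatmap, early and late stage per species
HEATMAP_COLUMNS = ("human_CH", "human_mHF", "mouse_1wTAC", "mouse_8wTAC")

_PROFILE_COLS = ["log2fc_ch", "q_ch", "log2fc_hf", "q_hf"]


def join_orthologs(
    human: pd.DataFrame, mouse: pd.DataFrame, orthologs: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join species DE tables through 1:1 ortholog pairs.

    ``orthologs`` needs columns ``human_id, mouse_id`` and optionally
    ``mapping_type`` (rows not labelled ``one2one`` are dropped).  Pairs in
    which either gene participates more than once are excluded, with counts
    logged.
    """
    pairs = orthologs.copy()
    if "mapping_type" in pairs.columns:
        n0 = len(pairs)
        pairs = pairs[pairs["mapping_type"] == "one2one"]
        if len(pairs) < n0:
            log.info("dropped %d non-one2one ortholog rows", n0 - len(pairs))
    dup = pairs["human_id"].duplicated(keep=False) | pairs["mouse_id"].duplicated(
        keep=False
    )
    if dup.any():
        log.info("dropped %d ortholog rows violating 1:1 uniqueness", int(dup.sum()))
        pairs = pairs[~dup]

    merged = pairs[["human_id", "mouse_id"]].merge(
        human.rename(columns={"gene_id": "human_id"}), on="human_id", how="inner"
    )
    merged = merged.merge(
        mouse.rename(columns={"gene_id": "mouse_id"}),
        on="mouse_id",
        how="inner",
        suffixes=("_human", "_mouse"),
    )
    if merged.empty:
        raise ValueError("no genes shared between the species tables and the map")
    return merged


def classify_profile(
    log2fc: float, q: float, lfc_min: float = 1.0, q_max: float = 0.05
) -> str:
    """Direction call for one contrast: 'up', 'down', or 'ns'."""
    if q < q_max and log2fc > lfc_min:
        return "up"
    if q < q_max and log2fc < -lfc_min:
        return "down"
    return "ns"


def classify_profiles(
    table: pd.DataFrame,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    suffix: str = "",
) -> pd.DataFrame:
    """Vectorized stage-profile calls for a table with columns
    ``log2fc_ch{suffix}, q_ch{suffix}, log2fc_hf{suffix}, q_hf{suffix}``."""
    out = {}
    for stage in ("ch", "hf"):
        lfc = table[f"log2fc_{stage}{suffix}"].to_numpy()
        q = table[f"q_{stage}{suffix}"].to_numpy()
        call = np.where(
            (q < q_max) & (lfc > lfc_min),
            "up",
            np.where((q < q_max) & (lfc < -lfc_min), "down", "ns"),
        )
        out[f"direction_{stage}{suffix}"] = call
    return pd.DataFrame(out, index=table.index)


@dataclass
class ConservedGeneSet:
    """Ortholog pairs with matching cross-species stage profiles."""

    entries: pd.DataFrame  # human_gene, mouse_gene, profile class, 4 x log2fc
    heatmap: pd.DataFrame  # genes x HEATMAP_COLUMNS log2FC matrix

    def __len__(self) -> int:
        return len(self.entries)


def conserved_set(
    paired: pd.DataFrame,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    require_stages: Literal["pattern", "all", "any"] = "pattern",
) -> ConservedGeneSet:
    """Extract genes regulated the same way in both species.

    ``require_stages``:

    * ``pattern`` (default): the per-stage direction patterns must be
      identical in both species and not (ns, ns);
    * ``all``: both stages must be significant, same direction, in both
      species;
    * ``any``: at least one stage significant with identical full patterns
      (equivalent to ``pattern``; kept as an explicit mode).
    """
    h = classify_profiles(paired, lfc_min, q_max, suffix="_human")
    m = classify_profiles(paired, lfc_min, q_max, suffix="_mouse")
    same = (h["direction_ch_human"].to_numpy() == m["direction_ch_mouse"].to_numpy()) & (
        h["direction_hf_human"].to_numpy() == m["direction_hf_mouse"].to_numpy()
    )
    ch = h["direction_ch_human"].to_numpy()
    hf = h["direction_hf_human"].to_numpy()
    if require_stages in ("pattern", "any"):
        informative = ~((ch == "ns") & (hf == "ns"))
    elif require_stages == "all":
        informative = (ch != "ns") & (hf != "ns")
    else:
        raise ValueError(f"unknown require_stages mode: {require_stages!r}")

    keep = same & informative
    entries = pd.DataFrame(
        {
            "human_gene": paired.loc[keep, "human_id"].to_numpy(),
            "mouse_gene": paired.loc[keep, "mouse_id"].to_numpy(),
            "profile_class": [f"{a}_{b}" for a, b in zip(ch[keep], hf[keep])],
            HEATMAP_COLUMNS[0]: paired.loc[keep, "log2fc_ch_human"].to_numpy(),
            HEATMAP_COLUMNS[1]: paired.loc[keep, "log2fc_hf_human"].to_numpy(),
            HEATMAP_COLUMNS[2]: paired.loc[keep, "log2fc_ch_mouse"].to_numpy(),
            HEATMAP_COLUMNS[3]: paired.loc[keep, "log2fc_hf_mouse"].to_numpy(),
        }
    )
    heatmap = entries.set_index("human_gene")[list(HEATMAP_COLUMNS)]
    return ConservedGeneSet(entries=entries, heatmap=heatmap)


def export_heatmap_matrix(cs: ConservedGeneSet, path: str | Path) -> Path:
    """Write the genes x 4-contrast log2FC matrix as TSV.

    Rows are ordered by shared profile class, then by decreasing mean
    |log2FC|.
    """
    if len(cs) == 0:
        raise ValueError("conserved set is empty: nothing to export")
    entries = cs.entries.copy()
    entries["_mag"] = entries[list(HEATMAP_COLUMNS)].abs().mean(axis=1)
    entries = entries.sort_values(
        ["profile_class", "_mag"], ascending=[True, False]
    )
    matrix = entries.set_index("human_gene")[list(HEATMAP_COLUMNS)]
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="gene")
    return path
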