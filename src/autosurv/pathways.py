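"""Binary gene-to-pathway connection masks built from GMT gene-set files.

The mask defines the sparse connections between the gene layer and the pathway
layer of the VAE encoder (and, transposed, the last two layers of the gene
decoder head): a weight is allowed only where the gene belongs to the pathway.
Pathways are size-filtered after intersecting with the measured gene universe,
keeping sets with between ``min_size`` and ``max_size`` member genes inclusive
(defaults 15 and 300: "fewer than 15" and "more than 300" are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PathwayMask", "read_gmt", "write_gmt", "build_mask"]

DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 300


@dataclass
class PathwayMask:
    """Genes x pathways binary membership matrix with recorded orderings."""

    gene_ids: list[str]
    pathway_ids: list[str]
    mask: np.ndarray  # (n_genes, n_pathways), float 0/1

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.mask.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("mask shape does not match id lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def pathway_sizes(self) -> pd.Series:
        return pd.Series(self.mask.sum(axis=0).astype(int), index=self.pathway_ids)

    def genes_in(self, pathway: str) -> list[str]:
        j = self.pathway_ids.index(pathway)
        return [g for g, m in zip(self.gene_ids, self.mask[:, j]) if m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mask, index=self.gene_ids, columns=self.pathway_ids)

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (gene, pathway) membership pairs, for audit export."""
        rows, cols = np.nonzero(self.mask)
        return pd.DataFrame(
            {
                "gene": [self.gene_ids[i] for i in rows],
                "pathway": [self.pathway_ids[j] for j in cols],
            }
        )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{pathway: member genes}`` (duplicates dropped)."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import, keep lazy

    raw = _read_gmt(str(path))
    return {name: list(dict.fromkeys(genes)) for name, genes in raw.items()}


def write_gmt(pathways: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def build_mask(
    gmt: Mapping[str, Sequence[str]],
    gene_universe: Sequence[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> PathwayMask:
    """Build the binary mask from GMT membership restricted to a gene universe.

    Membership is intersected with ``gene_universe`` first, then pathways with
    fewer than ``min_size`` or more than ``max_size`` in-universe members are
    dropped, and finally genes belonging to no surviving pathway are dropped.
    Gene and pathway orderings are lexicographic so masks are reproducible.
    """
    if len(gene_universe) == 0:
        raise ValueError("gene_universe must be nonempty")
    universe = set(gene_universe)

    kept: dict[str, set[str]] = {}
    for name, genes in gmt.items():
        members = set(dict.fromkeys(genes)) & universe
        if min_size <= len(members) <= max_size:
            kept[name] = members
    if not kept:
        raise ValueError(
            f"no pathway has between {min_size} and {max_size} member genes "
            "within the gene universe"
        )

    pathway_ids = sorted(kept)
    gene_ids = sorted(set().union(*kept.values()))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros((len(gene_ids), len(pathway_ids)))
    for j, name in enumerate(pathway_ids):
        for g in kept[name]:
            mask[gene_index[g], j] = 1.0
    return PathwayMask(gene_ids=gene_ids, pathway_ids=pathway_ids, mask=mask)
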