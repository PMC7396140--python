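"""KO annotation from alignment hit tables and paralog-count aggregation.

Genes are annotated with the KO of their top-ranked hit (first record per
query in file order — tabular aligners emit the best hit first) when that
hit's e-value is strictly below the cutoff (default 1e-8).  Paralog counts
per genome are then summarized to per-genus medians; a strain lacking a KO
contributes a copy number of zero to its genus median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HitRecord

__all__ = [
    "KOAssignment",
    "assign_kos",
    "count_paralogs",
    "genus_median_profile",
]

DEFAULT_E_MAX = 1e-8


@dataclass(frozen=True)
class KOAssignment:
    genome_id: str
    gene_id: str
    ko_id: str


def assign_kos(
    hits_per_genome: Mapping[str, Sequence[HitRecord]],
    e_max: float = DEFAULT_E_MAX,
) -> list[KOAssignment]:
    """Assign each gene the KO of its top hit, if e-value < ``e_max``.

    ``hits_per_genome`` maps genome id to that genome's hit records in file
    order.  For each gene only the first-ranked hit is consulted; the gene
    is unassigned when that hit's e-value fails the strict cutoff.  At most
    one KO per gene.
    """
    assignments: list[KOAssignment] = []
    for genome_id, hits in hits_per_genome.items():
        seen: set[str] = set()
        for hit in hits:
            if hit.query_id in seen:
                continue  # only the top hit counts, later ranks are ignored
            seen.add(hit.query_id)
            if hit.e_value < e_max:
                assignments.append(KOAssignment(genome_id, hit.query_id, hit.subject_id))
    return assignments


def count_paralogs(
    assignments: Iterable[KOAssignment],
    genomes: Sequence[str],
) -> pd.DataFrame:
    """Per-genome KO paralog counts: cell (genome, KO) = assigned gene count.

    The column set is the union of assigned KOs (sorted); genomes with no
    assignment for a KO get 0.  An assignment naming a genome outside
    ``genomes`` raises ``ValueError``.
    """
    if len(set(genomes)) != len(genomes):
        raise ValueError("duplicate genome ids")
    known = set(genomes)
    assignments = list(assignments)
    for a in assignments:
        if a.genome_id not in known:
            raise ValueError(f"unknown genome id {a.genome_id!r}")
    kos = sorted({a.ko_id for a in assignments})
    matrix = pd.DataFrame(
        np.zeros((len(genomes), len(kos)), dtype=np.int64),
        index=list(genomes),
        columns=kos,
    )
    for a in assignments:
        matrix.loc[a.genome_id, a.ko_id] += 1
    return matrix


def genus_median_profile(
    strain_matrix: pd.DataFrame,
    strain_to_genus: Mapping[str, str],
) -> pd.DataFrame:
    """Median paralog count per KO within each genus.

    Every strain row must map to exactly one genus; medians over an even
    number of strains are the midpoint of the two central values, so genus
    rows may carry half-integers.
    """
    missing = [s for s in strain_matrix.index if s not in strain_to_genus]
    if missing:
        raise ValueError(f"strains without genus assignment: {missing}")
    genus = pd.Series({s: strain_to_genus[s] for s in strain_matrix.index})
    if genus.empty:
        raise ValueError("empty strain matrix")
    profile = strain_matrix.groupby(genus).median()
    profile.index.name = None
    return profile
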