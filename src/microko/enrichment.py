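"""KO-ratio statistic and functional-unit enrichment by Fisher's exact test.

The per-KO statistic compares a focal genus against a background of other
genera:

    ratio_i = focal_median_i / mean_j(background_median_{i,j})

converted to a log2 fold-change.  KOs at or above the fold-change threshold
(default log2 fc >= 1) form the over-represented set.  Each functional unit
(KEGG module ``Mxxxxx`` or pathway ``mapxxxxx``) is then tested for
enrichment of over-represented KOs with a one-sided Fisher's exact test on

    [[C, A - C],
     [D, B - D]]

where A = KOs in the unit, B = KOs outside it, C/D = over-represented KOs
inside/outside the unit (all counted within the shared KO universe).  No
multiple-testing correction drives the significance flag; Benjamini-
Hochberg q-values are emitted as an extra column for the user.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionalUnit",
    "ContingencyTable",
    "EnrichmentResult",
    "ko_ratio",
    "overrepresented_set",
    "unit_contingency",
    "fisher_one_sided",
    "fisher_two_sided",
    "enrich_units",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class FunctionalUnit:
    """A named KO set: a KEGG module or pathway."""

    unit_id: str
    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"unit {self.unit_id}: empty member set")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts A (KOs in unit), B (outside), C (over-represented in unit),
    D (over-represented outside)."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if not (0 <= self.C <= self.A and 0 <= self.D <= self.B):
            raise ValueError(f"invalid contingency counts {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    unit_id: str
    label: str
    table: ContingencyTable
    p_value: float
    significant: bool
    over_members: tuple[str, ...] = ()
    q_value: float = math.nan


def ko_ratio(
    focal_profile: pd.Series,
    background_profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Per-KO ratio of the focal median to the mean of background medians.

    Profiles are aligned on the union of their KO columns with absent KOs
    treated as copy number 0; KOs that are zero in the focal genus and in
    every background genus are dropped from the universe.  Returns a frame
    with columns ``focal_median``, ``background_mean_of_medians``,
    ``ratio`` and ``log2fc`` (``-inf`` at ratio 0, ``+inf`` where the
    background mean is 0).
    """
    if background_profiles.shape[0] == 0:
        raise ValueError("at least one background genus is required")
    universe = focal_profile.index.union(background_profiles.columns)
    focal = focal_profile.reindex(universe, fill_value=0.0).astype(float)
    background = background_profiles.reindex(columns=universe, fill_value=0.0).astype(float)
    bg_mean = background.mean(axis=0)

    keep = (focal != 0) | (bg_mean != 0)
    focal = focal[keep]
    bg_mean = bg_mean[keep]

    with np.errstate(divide="ignore"):
        ratio = np.where(bg_mean > 0, focal / bg_mean, np.inf)
        log2fc = np.log2(ratio)  # log2(0) = -inf, log2(inf) = +inf
    return pd.DataFrame(
        {
            "focal_median": focal,
            "background_mean_of_medians": bg_mean,
            "ratio": ratio,
            "log2fc": log2fc,
        }
    )


def overrepresented_set(
    table: pd.DataFrame,
    threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    inclusive: bool = True,
) -> set[str]:
    """KOs whose log2 fold-change meets the threshold (``+inf`` qualifies).

    ``inclusive`` keeps KOs at exactly the threshold (log2 fc >= t); with
    ``inclusive=False`` the comparison is strict.
    """
    fc = table["log2fc"]
    mask = fc >= threshold if inclusive else fc > threshold
    return set(table.index[mask])


def unit_contingency(
    unit: FunctionalUnit,
    universe: Iterable[str],
    over: Iterable[str],
) -> ContingencyTable | None:
    """Contingency counts for one unit against the KO universe.

    Unit members are intersected with the universe first; a unit disjoint
    from the universe is skipped (returns ``None`` after a logged warning).
    """
    universe = set(universe)
    over = set(over)
    if not over <= universe:
        raise ValueError("over-represented set must be a subset of the universe")
    members = unit.members & universe
    a = len(members)
    if a == 0:
        logger.warning("unit %s has no KOs in the universe; skipped", unit.unit_id)
        return None
    b = len(universe) - a
    c = len(members & over)
    d = len(over - members)
    return ContingencyTable(A=a, B=b, C=c, D=d)


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (enrichment) exact p-value for ``[[C, A-C], [D, B-D]]``.

    Equals the hypergeometric upper tail P(X >= C) with population
    ``A + B``, ``C + D`` successes and ``A`` draws.
    """
    return float(stats.hypergeom.sf(t.C - 1, t.A + t.B, t.C + t.D, t.A))


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value on the same reconstructed 2x2 table."""
    _, p = stats.fisher_exact(
        [[t.C, t.A - t.C], [t.D, t.B - t.D]], alternative="two-sided"
    )
    return float(p)


def _bh_qvalues(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def enrich_units(
    units: Mapping[str, FunctionalUnit] | Sequence[FunctionalUnit],
    table: pd.DataFrame,
    threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    inclusive: bool = True,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Test every functional unit for over-represented-KO enrichment.

    Results are sorted by ascending p-value with ties broken by unit id;
    the significance flag is ``p <= alpha`` with no multiple-testing
    correction (BH q-values are attached for reference only).
    """
    if isinstance(units, Mapping):
        unit_list = list(units.values())
    else:
        unit_list = list(units)
    if not unit_list:
        raise ValueError("empty unit map")
    universe = set(table.index)
    over = overrepresented_set(table, threshold=threshold, inclusive=inclusive)

    tested: list[tuple[FunctionalUnit, ContingencyTable, float]] = []
    for unit in unit_list:
        ct = unit_contingency(unit, universe, over)
        if ct is None:
            continue
        p = fisher_two_sided(ct) if two_sided else fisher_one_sided(ct)
        tested.append((unit, ct, p))

    qvals = _bh_qvalues([p for _, _, p in tested]) if tested else np.array([])
    results = [
        EnrichmentResult(
            unit_id=unit.unit_id,
            label=unit.label,
            table=ct,
            p_value=p,
            significant=p <= alpha,
            over_members=tuple(sorted(unit.members & over)),
            q_value=float(q),
        )
        for (unit, ct, p), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.unit_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV output."""
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "label": [r.label for r in results],
            "A": [r.table.A for r in results],
            "B": [r.table.B for r in results],
            "C": [r.table.C for r in results],
            "D": [r.table.D for r in results],
            "p_value": [r.p_value for r in results],
            "bh_q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
            "over_members": [",".join(r.over_members) for r in results],
        }
    ).set_index("unit_id")


def read_unit_map(path: str) -> dict[str, FunctionalUnit]:
    """Read a unit map TSV: columns ``unit_id``, ``label``, comma-separated
    ``members``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"unit_id", "label", "members"}
    if not required <= set(df.columns):
        raise ValueError(f"unit map must have columns {sorted(required)}")
    units: dict[str, FunctionalUnit] = {}
    for _, row in df.iterrows():
        uid = row["unit_id"]
        if uid in units:
            raise ValueError(f"duplicate unit id {uid!r}")
        members = frozenset(m for m in str(row["members"]).split(",") if m)
        units[uid] = FunctionalUnit(uid, str(row["label"]), members)
    return units


def write_unit_map(units: Mapping[str, FunctionalUnit], path: str) -> None:
    rows = [
        {"unit_id": u.unit_id, "label": u.label, "members": ",".join(sorted(u.members))}
        for u in units.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
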