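"""Seeded generators for synthetic inputs with known ground truth.

Four generators cover the pipeline's input space:

* KO paralog count matrices with a planted fold-change between a focal
  strain group and background genera (Poisson counts — the minimal
  overdispersion-free model, which keeps planted fold-changes directly
  interpretable);
* per-sample genus count vectors from host-specific Dirichlet-multinomial
  distributions, including forced low-coverage samples;
* gapless nucleotide alignments evolved on a known tree under the Kimura
  2-parameter substitution model, using the exact closed-form per-branch
  transition matrices;
* reads with fully controlled per-base quality arrays for trimming tests.

Every generator is deterministic in (config, seed).  Per-strain and
per-sample randomness comes from spawned :class:`numpy.random.SeedSequence`
sub-streams, so enlarging a dataset never perturbs earlier rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import QualityRead

__all__ = [
    "KOProfileConfig",
    "HostSpec",
    "CompositionConfig",
    "SeqSimConfig",
    "SyntheticTruth",
    "simulate_ko_profiles",
    "simulate_composition",
    "simulate_sequences",
    "random_tree",
    "simulate_reads",
    "k2p_transition_matrix",
]

_BASES = np.array(list("ACGT"))
# index order A, C, G, T; transitions are A<->G (0, 2) and C<->T (1, 3)
_TRANSITION_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters emitted alongside every synthetic dataset."""

    planted_units: tuple[str, ...] = ()
    planted_fold_change: float | None = None
    strain_to_genus: dict[str, str] = field(default_factory=dict)
    host_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_to_host: dict[str, str] = field(default_factory=dict)
    low_coverage_samples: tuple[str, ...] = ()
    newick: str | None = None

    def to_json(self) -> str:
        payload = {
            "planted_units": list(self.planted_units),
            "planted_fold_change": self.planted_fold_change,
            "strain_to_genus": self.strain_to_genus,
            "host_weights": self.host_weights,
            "sample_to_host": self.sample_to_host,
            "low_coverage_samples": list(self.low_coverage_samples),
            "newick": self.newick,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# KO paralog profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KOProfileConfig:
    """Configuration for the planted-enrichment paralog simulator.

    KOs are labeled ``K00001``...; the first ``n_units * unit_size`` of them
    are partitioned into disjoint functional units ``M00001``....  Background
    strains draw every KO count from ``Poisson(background_mean)``; focal
    strains draw KOs inside ``planted_units`` from
    ``Poisson(planted_fold_change * background_mean)``.
    """

    seed: int
    n_kos: int = 2000
    n_units: int = 100
    unit_size: int = 20
    n_background_genera: int = 9
    strains_per_genus: int = 5
    n_focal_strains: int = 10
    background_mean: float = 1.0
    planted_units: tuple[str, ...] = ()
    planted_fold_change: float = 4.0
    focal_genus: str = "Gluconobacter"

    def __post_init__(self) -> None:
        if self.n_units * self.unit_size > self.n_kos:
            raise ValueError("n_units * unit_size must not exceed n_kos")
        if self.background_mean <= 0 or self.planted_fold_change <= 0:
            raise ValueError("background_mean and planted_fold_change must be > 0")
        unit_ids = {f"M{i + 1:05d}" for i in range(self.n_units)}
        missing = set(self.planted_units) - unit_ids
        if missing:
            raise ValueError(f"planted units not generated: {sorted(missing)}")


def simulate_ko_profiles(
    cfg: KOProfileConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]], SyntheticTruth]:
    """Simulate a strain x KO paralog count matrix with planted enrichment.

    Returns the count matrix, the strain -> genus map, the unit -> KO map
    and the planted truth.
    """
    ko_ids = [f"K{i + 1:05d}" for i in range(cfg.n_kos)]
    unit_map: dict[str, list[str]] = {}
    for u in range(cfg.n_units):
        unit_id = f"M{u + 1:05d}"
        unit_map[unit_id] = ko_ids[u * cfg.unit_size : (u + 1) * cfg.unit_size]

    planted_kos = np.zeros(cfg.n_kos, dtype=bool)
    for unit_id in cfg.planted_units:
        u = int(unit_id[1:]) - 1
        planted_kos[u * cfg.unit_size : (u + 1) * cfg.unit_size] = True

    strain_to_genus: dict[str, str] = {}
    strain_ids: list[str] = []
    for g in range(cfg.n_background_genera):
        genus = f"genus{g + 1:02d}"
        for s in range(cfg.strains_per_genus):
            strain = f"{genus}_s{s + 1}"
            strain_ids.append(strain)
            strain_to_genus[strain] = genus
    for s in range(cfg.n_focal_strains):
        strain = f"{cfg.focal_genus}_s{s + 1}"
        strain_ids.append(strain)
        strain_to_genus[strain] = cfg.focal_genus

    streams = np.random.SeedSequence(cfg.seed).spawn(len(strain_ids))
    rows = np.empty((len(strain_ids), cfg.n_kos), dtype=np.int64)
    for i, (strain, ss) in enumerate(zip(strain_ids, streams)):
        rng = np.random.default_rng(ss)
        mean = np.full(cfg.n_kos, cfg.background_mean)
        if strain_to_genus[strain] == cfg.focal_genus:
            mean[planted_kos] *= cfg.planted_fold_change
        rows[i] = rng.poisson(mean)

    matrix = pd.DataFrame(rows, index=strain_ids, columns=ko_ids)
    truth = SyntheticTruth(
        planted_units=tuple(cfg.planted_units),
        planted_fold_change=cfg.planted_fold_change,
        strain_to_genus=dict(strain_to_genus),
    )
    return matrix, strain_to_genus, unit_map, truth


# ---------------------------------------------------------------------------
# Genus composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostSpec:
    """One host category: sample count, Dirichlet weights, total-count range."""

    label: str
    n_samples: int
    dirichlet_weights: Mapping[str, float]
    total_range: tuple[int, int] = (5000, 20000)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"host {self.label}: n_samples must be >= 1")
        if any(w <= 0 for w in self.dirichlet_weights.values()):
            raise ValueError(f"host {self.label}: Dirichlet weights must be > 0")
        lo, hi = self.total_range
        if not (1000 <= lo <= hi):
            raise ValueError(
                f"host {self.label}: total_range must satisfy 1000 <= lo <= hi"
            )


@dataclass(frozen=True)
class CompositionConfig:
    seed: int
    hosts: tuple[HostSpec, ...]
    n_low_coverage: int = 0
    low_coverage_range: tuple[int, int] = (100, 999)

    def __post_init__(self) -> None:
        if not self.hosts:
            raise ValueError("at least one host required")
        genera = list(self.hosts[0].dirichlet_weights)
        for h in self.hosts:
            if list(h.dirichlet_weights) != genera:
                raise ValueError("all hosts must share the same genus list")
        total = sum(h.n_samples for h in self.hosts)
        if self.n_low_coverage > total:
            raise ValueError("n_low_coverage exceeds the number of samples")
        lo, hi = self.low_coverage_range
        if not (1 <= lo <= hi < 1000):
            raise ValueError("low_coverage_range must lie within [1, 999]")


def simulate_composition(
    cfg: CompositionConfig,
) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Simulate a sample x genus count table from host Dirichlet weights.

    Per sample: proportions ~ Dirichlet(host weights), counts ~
    Multinomial(total, proportions).  Exactly ``n_low_coverage`` samples
    (the first ones in sample order) receive totals below the 1,000-count
    coverage threshold.
    """
    genera = list(cfg.hosts[0].dirichlet_weights)
    sample_ids: list[str] = []
    sample_host: dict[str, str] = {}
    specs: list[HostSpec] = []
    for host in cfg.hosts:
        for i in range(host.n_samples):
            sid = f"{host.label}_{i + 1:03d}"
            sample_ids.append(sid)
            sample_host[sid] = host.label
            specs.append(host)

    streams = np.random.SeedSequence(cfg.seed).spawn(len(sample_ids))
    counts = np.zeros((len(sample_ids), len(genera)), dtype=np.int64)
    low_cov: list[str] = []
    for i, (sid, host, ss) in enumerate(zip(sample_ids, specs, streams)):
        rng = np.random.default_rng(ss)
        props = rng.dirichlet([host.dirichlet_weights[g] for g in genera])
        if i < cfg.n_low_coverage:
            lo, hi = cfg.low_coverage_range
            low_cov.append(sid)
        else:
            lo, hi = host.total_range
        total = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(total, props)

    table = pd.DataFrame(counts, index=sample_ids, columns=genera)
    truth = SyntheticTruth(
        host_weights={h.label: dict(h.dirichlet_weights) for h in cfg.hosts},
        sample_to_host=dict(sample_host),
        low_coverage_samples=tuple(low_cov),
    )
    return table, sample_host, truth


# ---------------------------------------------------------------------------
# Sequence evolution under K2P
# ---------------------------------------------------------------------------

def k2p_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """Exact K2P transition probability matrix for a branch of length ``d``.

    ``d`` is in expected substitutions per site and ``kappa`` is the
    transition/transversion rate ratio.  With per-site transition rate
    ``alpha`` and per-target transversion rate ``beta`` (``alpha = kappa *
    beta``), ``d = (alpha + 2 beta) t`` and the closed form is

        P(transition)       = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t}
        P(each transversion)= 1/4 - 1/4 e^{-4 beta t}
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if d < 0:
        raise ValueError("branch length must be >= 0")
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # per transversion target (two targets)
    p_same = 1.0 - p_ts - 2.0 * p_tv
    m = np.full((4, 4), p_tv)
    for i in range(4):
        m[i, i] = p_same
        m[i, _TRANSITION_PARTNER[i]] = p_ts
    return m


@dataclass(frozen=True)
class SeqSimConfig:
    """Tree, site count and kappa for the K2P sequence simulator.

    Base frequencies are fixed uniform (1/4 each), matching the model's
    stationary distribution.  Branch lengths are read from the tree in
    expected substitutions per site.
    """

    seed: int
    tree: dendropy.Tree
    length: int
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


def _validate_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        k = len(node.child_nodes())
        if node is tree.seed_node:
            if k not in (2, 3):
                raise ValueError(
                    f"root must have 2 (rooted) or 3 (unrooted) children, got {k}"
                )
        elif k not in (0, 2):
            raise ValueError(f"non-binary internal node with {k} children")


def simulate_sequences(cfg: SeqSimConfig) -> dict[str, str]:
    """Evolve a gapless alignment on ``cfg.tree`` under the K2P model.

    The root sequence is uniform over {A, C, G, T} per site; each branch
    applies the exact K2P transition matrix for its length.  Returns one
    sequence per leaf, keyed by leaf label, in leaf-iteration order.
    """
    _validate_binary(cfg.tree)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    root_seq = rng.integers(0, 4, size=cfg.length)
    states: dict[int, np.ndarray] = {id(cfg.tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in cfg.tree.preorder_node_iter():
        if node is cfg.tree.seed_node:
            seq = root_seq
        else:
            parent_seq = states[id(node.parent_node)]
            m = k2p_transition_matrix(node.edge.length or 0.0, cfg.kappa)
            cum = np.cumsum(m, axis=1)
            u = rng.random(cfg.length)
            seq = (u[:, None] > cum[parent_seq]).sum(axis=1)
            states[id(node)] = seq
        if node.is_leaf():
            if node.taxon is None:
                raise ValueError("leaf without a taxon label")
            out[node.taxon.label] = "".join(_BASES[seq])
    return out


# ---------------------------------------------------------------------------
# Random trees and reads
# ---------------------------------------------------------------------------

def random_tree(
    n_taxa: int,
    seed: int,
    bl_range: tuple[float, float] = (0.05, 0.5),
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Random unrooted binary tree by sequential random joins.

    Branch lengths are drawn uniformly from ``bl_range``; the result has
    ``2 n - 3`` edges.  Deterministic in (n_taxa, seed).
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    lo, hi = bl_range
    if not (0 < lo <= hi):
        raise ValueError("bl_range must satisfy 0 < lo <= hi")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    lineages = [dendropy.Node(taxon=tns.new_taxon(lb)) for lb in labels]
    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[i] = parent
        del lineages[j]
    for node in lineages:
        tree.seed_node.add_child(node)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(lo, hi))
    tree.is_rooted = False
    return tree


def simulate_reads(
    n: int,
    length: int,
    qual_pattern: int | tuple[int, int] | Sequence[int],
    seed: int,
) -> list[QualityRead]:
    """Generate reads with exactly the requested per-base quality arrays.

    ``qual_pattern`` is a constant Phred score, a ``(lo, hi)`` linear ramp,
    or an explicit per-base vector of length ``length``.  Bases are random
    (seeded); qualities are deterministic in the pattern.
    """
    if isinstance(qual_pattern, int):
        quals = tuple([qual_pattern] * length)
    elif isinstance(qual_pattern, tuple) and len(qual_pattern) == 2 and all(
        isinstance(q, int) for q in qual_pattern
    ):
        lo, hi = qual_pattern
        quals = tuple(
            int(round(lo + (hi - lo) * i / max(length - 1, 1))) for i in range(length)
        )
    else:
        quals = tuple(int(q) for q in qual_pattern)
        if len(quals) != length:
            raise ValueError("custom quality vector length must equal read length")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reads = []
    for i in range(n):
        bases = "".join(_BASES[rng.integers(0, 4, size=length)])
        reads.append(QualityRead(f"read{i + 1}", bases, quals))
    return reads
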