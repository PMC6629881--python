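"""Synthetic inputs with the statistical structure the analyses assume.

Three generator families, all pure functions of (config, seed):

* clade-structured trait-range systems (tribe level with nested genera) with
  controllable inter-clade separation, plus a species-level meristic table;
* a partially observed "fossil" drawn from a known clade with a recorded
  ground-truth label — the test bed for the best-fit engine;
* discrete character matrices evolved on a known binary tree by a symmetric
  k-state change process with one per-edge change probability, optionally
  masked to missing — the test bed for the parsimony engine.

Trait ranges live inside biologically plausible bounds (total vertebrae
20–45, fin counts in cichlid-typical windows); character evolution uses a
per-edge change probability rather than branch lengths because the
parsimony engine is branch-length-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bestfit import (
    FossilObservation,
    GroupProfile,
    ReferenceTraitTable,
    TraitRange,
)
from .charmatrix import CellState, CharacterDef, CharacterMatrix
from .trees import PhyloTree

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "ReferenceSystem",
    "gen_reference_system",
    "gen_fossil",
    "random_binary_tree",
    "gen_matrix_on_tree",
]

# plausible bounds per default trait (integer counts)
DEFAULT_TRAITS = {
    "Vt": (20, 45),  # total vertebrae incl. urostyle
    "D_spines": (7, 20),
    "D_rays": (7, 16),
    "A_spines": (3, 10),
    "A_rays": (6, 14),
    "LL": (1, 3),  # lateral-line segments
    "#Lt": (3, 6),  # lacrimal tubules
    "#Sn": (0, 3),  # supraneurals
    "VtPtLDs": (10, 18),
}


@dataclass(frozen=True)
class TraitSpec:
    name: str
    lo: int
    hi: int


@dataclass
class SimulationConfig:
    seed: int
    n_clades: int = 5
    n_genera_per_clade: int = 2
    n_species_per_genus: int = 4
    range_width: int = 3  # width of each clade's generative interval
    separation: int = 2  # gap between consecutive clade intervals (0 = identical)
    mask_fraction: float = 0.3
    traits: tuple = tuple(TraitSpec(k, lo, hi) for k, (lo, hi) in DEFAULT_TRAITS.items())

    def __post_init__(self) -> None:
        if not 0 <= self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in [0, 1]")
        if self.separation < 0 or self.range_width < 1:
            raise ValueError("separation >= 0 and range_width >= 1 required")


@dataclass
class ReferenceSystem:
    tribe_table: ReferenceTraitTable
    genus_tables: dict  # tribe name -> ReferenceTraitTable
    species: pd.DataFrame  # specimen-level meristics with tribe/genus labels
    membership: dict  # genus -> tribe


def _is_separating(spec: TraitSpec, cfg: SimulationConfig) -> bool:
    """Whether the trait's plausible bounds can host n_clades stepped-apart
    disjoint intervals at the configured width and separation."""
    need = cfg.n_clades * cfg.range_width + (cfg.n_clades - 1) * cfg.separation
    return cfg.separation > 0 and need <= (spec.hi - spec.lo + 1)


def _clade_interval(spec: TraitSpec, k: int, cfg: SimulationConfig, rng):
    """Interval for clade k.

    Separating traits (bounds wide enough) get pairwise-disjoint stepped
    intervals; narrow traits and separation 0 get clade intervals inside the
    bounds that may overlap (identical when separation is 0).
    """
    if _is_separating(spec, cfg):
        lo = spec.lo + k * (cfg.range_width + cfg.separation)
        return lo, lo + cfg.range_width - 1
    if cfg.separation == 0:
        return spec.lo, min(spec.lo + cfg.range_width - 1, spec.hi)
    width = min(cfg.range_width, spec.hi - spec.lo + 1)
    lo = int(rng.integers(spec.lo, spec.hi - width + 2))
    return lo, lo + width - 1


def gen_reference_system(config: SimulationConfig) -> ReferenceSystem:
    """Tribe- and genus-level trait tables plus a species meristic table."""
    rng = np.random.default_rng(config.seed)
    if config.separation > 0 and not any(
        _is_separating(spec, config) for spec in config.traits
    ):
        raise ValueError(
            f"no trait can host {config.n_clades} disjoint intervals at width "
            f"{config.range_width} + separation {config.separation}"
        )

    tribes, genus_tables, membership = [], {}, {}
    species_rows = []
    for k in range(config.n_clades):
        tribe_name = f"Tribe{k:02d}"
        tribe = GroupProfile(name=tribe_name, n_species=0)
        genera = []
        for spec in config.traits:
            lo, hi = _clade_interval(spec, k, config, rng)
            tribe.traits[spec.name] = TraitRange.interval(lo, hi, provenance="synthetic")
        for j in range(config.n_genera_per_clade):
            genus_name = f"Tribe{k:02d}_Gen{j}"
            genus = GroupProfile(name=genus_name, n_species=config.n_species_per_genus)
            membership[genus_name] = tribe_name
            for spec in config.traits:
                lo, hi = tribe.traits[spec.name].lo, tribe.traits[spec.name].hi
                # genus range: random subinterval of the tribe range
                glo = int(rng.integers(lo, hi + 1))
                ghi = int(rng.integers(glo, hi + 1))
                genus.traits[spec.name] = TraitRange.interval(glo, ghi, provenance="synthetic")
            for s in range(config.n_species_per_genus):
                row = {"species": f"{genus_name}_sp{s}", "genus": genus_name, "tribe": tribe_name}
                for spec in config.traits:
                    tr = genus.traits[spec.name]
                    row[spec.name] = int(rng.integers(int(tr.lo), int(tr.hi) + 1))
                species_rows.append(row)
                tribe.n_species += 1
            genera.append(genus)
        genus_tables[tribe_name] = ReferenceTraitTable(level="genus", groups=genera)
        tribes.append(tribe)
    species = pd.DataFrame(species_rows).set_index("species")
    return ReferenceSystem(
        tribe_table=ReferenceTraitTable(level="tribe", groups=tribes),
        genus_tables=genus_tables,
        species=species,
        membership=membership,
    )


def gen_fossil(
    system: ReferenceSystem, clade: str, mask_fraction: float, seed: int
):
    """Draw a species of ``clade`` and observe each trait with prob 1−mask.

    Returns (FossilObservation, true_label dict with tribe/genus/species).
    A fully masked draw yields an empty observation (downstream reports
    indeterminate).
    """
    rng = np.random.default_rng(seed)
    pool = system.species[system.species["tribe"] == clade]
    if pool.empty:
        raise KeyError(f"no species in clade {clade!r}")
    pick = pool.iloc[int(rng.integers(0, len(pool)))]
    traits = {}
    trait_names = [c for c in system.species.columns if c not in ("genus", "tribe")]
    for name in trait_names:
        if rng.random() >= mask_fraction:
            traits[name] = int(pick[name])
    truth = {"tribe": pick["tribe"], "genus": pick["genus"], "species": pick.name}
    return FossilObservation(traits=traits), truth


# ---------------------------------------------------------------------------
# Character matrices on trees
# ---------------------------------------------------------------------------

def random_binary_tree(taxa, seed: int) -> PhyloTree:
    """Uniform random unrooted binary tree by random stepwise addition."""
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    hub = n
    adj = {hub: set(order[:3])}
    for leaf in order[:3]:
        adj[leaf] = {hub}
    next_id = n + 1
    tree = PhyloTree(taxa=taxa, adj=adj)
    for leaf in order[3:]:
        edges = list(tree.edges())
        u, v = edges[int(rng.integers(0, len(edges)))]
        tree.adj[u].discard(v)
        tree.adj[v].discard(u)
        tree.adj[next_id] = {u, v, leaf}
        tree.adj[u].add(next_id)
        tree.adj[v].add(next_id)
        tree.adj[leaf] = {next_id}
        next_id += 1
    return tree


def gen_matrix_on_tree(
    tree: PhyloTree,
    n_characters: int,
    change_prob: float,
    missing_prob: float = 0.0,
    seed: int = 0,
    n_states: int = 2,
) -> CharacterMatrix:
    """Evolve unordered characters down ``tree`` with a per-edge change
    probability; mask cells to missing with ``missing_prob``."""
    if not 0 <= change_prob <= 1 or not 0 <= missing_prob <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = tree.n_taxa
    leaf_states = np.zeros((n_characters, n), dtype=int)
    root = max(tree.adj)  # any internal node
    order = tree.postorder(root)[::-1]  # preorder: parents before children
    for ch in range(n_characters):
        state = {root: int(rng.integers(0, n_states))}
        for node, parent in order:
            if parent is None:
                continue
            s = state[parent]
            if rng.random() < change_prob:
                # symmetric change to a different state
                s = int((s + 1 + rng.integers(0, n_states - 1)) % n_states)
            state[node] = s
            if node < n:
                leaf_states[ch, node] = s
    chars = [CharacterDef(index=j + 1, n_states=n_states) for j in range(n_characters)]
    cells = []
    for i in range(n):
        row = []
        for ch in range(n_characters):
            if rng.random() < missing_prob:
                row.append(CellState.missing())
            else:
                row.append(CellState.observed(int(leaf_states[ch, i])))
        cells.append(row)
    return CharacterMatrix(taxa=list(tree.taxa), characters=chars, cells=cells)
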