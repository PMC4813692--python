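"""Synthetic structures and simulated sulfo-SDA cross-link data.

Generates the inputs every other module consumes, with the statistical
structure the pipeline assumes about real photo-cross-linking data:

* toy helix-bundle Cα structures with ideal geometry (3.8 Å virtual bonds,
  1.5 Å rise and 100°/turn on a 2.3 Å helix radius), built in internal
  coordinates so bond lengths are exact;
* cross-links respecting SDA chemistry — the NHS-ester end at K/S/T/Y or
  the N terminus, the promiscuous diazirine end anywhere — with true links
  bounded by a Cα–Cα distance cutoff (20 Å by default) and a configurable
  fraction of false links drawn without any distance condition, emulating
  identifications at a 1–20% false discovery rate;
* linkage-site imprecision, the diazirine site jittered within a
  peptide-sized window;
* scored target/decoy PSM populations for exercising the FDR machinery.

Eligibility is sequence- and distance-based only; solvent accessibility is
not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mbs_search import build_coords
from .struct_analysis import CaStructure
from .xlink_data import (
    NHS_RESIDUES,
    CrossLink,
    CrossLinkMatch,
    CrossLinkSet,
    DecoyClass,
    EndChemistry,
    ResidueSite,
)

__all__ = [
    "SimulationConfig",
    "make_toy_structure",
    "simulate_sda_links",
    "corrupt_sites",
    "simulate_scored_matches",
    "helix_bundle_ss",
]

# Ideal Cα pseudo internal coordinates (radians): α-helix from the cylinder
# parametrisation above; turn values tuned once for antiparallel hairpins
# packing at ~10 Å axis separation without steric clashes.
HELIX_THETA = math.radians(90.37)
HELIX_TAU = math.radians(50.04)
TURN_THETA = math.radians(100.0)
TURN_TAU = math.radians(-80.0)


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults mirror the assumptions made for SDA cross-linking: a 20 Å
    Cα–Cα upper bound for true links, a noise fraction playing the role of
    the FDR of the identification step, and an odd site-imprecision window
    emulating uncertain diazirine placement within a peptide.
    """

    n_helices: int = 3
    helix_length: int = 12
    turn_length: int = 4
    nhs_density: float = 0.3  # fraction of K/S/T/Y residues in the sequence
    n_links: int = 110  # ~2.5 links per residue for the default 44-mer
    max_true_distance: float = 20.0
    noise_fraction: float = 0.1
    imprecision_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError(f"noise_fraction must lie in [0,1], got {self.noise_fraction}")
        if self.imprecision_window % 2 == 0 or self.imprecision_window < 1:
            raise ValueError(f"imprecision_window must be odd, got {self.imprecision_window}")
        if self.n_helices < 1 or self.helix_length < 4:
            raise ValueError("need n_helices >= 1 and helix_length >= 4")

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.helix_length + (self.n_helices - 1) * self.turn_length


def helix_bundle_ss(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (θ, τ) preference arrays for the bundle (NaN on turns).

    These serve as the secondary-structure bias for the search — the
    generator's own helix annotations, analogous to secondary-structure
    prediction feeding a fragment library.
    """
    theta, tau = _bundle_internal(config)
    theta = np.where(np.isclose(theta, HELIX_THETA), theta, np.nan)
    tau = np.where(np.isclose(tau, HELIX_TAU), tau, np.nan)
    return theta, tau


def _bundle_internal(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_residues
    theta = np.full(n - 2, HELIX_THETA)
    tau = np.full(n - 3, HELIX_TAU)
    pos = 0
    for _ in range(config.n_helices - 1):
        pos += config.helix_length
        for i in range(pos, pos + config.turn_length):
            if 0 <= i - 1 < len(theta):
                theta[i - 1] = TURN_THETA
            if 0 <= i - 2 < len(tau):
                tau[i - 2] = TURN_TAU
            if 0 <= i - 1 < len(tau):
                tau[i - 1] = TURN_TAU
        pos += config.turn_length
    return theta, tau


def make_toy_structure(config: SimulationConfig) -> tuple[CaStructure, str]:
    """Ideal-geometry helix bundle plus a sequence with NHS-reactive residues.

    The sequence scatters K/S/T/Y at ``nhs_density`` (deterministically for
    the seed); all other positions are alanine.
    """
    theta, tau = _bundle_internal(config)
    coords = build_coords(theta, tau)
    n = config.n_residues
    rng = np.random.default_rng(config.seed)
    nhs_choices = "KSTY"
    seq = [
        nhs_choices[int(rng.integers(4))] if rng.random() < config.nhs_density else "A"
        for _ in range(n)
    ]
    sequence = "".join(seq)
    structure = CaStructure(
        residue_indices=np.arange(1, n + 1),
        amino_acids=sequence,
        coords=coords,
        chain_id="A",
        source=f"toy_bundle(n_helices={config.n_helices},L={config.helix_length})",
    )
    return structure, sequence


def _eligible_nhs_sites(sequence: str) -> list[int]:
    sites = [i + 1 for i, aa in enumerate(sequence) if aa in NHS_RESIDUES]
    if 1 not in sites:
        sites.insert(0, 1)  # N terminus is always NHS-reactive
    return sorted(sites)


def simulate_sda_links(
    structure: CaStructure,
    sequence: str,
    config: SimulationConfig,
) -> CrossLinkSet:
    """Simulate a unique-residue-pair cross-link set with planted noise.

    True links are drawn uniformly without replacement from chemistry-eligible
    pairs (NHS end at K/S/T/Y or residue 1, diazirine end anywhere) whose
    Cα–Cα distance is at most ``max_true_distance``.  A ``noise_fraction`` of
    the requested links is drawn instead from all eligible pairs with no
    distance condition, emulating false identifications.  q-values are
    assigned so the noise survives a permissive (20%) FDR cut: true links
    get q ~ U(0, 0.1), false links q ~ U(0.02, 0.2).
    """
    if len(sequence) != len(structure):
        raise ValueError("sequence length must match structure")
    rng = np.random.default_rng(config.seed)
    nhs = set(_eligible_nhs_sites(sequence))
    all_res = [int(r) for r in structure.residue_indices]
    true_pool, any_pool = [], []
    seen = set()
    for i in sorted(nhs):
        for j in all_res:
            if i == j:
                continue
            pair = (min(i, j), max(i, j))
            if pair in seen:
                continue
            seen.add(pair)
            any_pool.append(pair)
            if structure.ca_distance(i, j) <= config.max_true_distance:
                true_pool.append(pair)
    n_false = int(round(config.noise_fraction * config.n_links))
    n_true = config.n_links - n_false
    if len(true_pool) < n_true:
        raise ValueError(f"only {len(true_pool)} eligible true pairs available, "
                         f"need {n_true}")
    chosen: dict[tuple[int, int], bool] = {}  # pair -> is_true
    t_idx = rng.choice(len(true_pool), size=n_true, replace=False)
    for k in t_idx:
        chosen[true_pool[k]] = True
    guard = 0
    while sum(not v for v in chosen.values()) < n_false:
        guard += 1
        if guard > 1000 * max(n_false, 1):
            raise ValueError("could not sample enough distinct false pairs")
        pair = any_pool[int(rng.integers(len(any_pool)))]
        if pair not in chosen:
            chosen[pair] = False
    links = []
    for (i, j), is_true in sorted(chosen.items()):
        q = rng.uniform(0.0, 0.10) if is_true else rng.uniform(0.02, 0.20)
        score = float(rng.normal(10.0 if is_true else 7.0, 1.0))
        nhs_first = i in nhs
        site_i = ResidueSite("toy", i, sequence[i - 1],
                             EndChemistry.NHS if nhs_first else EndChemistry.DIAZIRINE)
        site_j = ResidueSite("toy", j, sequence[j - 1],
                             EndChemistry.DIAZIRINE if nhs_first else EndChemistry.NHS)
        links.append(CrossLink(site_a=site_i, site_b=site_j, best_score=score, q_value=q))
    return CrossLinkSet(links=links, protein_length=len(sequence),
                        provenance=f"simulate_sda_links(seed={config.seed},"
                                   f"noise={config.noise_fraction})")


def corrupt_sites(
    linkset: CrossLinkSet, imprecision_window: int, seed: int = 0
) -> CrossLinkSet:
    """Jitter every diazirine site uniformly within ±(W−1)/2, clipped to the chain.

    Emulates imprecise linkage-site calling for the promiscuous photo-reactive
    end.  Pairs that collide after jittering are merged keeping the best
    score; a pair collapsing onto a single residue is dropped.
    """
    if imprecision_window % 2 == 0 or imprecision_window < 1:
        raise ValueError(f"imprecision window must be odd, got {imprecision_window}")
    half = (imprecision_window - 1) // 2
    length = linkset.protein_length
    if length is None:
        length = max(max(ln.site_a.residue_index, ln.site_b.residue_index)
                     for ln in linkset.links)
    rng = np.random.default_rng(seed)
    best: dict[tuple, CrossLink] = {}
    for ln in linkset.links:
        new_sites = []
        for site in (ln.site_a, ln.site_b):
            if site.end_chemistry is EndChemistry.DIAZIRINE and half:
                idx = int(np.clip(site.residue_index + rng.integers(-half, half + 1),
                                  1, length))
                site = ResidueSite(site.protein_id, idx, "X", site.end_chemistry)
            new_sites.append(site)
        a, b = new_sites
        if a.residue_index == b.residue_index and a.protein_id == b.protein_id:
            continue
        if (b.protein_id, b.residue_index) < (a.protein_id, a.residue_index):
            a, b = b, a
        moved = CrossLink(site_a=a, site_b=b, best_score=ln.best_score, q_value=ln.q_value)
        key = (a.protein_id, a.residue_index, b.protein_id, b.residue_index)
        prev = best.get(key)
        if prev is None or moved.best_score > prev.best_score:
            best[key] = moved
    return CrossLinkSet(links=sorted(best.values(), key=lambda ln: ln.pair),
                        protein_length=linkset.protein_length,
                        provenance=f"{linkset.provenance}|corrupt(W={imprecision_window})")


def simulate_scored_matches(
    n_true: int,
    n_false: int,
    score_gap: float = 3.0,
    seed: int = 0,
    decoy_rates: Sequence[float] = (0.25, 0.5, 0.25),
) -> list[CrossLinkMatch]:
    """Scored PSM population for exercising target-decoy FDR estimation.

    True matches are TT with scores ~ N(score_gap, 1); false matches draw
    scores ~ N(0, 1) and a TT/TD/DD label with the given rates — the
    (1/4, 1/2, 1/4) default is what independent decoy draws for the two
    peptides of a match produce.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    classes = [DecoyClass.TT, DecoyClass.TD, DecoyClass.DD]
    matches = []
    for k in range(n_true):
        matches.append(_match(f"t{k}", k, float(rng.normal(score_gap, 1.0)), DecoyClass.TT))
    for k in range(n_false):
        cls = classes[int(rng.choice(3, p=list(decoy_rates)))]
        matches.append(_match(f"f{k}", 1000 + k, float(rng.normal(0.0, 1.0)), cls))
    return matches


def _match(sid: str, k: int, score: float, cls: DecoyClass) -> CrossLinkMatch:
    return CrossLinkMatch(
        spectrum_id=sid,
        site_a=ResidueSite("sim", 2 * k + 1, "K", EndChemistry.NHS),
        site_b=ResidueSite("sim", 2 * k + 20, "X", EndChemistry.DIAZIRINE),
        score=score,
        decoy_class=cls,
    )
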