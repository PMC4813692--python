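"""Model-based conformational search guided by cross-link restraints.

A simplified, fragment-library-free re-implementation of staged model-based
search (MBS) over a coarse-grained Cα chain.  The chain lives in internal
coordinates — fixed 3.8 Å virtual bonds, pseudo bond angles θ and pseudo
torsions τ — so every move preserves geometry exactly.  The energy combines

* a soft-core steric repulsion between non-adjacent Cα pairs,
* a compaction term penalising radius of gyration beyond a length-scaled
  target,
* an optional secondary-structure bias (per-residue preferred θ/τ, the
  stand-in for fragment libraries derived from secondary-structure
  prediction), and
* the Lorentzian cross-link restraint bonus, subtracted from the energy.

Flexible loop / terminal residues can be masked: they keep only the
repulsive steric term and are excluded from compaction, bias and restraint
scoring, so disordered regions are modeled but not scored.

The search runs in stages.  Stage 1 seeds a pool with large-scale moves;
middle stages explore with 9-residue window resampling, the final stage
refines with 3-residue windows.  After each stage the pool is clustered
into *funnels* (densely sampled low-energy regions), each funnel's quality
is estimated from its five lowest-energy members after a short greedy
refinement, and sampling effort for the next stage is reallocated toward
high-quality funnels through a softmax over qualities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .restraints import DistanceRestraint, RestraintParams, score_coordinates
from .struct_analysis import CaStructure, ResidueSelection, kabsch_rmsd

__all__ = [
    "BOND_LENGTH",
    "ChainConformation",
    "EnergyTerms",
    "Funnel",
    "SearchConfig",
    "ModelRecord",
    "SearchResult",
    "initialize_pool",
    "conformation_energy",
    "propose_move",
    "cluster_pool",
    "funnel_quality",
    "reallocate",
    "run_search",
]

BOND_LENGTH = 3.8  # Å, fixed virtual Cα–Cα bond

# Ideal right-handed α-helix in Cα pseudo internal coordinates (radius 2.3 Å,
# rise 1.5 Å/residue, 100°/turn) — used by the generic move prior.
HELIX_THETA = 1.5774  # rad, ≈ 90.4°
HELIX_TAU = 0.8734  # rad, ≈ 50.0°


def build_coords(theta: np.ndarray, tau: np.ndarray, bond: float = BOND_LENGTH) -> np.ndarray:
    """Cartesian Cα coordinates from pseudo bond angles and torsions (NeRF).

    Implemented with scalar arithmetic: chain extension is inherently
    sequential and plain floats beat per-residue array operations here.
    """
    n = len(theta) + 2
    out = [(0.0, 0.0, 0.0), (bond, 0.0, 0.0)]
    if n > 2:
        t0 = float(theta[0])
        out.append((bond - bond * math.cos(t0), bond * math.sin(t0), 0.0))
    th_l = [float(v) for v in theta]
    ta_l = [float(v) for v in tau]
    for i in range(3, n):
        ax, ay, az = out[i - 3]
        bx, by, bz = out[i - 2]
        cx, cy, cz = out[i - 1]
        th, ta = th_l[i - 2], ta_l[i - 3]
        ux, uy, uz = cx - bx, cy - by, cz - bz
        un = math.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux / un, uy / un, uz / un
        vx, vy, vz = bx - ax, by - ay, bz - az
        # n = v × u (normal to the previous bond plane)
        nx = vy * uz - vz * uy
        ny = vz * ux - vx * uz
        nz = vx * uy - vy * ux
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-12:  # colinear backbone: pick an arbitrary normal
            nx, ny, nz = uy * 0.0 - uz * 0.0, uz * 1.0 - ux * 0.0, ux * 0.0 - uy * 1.0
            nx, ny, nz = 0.0, uz, -uy
            nn = math.sqrt(ny * ny + nz * nz)
            if nn < 1e-12:
                nx, ny, nz = -uz, 0.0, ux
                nn = math.sqrt(nx * nx + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        # m = n × u completes the right-handed frame (u, m, n)
        mx = ny * uz - nz * uy
        my = nz * ux - nx * uz
        mz = nx * uy - ny * ux
        st = math.sin(th)
        d0 = -bond * math.cos(th)
        d1 = bond * st * math.cos(ta)
        d2 = bond * st * math.sin(ta)
        out.append((cx + ux * d0 + mx * d1 + nx * d2,
                    cy + uy * d0 + my * d1 + ny * d2,
                    cz + uz * d0 + mz * d1 + nz * d2))
    return np.array(out)


@dataclass
class ChainConformation:
    """Coarse-grained chain state: internal coordinates + derived Cartesians.

    Residues are numbered 1..length.  Coordinates regenerate
    deterministically from (θ, τ); consecutive Cα distances are exactly the
    virtual bond length.
    """

    theta: np.ndarray  # (n-2,) radians
    tau: np.ndarray  # (n-3,) radians
    energy: Optional[float] = None
    _coords: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.theta) + 2

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = build_coords(self.theta, self.tau)
        return self._coords

    def invalidate(self) -> None:
        self._coords = None

    def to_ca_structure(self, sequence: Optional[str] = None, chain_id: str = "A") -> CaStructure:
        n = self.length
        return CaStructure(
            residue_indices=np.arange(1, n + 1),
            amino_acids=(sequence or "X" * n),
            coords=self.coords.copy(),
            chain_id=chain_id,
            source="mbs_search",
        )


@dataclass
class EnergyTerms:
    """Weights and parameters of the coarse-grained scoring function.

    ``ss_theta``/``ss_tau`` hold per-residue preferred pseudo angles in
    radians (NaN = no preference); they play the role of secondary-structure
    information that fragment libraries would otherwise inject.
    """

    steric_weight: float = 1.0
    hard_core: float = 4.0  # Å, Cα soft-core diameter for |i-j| >= 2
    compaction_weight: float = 0.5
    rg_target: Optional[float] = None  # Å; None → 2.2 * N**0.38
    bias_weight: float = 0.0
    ss_theta: Optional[np.ndarray] = None
    ss_tau: Optional[np.ndarray] = None
    restraint_weight: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.steric_weight, self.compaction_weight, self.bias_weight,
                  self.restraint_weight):
            if w < 0:
                raise ValueError("energy weights must be >= 0")


def _rg_target(n: int, terms: EnergyTerms) -> float:
    return terms.rg_target if terms.rg_target is not None else 2.2 * n ** 0.38


class _Scorer:
    """Precomputed scoring context for one (terms, restraints, mask) triple."""

    def __init__(
        self,
        n: int,
        terms: EnergyTerms,
        restraints: Sequence[DistanceRestraint],
        mask: Optional[ResidueSelection],
    ) -> None:
        self.n = n
        self.terms = terms
        masked = np.zeros(n, dtype=bool)
        if mask is not None:
            for r in range(1, n + 1):
                masked[r - 1] = mask.contains(r)
        self.unmasked = ~masked
        pairs = []
        for r in restraints:
            if not (1 <= r.residue_i <= n and 1 <= r.residue_j <= n):
                raise KeyError(f"restrained residue {r.residue_i}-{r.residue_j} "
                               f"outside chain of length {n}")
            if masked[r.residue_i - 1] or masked[r.residue_j - 1]:
                continue  # masked residues carry no restraint bonus
            pairs.append((r.residue_i - 1, r.residue_j - 1))
        self.pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self.rparams = restraints[0].params if restraints else RestraintParams()
        # steric pair pre-selection: all |i-j| >= 2 pairs
        iu = np.triu_indices(n, k=2)
        self._steric_rows = iu
        bt = terms.ss_theta
        self.bias_theta = None if bt is None else np.asarray(bt, dtype=float)
        btau = terms.ss_tau
        self.bias_tau = None if btau is None else np.asarray(btau, dtype=float)
        self.rg_target = _rg_target(int(self.unmasked.sum()) or n, terms)

    def energy(self, conf: ChainConformation) -> tuple[float, float, int]:
        """Return (energy, restraint_bonus, n_satisfied)."""
        t = self.terms
        coords = conf.coords
        e = 0.0
        if t.steric_weight > 0:
            d = coords[self._steric_rows[0]] - coords[self._steric_rows[1]]
            dist = np.sqrt((d * d).sum(axis=1))
            overlap = t.hard_core - dist
            np.clip(overlap, 0.0, None, out=overlap)
            e += t.steric_weight * float((overlap * overlap).sum())
        sub = coords[self.unmasked]
        if t.compaction_weight > 0 and len(sub) >= 2:
            c = sub - sub.mean(axis=0)
            rg = math.sqrt(float((c * c).sum()) / len(sub))
            excess = rg - self.rg_target
            if excess > 0:  # only expansion is penalised; steric resists collapse
                e += t.compaction_weight * excess * excess
        if t.bias_weight > 0:
            if self.bias_theta is not None:
                dv = conf.theta - self.bias_theta
                ok = np.isfinite(dv) & self.unmasked[1:-1]
                e += t.bias_weight * float((dv[ok] ** 2).sum())
            if self.bias_tau is not None:
                dv = np.mod(conf.tau - self.bias_tau + math.pi, 2 * math.pi) - math.pi
                ok = np.isfinite(dv) & self.unmasked[1:-2] & self.unmasked[2:-1]
                e += t.bias_weight * float((dv[ok] ** 2).sum())
        bonus, n_sat = score_coordinates(coords, self.pairs, self.rparams)
        e -= t.restraint_weight * bonus
        return e, bonus, n_sat


def conformation_energy(
    c: ChainConformation,
    terms: EnergyTerms,
    restraints: Sequence[DistanceRestraint] = (),
    mask: Optional[ResidueSelection] = None,
) -> float:
    """Coarse-grained energy of a conformation (lower is better)."""
    return _Scorer(c.length, terms, restraints, mask).energy(c)[0]


def _sample_angles(
    k_theta: int, k_tau: int, rng: np.random.Generator,
    bias_theta: Optional[np.ndarray] = None, bias_tau: Optional[np.ndarray] = None,
    p_local: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (θ, τ) window values from the move prior.

    With per-residue preferences available, each position is drawn near its
    preference with probability ``p_local`` (narrow Gaussian), otherwise from
    a generic mixture of helix-like and extended geometry.
    """
    theta = np.empty(k_theta)
    tau = np.empty(k_tau)
    for k in range(k_theta):
        pref = bias_theta[k] if bias_theta is not None else math.nan
        if math.isfinite(pref) and rng.random() < p_local:
            theta[k] = rng.normal(pref, 0.10)
        elif rng.random() < 0.5:
            theta[k] = rng.normal(HELIX_THETA, 0.15)
        else:
            theta[k] = rng.uniform(math.radians(75), math.radians(150))
    for k in range(k_tau):
        pref = bias_tau[k] if bias_tau is not None else math.nan
        if math.isfinite(pref) and rng.random() < p_local:
            tau[k] = rng.normal(pref, 0.18)
        elif rng.random() < 0.5:
            tau[k] = rng.normal(HELIX_TAU, 0.25)
        else:
            tau[k] = rng.uniform(-math.pi, math.pi)
    np.clip(theta, math.radians(45), math.radians(175), out=theta)
    return theta, tau


def propose_move(
    c: ChainConformation,
    stage: int,
    rng: np.random.Generator,
    n_stages: int = 6,
    terms: Optional[EnergyTerms] = None,
    polish_sigma: float = 0.06,
) -> ChainConformation:
    """Resample the internal coordinates of one contiguous window.

    Window length follows the stage schedule: any length up to the whole
    chain in stage 1 (pivot-scale moves), 9 residues in the middle stages,
    and 3 residues in the final stage.  In the final stage half of the
    proposals are *polish* moves — small Gaussian perturbations of the
    current window angles — so trajectories can descend into their basin
    instead of only jumping between prior draws.  Bond lengths are
    untouched.
    """
    if not 1 <= stage <= n_stages:
        raise ValueError(f"stage {stage} outside [1, {n_stages}]")
    n = c.length
    final = stage == n_stages
    if stage == 1:
        wlen = int(rng.integers(3, n + 1))
    elif final:
        wlen = 3
    else:
        wlen = 9
    wlen = min(wlen, n)
    start = int(rng.integers(0, n - wlen + 1))  # 0-based residue window [start, start+wlen)
    lo_t = max(0, start - 1)
    hi_t = min(len(c.theta), start + wlen - 1)
    lo_p = max(0, start - 2)
    hi_p = min(len(c.tau), start + wlen - 2)
    new_theta = c.theta.copy()
    new_tau = c.tau.copy()
    if final and rng.random() < 0.5:
        new_theta[lo_t:hi_t] += rng.normal(0.0, polish_sigma, hi_t - lo_t)
        np.clip(new_theta, math.radians(45), math.radians(175), out=new_theta)
        new_tau[lo_p:hi_p] += rng.normal(0.0, polish_sigma, hi_p - lo_p)
    else:
        bt = (terms.ss_theta[lo_t:hi_t]
              if terms is not None and terms.ss_theta is not None else None)
        bp = (terms.ss_tau[lo_p:hi_p]
              if terms is not None and terms.ss_tau is not None else None)
        th, ta = _sample_angles(hi_t - lo_t, hi_p - lo_p, rng, bt, bp)
        new_theta[lo_t:hi_t] = th
        new_tau[lo_p:hi_p] = ta
    return ChainConformation(theta=new_theta, tau=new_tau)


def initialize_pool(config: "SearchConfig") -> list[ChainConformation]:
    """Seed pool of random-prior conformations (reproducible for a seed)."""
    if config.length < 10:
        raise ValueError(f"chain length must be >= 10, got {config.length}")
    rng = np.random.default_rng(config.seed)
    pool = []
    for _ in range(config.structures_per_stage):
        th, ta = _sample_angles(config.length - 2, config.length - 3, rng)
        pool.append(ChainConformation(theta=th, tau=ta))
    return pool


@dataclass
class Funnel:
    """A cluster of similar low-energy conformations."""

    member_ids: list[int]
    representative: int  # id of the lowest-energy member
    quality: Optional[float] = None
    allocation: float = 0.0


@dataclass
class SearchConfig:
    length: int = 40
    n_stages: int = 6
    structures_per_stage: int = 200  # production scale: 5000
    cluster_cutoff: float = 4.0  # Å selected-Cα RMSD
    masked: Optional[ResidueSelection] = None
    seed: int = 0
    moves_per_structure: int = 40
    temp_initial: float = 2.5
    temp_final: float = 0.4
    alloc_temperature: float = 1.0
    refine_moves: int = 25
    refine_margin: float = 15.0  # energy window above the best funnel worth refining

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.structures_per_stage < 10:
            raise ValueError("structures_per_stage must be >= 10")

    def stage_temperature(self, stage: int) -> float:
        if self.n_stages == 1:
            return self.temp_final
        frac = (stage - 1) / (self.n_stages - 1)
        return self.temp_initial * (self.temp_final / self.temp_initial) ** frac


@dataclass
class ModelRecord:
    """One sampled conformation with its provenance and scores."""

    model_id: int
    conformation: ChainConformation
    energy: float  # full search energy (restraint bonus subtracted)
    stage: int
    funnel_id: int = -1
    restraint_bonus: float = 0.0
    n_satisfied: int = 0
    physics_energy: float = 0.0  # energy with the restraint term removed


@dataclass
class SearchResult:
    records: list[ModelRecord]
    funnels: list[Funnel]
    config: SearchConfig

    def __len__(self) -> int:
        return len(self.records)

    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])


def cluster_pool(
    pool: Sequence[ChainConformation],
    cutoff: float,
    energies: Optional[Sequence[float]] = None,
    selection: Optional[ResidueSelection] = None,
) -> list[Funnel]:
    """Greedy leader clustering by selected-Cα RMSD, visiting by energy.

    Conformations are visited in order of increasing energy; each joins the
    first funnel whose representative lies within ``cutoff`` RMSD, otherwise
    it founds a new funnel.  Deterministic for a given pool.
    """
    if not pool:
        raise ValueError("cannot cluster an empty pool")
    if energies is None:
        energies = [c.energy if c.energy is not None else 0.0 for c in pool]
    order = sorted(range(len(pool)), key=lambda k: (energies[k], k))
    if selection is None:
        sel_idx = np.arange(pool[0].length)
    else:
        sel_idx = np.array([r - 1 for r in selection.indices() if 1 <= r <= pool[0].length])
    funnels: list[Funnel] = []
    reps: list[np.ndarray] = []
    for k in order:
        xyz = pool[k].coords[sel_idx]
        placed = False
        for f, rep in zip(funnels, reps):
            if kabsch_rmsd(xyz, rep) <= cutoff:
                f.member_ids.append(k)
                placed = True
                break
        if not placed:
            funnels.append(Funnel(member_ids=[k], representative=k))
            reps.append(xyz)
    return funnels


def _greedy_refine(
    conf: ChainConformation,
    scorer: _Scorer,
    rng: np.random.Generator,
    n_moves: int,
    n_stages: int,
    terms: EnergyTerms,
) -> float:
    """Short greedy (downhill-only) refinement; returns the refined energy."""
    cur = conf
    e_cur = scorer.energy(cur)[0]
    for _ in range(n_moves):
        cand = propose_move(cur, n_stages, rng, n_stages=n_stages, terms=terms)
        e_new = scorer.energy(cand)[0]
        if e_new <= e_cur:
            cur, e_cur = cand, e_new
    return e_cur


def funnel_quality(
    funnel: Funnel,
    pool: Sequence[ChainConformation],
    terms: EnergyTerms,
    restraints: Sequence[DistanceRestraint] = (),
    mask: Optional[ResidueSelection] = None,
    rng: Optional[np.random.Generator] = None,
    refine_moves: int = 25,
    n_stages: int = 6,
) -> float:
    """Mean refined energy of the funnel's five lowest-energy members."""
    if not funnel.member_ids:
        raise ValueError("funnel has no members")
    rng = rng or np.random.default_rng(0)
    scorer = _Scorer(pool[funnel.member_ids[0]].length, terms, restraints, mask)
    members = sorted(
        funnel.member_ids,
        key=lambda k: pool[k].energy if pool[k].energy is not None else scorer.energy(pool[k])[0],
    )[:5]
    refined = [_greedy_refine(pool[k], scorer, rng, refine_moves, n_stages, terms)
               for k in members]
    funnel.quality = float(np.mean(refined))
    return funnel.quality


def reallocate(funnels: Sequence[Funnel], alloc_temperature: float) -> list[Funnel]:
    """Softmax sampling weights over funnel qualities (lower quality value = better).

    weight_i ∝ exp(−quality_i / T), normalised to sum to one.
    """
    if alloc_temperature <= 0:
        raise ValueError(f"alloc_temperature must be > 0, got {alloc_temperature}")
    qs = np.array([f.quality for f in funnels], dtype=float)
    if np.any(~np.isfinite(qs)):
        raise ValueError("all funnel qualities must be computed before reallocation")
    z = -(qs - qs.min()) / alloc_temperature
    w = np.exp(z)
    w /= w.sum()
    for f, wi in zip(funnels, w):
        f.allocation = float(wi)
    return list(funnels)


def polish_ensemble(
    result: "SearchResult",
    terms: EnergyTerms,
    restraints: Sequence[DistanceRestraint] = (),
    mask: Optional[ResidueSelection] = None,
    n_candidates: int = 20,
    n_moves: int = 400,
    sigma: float = 0.05,
    temperature: float = 0.1,
    seed: int = 0,
) -> "SearchResult":
    """Low-temperature local polish of the lowest-energy conformations.

    The stage moves resample windows from the prior, which explores basins
    but rarely reaches their floors.  This pass takes the ``n_candidates``
    lowest-energy structures and runs each through a Metropolis trajectory
    of small Gaussian angle perturbations (σ ≈ 0.05 rad) at low
    temperature, appending the polished structures to the result (tagged
    with the final stage and their origin's funnel).  Run between search
    and selection; the original ensemble is kept intact.
    """
    rng = np.random.default_rng(seed)
    scorer = _Scorer(result.config.length, terms, restraints, mask)
    order = np.argsort([r.energy for r in result.records])[:n_candidates]
    base = len(result.records)
    n_stages = result.config.n_stages
    for k, idx in enumerate(order):
        origin = result.records[int(idx)]
        cur = ChainConformation(theta=origin.conformation.theta.copy(),
                                tau=origin.conformation.tau.copy())
        e_cur = scorer.energy(cur)[0]
        for _ in range(n_moves):
            th, ta = cur.theta.copy(), cur.tau.copy()
            w = int(rng.integers(1, 4))
            i = int(rng.integers(0, len(th)))
            th[i:i + w] += rng.normal(0.0, sigma, len(th[i:i + w]))
            np.clip(th, math.radians(45), math.radians(175), out=th)
            j = int(rng.integers(0, len(ta)))
            ta[j:j + w] += rng.normal(0.0, sigma, len(ta[j:j + w]))
            cand = ChainConformation(theta=th, tau=ta)
            e_new = scorer.energy(cand)[0]
            if e_new <= e_cur or rng.random() < math.exp(-(e_new - e_cur) / temperature):
                cur, e_cur = cand, e_new
        cur.energy = e_cur
        _, bonus, n_sat = scorer.energy(cur)
        result.records.append(ModelRecord(
            model_id=base + k,
            conformation=cur,
            energy=e_cur,
            stage=n_stages,
            funnel_id=origin.funnel_id,
            restraint_bonus=bonus,
            n_satisfied=n_sat,
            physics_energy=e_cur + terms.restraint_weight * bonus,
        ))
        for f in result.funnels:
            if f.member_ids and origin.model_id in f.member_ids:
                f.member_ids.append(base + k)
                break
    return result


def run_search(
    config: SearchConfig,
    terms: EnergyTerms,
    restraints: Sequence[DistanceRestraint] = (),
) -> SearchResult:
    """Run the full staged search; returns every sampled conformation.

    Stage 1 is the seed pool from :func:`initialize_pool` pushed through a
    short Metropolis run each.  Later stages start trajectories from members
    of funnels drawn according to the allocation weights.  Structures from
    every stage are retained in the result.
    """
    rng = np.random.default_rng(config.seed)
    scorer = _Scorer(config.length, terms, restraints, config.masked)
    records: list[ModelRecord] = []
    funnels: list[Funnel] = []
    pool_confs: list[ChainConformation] = []  # current stage pool for clustering

    def metropolis(start: ChainConformation, stage: int, temp: float) -> ChainConformation:
        cur = start
        e_cur = scorer.energy(cur)[0]
        for _ in range(config.moves_per_structure):
            cand = propose_move(cur, stage, rng, n_stages=config.n_stages, terms=terms)
            e_new = scorer.energy(cand)[0]
            if e_new <= e_cur or rng.random() < math.exp(-(e_new - e_cur) / temp):
                cur, e_cur = cand, e_new
        cur.energy = e_cur
        return cur

    prev_pool: list[ChainConformation] = []
    prev_funnels: list[Funnel] = []
    for stage in range(1, config.n_stages + 1):
        temp = config.stage_temperature(stage)
        stage_pool: list[ChainConformation] = []
        if stage == 1:
            seeds = initialize_pool(config)
            for s in seeds:
                stage_pool.append(metropolis(s, stage, temp))
        else:
            alloc = np.array([f.allocation for f in prev_funnels])
            for _ in range(config.structures_per_stage):
                fidx = int(rng.choice(len(prev_funnels), p=alloc))
                member = prev_funnels[fidx].member_ids[
                    int(rng.integers(len(prev_funnels[fidx].member_ids)))]
                start = replace(prev_pool[member])
                start.invalidate()
                stage_pool.append(metropolis(start, stage, temp))
        stage_funnels = cluster_pool(
            stage_pool, config.cluster_cutoff,
            energies=[c.energy for c in stage_pool],
        )
        # Refinement sharpens the quality estimate only where it can matter:
        # funnels whose raw five-best mean is hopelessly above the best funnel
        # keep the unrefined estimate (their allocation weight is ~0 anyway).
        raw_means = []
        for f in stage_funnels:
            five = sorted(stage_pool[k].energy for k in f.member_ids)[:5]
            raw_means.append(float(np.mean(five)))
        best_raw = min(raw_means)
        for f, raw in zip(stage_funnels, raw_means):
            if raw <= best_raw + config.refine_margin:
                funnel_quality(f, stage_pool, terms, restraints, config.masked,
                               rng=rng, refine_moves=config.refine_moves,
                               n_stages=config.n_stages)
            else:
                f.quality = raw
        reallocate(stage_funnels, config.alloc_temperature)
        base_id = len(records)
        fid_offset = len(funnels)
        member_to_funnel = {}
        for fi, f in enumerate(stage_funnels):
            for m in f.member_ids:
                member_to_funnel[m] = fid_offset + fi
        for k, conf in enumerate(stage_pool):
            _, bonus, n_sat = scorer.energy(conf)
            records.append(ModelRecord(
                model_id=base_id + k,
                conformation=conf,
                energy=float(conf.energy),
                stage=stage,
                funnel_id=member_to_funnel[k],
                restraint_bonus=bonus,
                n_satisfied=n_sat,
                physics_energy=float(conf.energy) + terms.restraint_weight * bonus,
            ))
        # re-key funnel member ids to global model ids before archiving
        archived = []
        for f in stage_funnels:
            archived.append(Funnel(
                member_ids=[base_id + m for m in f.member_ids],
                representative=base_id + f.representative,
                quality=f.quality,
                allocation=f.allocation,
            ))
        funnels.extend(archived)
        prev_pool, prev_funnels = stage_pool, stage_funnels
    return SearchResult(records=records, funnels=funnels, config=config)
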