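"""Lorentzian distance restraints derived from cross-links.

A cross-link between residues i and j bounds their Cα–Cα distance: for the
SDA linker the satisfied band is l = 1.5 Å < d ≤ u = 20 Å.  Instead of a
harmonic penalty that would let a handful of false links dominate the energy,
a bounded Lorentzian *bonus* is awarded:

    E(d) = E_max * w^2 / (w^2 + v(d)^2)

where v(d) is the violation (0 inside the band, distance past the nearer
bound outside) and w is the half-width — the violation at which E_max/2 is
still rewarded.  A restraint violated by much more than 2w contributes almost
nothing, so grossly false links are effectively ignored and the term drives
the search to maximise the *number* of satisfied restraints rather than to
fit exact distances.  The bonus is subtracted from the search energy (lower
energy = better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .struct_analysis import CaStructure
    from .xlink_data import CrossLinkSet

__all__ = [
    "RestraintParams",
    "DistanceRestraint",
    "violation",
    "restraint_bonus",
    "restraint_score",
    "links_to_restraints",
    "write_restraints",
    "read_restraints",
]


@dataclass(frozen=True)
class RestraintParams:
    """Bounds and shape of the Lorentzian restraint term (Å / energy units)."""

    l: float = 1.5
    u: float = 20.0
    w: float = 1.0
    e_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.l < self.u:
            raise ValueError(f"need 0 <= l < u, got l={self.l}, u={self.u}")
        if self.w <= 0:
            raise ValueError(f"half-width w must be > 0, got {self.w}")
        if self.e_max <= 0:
            raise ValueError(f"E_max must be > 0, got {self.e_max}")


@dataclass(frozen=True)
class DistanceRestraint:
    residue_i: int
    residue_j: int
    params: RestraintParams = field(default_factory=RestraintParams)

    def __post_init__(self) -> None:
        if self.residue_i == self.residue_j:
            raise ValueError(f"restraint needs two distinct residues, got {self.residue_i}")


def violation(d: float, params: RestraintParams) -> float:
    """Distance by which d falls outside the satisfied band (0 inside).

    Returns l - d below the band and d - u above it.  d == l sits on the
    band edge with violation 0 (the continuous limit); the satisfied *count*
    in :func:`restraint_score` uses the strict condition l < d <= u.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d <= params.l:
        return params.l - d
    if d > params.u:
        return d - params.u
    return 0.0


def restraint_bonus(d: float, params: RestraintParams) -> float:
    """Lorentzian energy bonus E_max·w²/(w² + v²) for a single distance."""
    v = violation(d, params)
    w2 = params.w * params.w
    return params.e_max * w2 / (w2 + v * v)


def _bonus_vec(d: np.ndarray, params: RestraintParams) -> np.ndarray:
    v = np.where(d <= params.l, params.l - d, np.where(d > params.u, d - params.u, 0.0))
    w2 = params.w * params.w
    return params.e_max * w2 / (w2 + v * v)


def restraint_score(
    structure: "CaStructure", restraints: Sequence[DistanceRestraint]
) -> tuple[float, int]:
    """Total Lorentzian bonus and satisfied count over a Cα structure.

    A restraint counts as satisfied when l < d <= u.  Raises a lookup error
    naming the residue when a restrained residue is absent.
    """
    total = 0.0
    n_sat = 0
    for r in restraints:
        d = structure.ca_distance(r.residue_i, r.residue_j)
        total += restraint_bonus(d, r.params)
        if r.params.l < d <= r.params.u:
            n_sat += 1
    return total, n_sat


def score_coordinates(
    coords: np.ndarray,
    pairs: np.ndarray,
    params: RestraintParams,
) -> tuple[float, int]:
    """Vectorised restraint score over 0-based index pairs into ``coords``."""
    if len(pairs) == 0:
        return 0.0, 0
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    d = np.sqrt((diff * diff).sum(axis=1))
    bonus = _bonus_vec(d, params)
    n_sat = int(((d > params.l) & (d <= params.u)).sum())
    return float(bonus.sum()), n_sat


def links_to_restraints(
    links: "CrossLinkSet", params: RestraintParams | None = None
) -> list[DistanceRestraint]:
    """One Cα–Cα restraint per unique cross-linked residue pair."""
    params = params or RestraintParams()
    out = []
    for ln in links:
        i, j = ln.pair
        if i == j:
            continue  # zero-length self link carries no distance information
        out.append(DistanceRestraint(i, j, params))
    return out


def write_restraints(restraints: Iterable[DistanceRestraint], path: str | Path) -> None:
    """Serialise to the plain 4-column text form: i  j  upper_bound  weight."""
    with Path(path).open("w") as fh:
        for r in restraints:
            fh.write(f"{r.residue_i}\t{r.residue_j}\t{r.params.u:g}\t{r.params.e_max:g}\n")


def read_restraints(path: str | Path, params: RestraintParams | None = None) -> list[DistanceRestraint]:
    """Read the 4-column text form written by :func:`write_restraints`."""
    base = params or RestraintParams()
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
        i, j, u, e_max = int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3])
        out.append(DistanceRestraint(i, j, RestraintParams(l=base.l, u=u, w=base.w, e_max=e_max)))
    return out
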