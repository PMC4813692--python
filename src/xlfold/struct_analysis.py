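"""Reference-structure handling and cross-link validation analyses.

Covers the structural side of a cross-link study: reading a Cα trace from a
PDB file, Cα–Cα distances for linked pairs, optimal-superposition RMSD over
residue selections, and three checks of cross-link data quality against a
structure:

* the distance distribution of identified links versus a chemistry-matched
  random (decoy surrogate) distribution,
* robustness of the distance distribution to linkage-site imprecision
  (random local shifts of the promiscuous photo-reactive end within a
  window of residues), and
* the helical-wheel test: linkage sites clustered on one face of a helix
  (angles at 100°/residue spanning an arc ≤ 180°) indicate α-helical
  secondary structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import gemmi
import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

if TYPE_CHECKING:  # pragma: no cover
    from .xlink_data import CrossLinkSet

__all__ = [
    "CaStructure",
    "ResidueSelection",
    "DistanceDistribution",
    "ShiftAnalysisResult",
    "read_ca_structure",
    "write_ca_pdb",
    "ca_distance",
    "link_distance_distribution",
    "decoy_distance_distribution",
    "superpose_rmsd",
    "site_shift_analysis",
    "helix_wheel_arc",
]

NHS_RESIDUES = frozenset("KSTY")


@dataclass
class CaStructure:
    """An ordered Cα trace: residue indices, one-letter codes and coordinates."""

    residue_indices: np.ndarray  # (n,) int, strictly increasing
    amino_acids: str  # length n, one-letter codes ('X' when unknown)
    coords: np.ndarray  # (n, 3) float, Å
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_indices), 3):
            raise ValueError("coords must be (n, 3) matching residue_indices")
        if len(self.amino_acids) != len(self.residue_indices):
            raise ValueError("amino_acids length must match residue count")
        if np.any(np.diff(self.residue_indices) <= 0):
            raise ValueError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self._pos = {int(r): k for k, r in enumerate(self.residue_indices)}

    def __len__(self) -> int:
        return len(self.residue_indices)

    @property
    def sequence(self) -> str:
        return self.amino_acids

    def has_residue(self, index: int) -> bool:
        return index in self._pos

    def xyz(self, index: int) -> np.ndarray:
        try:
            return self.coords[self._pos[index]]
        except KeyError:
            raise KeyError(f"residue {index} not present in structure "
                           f"(chain {self.chain_id}, {len(self)} residues)") from None

    def ca_distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.xyz(i) - self.xyz(j)))

    def subset(self, selection: "ResidueSelection") -> "CaStructure":
        mask = np.array([selection.contains(int(r)) for r in self.residue_indices])
        return CaStructure(
            residue_indices=self.residue_indices[mask],
            amino_acids="".join(c for c, m in zip(self.amino_acids, mask) if m),
            coords=self.coords[mask],
            chain_id=self.chain_id,
            source=self.source,
        )


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive residue-index intervals, textual form ``"a-b:c-d"``.

    En dashes are accepted in place of hyphens.  Intervals must be ascending
    and non-overlapping.
    """

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for a, b in self.ranges:
            if a > b:
                raise ValueError(f"interval {a}-{b} is inverted")
            if prev_end is not None and a <= prev_end:
                raise ValueError("intervals must be ascending and non-overlapping")
            prev_end = b

    @classmethod
    def parse(cls, text: str) -> "ResidueSelection":
        ranges = []
        for part in re.split(r"[:,]", text.strip()):
            m = re.fullmatch(r"\s*(\d+)\s*[-–]\s*(\d+)\s*", part)
            if m:
                ranges.append((int(m.group(1)), int(m.group(2))))
            else:
                m1 = re.fullmatch(r"\s*(\d+)\s*", part)
                if not m1:
                    raise ValueError(f"cannot parse selection component {part!r}")
                ranges.append((int(m1.group(1)), int(m1.group(1))))
        return cls(tuple(ranges))

    def contains(self, index: int) -> bool:
        return any(a <= index <= b for a, b in self.ranges)

    def indices(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out

    def __str__(self) -> str:
        return ":".join(f"{a}-{b}" for a, b in self.ranges)


@dataclass
class DistanceDistribution:
    """Sorted Cα–Cα distances with summary statistics."""

    values: np.ndarray
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if len(self.values) and self.values[0] < 0:
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))

    def summary(self) -> dict:
        return {
            "n": len(self.values),
            "median": self.median,
            "p5": self.percentile(5),
            "p95": self.percentile(95),
            "max": float(self.values[-1]) if len(self.values) else float("nan"),
            "n_unmapped": self.n_unmapped,
        }


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}
_AA1TO3["X"] = "UNK"


def read_ca_structure(
    path: str | Path, chain: str = "A", model: int = 0, offset: int = 0
) -> CaStructure:
    """Read one Cα per residue from a PDB file (first model by default).

    Altloc 'A' is preferred, then blank.  Residues lacking a Cα are skipped
    (their count is recorded in ``source``).  ``offset`` is added to PDB
    residue numbers to reconcile PDB and sequence numbering.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    mdl = st[model]
    names = [ch.name for ch in mdl]
    if chain not in names:
        raise KeyError(f"chain {chain!r} not in {Path(path).name}; available: {names}")
    ch = mdl[chain]
    idx, aas, xyz = [], [], []
    skipped = 0
    for res in ch:
        ca = None
        for atom in res:
            if atom.name == "CA":
                if atom.altloc in ("", " ", "\0", "A"):
                    ca = atom
                    if atom.altloc == "A":
                        break
        if ca is None:
            skipped += 1
            continue
        num = res.seqid.num + offset
        if idx and num <= idx[-1]:
            continue  # duplicate/inserted residue numbering; keep first occurrence
        idx.append(num)
        aas.append(_AA3TO1.get(res.name.upper(), "X"))
        xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
    return CaStructure(
        residue_indices=np.array(idx, dtype=int),
        amino_acids="".join(aas),
        coords=np.array(xyz, dtype=float).reshape(-1, 3),
        chain_id=chain,
        source=f"{Path(path).name}:{chain} (skipped_no_ca={skipped})",
    )


def write_ca_pdb(structures: "CaStructure | Sequence[CaStructure]", path: str | Path) -> None:
    """Write one or more Cα traces as a (multi-MODEL) PDB file."""
    if isinstance(structures, CaStructure):
        structures = [structures]
    lines = []
    multi = len(structures) > 1
    for mnum, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {mnum:4d}")
        for k, (ri, aa) in enumerate(zip(s.residue_indices, s.amino_acids), start=1):
            x, y, z = s.coords[k - 1]
            res3 = _AA1TO3.get(aa, "UNK")
            lines.append(
                f"ATOM  {k:5d}  CA  {res3:>3s} {s.chain_id[:1]}{int(ri):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def ca_distance(s: CaStructure, i: int, j: int) -> float:
    """Euclidean Cα–Cα distance between residues i and j."""
    return s.ca_distance(i, j)


def link_distance_distribution(s: CaStructure, links: "CrossLinkSet") -> DistanceDistribution:
    """Cα–Cα distance of every mappable cross-link in the structure."""
    vals = []
    unmapped = 0
    for ln in links:
        i, j = ln.site_a.residue_index, ln.site_b.residue_index
        if s.has_residue(i) and s.has_residue(j):
            vals.append(s.ca_distance(i, j))
        else:
            unmapped += 1
    if not vals:
        raise ValueError(f"no links mappable onto structure ({unmapped} unmapped)")
    return DistanceDistribution(values=np.array(vals), n_unmapped=unmapped)


def decoy_distance_distribution(
    s: CaStructure,
    n: int,
    sequence: Optional[str] = None,
    min_separation: int = 0,
    seed: int = 0,
) -> DistanceDistribution:
    """Distance distribution of n random chemistry-respecting residue pairs.

    A surrogate for decoy-database hits: the NHS end is drawn from K/S/T/Y
    sites (or the N terminus) and the diazirine end from any residue, with
    sequence separation > ``min_separation``.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = sequence if sequence is not None else s.amino_acids
    rng = np.random.default_rng(seed)
    res = s.residue_indices
    nhs = [int(r) for k, r in enumerate(res)
           if (k < len(seq) and seq[k] in NHS_RESIDUES) or int(r) == int(res[0])]
    if not nhs:
        raise ValueError("no eligible NHS-end sites (K/S/T/Y or N terminus) in structure")
    pairs = []
    all_idx = [int(r) for r in res]
    attempts = 0
    while len(pairs) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError("could not sample enough pairs satisfying the separation filter")
        i = nhs[rng.integers(len(nhs))]
        j = all_idx[rng.integers(len(all_idx))]
        if abs(i - j) > min_separation:
            pairs.append((i, j))
    vals = [s.ca_distance(i, j) for i, j in pairs]
    return DistanceDistribution(values=np.array(vals))


def superpose_rmsd(
    a: CaStructure, b: CaStructure, selection: Optional[ResidueSelection] = None
) -> float:
    """Cα RMSD after optimal proper-rotation superposition over a selection.

    Residues common to both structures (and inside the selection, when one
    is given) are paired by residue index; at least three are required.
    """
    common = sorted(set(map(int, a.residue_indices)) & set(map(int, b.residue_indices)))
    if selection is not None:
        common = [r for r in common if selection.contains(r)]
    if len(common) < 3:
        raise ValueError(f"need >= 3 common selected residues, found {len(common)}")
    pa = np.array([a.xyz(r) for r in common])
    pb = np.array([b.xyz(r) for r in common])
    return kabsch_rmsd(pa, pb)


def kabsch_rmsd(pa: np.ndarray, pb: np.ndarray) -> float:
    """RMSD between two (n,3) point sets after centering and optimal rotation."""
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    # align_vectors finds the proper rotation (det +1) minimising the RSSD
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(pa)))


@dataclass
class ShiftAnalysisResult:
    """Per-window summary of the site-imprecision robustness analysis."""

    windows: list[int]
    median_shift: dict[int, float] = field(default_factory=dict)  # mean over reps, Å
    shift_sd: dict[int, float] = field(default_factory=dict)
    p_value: dict[int, float] = field(default_factory=dict)  # mean KS p over reps
    significance_threshold: float = 0.05

    def significant_windows(self) -> list[int]:
        return [w for w in self.windows if self.p_value[w] < self.significance_threshold]


def site_shift_analysis(
    links: "CrossLinkSet",
    s: CaStructure,
    windows: Sequence[int] = tuple(range(3, 41, 2)),
    reps: int = 100,
    seed: int = 0,
) -> ShiftAnalysisResult:
    """Robustness of the link distance distribution to linkage-site imprecision.

    For each odd window size W and each repetition, every diazirine site is
    moved once to a uniformly random index within ±(W−1)/2 (clipped to the
    chain), the shifted distance distribution is recomputed on the structure,
    and two comparisons against the original distribution are recorded: the
    absolute change of the median (effect size, Å) and a two-sample
    Kolmogorov–Smirnov p-value.  Means ± sd over repetitions are reported.
    """
    for w in windows:
        if w % 2 == 0 or w < 1:
            raise ValueError(f"window sizes must be odd and >= 1, got {w}")
    base = link_distance_distribution(s, links)
    lo, hi = int(s.residue_indices[0]), int(s.residue_indices[-1])
    pairs = [(ln.site_a.residue_index, ln.site_b.residue_index) for ln in links
             if s.has_residue(ln.site_a.residue_index) and s.has_residue(ln.site_b.residue_index)]
    rng = np.random.default_rng(seed)
    result = ShiftAnalysisResult(windows=list(windows))
    valid = set(map(int, s.residue_indices))
    for w in windows:
        half = (w - 1) // 2
        shifts, ps = [], []
        for _ in range(reps):
            vals = []
            for i, j in pairs:
                if half:
                    jj = int(np.clip(j + rng.integers(-half, half + 1), lo, hi))
                    if jj not in valid:  # fall back to nearest present residue
                        jj = min(valid, key=lambda r: abs(r - jj))
                else:
                    jj = j
                vals.append(s.ca_distance(i, jj))
            shifted = np.array(vals)
            shifts.append(abs(float(np.median(shifted)) - base.median))
            if half:
                ps.append(float(stats.ks_2samp(base.values, shifted).pvalue))
            else:
                ps.append(1.0)
        result.median_shift[w] = float(np.mean(shifts))
        result.shift_sd[w] = float(np.std(shifts, ddof=1)) if reps > 1 else 0.0
        result.p_value[w] = float(np.mean(ps))
    return result


def helix_wheel_arc(
    sites: Sequence[int], helix_start: int, degrees_per_residue: float = 100.0
) -> tuple[float, bool]:
    """Smallest circular arc covering linkage sites on a helical wheel.

    Each site maps to ((site − helix_start) · 100°) mod 360 on an α-helical
    wheel.  Sites confined to an arc ≤ 180° sit on one face of the helix —
    the pattern expected when a single nearby residue cross-links to the
    exposed face of a helix.
    """
    if not sites:
        raise ValueError("need at least one site")
    angles = sorted(((s - helix_start) * degrees_per_residue) % 360.0 for s in sites)
    if len(angles) == 1:
        return 0.0, True
    gaps = [angles[k + 1] - angles[k] for k in range(len(angles) - 1)]
    gaps.append(360.0 - angles[-1] + angles[0])
    arc = 360.0 - max(gaps)
    return arc, arc <= 180.0
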