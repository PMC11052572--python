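"""Coordinate-level validation operators.

Residue matching between two models, least-squares rigid superposition
(Kabsch) with iterative sigma-based outlier rejection, buried interface
area by rolling-probe (Shrake-Rupley) solvent accessibility, maximum
assembly extent, disulfide detection and pLDDT averages over residue
ranges.
"""

from __future__ import annotations

import copy
import warnings
from typing import Callable, Iterable, Optional, Union

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .scoring import interface_contacts
from .types import Correspondence, InterfaceReport, Structure, SuperpositionResult

__all__ = [
    "match_residues",
    "kabsch",
    "superpose_with_rejection",
    "RejectionEmptiedError",
    "buried_surface_area",
    "shrake_rupley_sasa",
    "max_extent",
    "find_disulfides",
    "mean_plddt",
    "transform_structure",
    "VDW_RADII",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def one_letter(resname: str) -> str:
    """Three-letter to one-letter code; modified residues map to X."""
    return _THREE_TO_ONE.get(resname.upper(), "X")


def _default_chain_map(a: Structure, b: Structure) -> dict[str, str]:
    shared = [cid for cid in a.chain_ids if cid in b.chain_ids]
    if shared:
        return {cid: cid for cid in shared}
    # no ids in common: pair chains positionally
    return dict(zip(a.chain_ids, b.chain_ids))


def match_residues(
    a: Structure,
    b: Structure,
    method: str = "author-number",
    chain_map: Optional[dict[str, str]] = None,
) -> Correspondence:
    """Pair Cα positions between two structures.

    ``author-number`` pairs residues with equal author seq_id within
    mapped chains (the right choice when both files share numbering
    provenance, e.g. a model vs. the crystal structure it is compared
    with, keeping only residues resolved in both). ``sequence-align``
    pairs via global alignment of the one-letter sequences, keeping
    identical-residue columns only.
    """
    if chain_map is None:
        chain_map = _default_chain_map(a, b)
    if not chain_map:
        raise ValueError("no chains to pair between the two structures")
    coords_a, coords_b, labels = [], [], []
    for cid_a, cid_b in chain_map.items():
        ch_a, ch_b = a.chain(cid_a), b.chain(cid_b)
        if method == "author-number":
            by_id = {r.seq_id: r for r in ch_b.residues}
            for ra in ch_a.residues:
                rb = by_id.get(ra.seq_id)
                if rb is None or ra.ca is None or rb.ca is None:
                    continue
                coords_a.append(ra.ca.coord)
                coords_b.append(rb.ca.coord)
                labels.append(((cid_a, ra.seq_id), (cid_b, rb.seq_id)))
        elif method == "sequence-align":
            res_a = [r for r in ch_a.residues if r.ca is not None]
            res_b = [r for r in ch_b.residues if r.ca is not None]
            seq_a = "".join(one_letter(r.name) for r in res_a)
            seq_b = "".join(one_letter(r.name) for r in res_b)
            aligner = Align.PairwiseAligner(
                mode="global", match_score=1, mismatch_score=-1,
                open_gap_score=-2, extend_gap_score=-0.5,
            )
            aln = aligner.align(seq_a, seq_b)[0]
            for (sa, ea), (sb, eb) in zip(*aln.aligned):
                for k in range(ea - sa):
                    ra, rb = res_a[sa + k], res_b[sb + k]
                    if one_letter(ra.name) != one_letter(rb.name):
                        continue
                    coords_a.append(ra.ca.coord)
                    coords_b.append(rb.ca.coord)
                    labels.append(((cid_a, ra.seq_id), (cid_b, rb.seq_id)))
        else:
            raise ValueError(f"unknown method {method!r}")
    if not coords_a:
        raise ValueError("empty correspondence: no matching residues with Cα")
    return Correspondence(
        coords_a=np.array(coords_a),
        coords_b=np.array(coords_b),
        labels=labels,
        method=method,
    )


def _fit(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform taking a onto b (Kabsch via SVD)."""
    cen_a = coords_a.mean(axis=0)
    cen_b = coords_b.mean(axis=0)
    A = coords_a - cen_a
    B = coords_b - cen_b
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cen_b - R @ cen_a
    dev = A @ R.T - B
    rmsd = float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
    return R, t, rmsd


def kabsch(pairs: Correspondence) -> SuperpositionResult:
    """Optimal rigid superposition over all pairs, no outlier rejection.

    Requires at least three non-collinear pairs; RMSD is reported over
    every pair.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs for superposition, got {len(pairs)}")
    A = pairs.coords_a - pairs.coords_a.mean(axis=0)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate geometry: paired points are collinear")
    R, t, rmsd = _fit(pairs.coords_a, pairs.coords_b)
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_used=len(pairs), n_rejected=0, cycles=0
    )


class RejectionEmptiedError(ValueError):
    """Outlier rejection left too few pairs to refit; carries the last
    valid fit in ``last_result``."""

    def __init__(self, message: str, last_result: SuperpositionResult):
        super().__init__(message)
        self.last_result = last_result


def superpose_with_rejection(
    pairs: Correspondence,
    sigma_cutoff: float = 2.0,
    max_cycles: int = 5,
    min_rmsd: float = 1e-6,
) -> SuperpositionResult:
    """Rigid superposition with iterative sigma-based outlier trimming.

    Each cycle fits the retained pairs, computes per-pair deviations and
    rejects pairs deviating by more than ``sigma_cutoff`` times the
    current RMSD, until no pair is rejected or ``max_cycles`` is reached.
    RMSD is non-increasing across cycles for ``sigma_cutoff >= 1``.
    An RMSD at or below ``min_rmsd`` (Å) counts as converged, so an
    essentially exact fit is never trimmed on floating-point noise.
    """
    if sigma_cutoff <= 0:
        raise ValueError("sigma_cutoff must be positive")
    keep = np.ones(len(pairs), dtype=bool)
    result = kabsch(pairs)
    cycles = 0
    for _ in range(max_cycles):
        if result.rmsd <= min_rmsd:
            break
        A = pairs.coords_a[keep]
        B = pairs.coords_b[keep]
        dev = np.linalg.norm(A @ result.rotation.T + result.translation - B, axis=1)
        reject = dev > sigma_cutoff * result.rmsd
        if not reject.any():
            break
        new_keep = keep.copy()
        new_keep[np.flatnonzero(keep)[reject]] = False
        if new_keep.sum() < 3:
            raise RejectionEmptiedError(
                f"outlier rejection left {int(new_keep.sum())} pairs (<3); "
                f"last valid fit: rmsd={result.rmsd:.3f} Å over {int(keep.sum())} pairs",
                last_result=result,
            )
        keep = new_keep
        cycles += 1
        R, t, rmsd = _fit(pairs.coords_a[keep], pairs.coords_b[keep])
        result = SuperpositionResult(
            rotation=R, translation=t, rmsd=rmsd,
            n_used=int(keep.sum()),
            n_rejected=len(pairs) - int(keep.sum()),
            cycles=cycles,
        )
    return SuperpositionResult(
        rotation=result.rotation, translation=result.translation,
        rmsd=result.rmsd, n_used=int(keep.sum()),
        n_rejected=len(pairs) - int(keep.sum()), cycles=cycles,
    )


# Van der Waals radii (Å) for heavy atoms; Bondi-style values.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by rolling-probe
    numerical sampling on a deterministic sphere lattice."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    unit = _fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.zeros(n)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + expanded.max())
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * ri * ri * frac
    return out


def _heavy_atoms(structure: Structure, chain_ids: Iterable[str]):
    coords, radii, labels = [], [], []
    for cid in chain_ids:
        for res in structure.chain(cid).residues:
            for atom in res.atoms:
                elem = atom.element.upper()
                if elem == "H":
                    continue
                coords.append(atom.coord)
                radii.append(VDW_RADII.get(elem, _DEFAULT_RADIUS))
                labels.append((cid, res.seq_id))
    return np.asarray(coords).reshape(-1, 3), np.asarray(radii), labels


def buried_surface_area(
    structure: Structure,
    group_a: Iterable[str],
    group_b: Iterable[str],
    probe: float = 1.4,
    n_points: int = 960,
    interface_delta: float = 0.1,
) -> InterfaceReport:
    """Interface area buried between two chain groups.

    buried_area = (SASA(A alone) + SASA(B alone) - SASA(A+B)) / 2, with
    solvent accessibility from :func:`shrake_rupley_sasa`. A residue is
    an interface residue when it loses more than ``interface_delta`` Å²
    of accessibility upon complexation. ``n_contacts`` is the Cβ-contact
    count at the default 8 Å cutoff.
    """
    ga, gb = tuple(sorted(set(group_a))), tuple(sorted(set(group_b)))
    if set(ga) & set(gb):
        raise ValueError("chain groups overlap")
    ca, ra, la = _heavy_atoms(structure, ga)
    cb, rb, lb = _heavy_atoms(structure, gb)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("a chain group contains no heavy atoms")
    sasa_a = shrake_rupley_sasa(ca, ra, probe, n_points)
    sasa_b = shrake_rupley_sasa(cb, rb, probe, n_points)
    sasa_ab = shrake_rupley_sasa(
        np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, n_points
    )
    bsa = (sasa_a.sum() + sasa_b.sum() - sasa_ab.sum()) / 2.0

    def _losses(labels, alone, together):
        loss: dict[tuple[str, int], float] = {}
        for lab, s0, s1 in zip(labels, alone, together):
            loss[lab] = loss.get(lab, 0.0) + (s0 - s1)
        return sorted(lab for lab, d in loss.items() if d > interface_delta)

    iface = {
        "a": _losses(la, sasa_a, sasa_ab[: len(ca)]),
        "b": _losses(lb, sasa_b, sasa_ab[len(ca):]),
    }
    n_contacts, _ = interface_contacts(structure, ga, gb)
    return InterfaceReport(
        group_a=ga, group_b=gb, buried_area=float(max(bsa, 0.0)),
        interface_residues=iface, n_contacts=n_contacts,
    )


def max_extent(
    structure: Structure,
    atom_filter: Union[str, Callable[[str], bool]] = "CA",
) -> float:
    """Maximum pairwise distance (Å) over the filtered atoms — the
    assembly's end-to-end extent (e.g. ~260 Å for an elongated dimer)."""
    if callable(atom_filter):
        keep = atom_filter
    else:
        name = atom_filter
        keep = lambda n: n == name  # noqa: E731
    coords = [a.coord for _, _, a in structure.atoms() if keep(a.name)]
    if not coords:
        raise ValueError("no atoms pass the filter")
    if len(coords) == 1:
        return 0.0
    return float(pdist(np.asarray(coords)).max())


def find_disulfides(
    structure: Structure, sg_cutoff: float = 2.5
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Cysteine pairs whose SG-SG distance is within ``sg_cutoff`` Å.

    Pairs are assigned greedily nearest-first so each cysteine appears in
    at most one bond; remaining within-cutoff clashes are warned about.
    """
    sgs = []
    for chain in structure.chains:
        for res in chain.residues:
            if res.name.upper() == "CYS":
                sg = res.atom("SG")
                if sg is not None:
                    sgs.append(((chain.chain_id, res.seq_id), sg.coord))
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= sg_cutoff:
                candidates.append((d, sgs[i][0], sgs[j][0]))
    candidates.sort()
    used: set[tuple[str, int]] = set()
    bonds = []
    leftovers = 0
    for d, a, b in candidates:
        if a in used or b in used:
            leftovers += 1
            continue
        bonds.append(tuple(sorted((a, b))))
        used.update((a, b))
    if leftovers:
        warnings.warn(
            f"{leftovers} additional SG-SG pairs within {sg_cutoff} Å involve "
            "already-bonded cysteines"
        )
    return sorted(bonds)


def mean_plddt(
    structure: Structure, chain_id: str, span: tuple[int, int]
) -> float:
    """Arithmetic mean per-residue pLDDT over an inclusive author-number
    span of one chain (per-residue value = Cα B-factor, else atom mean)."""
    lo, hi = span
    residues = [r for r in structure.chain(chain_id).residues if lo <= r.seq_id <= hi]
    if not residues:
        raise ValueError(f"no residues of chain {chain_id} in span {lo}-{hi}")
    return float(np.mean([r.plddt() for r in residues]))


def transform_structure(
    structure: Structure, result: SuperpositionResult
) -> Structure:
    """Copy of a structure with the superposition transform applied."""
    new = copy.deepcopy(structure)
    for _, _, atom in new.atoms():
        atom.coord = result.rotation @ atom.coord + result.translation
    return new
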