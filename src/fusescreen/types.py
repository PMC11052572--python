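"""Core domain types shared across the pipeline.

The object model is deliberately small: a ``Structure`` is chains of
residues of atoms, with per-residue prediction confidence (pLDDT, 0-100)
carried in the B-factor slot when the structure is a predicted model.
Author residue numbering from the source file is preserved end-to-end and
all residue ranges are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ModelScore",
    "PAEMatrix",
    "SequenceRecord",
    "ScreenEntry",
    "ChainDockScore",
    "ProteinEntry",
    "Correspondence",
    "SuperpositionResult",
    "InterfaceReport",
    "AnchorPoint",
    "TopologyVerdict",
    "SequonHit",
    "GlycanClashReport",
]

RC_IPTM_WEIGHT = 0.8
RC_PTM_WEIGHT = 0.2


@dataclass
class Atom:
    """One atom: label, element, Cartesian coordinates (Å) and B-factor.

    For predicted models the B-factor column carries the per-residue
    confidence (pLDDT) on a 0-100 scale.
    """

    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")


@dataclass
class Residue:
    seq_id: int  # author residue number, 1-based, from the source file
    name: str  # three-letter code; non-standard names preserved
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def contact_atom(self) -> Optional[Atom]:
        """Cβ, falling back to Cα (glycine or missing side chain)."""
        return self.atom("CB") or self.atom("CA")

    def plddt(self) -> float:
        """Per-residue confidence: Cα B-factor, else mean over atoms."""
        ca = self.ca
        if ca is not None:
            return ca.bfactor
        if not self.atoms:
            raise ValueError(f"residue {self.seq_id} has no atoms")
        return float(np.mean([a.bfactor for a in self.atoms]))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    entity_name: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residues must be strictly increasing in seq_id"
            )

    def residue(self, seq_id: int) -> Optional[Residue]:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A multi-chain coordinate model.

    ``predicted`` marks the B-factor column as pLDDT; experimental
    structures (e.g. crystal structures used as superposition references)
    keep their B-factors as B-factors.
    """

    model_id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: str = ""
    predicted: bool = True

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in {self.model_id!r}: {ids}")
        if not self.chains:
            raise ValueError("structure must have at least one chain")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.model_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a


@dataclass
class ModelScore:
    """Per-model confidence: ipTM, pTM and the derived ranking confidence.

    rc = 0.8*ipTM + 0.2*pTM, always recomputed from ipTM/pTM, never
    trusted from a metrics file.
    """

    model_name: str
    iptm: float
    ptm: float
    rank: int
    rc: float = field(init=False)

    def __post_init__(self) -> None:
        for label, v in (("iptm", self.iptm), ("ptm", self.ptm)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.model_name}: {label}={v} outside [0, 1]")
        if self.rank < 1:
            raise ValueError(f"{self.model_name}: rank must be >= 1")
        self.rc = RC_IPTM_WEIGHT * self.iptm + RC_PTM_WEIGHT * self.ptm


@dataclass
class PAEMatrix:
    """Predicted aligned error matrix with a chain -> row-range map.

    ``chain_ranges`` maps each chain id to its half-open 0-based row
    interval ``(start, stop)``; the intervals partition ``range(size)``.
    """

    values: np.ndarray
    chain_ranges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError(f"PAE matrix must be square, got {n}x{m}")
        if np.any(self.values < 0):
            raise ValueError("PAE entries must be >= 0")
        covered = sorted(self.chain_ranges.values())
        pos = 0
        for start, stop in covered:
            if start != pos or stop <= start:
                raise ValueError("chain ranges must partition the matrix rows")
            pos = stop
        if pos != n:
            raise ValueError(
                f"chain ranges cover {pos} rows but matrix has {n}"
            )

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def index_of(self, chain_id: str, residue_pos: int) -> int:
        """Matrix index of the ``residue_pos``-th residue (1-based) of a chain."""
        start, stop = self.chain_ranges[chain_id]
        idx = start + residue_pos - 1
        if not (start <= idx < stop):
            raise IndexError(f"residue {residue_pos} outside chain {chain_id}")
        return idx

    def chain_of(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`index_of`: (chain_id, 1-based position)."""
        for cid, (start, stop) in self.chain_ranges.items():
            if start <= index < stop:
                return cid, index - start + 1
        raise IndexError(f"index {index} outside matrix")


_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequenceRecord:
    id: str
    seq: str
    region: Optional[tuple[int, int]] = None  # 1-based inclusive span

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _AA_LETTERS
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid letters {sorted(bad)}")
        if self.region is not None:
            lo, hi = self.region
            if not (1 <= lo <= hi <= len(self.seq)):
                raise ValueError(f"{self.id}: region {self.region} outside 1..{len(self.seq)}")


@dataclass
class ScreenEntry:
    """Aggregated ensemble scores for one screened protein pair."""

    pair: tuple[str, str]  # sorted; equal names = homodimer
    top_rc: float
    mean_rc: float
    top_iptm: float
    n_models: int
    pdockq_a: float = math.nan
    pdockq_b: float = math.nan

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(self.pair))  # type: ignore[assignment]
        if not (0.0 <= self.mean_rc <= 1.0):
            raise ValueError(f"{self.pair}: mean_rc={self.mean_rc} outside [0, 1]")
        if self.n_models < 1:
            raise ValueError(f"{self.pair}: empty ensemble")


@dataclass
class ChainDockScore:
    """Interface quality of one chain against the rest of its complex."""

    chain_id: str
    pdockq: float
    n_contacts: int
    mean_interface_plddt: float

    def __post_init__(self) -> None:
        if self.n_contacts < 0:
            raise ValueError("n_contacts must be >= 0")


@dataclass
class ProteinEntry:
    """One screened protein: name, gamete side and the modeled region."""

    name: str
    side: str  # "egg" or "sperm"
    region: Optional[tuple[int, int]] = None
    accession: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("egg", "sperm"):
            raise ValueError(f"{self.name}: side must be 'egg' or 'sperm'")


@dataclass
class Correspondence:
    """Matched Cα positions between two structures."""

    coords_a: np.ndarray  # (N, 3)
    coords_b: np.ndarray  # (N, 3)
    labels: list[tuple]  # per-pair provenance, e.g. ((chain, seq_id), (chain, seq_id))
    method: str = "author-number"

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float).reshape(-1, 3)
        self.coords_b = np.asarray(self.coords_b, dtype=float).reshape(-1, 3)
        if self.coords_a.shape != self.coords_b.shape:
            raise ValueError("coordinate sets differ in length")
        if len(self.coords_a) == 0:
            raise ValueError("empty correspondence")

    def __len__(self) -> int:
        return len(self.coords_a)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_used: int
    n_rejected: int = 0
    cycles: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation determinant != +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class InterfaceReport:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    buried_area: float  # Å^2
    interface_residues: dict[str, list[tuple[str, int]]]  # "a"/"b" -> (chain, seq_id)
    n_contacts: int

    def __post_init__(self) -> None:
        if self.buried_area < -1e-6:
            raise ValueError("buried area must be >= 0")
        self.buried_area = max(self.buried_area, 0.0)


@dataclass
class AnchorPoint:
    """Membrane-proximal point of one chain: its Cα position and gamete side."""

    protein: str
    side: str  # "egg" or "sperm"
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in ("egg", "sperm"):
            raise ValueError(f"{self.protein}: side must be 'egg' or 'sperm'")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"{self.protein}: position must be a finite 3-vector")


@dataclass
class TopologyVerdict:
    """Outcome of the membrane-side segregation test.

    ``margin`` is the gap (Å) between the egg-side and sperm-side anchor
    projections along ``axis``; positive means the two sides separate
    cleanly, as a trans-synapse assembly requires.
    """

    separable: bool
    axis: np.ndarray
    margin: float
    per_anchor_projections: list[tuple[str, str, float]]  # (protein, side, projection)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.separable != (self.margin > 0):
            raise ValueError("separable must equal margin > 0")


@dataclass
class SequonHit:
    """One N-X-S/T (X != P) sequon: the Asn position and its triplet."""

    protein: str
    position: int  # 1-based index of the Asn in the sequence
    triplet: str
    species_tag: str = ""
    on_structure: Optional[tuple[str, int]] = None  # (chain_id, author seq_id)

    def __post_init__(self) -> None:
        t = self.triplet.upper()
        if not (len(t) == 3 and t[0] == "N" and t[1] != "P" and t[2] in "ST"):
            raise ValueError(f"{self.protein}@{self.position}: {t!r} is not a sequon")
        self.triplet = t


@dataclass
class GlycanClashReport:
    sequon: SequonHit
    nearest_interface_residue: Optional[tuple[str, int]]
    distance: float
    flagged: bool

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
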