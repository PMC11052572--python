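"""N-glycosylation sequon detection and structural mapping.

A sequon is the tripeptide N-X-S/T with X != P. Because structure
predictors know nothing about glycans, an N-glycan at a sequon close to
a predicted protein-protein interface could sterically interfere with
that interface in vivo; this module finds sequons in sequences, maps
their Asn residues onto a model's chains, and flags those whose Asn
sits within a configurable reach of any interface residue.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .types import GlycanClashReport, SequenceRecord, SequonHit, Structure

__all__ = [
    "find_sequons",
    "map_sequons",
    "glycan_interface_clash",
    "shared_sequons",
]


def find_sequons(record: SequenceRecord, species_tag: str = "") -> list[SequonHit]:
    """All N-X-S/T (X != P) sequons in a sequence, 1-based Asn positions.

    Overlapping sequons are all reported. When the record carries a
    region (e.g. an ectodomain span), only Asn positions inside it count.
    """
    seq = record.seq
    lo, hi = record.region if record.region else (1, len(seq))
    hits = []
    for i in range(lo - 1, min(hi, len(seq) - 2)):
        tri = seq[i : i + 3]
        if tri[0] == "N" and tri[1] != "P" and tri[2] in "ST":
            hits.append(
                SequonHit(
                    protein=record.id,
                    position=i + 1,
                    triplet=tri,
                    species_tag=species_tag,
                )
            )
    return hits


def map_sequons(
    structure: Structure,
    hits: Sequence[SequonHit],
    chain_map: Mapping[str, tuple[str, int]],
) -> list[SequonHit]:
    """Annotate sequon hits with their (chain, author seq_id) on a model.

    ``chain_map`` maps each protein name to ``(chain_id, offset)`` where
    ``author seq_id = sequence position + offset`` (offset 0 when the
    model uses the same numbering as the sequence). Hits whose Asn
    residue is absent from the chain are kept unmapped, with a warning.
    """
    mapped = []
    for hit in hits:
        if hit.protein not in chain_map:
            raise KeyError(f"no chain mapping for protein {hit.protein!r}")
        chain_id, offset = chain_map[hit.protein]
        chain = structure.chain(chain_id)  # KeyError if chain absent
        seq_id = hit.position + offset
        res = chain.residue(seq_id)
        on_structure = None
        if res is None:
            warnings.warn(
                f"{hit.protein} sequon at {hit.position}: residue {seq_id} "
                f"not present in chain {chain_id}; left unmapped"
            )
        elif res.name.upper() not in ("ASN", "UNK") and res.name.upper() != "N":
            warnings.warn(
                f"{hit.protein} sequon at {hit.position}: chain {chain_id} "
                f"residue {seq_id} is {res.name}, not ASN; left unmapped"
            )
        else:
            on_structure = (chain_id, seq_id)
        mapped.append(
            SequonHit(
                protein=hit.protein,
                position=hit.position,
                triplet=hit.triplet,
                species_tag=hit.species_tag,
                on_structure=on_structure,
            )
        )
    return mapped


def glycan_interface_clash(
    structure: Structure,
    mapped_hits: Sequence[SequonHit],
    interface_residues: Iterable[tuple[str, int]],
    threshold: float = 10.0,
) -> list[GlycanClashReport]:
    """Distance from each mapped sequon's Asn to the nearest interface residue.

    The Asn is represented by its side-chain nitrogen ND2 when present
    (the glycan attachment atom), else its Cα; the interface residue by
    its nearest heavy atom. Sequons closer than ``threshold`` Å are
    flagged as potential glycan-interface clashes. One report is emitted
    per mapped hit; unmapped hits are passed through unflagged with an
    infinite distance.
    """
    iface = list(interface_residues)
    iface_atoms: list[tuple[tuple[str, int], np.ndarray]] = []
    for cid, sid in iface:
        res = structure.chain(cid).residue(sid)
        if res is None:
            continue
        for atom in res.atoms:
            if atom.element.upper() != "H":
                iface_atoms.append(((cid, sid), atom.coord))
    reports = []
    for hit in mapped_hits:
        if hit.on_structure is None or not iface_atoms:
            reports.append(
                GlycanClashReport(
                    sequon=hit, nearest_interface_residue=None,
                    distance=float("inf"), flagged=False,
                )
            )
            continue
        cid, sid = hit.on_structure
        res = structure.chain(cid).residue(sid)
        ref = res.atom("ND2") or res.ca or res.atoms[0]
        dists = [(float(np.linalg.norm(ref.coord - pos)), lab) for lab, pos in iface_atoms]
        d, lab = min(dists)
        reports.append(
            GlycanClashReport(
                sequon=hit, nearest_interface_residue=lab,
                distance=d, flagged=d < threshold,
            )
        )
    return reports


def shared_sequons(
    rec_a: SequenceRecord,
    rec_b: SequenceRecord,
    hits_a: Sequence[SequonHit],
    hits_b: Sequence[SequonHit],
) -> list[tuple[SequonHit, SequonHit]]:
    """Sequons shared between two species' orthologs.

    Two sequons count as one shared site when their Asn positions fall in
    the same column of a global alignment of the two sequences. The
    relation is symmetric.
    """
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-0.5,
    )
    aln = aligner.align(rec_a.seq, rec_b.seq)[0]
    a_to_b: dict[int, int] = {}
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for k in range(ea - sa):
            a_to_b[sa + k + 1] = sb + k + 1  # 1-based positions
    pos_b = {h.position: h for h in hits_b}
    shared = []
    for ha in hits_a:
        hb = pos_b.get(a_to_b.get(ha.position, -1))
        if hb is not None:
            shared.append((ha, hb))
    return shared
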