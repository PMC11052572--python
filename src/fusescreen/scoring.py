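"""Model-confidence scoring and aggregation.

Implements the ranking confidence rc = 0.8*ipTM + 0.2*pTM used to rank
and aggregate multimer predictions, ensemble statistics for a screened
protein pair, per-chain pDockQ computed against the rest of the complex,
and inter-chain PAE block summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .types import (
    ChainDockScore,
    ModelScore,
    PAEMatrix,
    ScreenEntry,
    Structure,
    RC_IPTM_WEIGHT,
    RC_PTM_WEIGHT,
)

__all__ = [
    "ranking_confidence",
    "aggregate_ensemble",
    "interface_contacts",
    "pdockq_chain_vs_rest",
    "interface_pae_summary",
    "PDockQParams",
]


def ranking_confidence(iptm: float, ptm: float) -> float:
    """rc = 0.8*ipTM + 0.2*pTM, both arguments in [0, 1]."""
    for label, v in (("iptm", iptm), ("ptm", ptm)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{label}={v} outside [0, 1]")
    return RC_IPTM_WEIGHT * iptm + RC_PTM_WEIGHT * ptm


def aggregate_ensemble(
    scores: Sequence[ModelScore], pair: tuple[str, str]
) -> ScreenEntry:
    """Collapse an ensemble of model scores for one pair into a ScreenEntry.

    mean_rc is the arithmetic mean over all models; the "top" model is the
    max-rc model (ties broken by model name), which recomputes the file's
    rank-1 choice rather than trusting it.
    """
    if not scores:
        raise ValueError(f"{pair}: empty ensemble")
    top = min(scores, key=lambda s: (-s.rc, s.model_name))
    return ScreenEntry(
        pair=pair,
        top_rc=top.rc,
        mean_rc=float(np.mean([s.rc for s in scores])),
        top_iptm=top.iptm,
        n_models=len(scores),
    )


def _contact_points(structure: Structure, chain_ids: Iterable[str]):
    """(coords, (chain_id, seq_id) labels) of Cβ (Cα fallback) atoms."""
    coords, labels = [], []
    for cid in chain_ids:
        for res in structure.chain(cid).residues:
            atom = res.contact_atom()
            if atom is None:
                warnings.warn(
                    f"chain {cid} residue {res.seq_id} ({res.name}): "
                    "no CB or CA atom, skipped for contacts"
                )
                continue
            coords.append(atom.coord)
            labels.append((cid, res.seq_id))
    return np.asarray(coords, dtype=float).reshape(-1, 3), labels


def interface_contacts(
    structure: Structure,
    group_a: Iterable[str],
    group_b: Iterable[str],
    cutoff: float = 8.0,
) -> tuple[int, dict[str, set[tuple[str, int]]]]:
    """Count residue-residue contacts between two disjoint chain groups.

    A contact is a pair of residues, one per group, whose Cβ atoms
    (Cα for glycine) lie within ``cutoff`` Å. Returns the count and the
    interface residue sets on both sides (keys ``"a"`` and ``"b"``).
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("both chain groups must be non-empty")
    if ga & gb:
        raise ValueError(f"chain groups overlap: {sorted(ga & gb)}")
    coords_a, labels_a = _contact_points(structure, sorted(ga))
    coords_b, labels_b = _contact_points(structure, sorted(gb))
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0, {"a": set(), "b": set()}
    pairs = cKDTree(coords_a).query_ball_tree(cKDTree(coords_b), r=cutoff)
    n = 0
    res_a: set[tuple[str, int]] = set()
    res_b: set[tuple[str, int]] = set()
    for i, js in enumerate(pairs):
        n += len(js)
        if js:
            res_a.add(labels_a[i])
            res_b.update(labels_b[j] for j in js)
    return n, {"a": res_a, "b": res_b}


@dataclass(frozen=True)
class PDockQParams:
    """Sigmoid constants of the pDockQ score:
    pDockQ = L / (1 + exp(-k*(x - x0))) + b with
    x = <interface pLDDT> * ln(n_contacts)."""

    L: float = 0.724
    k: float = 0.052
    x0: float = 152.611
    b: float = 0.018


def pdockq_chain_vs_rest(
    structure: Structure,
    chain_id: str,
    cutoff: float = 8.0,
    params: PDockQParams = PDockQParams(),
    plddt_scope: str = "union",
) -> ChainDockScore:
    """pDockQ of one chain scored against all remaining chains.

    x = mean pLDDT over the interface residues times the natural log of
    the contact count; with zero contacts the score is pinned to the
    additive floor ``b`` (no interface). ``plddt_scope`` averages over the
    interface residues of both sides (``"union"``, default) or of the
    query chain only (``"query"``).
    """
    if len(structure.chains) < 2:
        raise ValueError("pDockQ needs a multi-chain structure")
    rest = [c for c in structure.chain_ids if c != chain_id]
    if not rest:
        raise KeyError(f"chain {chain_id!r} not present")
    n_contacts, residues = interface_contacts(
        structure, [chain_id], rest, cutoff=cutoff
    )
    if n_contacts == 0:
        return ChainDockScore(
            chain_id=chain_id,
            pdockq=params.b,
            n_contacts=0,
            mean_interface_plddt=0.0,
        )
    if plddt_scope == "union":
        iface = residues["a"] | residues["b"]
    elif plddt_scope == "query":
        iface = residues["a"]
    else:
        raise ValueError(f"unknown plddt_scope {plddt_scope!r}")
    plddts = [structure.chain(cid).residue(sid).plddt() for cid, sid in iface]
    mean_plddt = float(np.mean(plddts))
    x = mean_plddt * math.log(n_contacts)
    pdockq = params.L / (1.0 + math.exp(-params.k * (x - params.x0))) + params.b
    return ChainDockScore(
        chain_id=chain_id,
        pdockq=pdockq,
        n_contacts=n_contacts,
        mean_interface_plddt=mean_plddt,
    )


def interface_pae_summary(
    pae: PAEMatrix, chain_a: str, chain_b: str
) -> tuple[float, float]:
    """(min, mean) PAE over the union of the two inter-chain blocks."""
    for cid in (chain_a, chain_b):
        if cid not in pae.chain_ranges:
            raise KeyError(f"chain {cid!r} not mapped by the PAE matrix")
    a0, a1 = pae.chain_ranges[chain_a]
    b0, b1 = pae.chain_ranges[chain_b]
    block_ab = pae.values[a0:a1, b0:b1]
    block_ba = pae.values[b0:b1, a0:a1]
    both = np.concatenate([block_ab.ravel(), block_ba.ravel()])
    return float(both.min()), float(both.mean())
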