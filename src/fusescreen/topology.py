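"""Membrane-topology consistency of a predicted trans-synapse assembly.

For a complex spanning two apposed plasma membranes, the membrane
anchors of egg-side subunits must all sit on the opposite side of the
assembly from the sperm-side anchors. Each chain contributes one or two
anchor points (Cα of its membrane-proximal residue: the C-terminus for
C-terminally anchored ectodomains and GPI-anchored proteins, both
termini for a multi-pass chain whose whole body is membrane-proximal),
and the verdict projects all anchors onto the axis joining the two
sides' centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .types import AnchorPoint, Structure, TopologyVerdict

__all__ = ["AnchorRule", "collect_anchors", "test_segregation"]

_VALID_RULES = ("c_term", "n_term", "both_termini")


@dataclass(frozen=True)
class AnchorRule:
    """How one chain anchors to its membrane.

    ``rule``: ``c_term`` (single-pass type-I ectodomain or GPI anchor),
    ``n_term``, or ``both_termini`` (multi-pass chain, e.g. a tetraspanin
    whose N- and C-termini both enter the membrane).
    """

    side: str  # "egg" or "sperm"
    rule: str = "c_term"

    def __post_init__(self) -> None:
        if self.side not in ("egg", "sperm"):
            raise ValueError(f"side must be 'egg' or 'sperm', got {self.side!r}")
        if self.rule not in _VALID_RULES:
            raise ValueError(f"rule must be one of {_VALID_RULES}, got {self.rule!r}")


def collect_anchors(
    structure: Structure, roster: Mapping[str, AnchorRule]
) -> list[AnchorPoint]:
    """Anchor points for every chain named in the roster (keyed by chain id).

    The anchor position is the literal Cα coordinate of the terminal
    residue(s) selected by each chain's rule.
    """
    anchors: list[AnchorPoint] = []
    for chain_id, rule in roster.items():
        chain = structure.chain(chain_id)  # KeyError if absent
        termini = []
        if rule.rule in ("n_term", "both_termini"):
            termini.append(chain.residues[0])
        if rule.rule in ("c_term", "both_termini"):
            termini.append(chain.residues[-1])
        for res in termini:
            ca = res.ca
            if ca is None:
                raise ValueError(
                    f"chain {chain_id}: terminal residue {res.seq_id} has no Cα"
                )
            anchors.append(
                AnchorPoint(protein=chain_id, side=rule.side, position=ca.coord)
            )
    return anchors


def test_segregation(anchors: Sequence[AnchorPoint]) -> TopologyVerdict:
    """Test whether egg and sperm anchors segregate to opposite sides.

    The axis is the unit vector from the sperm-anchor centroid to the
    egg-anchor centroid; the margin is the gap between the lowest egg
    projection and the highest sperm projection along that axis
    (negative when the two sides' projections overlap). The verdict is
    invariant under rigid transforms of all anchors together.
    """
    egg = [a for a in anchors if a.side == "egg"]
    sperm = [a for a in anchors if a.side == "sperm"]
    if not egg or not sperm:
        raise ValueError("need at least one anchor on each side")
    cen_egg = np.mean([a.position for a in egg], axis=0)
    cen_sperm = np.mean([a.position for a in sperm], axis=0)
    diff = cen_egg - cen_sperm
    norm = float(np.linalg.norm(diff))
    if norm < 1e-12:
        # coincident centroids: any axis gives margin <= 0 (mean projections equal)
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = diff / norm
    projections = [
        (a.protein, a.side, float(np.dot(a.position, axis))) for a in anchors
    ]
    egg_proj = [p for _, s, p in projections if s == "egg"]
    sperm_proj = [p for _, s, p in projections if s == "sperm"]
    margin = min(egg_proj) - max(sperm_proj)
    return TopologyVerdict(
        separable=margin > 0,
        axis=axis,
        margin=float(margin),
        per_anchor_projections=projections,
    )
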