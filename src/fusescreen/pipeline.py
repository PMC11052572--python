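"""End-to-end orchestration: screen summarization, network construction
and per-complex validation reports, with manifest provenance.

Numeric report values are serialized at fixed precision (scores to 3
decimals, distances to 2, areas to 0) so outputs diff cleanly between
runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx

from . import __version__
from .geometry import (
    buried_surface_area,
    match_residues,
    superpose_with_rejection,
)
from .glycosites import find_sequons, glycan_interface_clash, map_sequons
from .io import (
    read_fasta,
    read_model_scores,
    read_structure,
    write_screen_table,
)
from .network import DEFAULT_MEAN_RC_CUTOFF, build_network, enumerate_pairs, graph_to_dict, hub_component
from .scoring import aggregate_ensemble, pdockq_chain_vs_rest
from .topology import AnchorRule, collect_anchors, test_segregation
from .types import ProteinEntry, ScreenEntry, Structure

logger = logging.getLogger("fusescreen")

__all__ = ["RunConfig", "run_screen", "run_validate", "load_roster", "write_manifest"]

EXIT_OK = 0
EXIT_OPERATIONAL_ERROR = 1
EXIT_VALIDATION_FAILED = 2


@dataclass
class RunConfig:
    """Cutoffs and knobs shared across pipeline stages."""

    mean_rc_cutoff: float = DEFAULT_MEAN_RC_CUTOFF
    contact_cutoff: float = 8.0  # Å, Cβ-Cβ
    clash_threshold: float = 10.0  # Å, sequon Asn to interface
    rejection_sigma: float = 2.0
    rejection_cycles: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_rc_cutoff", "contact_cutoff", "clash_threshold", "rejection_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "mean_rc_cutoff": self.mean_rc_cutoff,
            "contact_cutoff": self.contact_cutoff,
            "clash_threshold": self.clash_threshold,
            "rejection_sigma": self.rejection_sigma,
            "rejection_cycles": self.rejection_cycles,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    inputs: Sequence[Union[str, Path]],
    config: Mapping,
    outputs: Sequence[Union[str, Path]],
) -> Path:
    manifest = {
        "package": "fusescreen",
        "version": __version__,
        "config": dict(config),
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))}
            for p in inputs
            if Path(p).is_file()
        ],
        "outputs": [str(p) for p in outputs],
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


@dataclass
class ScreenResult:
    entries: list[ScreenEntry]
    graph: nx.Graph
    hub_graph: Optional[nx.Graph]
    missing_pairs: list[tuple[str, str]]
    table_path: Optional[Path] = None
    graph_path: Optional[Path] = None


def run_screen(
    pairs_dir: Union[str, Path],
    proteins: Sequence[ProteinEntry],
    out_dir: Union[str, Path],
    config: RunConfig = RunConfig(),
    hub: Optional[str] = None,
) -> ScreenResult:
    """Summarize a directory of per-pair metrics into a screen table and
    thresholded interaction graph.

    Each enumerated pair (self-pairs included) is looked up as
    ``<A>__<B>.json`` in ``pairs_dir``; missing pairs are warned about
    and the run continues. Writes ``screen.tsv``, ``graph.json``, a
    human-readable ``summary.txt`` and a manifest.
    """
    pairs_dir = Path(pairs_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ScreenEntry] = []
    missing: list[tuple[str, str]] = []
    inputs = []
    for a, b in enumerate_pairs(proteins):
        path = pairs_dir / f"{a}__{b}.json"
        if not path.exists():
            warnings.warn(f"no metrics for pair {a}-{b}; skipped")
            missing.append((a, b))
            continue
        scores = read_model_scores(path)
        entries.append(aggregate_ensemble(scores, (a, b)))
        inputs.append(path)
    if not entries:
        raise FileNotFoundError(f"no readable pair metrics under {pairs_dir}")

    graph = build_network(entries, cutoff=config.mean_rc_cutoff, proteins=proteins)
    hub_graph = hub_component(graph, hub) if hub else None

    table_path = out_dir / "screen.tsv"
    write_screen_table(entries, table_path)
    graph_doc = graph_to_dict(hub_graph if hub_graph is not None else graph)
    graph_path = out_dir / "graph.json"
    graph_path.write_text(json.dumps(graph_doc, indent=1, sort_keys=True))

    lines = [
        f"screen: {len(entries)} pairs scored, {len(missing)} missing",
        f"network: {graph.number_of_edges()} interactions at mean rc >= "
        f"{config.mean_rc_cutoff}",
    ]
    if hub_graph is not None:
        classes = [d["classification"] for _, _, d in hub_graph.edges(data=True)]
        lines.append(
            f"hub {hub}: component of {hub_graph.number_of_nodes()} proteins, "
            f"{classes.count('direct')} direct, {classes.count('indirect')} indirect, "
            f"{classes.count('homodimer')} homodimeric interactions"
        )
    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    write_manifest(
        out_dir, inputs, config.to_dict(),
        [table_path, graph_path, summary_path],
    )
    return ScreenResult(
        entries=entries, graph=graph, hub_graph=hub_graph,
        missing_pairs=missing, table_path=table_path, graph_path=graph_path,
    )


def load_roster(path: Union[str, Path]) -> dict[str, AnchorRule]:
    """Read a chain roster from TOML: one table per chain id with
    ``side`` ("egg"/"sperm") and optional ``anchor`` rule."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    roster = {}
    for chain_id, rec in data.items():
        roster[chain_id] = AnchorRule(
            side=rec["side"], rule=rec.get("anchor", "c_term")
        )
    return roster


def _round(value: float, digits: int) -> float:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return value
    return round(float(value), digits)


def run_validate(
    structure_path: Union[str, Path],
    roster: Mapping[str, AnchorRule],
    out_dir: Union[str, Path],
    config: RunConfig = RunConfig(),
    reference_path: Optional[Union[str, Path]] = None,
    fasta_path: Optional[Union[str, Path]] = None,
    chain_map: Optional[Mapping[str, tuple[str, int]]] = None,
    interface_groups: Optional[Sequence[tuple[Sequence[str], Sequence[str]]]] = None,
) -> tuple[dict, int]:
    """Validate one predicted complex: per-chain pDockQ, membrane-side
    segregation, optional glycan-clash screening, buried interface areas
    and superposition against a reference.

    Returns the report dict and an exit status (0 ok, 2 when topology
    fails or any check errors; per-check errors are captured in the
    report rather than aborting the run).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure = read_structure(structure_path)
    missing_roster = [c for c in structure.chain_ids if c not in roster]
    if missing_roster:
        raise ValueError(f"roster does not cover chains {missing_roster}")

    report: dict = {"structure": str(structure_path), "checks": {}}
    failed = False

    def run_check(name, fn):
        nonlocal failed
        try:
            report["checks"][name] = fn()
        except Exception as exc:  # captured, not fatal to the run
            logger.error("check %s failed: %s", name, exc)
            report["checks"][name] = {"error": str(exc)}
            failed = True

    def chain_scores():
        out = []
        for cid in structure.chain_ids:
            s = pdockq_chain_vs_rest(structure, cid, cutoff=config.contact_cutoff)
            out.append(
                {
                    "chain": cid,
                    "pdockq": _round(s.pdockq, 3),
                    "n_contacts": s.n_contacts,
                    "mean_interface_plddt": _round(s.mean_interface_plddt, 3),
                }
            )
        return out

    run_check("per_chain_pdockq", chain_scores)

    def topology_check():
        anchors = collect_anchors(structure, roster)
        verdict = test_segregation(anchors)
        return {
            "separable": verdict.separable,
            "margin": _round(verdict.margin, 2),
            "axis": [_round(x, 3) for x in verdict.axis],
            "projections": [
                [p, s, _round(v, 2)] for p, s, v in verdict.per_anchor_projections
            ],
        }

    run_check("topology", topology_check)

    if interface_groups:
        def interfaces():
            out = []
            for ga, gb in interface_groups:
                rep = buried_surface_area(structure, ga, gb)
                out.append(
                    {
                        "group_a": list(rep.group_a),
                        "group_b": list(rep.group_b),
                        "buried_area": _round(rep.buried_area, 0),
                        "n_contacts": rep.n_contacts,
                        "interface_residues": {
                            k: [[c, s] for c, s in v]
                            for k, v in rep.interface_residues.items()
                        },
                    }
                )
            return out

        run_check("interfaces", interfaces)

    if fasta_path and chain_map:
        def glycans():
            records = read_fasta(fasta_path)
            iface: set[tuple[str, int]] = set()
            chains = structure.chain_ids
            from .scoring import interface_contacts

            for i, cid in enumerate(chains):
                rest = [c for c in chains if c != cid]
                if not rest:
                    break
                _, residues = interface_contacts(
                    structure, [cid], rest, cutoff=config.contact_cutoff
                )
                iface |= residues["a"] | residues["b"]
            out = []
            for rec in records:
                if rec.id not in chain_map:
                    continue
                hits = map_sequons(structure, find_sequons(rec), chain_map)
                reports = glycan_interface_clash(
                    structure, hits, sorted(iface), threshold=config.clash_threshold
                )
                for r in reports:
                    out.append(
                        {
                            "protein": r.sequon.protein,
                            "position": r.sequon.position,
                            "triplet": r.sequon.triplet,
                            "on_structure": list(r.sequon.on_structure)
                            if r.sequon.on_structure
                            else None,
                            "distance": _round(r.distance, 2)
                            if math.isfinite(r.distance)
                            else None,
                            "flagged": r.flagged,
                        }
                    )
            return out

        run_check("glycan_clashes", glycans)

    if reference_path:
        def superposition():
            reference = read_structure(reference_path, predicted=False)
            pairs = match_residues(structure, reference, method="author-number")
            res = superpose_with_rejection(
                pairs,
                sigma_cutoff=config.rejection_sigma,
                max_cycles=config.rejection_cycles,
            )
            return {
                "rmsd": _round(res.rmsd, 2),
                "n_used": res.n_used,
                "n_rejected": res.n_rejected,
                "cycles": res.cycles,
            }

        run_check("superposition", superposition)

    topo = report["checks"].get("topology", {})
    topology_ok = bool(topo.get("separable", False))
    status = EXIT_OK if (topology_ok and not failed) else EXIT_VALIDATION_FAILED
    report["status"] = status

    report_path = out_dir / "validation_report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    inputs = [p for p in (structure_path, reference_path, fasta_path) if p]
    write_manifest(out_dir, inputs, config.to_dict(), [report_path])
    return report, status
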