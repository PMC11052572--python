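#!/usr/bin/env python
"""Reproduce the published-complex analyses from locally downloaded files.

This optional companion to scripts/acceptance.py operates on real
deposited prediction files (coordinate + metrics archives for the
gamete-fusion screen) and an experimental reference structure, none of
which ship with the repository. Point it at whichever inputs you have:

  python scripts/reproduce.py \
      --model human_juno_izumo1.pdb --reference 5f4e.pdb \
      --metrics ranking.json \
      --pairs-dir screen_pairs/ --proteins proteins.json \
      --extent-model dcst1_dcst2.pdb \
      --interface-model fivemer.pdb --interface-groups CD9:IZUMO1,SPACA6 \
      --plddt-model tmem81.pdb --plddt-range A:31-184

Each analysis runs only when its inputs are supplied, and prints the
recomputed quantity: top/mean ensemble rc, RMSD vs. the reference before
and after outlier rejection (the rejection scheme is this package's
iterative sigma trimming; numbers from other programs' rejection
heuristics will differ), the interaction network at a mean-rc cutoff of
0.4, maximum assembly extent, combined buried interface area (expect
~10-15% spread against figures computed with other SASA parameters), and
mean pLDDT over a residue range.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from fusescreen import io as fio
from fusescreen.geometry import (
    buried_surface_area,
    kabsch,
    match_residues,
    max_extent,
    mean_plddt,
    superpose_with_rejection,
)
from fusescreen.pipeline import RunConfig, run_screen
from fusescreen.types import ProteinEntry


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--model", type=Path, help="predicted complex (PDB/mmCIF)")
    p.add_argument("--reference", type=Path, help="experimental reference structure")
    p.add_argument("--metrics", type=Path, help="per-model metrics JSON (or directory)")
    p.add_argument("--pairs-dir", type=Path, help="directory of per-pair metrics files")
    p.add_argument("--proteins", type=Path, help="JSON list of {name, side}")
    p.add_argument("--hub", default="IZUMO1")
    p.add_argument("--cutoff", type=float, default=0.4)
    p.add_argument("--extent-model", type=Path, help="structure for max-extent measurement")
    p.add_argument("--interface-model", type=Path)
    p.add_argument("--interface-groups", help="e.g. CD9:IZUMO1,SPACA6 (chain ids)")
    p.add_argument("--plddt-model", type=Path)
    p.add_argument("--plddt-range", help="CHAIN:START-END, e.g. A:31-184")
    p.add_argument("--out", type=Path, default=Path("results/reproduce.json"))
    args = p.parse_args()
    out: dict[str, float] = {}

    if args.metrics:
        scores = fio.read_model_scores(args.metrics)
        rcs = [s.rc for s in scores]
        out["ensemble_top_rc"] = max(rcs)
        out["ensemble_mean_rc"] = float(np.mean(rcs))
        out["ensemble_mean_iptm"] = float(np.mean([s.iptm for s in scores]))
        print(f"ensemble: top rc {max(rcs):.2f}, mean rc {np.mean(rcs):.2f}, "
              f"mean ipTM {np.mean([s.iptm for s in scores]):.2f} over {len(rcs)} models")

    if args.model and args.reference:
        model = fio.read_structure(args.model)
        reference = fio.read_structure(args.reference, predicted=False)
        pairs = match_residues(model, reference, method="author-number")
        plain = kabsch(pairs)
        trimmed = superpose_with_rejection(pairs)
        out["rmsd_all_pairs"] = plain.rmsd
        out["n_ca_pairs"] = plain.n_used
        out["rmsd_after_rejection"] = trimmed.rmsd
        out["n_ca_after_rejection"] = trimmed.n_used
        print(f"superposition: {plain.rmsd:.2f} Å over {plain.n_used} Cα "
              f"({trimmed.rmsd:.2f} Å over {trimmed.n_used} Cα after rejection)")

    if args.pairs_dir and args.proteins:
        proteins = [
            ProteinEntry(name=r["name"], side=r["side"])
            for r in json.loads(args.proteins.read_text())
        ]
        res = run_screen(
            args.pairs_dir, proteins, args.out.parent / "screen_out",
            config=RunConfig(mean_rc_cutoff=args.cutoff), hub=args.hub,
        )
        classes = [d["classification"] for _, _, d in res.hub_graph.edges(data=True)]
        out["network_interactions"] = res.graph.number_of_edges()
        out["hub_cluster_interactions"] = classes.count("direct") + classes.count("indirect")
        out["hub_direct_interactions"] = classes.count("direct")
        print(f"network: {res.graph.number_of_edges()} interactions at mean rc >= "
              f"{args.cutoff}; hub {args.hub}: {classes.count('direct')} direct, "
              f"{classes.count('indirect')} indirect")

    if args.extent_model:
        extent = max_extent(fio.read_structure(args.extent_model))
        out["max_extent"] = extent
        print(f"max extent: {extent:.0f} Å")

    if args.interface_model and args.interface_groups:
        ga, gb = args.interface_groups.split(":")
        rep = buried_surface_area(
            fio.read_structure(args.interface_model), ga.split(","), gb.split(",")
        )
        out["combined_interface_area"] = rep.buried_area
        print(f"combined interface area {ga} vs {gb}: {rep.buried_area:.0f} Å^2")

    if args.plddt_model and args.plddt_range:
        chain, span = args.plddt_range.split(":")
        lo, hi = (int(x) for x in span.split("-"))
        value = mean_plddt(fio.read_structure(args.plddt_model), chain, (lo, hi))
        out["mean_plddt"] = value
        print(f"mean pLDDT {chain} {lo}-{hi}: {value:.1f}")

    if not out:
        p.error("no inputs supplied; see --help for the available analyses")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
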