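"""Readers and writers for every external artifact the pipeline touches.

Coordinate files (PDB/mmCIF) are parsed with gemmi; per-model confidence
metrics and PAE matrices come from JSON files in the two dialects that
predictor deposits commonly use; sequences from FASTA via Biopython;
screen results go to/from tab-separated tables.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    Atom,
    Chain,
    ModelScore,
    PAEMatrix,
    Residue,
    ScreenEntry,
    SequenceRecord,
    Structure,
)

__all__ = [
    "read_structure",
    "write_structure_pdb",
    "read_model_scores",
    "read_pae",
    "read_fasta",
    "write_screen_table",
    "read_screen_table",
]

PathLike = Union[str, Path]

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(
    path: PathLike, format: str = "auto", predicted: bool = True
) -> Structure:
    """Read a multi-chain coordinate file into a :class:`Structure`.

    Author residue numbering and the B-factor column are preserved
    verbatim. With ``predicted=True`` the B-factor column is interpreted
    as pLDDT (0-100); out-of-range values are flagged with a warning but
    kept, so that experimental B-factors are never silently rewritten.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    chains: list[Chain] = []
    n_atoms = 0
    out_of_range = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = []
            for ga in gres:
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        bfactor=float(ga.b_iso),
                    )
                )
                if predicted and not (0.0 <= ga.b_iso <= 100.0):
                    out_of_range += 1
            if atoms:
                n_atoms += len(atoms)
                residues.append(
                    Residue(seq_id=gres.seqid.num, name=gres.name, atoms=atoms)
                )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if n_atoms == 0:
        raise ValueError(f"{path}: structure contains no atoms")
    if out_of_range:
        warnings.warn(
            f"{path}: {out_of_range} atoms have B-factors outside [0, 100] "
            "in a structure flagged as predicted (pLDDT expected)"
        )
    return Structure(
        model_id=path.stem, chains=chains, source_path=str(path), predicted=predicted
    )


def write_structure_pdb(structure: Structure, path: PathLike) -> None:
    """Write a :class:`Structure` back to PDB (coordinates to 3 decimals,
    B-factors to 2 — the format's own precision)."""
    st = gemmi.Structure()
    st.name = structure.model_id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.b_iso = atom.bfactor
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _scores_from_mapping(models: Mapping[str, Mapping[str, float]]) -> list[tuple[str, float, float, Optional[float]]]:
    out = []
    for name, rec in models.items():
        if "iptm" not in rec or "ptm" not in rec:
            raise ValueError(f"model {name!r}: metrics must carry both iptm and ptm")
        out.append((name, float(rec["iptm"]), float(rec["ptm"]), rec.get("rc")))
    return out


def read_model_scores(path: PathLike) -> list[ModelScore]:
    """Read per-model confidence metrics and recompute ranking confidence.

    Two dialects are accepted:

    * a consolidated JSON file: either a flat ``{model: {"iptm": .., "ptm": ..}}``
      mapping, or ``{"models": {...}, "order": [names rank-first]}``;
    * a directory of per-model ``*.json`` files, each with ``iptm``/``ptm``.

    rc is always recomputed as 0.8*ipTM + 0.2*pTM; an rc stored in the
    file that disagrees by more than 1e-6 triggers a warning and the
    recomputed value wins. Ranks come from an explicit ``order`` list when
    present, otherwise from descending rc with ties broken by model name.
    """
    path = Path(path)
    order: Optional[list[str]] = None
    if path.is_dir():
        raw = []
        for f in sorted(path.glob("*.json")):
            rec = json.loads(f.read_text())
            name = rec.get("model_name", f.stem)
            raw.extend(_scores_from_mapping({name: rec}))
    else:
        data = json.loads(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: metrics JSON must be an object")
        if "models" in data:
            order = data.get("order")
            raw = _scores_from_mapping(data["models"])
        else:
            raw = _scores_from_mapping(
                {k: v for k, v in data.items() if isinstance(v, Mapping)}
            )
    if not raw:
        raise ValueError(f"{path}: no models found")

    for name, iptm, ptm, stored_rc in raw:
        if stored_rc is not None and abs(stored_rc - (0.8 * iptm + 0.2 * ptm)) > 1e-6:
            warnings.warn(
                f"model {name!r}: stored rc {stored_rc} disagrees with "
                f"0.8*iptm+0.2*ptm; recomputed value used"
            )

    if order is not None:
        known = {name for name, *_ in raw}
        if set(order) != known:
            raise ValueError("explicit rank order does not match the model set")
        rank_of = {name: i + 1 for i, name in enumerate(order)}
    else:
        by_rc = sorted(raw, key=lambda r: (-(0.8 * r[1] + 0.2 * r[2]), r[0]))
        rank_of = {name: i + 1 for i, (name, *_) in enumerate(by_rc)}

    scores = [
        ModelScore(model_name=name, iptm=iptm, ptm=ptm, rank=rank_of[name])
        for name, iptm, ptm, _ in raw
    ]
    scores.sort(key=lambda s: s.rank)
    return scores


def read_pae(path: PathLike, chain_lengths: Mapping[str, int]) -> PAEMatrix:
    """Read a PAE matrix from JSON and attach the chain -> row map.

    Accepts ``{"predicted_aligned_error": [[..]]}``, ``{"pae": [[..]]}``
    or a single-element list wrapping either (the predictor's own output
    shape). ``chain_lengths`` gives the residue count of each chain in
    matrix order; their sum must equal the matrix size.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if isinstance(data, list):
        if len(data) != 1 or not isinstance(data[0], dict):
            raise ValueError(f"{path}: unrecognized PAE JSON layout")
        data = data[0]
    for key in ("predicted_aligned_error", "pae"):
        if key in data:
            values = np.asarray(data[key], dtype=float)
            break
    else:
        raise ValueError(f"{path}: no 'predicted_aligned_error' or 'pae' field")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: PAE matrix must be square, got {values.shape}")
    total = sum(chain_lengths.values())
    if total != values.shape[0]:
        raise ValueError(
            f"{path}: chain lengths sum to {total} but matrix is {values.shape[0]}"
        )
    ranges: dict[str, tuple[int, int]] = {}
    pos = 0
    for cid, length in chain_lengths.items():
        ranges[cid] = (pos, pos + length)
        pos += length
    return PAEMatrix(values=values, chain_ranges=ranges)


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA records. A header token ``region=START-END`` (1-based,
    inclusive) is parsed into the record's region, e.g. an ectodomain span."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        region = None
        for token in rec.description.split():
            if token.startswith("region="):
                lo, hi = token[len("region="):].split("-")
                region = (int(lo), int(hi))
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), region=region))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


_SCREEN_COLUMNS = [
    "protein_a",
    "protein_b",
    "top_rc",
    "mean_rc",
    "top_iptm",
    "n_models",
    "pdockq_a",
    "pdockq_b",
]


def write_screen_table(entries: Iterable[ScreenEntry], path: PathLike) -> None:
    """Write screen results as a TSV with a stable column order; floats at
    6 decimals so the table round-trips losslessly through the reader."""
    entries = list(entries)
    if not entries:
        raise ValueError("refusing to write an empty screen table")
    rows = [
        {
            "protein_a": e.pair[0],
            "protein_b": e.pair[1],
            "top_rc": e.top_rc,
            "mean_rc": e.mean_rc,
            "top_iptm": e.top_iptm,
            "n_models": e.n_models,
            "pdockq_a": e.pdockq_a,
            "pdockq_b": e.pdockq_b,
        }
        for e in entries
    ]
    df = pd.DataFrame(rows, columns=_SCREEN_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_screen_table(path: PathLike) -> list[ScreenEntry]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SCREEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing screen columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            ScreenEntry(
                pair=(str(row.protein_a), str(row.protein_b)),
                top_rc=float(row.top_rc),
                mean_rc=float(row.mean_rc),
                top_iptm=float(row.top_iptm),
                n_models=int(row.n_models),
                pdockq_a=float(row.pdockq_a) if not pd.isna(row.pdockq_a) else math.nan,
                pdockq_b=float(row.pdockq_b) if not pd.isna(row.pdockq_b) else math.nan,
            )
        )
    return entries
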