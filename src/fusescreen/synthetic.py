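"""Synthetic fixtures with planted ground truth.

Every input class the pipeline consumes can be generated here with known
answers: toy multi-chain structures with an exact planted inter-chain
contact count and pLDDT profile, paired metrics/PAE files in both
supported JSON dialects, all-vs-all screens with a planted interaction
network, and sequences with sequons planted at known positions and
nowhere else. Chains are geometric traces, not physically plausible
folds: the scored quantities (contacts, confidences, distances) are what
the pipeline evaluates, never stereochemistry.

All generators are deterministic under a fixed seed (one rng per call,
no global state) and their outputs are verified internally against
brute force before anything is written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io import write_structure_pdb
from .network import enumerate_pairs
from .types import Atom, Chain, ProteinEntry, Residue, SequenceRecord, Structure

__all__ = [
    "ChainPlan",
    "ContactPlan",
    "ToyComplexSpec",
    "ScreenSpec",
    "SequencePlan",
    "FixtureSpec",
    "build_toy_structure",
    "make_toy_complex",
    "make_screen",
    "make_sequences",
    "default_screen_spec",
]

_CA_SPACING = 3.8  # Å between consecutive residues along a trace
_CHAIN_SEPARATION = 200.0  # Å between baseline traces of different chains
_CONTACT_DISTANCE = 7.5  # Å, inside the 8 Å cutoff; neighbors land at 8.41 Å
_SLOT_STRIDE = 3  # residues between planted contacts (11.4 Å > cutoff)


@dataclass
class ChainPlan:
    """One synthetic chain: id, length and a pLDDT profile (scalar or
    one value per residue, 0-100)."""

    chain_id: str
    length: int
    plddt: Union[float, Sequence[float]] = 90.0
    side: str = "sperm"  # used when the fixture feeds topology tests

    def plddt_values(self) -> np.ndarray:
        if np.isscalar(self.plddt):
            return np.full(self.length, float(self.plddt))
        vals = np.asarray(self.plddt, dtype=float)
        if len(vals) != self.length:
            raise ValueError(
                f"chain {self.chain_id}: {len(vals)} pLDDT values for "
                f"{self.length} residues"
            )
        return vals


@dataclass
class ContactPlan:
    """Exactly ``n_contacts`` Cβ-contact residue pairs between two chains."""

    chain_a: str
    chain_b: str
    n_contacts: int

    def __post_init__(self) -> None:
        if self.chain_a == self.chain_b:
            raise ValueError("contact plans are inter-chain; got a self-pair")
        if self.n_contacts < 0:
            raise ValueError("n_contacts must be >= 0")


@dataclass
class ToyComplexSpec:
    seed: int
    chains: list[ChainPlan]
    contacts: list[ContactPlan] = field(default_factory=list)
    # per-model (iptm, ptm); rc follows as 0.8*iptm + 0.2*ptm
    metrics: list[tuple[float, float]] = field(default_factory=lambda: [(0.8, 0.7)])
    pae_intra: float = 3.0
    pae_inter_default: float = 20.0
    # planted inter-chain PAE block values, keyed by (chain_a, chain_b)
    pae_inter: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class ScreenSpec:
    """All-vs-all screen over named proteins with a planted true network.

    True edges receive ensemble mean rc inside ``edge_band``, all other
    pairs inside ``nonedge_band``; the bands must not overlap, otherwise
    recovery of the planted graph would be ill-posed.
    """

    seed: int
    proteins: list[ProteinEntry]
    true_edges: set[tuple[str, str]]
    edge_band: tuple[float, float] = (0.45, 0.95)
    nonedge_band: tuple[float, float] = (0.05, 0.35)
    n_models: int = 5

    def __post_init__(self) -> None:
        self.true_edges = {tuple(sorted(e)) for e in self.true_edges}
        names = {p.name for p in self.proteins}
        stray = {e for e in self.true_edges if not set(e) <= names}
        if stray:
            raise ValueError(f"true edges name unknown proteins: {sorted(stray)}")
        lo_e, hi_e = self.edge_band
        lo_n, hi_n = self.nonedge_band
        if not (0 <= lo_n <= hi_n and lo_e <= hi_e <= 1):
            raise ValueError("bands must be ordered and within [0, 1]")
        if max(lo_e, lo_n) <= min(hi_e, hi_n):
            raise ValueError("edge and non-edge rc bands overlap; recovery ill-posed")


@dataclass
class SequencePlan:
    """One synthetic sequence with sequons planted at exact Asn positions."""

    name: str
    length: int
    sequon_positions: list[int] = field(default_factory=list)


@dataclass
class FixtureSpec:
    """Aggregate plan covering every generator; sub-plans are optional."""

    seed: int
    complex_spec: Optional[ToyComplexSpec] = None
    screen_spec: Optional[ScreenSpec] = None
    sequence_plans: list[SequencePlan] = field(default_factory=list)


def _allocate_slots(spec: ToyComplexSpec) -> dict[int, list[tuple[str, int, int]]]:
    """Per contact plan, choose target residue indices (on the lexicographic
    smaller chain) and source residue indices (moved residues of the other
    chain) so that every planted contact is an isolated Cβ pair.

    Raises before any file is written if a plan is unrealizable.
    """
    lengths = {c.chain_id: c.length for c in spec.chains}
    target_cursor: dict[str, int] = {}
    # source residues are taken from the chain end downward so they never
    # collide with the same chain's use as a contact target
    source_next = dict(lengths)
    max_target: dict[str, int] = {}
    min_source: dict[str, int] = {}
    layout: dict[int, list[tuple[str, int, int]]] = {}
    for p_idx, plan in enumerate(spec.contacts):
        for cid in (plan.chain_a, plan.chain_b):
            if cid not in lengths:
                raise ValueError(f"contact plan names unknown chain {cid!r}")
        target, source = sorted((plan.chain_a, plan.chain_b))
        pairs = []
        for _ in range(plan.n_contacts):
            t_idx = target_cursor.get(target, 0)
            s_idx = source_next[source] - 1
            target_cursor[target] = t_idx + _SLOT_STRIDE
            source_next[source] = s_idx
            if t_idx >= lengths[target] or s_idx < 0:
                raise ValueError(
                    f"contact plan {plan.chain_a}-{plan.chain_b}: chains too "
                    f"short for {plan.n_contacts} isolated contacts"
                )
            max_target[target] = max(max_target.get(target, -1), t_idx)
            min_source[source] = min(min_source.get(source, lengths[source]), s_idx)
            pairs.append((target, t_idx, s_idx))
        # leave a gap between plans so moved residues of different plans
        # never come within the contact cutoff of each other
        if plan.n_contacts and target in target_cursor:
            target_cursor[target] += _SLOT_STRIDE
        layout[p_idx] = pairs
    for cid in set(max_target) & set(min_source):
        if max_target[cid] >= min_source[cid]:
            raise ValueError(
                f"chain {cid!r} too short to serve as both contact target and source"
            )
    return layout


def build_toy_structure(spec: ToyComplexSpec) -> Structure:
    """Build the planted-contact toy complex in memory.

    Each chain is a straight Cα/Cβ poly-alanine trace on its own
    baseline, 200 Å from every other chain; for each planted contact one
    residue of the source chain is relocated next to the target chain at
    7.5 Å Cβ-Cβ, spaced so that no unplanned pair falls within 8 Å.
    The realized contact counts are verified against an all-pairs brute
    force before returning.
    """
    layout = _allocate_slots(spec)
    baselines = {c.chain_id: i * _CHAIN_SEPARATION for i, c in enumerate(spec.chains)}
    # position overrides: (chain, residue index) -> (x, y)
    overrides: dict[tuple[str, int], tuple[float, float]] = {}
    planted: dict[tuple[str, str], int] = {}
    for p_idx, plan in enumerate(spec.contacts):
        target, _source = sorted((plan.chain_a, plan.chain_b))
        source = plan.chain_b if target == plan.chain_a else plan.chain_a
        key = tuple(sorted((plan.chain_a, plan.chain_b)))
        planted[key] = planted.get(key, 0) + plan.n_contacts
        for tgt, t_idx, s_idx in layout[p_idx]:
            # source residue s_idx sits opposite target residue t_idx
            overrides[(source, s_idx)] = (
                t_idx * _CA_SPACING,
                baselines[tgt] + _CONTACT_DISTANCE,
            )

    chains = []
    for plan in spec.chains:
        plddts = plan.plddt_values()
        residues = []
        for i in range(plan.length):
            x, y = overrides.get((plan.chain_id, i), (i * _CA_SPACING, baselines[plan.chain_id]))
            ca = Atom("CA", "C", np.array([x, y, 0.0]), bfactor=float(plddts[i]))
            cb = Atom("CB", "C", np.array([x, y, 1.5]), bfactor=float(plddts[i]))
            residues.append(Residue(seq_id=i + 1, name="ALA", atoms=[ca, cb]))
        chains.append(Chain(chain_id=plan.chain_id, residues=residues))
    structure = Structure(model_id=f"toy_seed{spec.seed}", chains=chains)

    _verify_contacts(structure, planted)
    return structure


def _verify_contacts(structure: Structure, planted: dict[tuple[str, str], int]) -> None:
    """Brute-force all-pairs check that realized == planted contacts."""
    cbs = {
        c.chain_id: np.array([r.contact_atom().coord for r in c.residues])
        for c in structure.chains
    }
    ids = structure.chain_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            d = np.linalg.norm(cbs[a][:, None, :] - cbs[b][None, :, :], axis=2)
            realized = int((d <= 8.0).sum())
            expected = planted.get((a, b), 0)
            if realized != expected:
                raise AssertionError(
                    f"planted contact plan not realized for {a}-{b}: "
                    f"{realized} != {expected}"
                )


def _metrics_payload(spec: ToyComplexSpec) -> dict:
    models = {}
    for k, (iptm, ptm) in enumerate(spec.metrics, start=1):
        models[f"model_{k}"] = {"iptm": iptm, "ptm": ptm}
    order = sorted(
        models, key=lambda m: (-(0.8 * models[m]["iptm"] + 0.2 * models[m]["ptm"]), m)
    )
    return {"models": models, "order": order}


def make_toy_complex(spec: ToyComplexSpec, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the toy complex and its paired metrics/PAE files.

    Metrics are serialized in both supported dialects (consolidated JSON
    and a per-model directory), the PAE matrix in both field spellings.
    Returns the paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    structure = build_toy_structure(spec)  # raises before any file is written
    out_dir.mkdir(parents=True, exist_ok=True)

    structure_path = out_dir / "complex.pdb"
    write_structure_pdb(structure, structure_path)

    payload = _metrics_payload(spec)
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    metrics_dir = out_dir / "metrics_per_model"
    metrics_dir.mkdir(exist_ok=True)
    for name, rec in payload["models"].items():
        (metrics_dir / f"{name}.json").write_text(json.dumps(rec, sort_keys=True))

    lengths = [c.length for c in spec.chains]
    size = sum(lengths)
    pae = np.full((size, size), spec.pae_inter_default)
    starts = np.concatenate([[0], np.cumsum(lengths)])
    for i, ci in enumerate(spec.chains):
        pae[starts[i]:starts[i + 1], starts[i]:starts[i + 1]] = spec.pae_intra
    for (a, b), value in spec.pae_inter.items():
        ia = [c.chain_id for c in spec.chains].index(a)
        ib = [c.chain_id for c in spec.chains].index(b)
        pae[starts[ia]:starts[ia + 1], starts[ib]:starts[ib + 1]] = value
        pae[starts[ib]:starts[ib + 1], starts[ia]:starts[ia + 1]] = value
    pae_list = pae.tolist()
    pae_path = out_dir / "pae.json"
    pae_path.write_text(json.dumps({"predicted_aligned_error": pae_list}))
    pae_alt_path = out_dir / "pae_alt.json"
    pae_alt_path.write_text(json.dumps([{"pae": pae_list}]))

    return {
        "structure": structure_path,
        "metrics": metrics_path,
        "metrics_dir": metrics_dir,
        "pae": pae_path,
        "pae_alt": pae_alt_path,
    }


def make_screen(spec: ScreenSpec, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write per-pair metrics files for an all-vs-all screen plus the truth.

    Every enumerated pair (self-pairs included) gets a consolidated
    metrics JSON whose per-model rc values all lie in the planted band
    for that pair (edge vs. non-edge), so the ensemble mean does too.
    The planted graph is recorded in ``truth.json``.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    pairs = enumerate_pairs(spec.proteins)
    pairs_dir = out_dir / "pairs"
    pairs_dir.mkdir(parents=True, exist_ok=True)
    for a, b in pairs:
        lo, hi = spec.edge_band if (a, b) in spec.true_edges else spec.nonedge_band
        models = {}
        for k in range(1, spec.n_models + 1):
            rc = float(rng.uniform(lo, hi))
            # iptm = ptm = rc makes the recomputed rc land exactly on target
            models[f"model_{k}"] = {"iptm": rc, "ptm": rc}
        (pairs_dir / f"{a}__{b}.json").write_text(
            json.dumps({"models": models}, sort_keys=True)
        )
    truth = {
        "proteins": [
            {"name": p.name, "side": p.side} for p in sorted(spec.proteins, key=lambda p: p.name)
        ],
        "true_edges": sorted(list(e) for e in spec.true_edges),
        "edge_band": list(spec.edge_band),
        "nonedge_band": list(spec.nonedge_band),
        "n_models": spec.n_models,
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"pairs_dir": pairs_dir, "truth": truth_path}


_BACKGROUND_AA = "ACDEFGHIKLMQRVWY"  # no N (would seed sequons), no S/T/P edge cases


def make_sequences(
    plans: Sequence[SequencePlan], seed: int, out_path: Union[str, Path]
) -> list[SequenceRecord]:
    """Write a FASTA whose sequences contain sequons exactly at the
    planted Asn positions and nowhere else.

    The background alphabet contains no asparagine, so no accidental
    sequon can arise; each planted position receives N with a compatible
    X (never P) and S/T downstream. Overlapping plants are honored when
    feasible (e.g. NNSS) and rejected with an error otherwise (a planted
    Asn two positions after another would need to be both N and S/T).
    """
    rng = np.random.default_rng(seed)
    records = []
    for plan in plans:
        positions = sorted(set(plan.sequon_positions))
        for p in positions:
            if not (1 <= p and p + 2 <= plan.length):
                raise ValueError(f"{plan.name}: sequon at {p} does not fit length {plan.length}")
            if p + 2 in positions:
                raise ValueError(
                    f"{plan.name}: sequons at {p} and {p + 2} conflict "
                    "(position would need to be both N and S/T)"
                )
        letters = list(rng.choice(list(_BACKGROUND_AA), size=plan.length))
        planted = set(positions)
        for p in positions:
            letters[p - 1] = "N"
        for p in positions:
            if p + 1 not in planted and letters[p] == "P":
                letters[p] = "A"
            if p + 2 not in planted:
                letters[p + 1] = str(rng.choice(["S", "T"]))
        records.append(SequenceRecord(id=plan.name, seq="".join(letters)))

    # closed-loop self check before writing
    from .glycosites import find_sequons

    for plan, rec in zip(plans, records):
        found = sorted(h.position for h in find_sequons(rec))
        if found != sorted(set(plan.sequon_positions)):
            raise AssertionError(
                f"{plan.name}: planted sequons {sorted(set(plan.sequon_positions))} "
                f"but found {found}"
            )

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")
    return records


def default_screen_spec(seed: int, n_models: int = 5) -> ScreenSpec:
    """The package's flagship study condition: a 15-protein all-vs-all
    screen (4 egg, 11 sperm proteins of the mammalian gamete-fusion
    roster, 120 unique combinations) with a planted hub cluster of seven
    heteromeric interactions centered on IZUMO1 — five direct (JUNO, CD9,
    CD81, SPACA6, TMEM81) and two indirect (IZUMO4 via JUNO, SOF1 via
    SPACA6) — plus the isolated interactions IZUMO2-IZUMO3, TMEM95-FIMP,
    DCST1-DCST2 and the IZUMO4 and DCST1 homodimers."""
    egg = ["JUNO", "CD9", "CD81", "MAIA"]
    sperm = [
        "IZUMO1", "IZUMO2", "IZUMO3", "IZUMO4", "SPACA6", "TMEM81",
        "TMEM95", "SOF1", "FIMP", "DCST1", "DCST2",
    ]
    proteins = [ProteinEntry(name=n, side="egg") for n in egg] + [
        ProteinEntry(name=n, side="sperm") for n in sperm
    ]
    true_edges = {
        ("IZUMO1", "JUNO"), ("CD9", "IZUMO1"), ("CD81", "IZUMO1"),
        ("IZUMO1", "SPACA6"), ("IZUMO1", "TMEM81"),
        ("IZUMO4", "JUNO"), ("SOF1", "SPACA6"),
        ("IZUMO2", "IZUMO3"), ("FIMP", "TMEM95"), ("DCST1", "DCST2"),
        ("IZUMO4", "IZUMO4"), ("DCST1", "DCST1"),
    }
    return ScreenSpec(seed=seed, proteins=proteins, true_edges=true_edges, n_models=n_models)
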