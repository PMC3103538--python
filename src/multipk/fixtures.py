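"""Synthetic structures, ensembles and energy tables with known ground truth.

The builders emit chemically plausible (not physically minimised) toy
peptides in standard PDB layout: extended backbones with side chains
alternating above/below the chain axis, titratable functional groups placed
at controlled distances.  A "salt bridge" is a charged pair at 2.8–3.0 Å
donor–acceptor distance.  Regime-biased ensembles emulate conformer sets
sampled under different fixed protonation states: the set generated with
neutral carboxyls (glu0) breaks acid–base salt bridges, the neutral-lysine
set (lys0) breaks amino-group contacts.  Everything is deterministic under a
fixed integer seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .structure_io import (
    Atom,
    Conformer,
    Ensemble,
    ParameterTable,
    load_default_parameters,
)
from .titration_core import default_microstates, Microstate
from .pb_electrostatics import MicroEnergyRecord, SiteEnergyTable

__all__ = [
    "FixtureSpec",
    "make_toy_peptide",
    "make_regime_ensembles",
    "make_energy_table",
    "random_energy_table",
    "AA3",
]

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# side-chain templates: atom -> offset from CA, in a frame where the side
# chain extends along +y; backbone atoms are placed separately
_LIN = lambda *names: {n: (0.5 * ((k + 1) % 2), 1.53 + 1.35 * k, 0.0)
                       for k, n in enumerate(names)}

_SIDE = {
    "ALA": _LIN("CB"),
    "GLY": {},
    "SER": _LIN("CB", "OG"),
    "CYS": _LIN("CB", "SG"),
    "THR": {**_LIN("CB"), "OG1": (-0.7, 2.7, 0.0), "CG2": (0.9, 2.7, 0.0)},
    "VAL": {**_LIN("CB"), "CG1": (-0.7, 2.7, 0.0), "CG2": (0.9, 2.7, 0.0)},
    "LEU": {**_LIN("CB", "CG"), "CD1": (-0.9, 4.1, 0.0), "CD2": (1.1, 4.1, 0.0)},
    "ILE": {**_LIN("CB"), "CG1": (-0.7, 2.7, 0.0), "CG2": (0.9, 2.7, 0.0),
            "CD1": (-0.7, 4.1, 0.0)},
    "PRO": _LIN("CB", "CG", "CD"),
    "MET": _LIN("CB", "CG", "SD", "CE"),
    "PHE": {**_LIN("CB", "CG"), "CD1": (-1.2, 3.6, 0.0), "CD2": (1.2, 3.6, 0.0),
            "CE1": (-1.2, 5.0, 0.0), "CE2": (1.2, 5.0, 0.0), "CZ": (0.0, 5.7, 0.0)},
    "TYR": {**_LIN("CB", "CG"), "CD1": (-1.2, 3.6, 0.0), "CD2": (1.2, 3.6, 0.0),
            "CE1": (-1.2, 5.0, 0.0), "CE2": (1.2, 5.0, 0.0), "CZ": (0.0, 5.7, 0.0),
            "OH": (0.0, 7.1, 0.0)},
    "TRP": {**_LIN("CB", "CG"), "CD1": (-1.1, 3.7, 0.0), "CD2": (1.1, 3.7, 0.0),
            "NE1": (-0.7, 5.0, 0.0), "CE2": (0.7, 5.0, 0.0), "CE3": (2.3, 3.5, 0.0),
            "CZ2": (1.4, 6.1, 0.0), "CZ3": (3.0, 4.7, 0.0), "CH2": (2.8, 6.0, 0.0)},
    "ASN": {**_LIN("CB", "CG"), "OD1": (-0.9, 4.0, 0.0), "ND2": (1.1, 4.0, 0.0)},
    "GLN": {**_LIN("CB", "CG", "CD"), "OE1": (-0.9, 5.3, 0.0), "NE2": (1.1, 5.3, 0.0)},
    "ASP": {**_LIN("CB", "CG"), "OD1": (-0.63, 4.0, 0.0), "OD2": (0.93, 4.0, 0.0)},
    "GLU": {**_LIN("CB", "CG", "CD"), "OE1": (-0.63, 5.3, 0.0), "OE2": (0.93, 5.3, 0.0)},
    "LYS": _LIN("CB", "CG", "CD", "CE", "NZ"),
    "ARG": {**_LIN("CB", "CG", "CD", "NE", "CZ"),
            "NH1": (-0.6, 7.7, 0.0), "NH2": (0.9, 7.7, 0.0)},
    "HIS": {**_LIN("CB", "CG"), "ND1": (-1.1, 3.7, 0.0), "CD2": (1.1, 3.7, 0.0),
            "CE1": (-0.7, 5.0, 0.0), "NE2": (0.7, 5.0, 0.0)},
}

#: the functional-group tip atom per residue (used to set contact distances)
_TIP = {"GLU": "OE2", "ASP": "OD2", "LYS": "NZ", "ARG": "NH1", "HIS": "NE2",
        "TYR": "OH", "CYS": "SG", "SER": "OG"}

_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_of(name: str) -> str:
    return _ELEMENT.get(name[0], "C")


class FixtureGeometryError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for a deterministic toy system.

    ``chains`` — one sequence (1-letter string or list of 3-letter codes)
    per chain.  ``bridge`` — optional ((chain_idx, resnum), (chain_idx,
    resnum), distance Å): the second chain is flipped to face the first and
    translated so the two functional tips sit at the given distance
    (a 2.8–3.0 Å distance is a salt bridge).  ``mirrored`` — chain B becomes
    an exact mirror image of chain A through the z = 0 plane, the two
    chains separated by ``z_separation``.  ``regime_shift`` — extra tip
    separation (Å) applied to the bridge partner chain when generating the
    named regime's ensemble; by default both neutralised regimes (glu0,
    lys0) lose the bridge, since a neutral partner no longer holds it.
    ``n_snapshots`` defaults to 280 conformers per
    ensemble (one per 50 ps over 14 ns); ``jitter_sigma`` is the coordinate
    noise between snapshots.
    """

    chains: Sequence = ("GSE",)
    bridge: tuple | None = None
    mirrored: bool = False
    z_separation: float = 10.0
    n_snapshots: int = 280
    jitter_sigma: float = 0.3
    regime_shift: Mapping[str, float] = field(
        default_factory=lambda: {"glu0": 5.0, "lys0": 5.0})
    seed: int = 0
    contact_limit: float = 2.6


def _sequence_3letter(seq) -> list:
    if isinstance(seq, str):
        return [AA3[c] for c in seq]
    return list(seq)


def _build_chain(seq3: list, chain_id: str) -> list:
    atoms = []
    for k, resname in enumerate(seq3):
        if resname not in _SIDE:
            raise FixtureGeometryError(f"no template for residue {resname}")
        x0 = 3.8 * k
        flip = -1.0 if k % 2 else 1.0
        resnum = k + 1
        # carbonyl points away from the side chain so the backbone dipole
        # does not sit on top of the functional groups
        bb = [("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
              ("C", (2.46, -0.9 * flip, 0.0)), ("O", (2.2, -2.1 * flip, 0.0))]
        for name, (dx, dy, dz) in bb:
            atoms.append(Atom(name, _element_of(name),
                              np.array([x0 + dx, dy, dz]),
                              chain_id, resname, resnum))
        ca = np.array([x0 + 1.46, 0.0, 0.0])
        for name, (dx, dy, dz) in _SIDE[resname].items():
            atoms.append(Atom(name, _element_of(name),
                              ca + np.array([dx, flip * dy, dz]),
                              chain_id, resname, resnum))
        if k == len(seq3) - 1:
            atoms.append(Atom("OXT", "O", np.array([x0 + 3.2, 1.5 * flip, 0.0]),
                              chain_id, resname, resnum))
    return atoms


def _tip_position(atoms: list, resnum: int, chain: str) -> np.ndarray:
    res_atoms = [a for a in atoms if a.resnum == resnum and a.chain == chain]
    if not res_atoms:
        raise FixtureGeometryError(f"no residue {resnum} in chain {chain}")
    tip = _TIP.get(res_atoms[0].resname)
    if tip is None:
        raise FixtureGeometryError(f"residue {res_atoms[0].resname} has no functional tip")
    for a in res_atoms:
        if a.name == tip:
            return a.coords
    raise FixtureGeometryError(f"tip atom {tip} missing")


def make_toy_peptide(spec: FixtureSpec) -> tuple:
    """Build the base conformer of a fixture spec.

    Returns (conformer, parameter_table); the table is the packaged default,
    which resolves every atom the builder emits.
    """
    chain_ids = [chr(ord("A") + i) for i in range(len(spec.chains))]
    chains = [_build_chain(_sequence_3letter(s), cid)
              for s, cid in zip(spec.chains, chain_ids)]

    if spec.mirrored:
        if len(chains) != 1:
            raise FixtureGeometryError("mirrored fixtures take a single template chain")
        for a in chains[0]:
            a.coords = a.coords + np.array([0.0, 0.0, spec.z_separation / 2.0])
        mirrored = [replace(a, chain="B", coords=a.coords * np.array([1.0, 1.0, -1.0]))
                    for a in chains[0]]
        chains.append(mirrored)
    elif spec.bridge is not None:
        (ca_idx, ra), (cb_idx, rb), dist = spec.bridge
        if dist < spec.contact_limit:
            raise FixtureGeometryError(
                f"bridge distance {dist} below contact limit {spec.contact_limit}")
        if ca_idx == cb_idx:
            raise FixtureGeometryError("bridge sites must sit on different chains")
        # flip the partner chain so its side chains face the first chain
        for a in chains[cb_idx]:
            a.coords = a.coords * np.array([1.0, -1.0, 1.0])
        tip_a = _tip_position(chains[ca_idx], ra, chain_ids[ca_idx])
        # direction: outward from chain A along +y if the acid tip is above
        direction = np.array([0.0, 1.0 if tip_a[1] >= 0 else -1.0, 0.0])
        tip_b = _tip_position(chains[cb_idx], rb, chain_ids[cb_idx])
        shift = tip_a + direction * dist - tip_b
        for a in chains[cb_idx]:
            a.coords = a.coords + shift

    atoms = [a for ch in chains for a in ch]
    return Conformer(atoms, source_label="fixture"), load_default_parameters()


def _bridge_axis(spec: FixtureSpec, conformer: Conformer) -> tuple:
    (ca_idx, ra), (cb_idx, rb), dist = spec.bridge
    chain_ids = [chr(ord("A") + i) for i in range(len(spec.chains))]
    tip_a = _tip_position(conformer.atoms, ra, chain_ids[ca_idx])
    tip_b = _tip_position(conformer.atoms, rb, chain_ids[cb_idx])
    axis = tip_b - tip_a
    norm = np.linalg.norm(axis)
    return chain_ids[cb_idx], axis / norm


def make_regime_ensembles(spec: FixtureSpec) -> dict:
    """Three regime-tagged ensembles of jittered conformers.

    The regimes share the base geometry; for each regime listed in
    ``spec.regime_shift`` the bridge partner chain is moved apart by the
    given extra distance, emulating the loss of the salt bridge when the
    acid (glu0) or base (lys0) is neutralised in the sampling run.  With
    ``mirrored`` specs the jitter of chain A is mirrored onto chain B so the
    two chains stay exactly symmetric.
    """
    base, _ = make_toy_peptide(spec)
    rng = np.random.default_rng(spec.seed)
    out = {}
    for regime in ("allC", "glu0", "lys0"):
        conformers = []
        shift_chain, axis = (None, None)
        extra = float(spec.regime_shift.get(regime, 0.0))
        if spec.bridge is not None and extra != 0.0:
            shift_chain, axis = _bridge_axis(spec, base)
        for mth in range(spec.n_snapshots):
            atoms = [replace(a, coords=a.coords.copy()) for a in base.atoms]
            if spec.mirrored:
                a_idx = [k for k, a in enumerate(atoms) if a.chain == "A"]
                b_idx = [k for k, a in enumerate(atoms) if a.chain == "B"]
                noise = rng.normal(0.0, spec.jitter_sigma, (len(a_idx), 3))
                for (k, nz) in zip(a_idx, noise):
                    atoms[k].coords = atoms[k].coords + nz
                mirror = np.array([1.0, 1.0, -1.0])
                for k, ka in zip(b_idx, a_idx):
                    atoms[k].coords = atoms[ka].coords * mirror
            else:
                noise = rng.normal(0.0, spec.jitter_sigma, (len(atoms), 3))
                for a, nz in zip(atoms, noise):
                    a.coords = a.coords + nz
            if shift_chain is not None:
                for a in atoms:
                    if a.chain == shift_chain:
                        a.coords = a.coords + axis * extra
            conformers.append(Conformer(atoms, source_label=f"{regime}:{mth + 1}"))
        out[regime] = Ensemble(regime, conformers)
    return out


def make_energy_table(
    site_classes: Sequence[str],
    pk_int: Sequence[float],
    w_kcal: Mapping[tuple, float] | np.ndarray | None = None,
    temperature: float = 298.0,
) -> SiteEnergyTable:
    """Site-energy table with prescribed intrinsic pK values and couplings.

    ``w_kcal`` maps site-index pairs (i, j) to the interaction energy of the
    two charged (non-reference) microstates, or is a symmetric matrix.
    Bypasses the PB solver entirely — the ground truth for titration tests.
    """
    n = len(site_classes)
    site_ids = [("A", cls.upper()[:3], i + 1, "") for i, cls in enumerate(site_classes)]
    records = []
    for cls, pk in zip(site_classes, pk_int):
        ms = default_microstates(cls, pk)
        ref_pk = next((m.pk_std for m in ms if not math.isnan(m.pk_std)), 0.0)
        recs = []
        for m in ms:
            pk_std = ref_pk if math.isnan(m.pk_std) else m.pk_std
            recs.append(MicroEnergyRecord(
                m.label, m.proton_count, m.is_reference, pk_std,
                pk_int=pk_std))
        records.append(recs)
    pair_w = {}
    if w_kcal is not None:
        if isinstance(w_kcal, np.ndarray):
            items = [((i, j), w_kcal[i, j]) for i in range(n) for j in range(i + 1, n)
                     if w_kcal[i, j] != 0.0]
        else:
            items = list(w_kcal.items())
        for (i, j), w in items:
            if i > j:
                i, j = j, i
            mat = np.zeros((len(records[i]), len(records[j])))
            mat[-1, -1] = w  # charged microstates are listed last
            pair_w[(i, j)] = mat
    return SiteEnergyTable(site_ids, list(site_classes), records, pair_w, temperature)


def random_energy_table(n_sites: int, seed: int, w_scale: float = 1.5,
                        coupling_density: float = 0.35) -> SiteEnergyTable:
    """Seeded random mixed-class system for sampler/enumeration cross-checks."""
    rng = np.random.default_rng(seed)
    classes = []
    pks = []
    for i in range(n_sites):
        cls = ("carboxyl", "amino", "imidazole")[int(rng.integers(0, 3))]
        base = {"carboxyl": 4.2, "amino": 10.4, "imidazole": 6.4}[cls]
        classes.append(cls)
        pks.append(base + rng.normal(0.0, 1.0))
    w = {}
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if rng.random() < coupling_density:
                w[(i, j)] = rng.normal(0.0, w_scale)
    return make_energy_table(classes, pks, w)
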