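"""PDB conformer I/O, titratable-site detection and charge/radius assignment.

Conformers are read from standard PDB ATOM/HETATM records (multi-model files
become regime-tagged ensembles).  Charges and cavity radii come from a
self-contained heavy-atom parameter table shipped with the package: polar
and aliphatic hydrogens are folded into their heavy atoms, and the charge
rearrangement on protonation/deprotonation is described per titratable site
by microstate charge sets rather than explicit proton coordinates, so input
snapshots do not need hydrogens.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .titration_core import Microstate, default_microstates

__all__ = [
    "Atom",
    "Conformer",
    "Ensemble",
    "TitratableSite",
    "ParameterTable",
    "PDBParseError",
    "ParameterError",
    "REGIMES",
    "MODEL_PK",
    "read_conformer",
    "read_ensemble",
    "write_conformer",
    "write_ensemble",
    "detect_sites",
    "assign_parameters",
    "regime_variants",
    "load_default_parameters",
]

REGIMES = ("allC", "glu0", "lys0", "single")

#: model-compound pK values per site class
MODEL_PK = {
    "GLU": ("carboxyl", 4.4),
    "ASP": ("carboxyl", 4.0),
    "LYS": ("amino", 10.4),
    "TYR": ("hydroxyl", 9.6),
    "HIS": ("imidazole", 6.4),
    "ARG": ("guanidine", 12.5),
    "NTER": ("n_terminus", 7.5),
    "CTER": ("c_terminus", 3.8),
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: model-compound fragment atoms per site class (used for the model-compound
#: electrostatics reference and for site–site interaction bookkeeping)
FRAGMENT_ATOMS = {
    ("carboxyl", "GLU"): ("CB", "CG", "CD", "OE1", "OE2"),
    ("carboxyl", "ASP"): ("CB", "CG", "OD1", "OD2"),
    ("amino", "LYS"): ("CB", "CG", "CD", "CE", "NZ"),
    ("guanidine", "ARG"): ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    ("imidazole", "HIS"): ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    ("hydroxyl", "TYR"): ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    ("n_terminus", None): ("N", "CA"),
    ("c_terminus", None): ("CA", "C", "O", "OXT"),
}


class PDBParseError(ValueError):
    pass


class ParameterError(KeyError):
    pass


@dataclass
class Atom:
    """A heavy atom with assigned electrostatic parameters."""

    name: str
    element: str
    coords: np.ndarray  # Å, shape (3,)
    chain: str
    resname: str
    resnum: int
    icode: str = ""
    partial_charge: float = np.nan
    radius: float = np.nan

    @property
    def residue_id(self) -> tuple:
        return (self.chain, self.resname, self.resnum)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Conformer:
    """One structure snapshot: an ordered atom list."""

    atoms: list
    source_label: str = ""

    def positions(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def residues(self) -> dict:
        """Ordered mapping (chain, resnum, icode) -> (resname, atom indices)."""
        out: dict = {}
        for idx, a in enumerate(self.atoms):
            key = (a.chain, a.resnum, a.icode)
            if key not in out:
                out[key] = (a.resname, [])
            out[key][1].append(idx)
        return out

    def chains(self) -> list:
        seen = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen


@dataclass
class Ensemble:
    """Conformers sampled under one protonation regime."""

    regime: str
    conformers: list

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")


@dataclass
class TitratableSite:
    """A titratable group with its microstate catalogue."""

    site_id: tuple  # (chain, resname, resnum, terminus flag "" | "NTER" | "CTER")
    site_class: str
    pk_mod: float
    microstates: list = field(default_factory=list)

    @property
    def chain(self) -> str:
        return self.site_id[0]

    @property
    def key(self) -> tuple:
        """Chain-independent identity used to pair homologous sites."""
        return self.site_id[1:]

    @property
    def family(self) -> str:
        """Coarse chemical family used by regime weighting."""
        if self.site_class in ("carboxyl", "c_terminus"):
            return "carboxyl"
        if self.site_class in ("amino", "n_terminus"):
            return "amino"
        return self.site_class


# ---------------------------------------------------------------------------
# PDB reading / writing


def _validate_pdb_text(text: str) -> None:
    for n, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {n}: truncated {rec} record")
        try:
            float(line[30:38]), float(line[38:46]), float(line[46:54])
        except ValueError:
            raise PDBParseError(f"line {n}: unparseable coordinates in {rec} record")


def _model_to_conformer(model, label: str) -> Conformer:
    atoms = []
    seen = set()
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(),
                       res.name, at.name, at.altloc)
                if key in seen:
                    raise PDBParseError(
                        f"duplicate atom {at.name} in residue "
                        f"{chain.name}/{res.name}{res.seqid.num}"
                    )
                seen.add(key)
                elem = at.element.name if at.element else at.name[0]
                atoms.append(Atom(
                    name=at.name, element=elem,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    chain=chain.name, resname=res.name, resnum=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                ))
    return Conformer(atoms, source_label=label)


def read_conformer(pdb_text: str, label: str = "") -> Conformer:
    """Parse the first model of a PDB text into a :class:`Conformer`."""
    _validate_pdb_text(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("no models found in PDB input")
    return _model_to_conformer(st[0], label or st.name)


def read_ensemble(pdb_text: str, regime: str = "single") -> Ensemble:
    """Parse a (multi-)model PDB text into a regime-tagged ensemble."""
    _validate_pdb_text(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("no models found in PDB input")
    conformers = [_model_to_conformer(m, f"model{k + 1}") for k, m in enumerate(st)]
    return Ensemble(regime, conformers)


def write_conformer(conformer: Conformer) -> str:
    """Serialize a conformer as PDB ATOM records (3-decimal coordinates)."""
    lines = []
    serial = 0
    for a in conformer.atoms:
        serial += 1
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial % 100000:5d} {name}{'':1s}{a.resname:>3s} "
            f"{a.chain[:1]:1s}{a.resnum:4d}{a.icode[:1] or ' '}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_ensemble(ensemble: Ensemble) -> str:
    parts = []
    for k, conf in enumerate(ensemble.conformers, start=1):
        parts.append(f"MODEL     {k:4d}")
        parts.append(write_conformer(conf).replace("\nEND\n", "\nENDMDL"))
    parts.append("END")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Parameter table


class ParameterTable:
    """Charge/radius lookup keyed by (residue, variant, atom).

    Variants: every residue has ``neutral`` (the reference protonation
    form); titratable residues add ``charged`` (HIS also ``neutral_nd1``).
    ``NTER``/``CTER`` blocks patch the terminal backbone group.
    """

    def __init__(self, rows: Iterable[tuple]):
        self._data: dict = {}
        for resname, variant, atom, charge, radius in rows:
            self._data.setdefault(resname, {}).setdefault(variant, {})[atom] = (
                float(charge), float(radius)
            )
        for resname, variants in self._data.items():
            for variant, block in variants.items():
                for atom, (q, r) in block.items():
                    if not r > 0:
                        raise ValueError(f"{resname}/{variant}/{atom}: radius must be > 0")

    @classmethod
    def from_tsv(cls, source) -> "ParameterTable":
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        rows = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("residue\t"):
                continue
            resname, variant, atom, charge, radius = line.split("\t")
            rows.append((resname, variant, atom, float(charge), float(radius)))
        return cls(rows)

    def to_tsv(self) -> str:
        out = ["residue\tvariant\tatom\tcharge\tradius"]
        for resname in self._data:
            for variant in self._data[resname]:
                for atom, (q, r) in self._data[resname][variant].items():
                    out.append(f"{resname}\t{variant}\t{atom}\t{q:.4f}\t{r:.2f}")
        return "\n".join(out) + "\n"

    def variants(self, resname: str) -> list:
        return list(self._data.get(resname, {}))

    def block(self, resname: str, variant: str) -> Mapping[str, tuple]:
        try:
            res = self._data[resname]
        except KeyError:
            raise ParameterError(f"residue {resname} not in parameter table")
        if variant not in res:
            variant = "neutral"
        try:
            return res[variant]
        except KeyError:
            raise ParameterError(f"{resname}: no variant {variant!r} in parameter table")

    def charge_sets(self, resname: str, atoms: Sequence[str] | None = None) -> dict:
        """Per-variant charge dictionaries restricted to the atoms whose
        charge differs between variants (the functional group)."""
        res = self._data[resname]
        names = set()
        for block in res.values():
            names |= set(block)
        if atoms is not None:
            names &= set(atoms)
        ref = res["neutral"]
        changing = set()
        for variant, block in res.items():
            for a in names:
                if abs(block.get(a, (0, 0))[0] - ref.get(a, (0, 0))[0]) > 1e-9:
                    changing.add(a)
        return {
            variant: {a: block[a][0] for a in sorted(changing) if a in block}
            for variant, block in res.items()
        }


def load_default_parameters() -> ParameterTable:
    ref = resources.files("multipk.data") / "charges_radii.tsv"
    return ParameterTable.from_tsv(io.StringIO(ref.read_text()))


def regime_variants(regime: str) -> dict:
    """Protonation variant per titratable residue implied by a regime.

    allC: all ionisable groups charged, tyrosine neutral; glu0: glutamates
    neutral, all other charged; lys0: lysines neutral, all other charged.
    The reference regime (``single``) keeps everything neutral.
    """
    charged = {"GLU": "charged", "ASP": "charged", "LYS": "charged",
               "ARG": "charged", "HIS": "charged", "TYR": "neutral",
               "NTER": "charged", "CTER": "charged"}
    if regime == "allC":
        return dict(charged)
    if regime == "glu0":
        return dict(charged, GLU="neutral")
    if regime == "lys0":
        return dict(charged, LYS="neutral")
    if regime in ("single", "reference", "neutral"):
        return {k: "neutral" for k in charged}
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# Site detection and parameter assignment


def detect_sites(
    conformer: Conformer,
    termini_policy: str = "both",
    include_arg: bool = False,
    parameter_table: ParameterTable | None = None,
    carboxyl_positions: bool = False,
) -> list:
    """Find titratable sites: one per Asp/Glu/Lys/His/Tyr (and optionally
    Arg) side chain plus the N- and C-terminal groups of each chain.

    Arginine is excluded by default: its guanidine pK lies far above the
    usual pH range and the group is treated as fixed protonated.  Unknown
    residue names are skipped with a warning.  The detection is idempotent
    and order-stable (chain order, then residue order).
    """
    if termini_policy not in ("both", "none", "nter", "cter"):
        raise ValueError(f"invalid termini_policy {termini_policy!r}")
    table = parameter_table or load_default_parameters()
    residues = conformer.residues()
    by_chain: dict = {}
    for key, (resname, idxs) in residues.items():
        by_chain.setdefault(key[0], []).append((key, resname, idxs))

    sites = []
    for chain, reslist in by_chain.items():
        for pos, (key, resname, idxs) in enumerate(reslist):
            _, resnum, icode = key
            if resname not in STANDARD_RESIDUES:
                warnings.warn(f"unknown residue {resname} {chain}{resnum}: skipped")
                continue
            if pos == 0 and termini_policy in ("both", "nter"):
                cls, pk = MODEL_PK["NTER"]
                sites.append(TitratableSite(
                    (chain, resname, resnum, "NTER"), cls, pk,
                    default_microstates(cls, pk, table.charge_sets("NTER")),
                ))
            if resname in MODEL_PK and resname != "ARG" or (resname == "ARG" and include_arg):
                cls, pk = MODEL_PK[resname]
                sites.append(TitratableSite(
                    (chain, resname, resnum, ""), cls, pk,
                    default_microstates(cls, pk, table.charge_sets(resname),
                                        carboxyl_positions=carboxyl_positions),
                ))
            if pos == len(reslist) - 1 and termini_policy in ("both", "cter"):
                cls, pk = MODEL_PK["CTER"]
                sites.append(TitratableSite(
                    (chain, resname, resnum, "CTER"), cls, pk,
                    default_microstates(cls, pk, table.charge_sets("CTER")),
                ))
    return sites


def fragment_atom_names(site: TitratableSite) -> tuple:
    key = (site.site_class, site.site_id[1])
    if key in FRAGMENT_ATOMS:
        return FRAGMENT_ATOMS[key]
    return FRAGMENT_ATOMS[(site.site_class, None)]


def site_atom_indices(conformer: Conformer, site: TitratableSite) -> list:
    """Indices of the site's model-compound fragment atoms in the conformer."""
    chain, resname, resnum, flag = site.site_id
    names = fragment_atom_names(site)
    out = []
    for idx, a in enumerate(conformer.atoms):
        if a.chain == chain and a.resnum == resnum and a.name in names:
            out.append(idx)
    if not out:
        raise KeyError(f"no fragment atoms found for site {site.site_id}")
    return out


def assign_parameters(
    conformer: Conformer,
    parameter_table: ParameterTable | None = None,
    variants: Mapping[str, str] | str | None = None,
    termini: bool = True,
) -> Conformer:
    """Return a copy of the conformer with charges and radii assigned.

    ``variants`` maps residue names (plus NTER/CTER) to protonation
    variants; a regime name string is also accepted.  Default is the
    all-neutral reference assignment.  After assignment every residue's net
    charge equals the formal charge of its protonation variant to 1e-6 e.
    """
    table = parameter_table or load_default_parameters()
    if isinstance(variants, str):
        variants = regime_variants(variants)
    variants = dict(variants or {})

    residues = conformer.residues()
    by_chain: dict = {}
    for key in residues:
        by_chain.setdefault(key[0], []).append(key)

    new_atoms = [replace(a) for a in conformer.atoms]
    for chain, keys in by_chain.items():
        for pos, key in enumerate(keys):
            resname, idxs = residues[key]
            variant = variants.get(resname, "neutral")
            block = dict(table.block(resname, variant))
            formal = round(sum(q for q, _ in block.values()))
            if termini and pos == 0:
                patch = table.block("NTER", variants.get("NTER", "neutral"))
                replaced = sum(block[a][0] for a in patch if a in block)
                block.update(patch)
                formal = round(sum(q for q, _ in block.values()))
            if termini and pos == len(keys) - 1:
                patch = table.block("CTER", variants.get("CTER", "neutral"))
                block.update(patch)
                formal = round(sum(q for q, _ in block.values()))
            assigned = 0.0
            for idx in idxs:
                a = new_atoms[idx]
                if a.name not in block:
                    raise ParameterError(
                        f"atom {a.name} of residue {resname} {chain}{a.resnum} "
                        "not found in parameter table"
                    )
                q, r = block[a.name]
                a.partial_charge, a.radius = q, r
                assigned += q
            present = {new_atoms[idx].name for idx in idxs}
            expected = sum(q for name, (q, _) in block.items() if name in present)
            missing = set(block) - present
            if abs(assigned - formal) > 1e-6:
                raise ParameterError(
                    f"residue {resname} {chain}{key[1]}: net charge {assigned:+.4f} "
                    f"differs from formal charge {formal:+d}"
                    + (f" (missing atoms: {sorted(missing)})" if missing else "")
                )
    return Conformer(new_atoms, conformer.source_label)
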