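"""Finite-difference linearised Poisson–Boltzmann electrostatics.

The solver discretises  ∇·(ε∇φ) − ε_s·κ²·φ = −4πC·ρ  on a regular grid
(7-point stencil, dielectric sampled at edge midpoints, charge spread by
trilinear interpolation) and solves the resulting symmetric
positive-definite system by Jacobi-preconditioned conjugate gradients with
Debye–Hückel Dirichlet boundary values.  Potentials are in kcal/(mol·e),
lengths in Å, charges in e.

Two-stage focusing (a coarse solve over the whole molecule providing
boundary values for a fine grid around the site of interest) follows
standard FD-PB practice.  Grids are centred on the bounding-box centre of
the system so that a mirror-symmetric structure sees a mirror-symmetric
discretisation.

Per-site energies: for each titratable site the charge difference Δq between
a microstate and the site's reference microstate is the source term.  The
desolvation (Born) contribution is the reaction-field self-energy of Δq in
the protein minus that in the conformation-matched model compound (the
site's fragment alone in solvent); the permanent-charge and reference-state
contributions are interactions of Δq's screened potential with the
non-titratable background and with the other sites' reference charges; the
site–site couplings W are interactions with the other sites' charge
differences.  All Δ-terms vanish for the reference microstate by
construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .constants import COULOMB_KCAL, LN10, debye_kappa2, kt
from .structure_io import Conformer, TitratableSite, fragment_atom_names, site_atom_indices
from .titration_core import Microstate, StateEnergyModel

__all__ = [
    "PBConfig",
    "GridMaps",
    "SiteEnergyTable",
    "PBConvergenceError",
    "build_maps",
    "solve_lpb",
    "solve_focused",
    "PotentialField",
    "reaction_field_energy",
    "coulomb_energy",
    "site_energy_terms",
]


class PBConvergenceError(RuntimeError):
    pass


@dataclass
class PBConfig:
    """Continuum-electrostatics parameters.

    Defaults follow common FD-PB practice for protein pK work: protein
    dielectric 4, solvent 78, 0.14 M ionic strength at 298 K, 1.4 Å solvent
    probe and a 2.0 Å ion exclusion layer.
    """

    eps_protein: float = 4.0
    eps_solvent: float = 78.0
    ionic_strength: float = 0.14
    temperature: float = 298.0
    probe_radius: float = 1.4
    ion_exclusion: float = 2.0
    grid_spacing_coarse: float = 1.0
    grid_spacing_fine: float = 0.4
    grid_padding: float = 8.0
    focus_margin: float = 6.0
    cg_tol: float = 1e-8
    cg_max_iter: int = 10_000
    origin_shift: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (self.eps_solvent > self.eps_protein >= 1.0):
            raise ValueError("require eps_solvent > eps_protein >= 1")
        for name in ("probe_radius", "ion_exclusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("grid_spacing_coarse", "grid_spacing_fine", "grid_padding", "focus_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def kappa2(self) -> float:
        return debye_kappa2(self.ionic_strength, self.eps_solvent, self.temperature)


@dataclass
class GridMaps:
    """Discretised dielectric/screening/charge maps on a regular grid."""

    origin: np.ndarray  # position of node (0,0,0), Å
    spacing: float
    shape: tuple
    eps_edges: tuple  # three arrays: eps at x-, y-, z-edge midpoints
    kappa2bar: np.ndarray  # ε_s·κ² at nodes (0 where ion-excluded), Å⁻²
    charge: np.ndarray  # e per node

    def node_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        points = np.atleast_2d(points)
        lo = self.origin + margin
        hi = self.origin + self.spacing * (np.array(self.shape) - 1) - margin
        return np.all((points >= lo) & (points <= hi), axis=1)


def _grid_geometry(points: np.ndarray, padding: float, spacing: float,
                   origin_shift=(0.0, 0.0, 0.0)) -> tuple:
    """Grid centred on the bounding-box centre, covering box + padding."""
    lo, hi = points.min(axis=0), points.max(axis=0)
    center = (lo + hi) / 2.0 + np.asarray(origin_shift, dtype=float)
    half = (hi - lo) / 2.0 + padding
    n = 2 * np.ceil(half / spacing).astype(int) + 1
    origin = center - (n - 1) / 2.0 * spacing
    return origin, tuple(int(k) for k in n)


def _rasterize(origin, spacing, shape, centers, radii) -> np.ndarray:
    """Boolean mask of grid nodes within radius of any centre."""
    mask = np.zeros(shape, dtype=bool)
    if len(centers) == 0:
        return mask
    inv = 1.0 / spacing
    for c, r in zip(centers, radii):
        lo_idx = np.maximum(np.floor((c - r - origin) * inv).astype(int), 0)
        hi_idx = np.minimum(np.ceil((c + r - origin) * inv).astype(int) + 1, shape)
        if np.any(lo_idx >= hi_idx):
            continue
        ax = [origin[d] + spacing * np.arange(lo_idx[d], hi_idx[d]) - c[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = mask[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
        sub |= d2 <= r * r
    return mask


def _spread_charges(origin, spacing, shape, positions, charges) -> np.ndarray:
    grid = np.zeros(shape)
    if len(positions) == 0:
        return grid
    frac = (np.asarray(positions) - origin) / spacing
    base = np.floor(frac).astype(int)
    if np.any(base < 0) or np.any(base + 1 >= np.array(shape)):
        raise ValueError("charge outside grid: enlarge padding")
    t = frac - base
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                np.add.at(grid, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                          np.asarray(charges) * wx * wy * wz)
    return grid


def build_maps(
    conformer,
    pb_config: PBConfig,
    *,
    spacing: float | None = None,
    charge_overlay: Sequence[tuple] | None = None,
    origin: np.ndarray | None = None,
    shape: tuple | None = None,
    uniform_eps: float | None = None,
    with_ions: bool = True,
) -> GridMaps:
    """Build dielectric, screening and charge maps for a conformer.

    ``charge_overlay`` — sequence of (position, charge) pairs — replaces the
    conformer's own charges as the source distribution (used for microstate
    charge differences).  ``uniform_eps`` fills a homogeneous dielectric
    (the reference medium for reaction-field self-energies).  The molecular
    volume is the union of atom spheres inflated by the solvent probe; ions
    are excluded within probe + ion_exclusion of any atom.
    """
    cfg = pb_config
    if isinstance(conformer, Conformer):
        atoms = conformer.atoms
        positions = conformer.positions() if atoms else np.zeros((0, 3))
        radii = conformer.radii() if atoms else np.zeros(0)
        atom_charges = conformer.charges() if atoms else np.zeros(0)
    else:
        arr = np.asarray(conformer, dtype=float)
        if arr.size == 0:
            positions, radii, atom_charges = np.zeros((0, 3)), np.zeros(0), np.zeros(0)
        else:
            positions, radii, atom_charges = arr[:, :3], arr[:, 3], arr[:, 4]

    if charge_overlay is not None:
        src_pos = np.array([p for p, _ in charge_overlay], dtype=float).reshape(-1, 3)
        src_q = np.array([q for _, q in charge_overlay], dtype=float)
    else:
        src_pos, src_q = positions, atom_charges

    spacing = spacing or cfg.grid_spacing_coarse
    if origin is None or shape is None:
        pts = np.vstack([positions, src_pos]) if len(positions) else src_pos
        if len(pts) == 0:
            raise ValueError("cannot size a grid without atoms or charges")
        origin, shape = _grid_geometry(pts, cfg.grid_padding, spacing, cfg.origin_shift)
    origin = np.asarray(origin, dtype=float)

    if uniform_eps is not None:
        eps_edges = tuple(
            np.full(tuple(s - (1 if d == a else 0) for a, s in enumerate(shape)), float(uniform_eps))
            for d in range(3)
        )
        kappa2bar = np.zeros(shape)
    else:
        r_eps = radii + cfg.probe_radius if len(radii) else radii
        # fractional edge dielectric: harmonic mean over sample points along
        # each edge (the harmonic mean is the series combination appropriate
        # for flux continuity across the dielectric boundary)
        n_sub = 4
        eps_edges = []
        for d in range(3):
            eshape = tuple(s - (1 if a == d else 0) for a, s in enumerate(shape))
            inv_sum = np.zeros(eshape)
            for k in range(n_sub):
                eorigin = origin.copy()
                eorigin[d] += spacing * (k + 0.5) / n_sub
                inside = _rasterize(eorigin, spacing, eshape, positions, r_eps)
                inv_sum += np.where(inside, 1.0 / cfg.eps_protein, 1.0 / cfg.eps_solvent)
            eps_edges.append(n_sub / inv_sum)
        eps_edges = tuple(eps_edges)
        kappa2bar = np.zeros(shape)
        if with_ions and cfg.ionic_strength > 0:
            r_ion = radii + cfg.probe_radius + cfg.ion_exclusion if len(radii) else radii
            excluded = _rasterize(origin, spacing, shape, positions, r_ion)
            kappa2bar = np.where(excluded, 0.0, cfg.eps_solvent * cfg.kappa2)

    charge = _spread_charges(origin, spacing, shape, src_pos, src_q)
    return GridMaps(origin, float(spacing), tuple(shape), eps_edges, kappa2bar, charge)


def _dh_boundary(maps: GridMaps, cfg: PBConfig, eps_medium: float, kappa: float) -> np.ndarray:
    """Debye–Hückel potential on the full grid, used for boundary faces."""
    phi = np.zeros(maps.shape)
    idx = np.argwhere(np.abs(maps.charge) > 0)
    if idx.size == 0:
        return phi
    q = maps.charge[tuple(idx.T)]
    src = maps.origin + idx * maps.spacing

    faces = []
    nx, ny, nz = maps.shape
    grids = [maps.node_coords(d) for d in range(3)]
    for axis, side in ((0, 0), (0, nx - 1), (1, 0), (1, ny - 1), (2, 0), (2, nz - 1)):
        sel = [slice(None)] * 3
        sel[axis] = side
        mesh = np.meshgrid(*[grids[d] if d != axis else np.array([grids[axis][side]])
                             for d in range(3)], indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        r = np.linalg.norm(pts[:, None, :] - src[None, :, :], axis=2)
        r = np.maximum(r, 1e-6)
        vals = (COULOMB_KCAL / eps_medium) * (q[None, :] * np.exp(-kappa * r) / r).sum(axis=1)
        phi[tuple(sel)] = vals.reshape(phi[tuple(sel)].shape)
    return phi


def solve_lpb(
    grid_maps: GridMaps,
    pb_config: PBConfig,
    boundary: np.ndarray | None = None,
    tol: float | None = None,
    max_iter: int | None = None,
) -> np.ndarray:
    """Solve the discrete LPB system; returns φ on all nodes, kcal/(mol·e).

    ``boundary`` supplies Dirichlet values on the outer faces (full-shape
    array; only faces are read).  Without it, Debye–Hückel values from the
    grid charge distribution are used.  Raises
    :class:`PBConvergenceError` if CG does not reach the residual tolerance.
    """
    cfg = pb_config
    maps = grid_maps
    h = maps.spacing
    nx, ny, nz = maps.shape
    if min(nx, ny, nz) < 3:
        raise ValueError("grid too small")
    if boundary is None:
        eps_b = float(maps.eps_edges[0].max())
        kap = math.sqrt(maps.kappa2bar.max() / eps_b) if maps.kappa2bar.max() > 0 else 0.0
        boundary = _dh_boundary(maps, cfg, eps_b, kap)

    ex, ey, ez = maps.eps_edges
    ix = slice(1, nx - 1)
    iy = slice(1, ny - 1)
    iz = slice(1, nz - 1)
    mx, my, mz = nx - 2, ny - 2, nz - 2
    m = mx * my * mz
    ids = np.arange(m).reshape(mx, my, mz)

    # edge dielectrics seen by interior node (i,j,k), global index (i+1,j+1,k+1)
    exp_ = ex[1:nx - 1, iy, iz]      # +x edge
    exm = ex[0:nx - 2, iy, iz]       # −x edge
    eyp = ey[ix, 1:ny - 1, iz]
    eym = ey[ix, 0:ny - 2, iz]
    ezp = ez[ix, iy, 1:nz - 1]
    ezm = ez[ix, iy, 0:nz - 2]

    diag = (exp_ + exm + eyp + eym + ezp + ezm
            + maps.kappa2bar[ix, iy, iz] * h * h).ravel()
    rhs = (4.0 * math.pi * COULOMB_KCAL / h) * maps.charge[ix, iy, iz].ravel()

    rows, cols, vals = [np.arange(m)], [np.arange(m)], [diag]

    def couple(eps_block, sel_a, sel_b):
        a = ids[sel_a].ravel()
        b = ids[sel_b].ravel()
        e = eps_block.ravel()
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([-e, -e])

    # interior-interior couplings
    couple(exp_[:-1, :, :], (slice(0, mx - 1), slice(None), slice(None)),
           (slice(1, mx), slice(None), slice(None)))
    couple(eyp[:, :-1, :], (slice(None), slice(0, my - 1), slice(None)),
           (slice(None), slice(1, my), slice(None)))
    couple(ezp[:, :, :-1], (slice(None), slice(None), slice(0, mz - 1)),
           (slice(None), slice(None), slice(1, mz)))

    # boundary contributions to RHS
    rhs3 = rhs.reshape(mx, my, mz)
    rhs3[0, :, :] += exm[0, :, :] * boundary[0, iy, iz]
    rhs3[-1, :, :] += exp_[-1, :, :] * boundary[nx - 1, iy, iz]
    rhs3[:, 0, :] += eym[:, 0, :] * boundary[ix, 0, iz]
    rhs3[:, -1, :] += eyp[:, -1, :] * boundary[ix, ny - 1, iz]
    rhs3[:, :, 0] += ezm[:, :, 0] * boundary[ix, iy, 0]
    rhs3[:, :, -1] += ezp[:, :, -1] * boundary[ix, iy, nz - 1]
    rhs = rhs3.ravel()

    a_mat = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    ).tocsr()
    precond = LinearOperator((m, m), matvec=lambda v: v / diag)
    tol = tol if tol is not None else cfg.cg_tol
    max_iter = max_iter or cfg.cg_max_iter
    x, info = cg(a_mat, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=precond)
    if info != 0:
        res = np.linalg.norm(a_mat @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise PBConvergenceError(
            f"CG did not converge within {max_iter} iterations (relative residual {res:.2e})"
        )
    phi = boundary.copy()
    phi[ix, iy, iz] = x.reshape(mx, my, mz)
    return phi


def _trilinear(maps: GridMaps, phi: np.ndarray, points: np.ndarray) -> np.ndarray:
    frac = (np.atleast_2d(points) - maps.origin) / maps.spacing
    base = np.floor(frac).astype(int)
    base = np.clip(base, 0, np.array(maps.shape) - 2)
    t = frac - base
    out = np.zeros(len(frac))
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                out += phi[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz] * wx * wy * wz
    return out


@dataclass
class PotentialField:
    """Solved potential on one or more nested grids (finest first)."""

    levels: list  # [(GridMaps, phi), ...] finest first

    def at(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), np.nan)
        remaining = np.ones(len(points), dtype=bool)
        for maps, phi in self.levels:
            inside = maps.contains(points, margin=maps.spacing) & remaining
            if inside.any():
                out[inside] = _trilinear(maps, phi, points[inside])
                remaining &= ~inside
        if remaining.any():
            maps, phi = self.levels[-1]
            out[remaining] = _trilinear(maps, phi, points[remaining])
        return out


def solve_focused(
    env,
    sources: Sequence[tuple],
    config: PBConfig,
    *,
    uniform_eps: float | None = None,
    with_ions: bool = True,
    focus: bool = True,
) -> PotentialField:
    """Coarse solve over the whole system plus a fine focused solve around
    the sources.  ``env`` is a Conformer (or (n,5) array of x,y,z,radius,q)
    defining the dielectric geometry; ``sources`` is a list of
    (position, charge) pairs.  The fine-grid geometry depends only on the
    sources and the configuration, so matched solves (heterogeneous vs
    homogeneous dielectric, protein vs model compound) share identical
    discretisation around the sources and their grid self-energies cancel
    in differences.
    """
    coarse = build_maps(env, config, spacing=config.grid_spacing_coarse,
                        charge_overlay=sources, uniform_eps=uniform_eps,
                        with_ions=with_ions)
    phi_c = solve_lpb(coarse, config)
    levels = [(coarse, phi_c)]
    if focus and config.grid_spacing_fine < config.grid_spacing_coarse:
        src_pos = np.array([p for p, _ in sources], dtype=float).reshape(-1, 3)
        f_origin, f_shape = _grid_geometry(src_pos, config.focus_margin,
                                           config.grid_spacing_fine)
        fine = build_maps(env, config, spacing=config.grid_spacing_fine,
                          charge_overlay=sources, origin=f_origin, shape=f_shape,
                          uniform_eps=uniform_eps, with_ions=with_ions)
        # fine boundary from the coarse solution
        bnd = np.zeros(f_shape)
        grids = [fine.node_coords(d) for d in range(3)]
        for axis in range(3):
            for side in (0, f_shape[axis] - 1):
                sel = [slice(None)] * 3
                sel[axis] = side
                mesh = np.meshgrid(*[grids[d] if d != axis else np.array([grids[axis][side]])
                                     for d in range(3)], indexing="ij")
                pts = np.stack([mm.ravel() for mm in mesh], axis=1)
                bnd[tuple(sel)] = _trilinear(coarse, phi_c, pts).reshape(bnd[tuple(sel)].shape)
        phi_f = solve_lpb(fine, config, boundary=bnd)
        levels.insert(0, (fine, phi_f))
    return PotentialField(levels)


def reaction_field_energy(env, sources: Sequence[tuple], config: PBConfig) -> float:
    """Reaction-field (solvation) self-energy of the sources, kcal/mol.

    ΔG = ½·Σ q·[φ_het − φ_hom] at the source positions, with the
    homogeneous reference at the protein dielectric; grid self-energy
    cancels between the two matched solves.
    """
    het = solve_focused(env, sources, config)
    hom = solve_focused(env, sources, config, uniform_eps=config.eps_protein,
                        with_ions=False)
    pts = np.array([p for p, _ in sources], dtype=float).reshape(-1, 3)
    q = np.array([c for _, c in sources], dtype=float)
    return 0.5 * float(np.dot(q, het.at(pts) - hom.at(pts)))


def coulomb_energy(q1: float, q2: float, r: float, eps: float) -> float:
    """Analytic Coulomb interaction, kcal/mol (oracle for solver tests)."""
    return COULOMB_KCAL * q1 * q2 / (eps * r)


# ---------------------------------------------------------------------------
# Site energy assembly


@dataclass
class MicroEnergyRecord:
    label: str
    proton_count: int
    is_reference: bool
    pk_std: float
    dpk_born: float = 0.0
    dpk_perm: float = 0.0
    dpk_ref: float = 0.0
    pk_int: float = 0.0
    offset_kcal: float = 0.0


@dataclass
class SiteEnergyTable:
    """Per-conformer intrinsic-pK terms and site–site interaction matrix."""

    site_ids: list
    site_classes: list
    records: list  # per site: list[MicroEnergyRecord]
    pair_w: dict  # (i, j) i<j -> array (m_i, m_j), kcal/mol
    temperature: float = 298.0
    asymmetry: float = 0.0  # max |W_ij − W_ji| before symmetrisation

    def to_model(self) -> StateEnergyModel:
        microstates = []
        pk_int = []
        offsets = []
        for recs in self.records:
            microstates.append([
                Microstate(r.label, r.proton_count, pk_std=r.pk_std,
                           is_reference=r.is_reference)
                for r in recs
            ])
            pk_int.append([r.pk_int for r in recs])
            offsets.append([r.offset_kcal for r in recs])
        return StateEnergyModel(self.site_ids, microstates, pk_int, offsets,
                                self.pair_w, self.temperature)

    def to_tsv(self) -> str:
        lines = [
            "kind\tsite_i\tmicro_i\tsite_j\tmicro_j\tclass\tlabel\tn_protons\t"
            "is_ref\tpk_std\tdpk_born\tdpk_perm\tdpk_ref\tpk_int\toffset_kcal\tw_kcal"
        ]
        lines.append(f"# temperature\t{self.temperature!r}")
        for i, recs in enumerate(self.records):
            sid = ":".join(str(x) for x in self.site_ids[i])
            for k, r in enumerate(recs):
                vals = "\t".join(repr(float(v)) for v in
                                 (r.pk_std, r.dpk_born, r.dpk_perm, r.dpk_ref,
                                  r.pk_int, r.offset_kcal))
                lines.append(
                    f"site\t{sid}\t{k}\t\t\t{self.site_classes[i]}\t{r.label}\t"
                    f"{r.proton_count}\t{int(r.is_reference)}\t{vals}\t"
                )
        for (i, j), w in sorted(self.pair_w.items()):
            sid_i = ":".join(str(x) for x in self.site_ids[i])
            sid_j = ":".join(str(x) for x in self.site_ids[j])
            for a in range(w.shape[0]):
                for b in range(w.shape[1]):
                    if w[a, b] != 0.0:
                        lines.append(
                            f"pair\t{sid_i}\t{a}\t{sid_j}\t{b}\t\t\t\t\t\t\t\t\t\t\t"
                            + repr(float(w[a, b]))
                        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, source) -> "SiteEnergyTable":
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        temperature = 298.0
        site_ids: list = []
        site_classes: list = []
        records: list = []
        raw_pairs: list = []
        index: dict = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("kind\t"):
                continue
            if line.startswith("# temperature"):
                temperature = float(line.split("\t")[1])
                continue
            f = line.split("\t")
            if f[0] == "site":
                sid = f[1]
                if sid not in index:
                    index[sid] = len(site_ids)
                    site_ids.append(tuple(sid.split(":")))
                    site_classes.append(f[5])
                    records.append([])
                records[index[sid]].append(MicroEnergyRecord(
                    label=f[6], proton_count=int(f[7]), is_reference=bool(int(f[8])),
                    pk_std=float(f[9]), dpk_born=float(f[10]), dpk_perm=float(f[11]),
                    dpk_ref=float(f[12]), pk_int=float(f[13]), offset_kcal=float(f[14]),
                ))
            elif f[0] == "pair":
                raw_pairs.append((index[f[1]], int(f[2]), index[f[3]], int(f[4]), float(f[15])))
        pair_w: dict = {}
        for i, a, j, b, w in raw_pairs:
            key = (i, j) if i < j else (j, i)
            if key not in pair_w:
                pair_w[key] = np.zeros((len(records[key[0]]), len(records[key[1]])))
            if i < j:
                pair_w[key][a, b] = w
            else:
                pair_w[key][b, a] = w
        # normalise site_ids: resnum back to int where possible
        norm_ids = []
        for sid in site_ids:
            norm_ids.append(tuple(int(x) if x.lstrip("-").isdigit() else x for x in sid))
        return cls(norm_ids, site_classes, records, pair_w, temperature)


def _delta_charges(conformer, site, micro, ref) -> list:
    """(position, Δq) pairs for a microstate vs the site's reference."""
    chain, resname, resnum, flag = site.site_id
    names = set(micro.charge_set) | set(ref.charge_set)
    out = []
    for a in conformer.atoms:
        if a.chain == chain and a.resnum == resnum and a.name in names:
            dq = micro.charge_set.get(a.name, 0.0) - ref.charge_set.get(a.name, 0.0)
            if abs(dq) > 1e-12:
                out.append((a.coords.copy(), dq))
    if not out:
        raise KeyError(f"no charge-difference atoms found for site {site.site_id} "
                       f"microstate {micro.label}")
    return out


def site_energy_terms(
    conformer: Conformer,
    sites: Sequence[TitratableSite],
    pb_config: PBConfig,
) -> SiteEnergyTable:
    """Assemble desolvation, permanent-charge, reference-state and pairwise
    interaction terms for every site microstate of a parameterised conformer.

    The conformer must carry the reference (all-neutral) charge assignment.
    One focused PB solve pair (heterogeneous + homogeneous reference) per
    non-reference microstate in the protein and in the isolated model
    compound; interactions are read from the heterogeneous protein solve.
    Intrinsic pK: pk_int = pk_std + ΔpK_born + ΔpK_perm + ΔpK_ref, with each
    ΔpK = −ΔG/(Δn·ln10·kT) so that positive desolvation penalties raise
    acid pK values and lower basic ones.
    """
    cfg = pb_config
    n = len(sites)
    lkt = LN10 * kt(cfg.temperature)
    positions = conformer.positions()
    charges = conformer.charges()
    if np.isnan(charges).any() or np.isnan(conformer.radii()).any():
        raise ValueError("conformer must be parameterised before site_energy_terms")

    frag_idx = [site_atom_indices(conformer, s) for s in sites]
    frag_sets = [set(ix) for ix in frag_idx]
    all_frag = set().union(*frag_sets) if frag_sets else set()
    background = [k for k in range(len(conformer.atoms)) if k not in all_frag]

    env_arr = np.column_stack([positions, conformer.radii(), charges])

    # the standard pK of a protonation transition is carried by the
    # protonated member of the pair (the reference microstate for acids)
    records = []
    for s in sites:
        sref = next(m for m in s.microstates if m.is_reference)
        recs = []
        for m in s.microstates:
            pk_std = m.pk_std
            if math.isnan(pk_std):
                pk_std = sref.pk_std
            if math.isnan(pk_std):
                pk_std = 0.0
            recs.append(MicroEnergyRecord(m.label, m.proton_count, m.is_reference, pk_std))
        records.append(recs)
    dims = [len(s.microstates) for s in sites]
    w_acc = {}
    for i in range(n):
        for j in range(i + 1, n):
            w_acc[(i, j)] = [np.zeros((dims[i], dims[j])), np.zeros((dims[i], dims[j]))]

    for i, site in enumerate(sites):
        ref = next(m for m in site.microstates if m.is_reference)
        model_env = env_arr[frag_idx[i]]
        for a, micro in enumerate(site.microstates):
            if micro.is_reference:
                rec = records[i][a]
                rec.pk_int = rec.pk_std
                continue
            sources = _delta_charges(conformer, site, micro, ref)
            src_pts = np.array([p for p, _ in sources])
            src_q = np.array([q for _, q in sources])

            het_p = solve_focused(env_arr, sources, cfg)
            hom_p = solve_focused(env_arr, sources, cfg,
                                  uniform_eps=cfg.eps_protein, with_ions=False)
            het_m = solve_focused(model_env, sources, cfg)
            hom_m = solve_focused(model_env, sources, cfg,
                                  uniform_eps=cfg.eps_protein, with_ions=False)

            g_rf_prot = 0.5 * float(np.dot(src_q, het_p.at(src_pts) - hom_p.at(src_pts)))
            g_rf_model = 0.5 * float(np.dot(src_q, het_m.at(src_pts) - hom_m.at(src_pts)))
            dg_born = g_rf_prot - g_rf_model

            phi_p = het_p.at(positions)
            phi_m = het_m.at(positions[frag_idx[i]])
            dg_perm = float(np.dot(charges[background], phi_p[background]))
            dg_perm += float(np.dot(charges[frag_idx[i]], phi_p[frag_idx[i]] - phi_m))

            dg_ref = 0.0
            for j in range(n):
                if j != i:
                    dg_ref += float(np.dot(charges[frag_idx[j]], phi_p[frag_idx[j]]))

            # pairwise couplings with other sites' charge differences
            for j, other in enumerate(sites):
                if j == i:
                    continue
                oref = next(m for m in other.microstates if m.is_reference)
                for b, om in enumerate(other.microstates):
                    if om.is_reference:
                        continue
                    osrc = _delta_charges(conformer, other, om, oref)
                    opts = np.array([p for p, _ in osrc])
                    oq = np.array([q for _, q in osrc])
                    w_val = float(np.dot(oq, het_p.at(opts)))
                    if i < j:
                        w_acc[(i, j)][0][a, b] = w_val
                    else:
                        w_acc[(j, i)][1][b, a] = w_val

            rec = records[i][a]
            dn = micro.proton_count - ref.proton_count
            if dn != 0:
                rec.dpk_born = -dg_born / (dn * lkt)
                rec.dpk_perm = -dg_perm / (dn * lkt)
                rec.dpk_ref = -dg_ref / (dn * lkt)
                rec.pk_int = rec.pk_std + rec.dpk_born + rec.dpk_perm + rec.dpk_ref
            else:
                rec.offset_kcal = dg_born + dg_perm + dg_ref

    pair_w = {}
    asym = 0.0
    for key, (wij, wji) in w_acc.items():
        both = (np.abs(wij) > 0) & (np.abs(wji) > 0)
        if both.any():
            asym = max(asym, float(np.abs(wij - wji)[both].max()))
        pair_w[key] = np.where(both, 0.5 * (wij + wji), wij + wji)

    return SiteEnergyTable(
        [s.site_id for s in sites],
        [s.site_class for s in sites],
        records,
        pair_w,
        cfg.temperature,
        asymmetry=asym,
    )
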