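"""Protonation-microstate partition function over coupled titratable sites.

A protein with N titratable groups is described by state vectors
x = (x₁, …, x_N), one microstate index per site.  Relative to the reference
state (all sites in their reference microstate, by convention the neutral
form) the energy of a state decomposes into singleton terms and pairwise
site–site interactions::

    ΔE(x) = Σ_i [ Δn_i(x_i)·ln10·kT·(pH − pk_int,i(x_i)) + g_i(x_i) ]
            + Σ_{i<j} W(i, x_i; j, x_j)

where Δn is the proton count of the microstate relative to the site's
reference microstate, pk_int the intrinsic pK of the protonation transition
(model-compound pK corrected for desolvation, permanent charges and the
reference-state field), g a pH-independent tautomer offset (kcal/mol) and W
the screened electrostatic coupling (kcal/mol).  Microstate populations

    p_iα(pH) = Σ_x δ(x_i, α)·exp(−ΔE(x)/kT) / Σ_x exp(−ΔE(x)/kT)

are evaluated either by exact enumeration of the state space or by
Metropolis Monte Carlo when enumeration is infeasible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import LN10, kt

__all__ = [
    "Microstate",
    "StateEnergyModel",
    "MicrostatePopulations",
    "MCConfig",
    "StateSpaceTooLarge",
    "default_microstates",
    "state_energy",
    "populations_exact",
    "populations_mc",
    "degree_of_deprotonation",
    "protonated_fraction",
]

DEFAULT_STATE_CAP = 2**20


class StateSpaceTooLarge(ValueError):
    """Raised by exact enumeration when the state space exceeds the cap.

    Callers should fall back to :func:`populations_mc`.
    """


@dataclass(frozen=True)
class Microstate:
    """One protonation/hydrogen-placement microstate of a titratable site."""

    label: str
    proton_count: int
    hydrogen_position: str = ""
    pk_std: float = math.nan
    charge_set: Mapping[str, float] = field(default_factory=dict)
    is_reference: bool = False


def default_microstates(
    site_class: str,
    pk_mod: float,
    charge_sets: Mapping[str, Mapping[str, float]] | None = None,
    carboxyl_positions: bool = False,
) -> list[Microstate]:
    """Default microstate catalogue for a site class.

    Acidic classes (carboxyl, hydroxyl, C-terminus) have a protonated
    (neutral) reference and a deprotonated microstate; basic classes the
    converse.  Imidazoles carry two neutral tautomers (Nδ-H and Nε-H) plus
    the doubly protonated form; the microscopic pK of the protonated state
    is pk_mod + log10(2) so that the isolated-site macroscopic midpoint
    equals pk_mod despite the two-fold neutral degeneracy.  With
    ``carboxyl_positions`` the carboxyl proton is resolved on either oxygen
    (pk_mod − log10(2) per microscopic state, two-fold protonated
    degeneracy).
    """
    cs = charge_sets or {}

    def q(key: str) -> Mapping[str, float]:
        return cs.get(key, {})

    acid = site_class in ("carboxyl", "hydroxyl", "c_terminus")
    base = site_class in ("amino", "guanidine", "n_terminus")
    if site_class == "imidazole":
        return [
            Microstate("neutral-NE2", 1, "NE2", charge_set=q("neutral"), is_reference=True),
            Microstate("neutral-ND1", 1, "ND1", charge_set=q("neutral_nd1")),
            Microstate("charged", 2, "ND1+NE2", pk_std=pk_mod + math.log10(2.0),
                       charge_set=q("charged")),
        ]
    if acid:
        if site_class == "carboxyl" and carboxyl_positions:
            micro_pk = pk_mod - math.log10(2.0)
            return [
                Microstate("prot-O2", 1, "O2", pk_std=micro_pk,
                           charge_set=q("neutral"), is_reference=True),
                Microstate("prot-O1", 1, "O1", pk_std=micro_pk,
                           charge_set=q("neutral_o1") or q("neutral")),
                Microstate("deprot", 0, charge_set=q("charged")),
            ]
        return [
            Microstate("prot", 1, pk_std=pk_mod, charge_set=q("neutral"), is_reference=True),
            Microstate("deprot", 0, charge_set=q("charged")),
        ]
    if base:
        return [
            Microstate("deprot", 0, charge_set=q("neutral"), is_reference=True),
            Microstate("prot", 1, pk_std=pk_mod, charge_set=q("charged")),
        ]
    raise ValueError(f"unknown site class: {site_class!r}")


class StateEnergyModel:
    """Compiled numeric form of a site-energy table.

    Parameters
    ----------
    site_ids : sequence of hashable site identifiers.
    microstates : per site, the list of :class:`Microstate` objects; exactly
        one per site must be flagged as reference.
    pk_int : per site, array of intrinsic pK values aligned with the
        microstates (ignored where Δn = 0).
    offsets : per site, pH-independent microstate offsets in kcal/mol
        (0 for the reference by construction).
    pair_w : mapping ``(i, j) -> array (m_i, m_j)`` with i < j, screened
        site–site interaction energies in kcal/mol.  Rows/columns addressed
        by microstate index; entries involving a reference microstate are
        zero by the charge-difference convention.
    """

    def __init__(
        self,
        site_ids: Sequence,
        microstates: Sequence[Sequence[Microstate]],
        pk_int: Sequence[Sequence[float]],
        offsets: Sequence[Sequence[float]] | None = None,
        pair_w: Mapping[tuple[int, int], np.ndarray] | None = None,
        temperature: float = 298.0,
    ):
        self.site_ids = list(site_ids)
        self.microstates = [list(ms) for ms in microstates]
        self.temperature = float(temperature)
        n = len(self.site_ids)
        if len(self.microstates) != n:
            raise ValueError("site_ids and microstates length mismatch")
        self.n_sites = n
        self.dims = [len(ms) for ms in self.microstates]
        if any(d < 2 for d in self.dims):
            raise ValueError("every site needs at least 2 microstates")
        self.ref_index = []
        for i, ms in enumerate(self.microstates):
            refs = [k for k, m in enumerate(ms) if m.is_reference]
            if len(refs) != 1:
                raise ValueError(f"site {self.site_ids[i]}: exactly one reference microstate required")
            self.ref_index.append(refs[0])
        self.dn = [
            np.array([m.proton_count - ms[self.ref_index[i]].proton_count for m in ms], dtype=float)
            for i, ms in enumerate(self.microstates)
        ]
        self.pk_int = [np.nan_to_num(np.asarray(p, dtype=float)) for p in pk_int]
        if offsets is None:
            offsets = [np.zeros(d) for d in self.dims]
        self.offsets = [np.asarray(o, dtype=float) for o in offsets]
        # singleton energy  e_i(α, pH) = a_i[α] + b_i[α]·pH   (kcal/mol)
        lkt = LN10 * kt(self.temperature)
        self._a = [o - lkt * dn * pk for o, dn, pk in zip(self.offsets, self.dn, self.pk_int)]
        self._b = [lkt * dn for dn in self.dn]
        # dense pair interactions, kcal/mol
        mmax = max(self.dims)
        self.w_dense = np.zeros((n, mmax, n, mmax))
        if pair_w:
            for (i, j), w in pair_w.items():
                if not (0 <= i < j < n):
                    raise ValueError(f"pair key must have i < j, got {(i, j)}")
                w = np.asarray(w, dtype=float)
                if w.shape != (self.dims[i], self.dims[j]):
                    raise ValueError(f"W[{i},{j}] shape {w.shape} != {(self.dims[i], self.dims[j])}")
                self.w_dense[i, : self.dims[i], j, : self.dims[j]] = w
                self.w_dense[j, : self.dims[j], i, : self.dims[i]] = w.T
        if not np.isfinite(self.w_dense).all():
            raise ValueError("non-finite pair interaction energies")
        self.pairs = sorted({k for k in (pair_w or {})})

    # -- convenience -------------------------------------------------------
    @property
    def reference_vector(self) -> np.ndarray:
        return np.array(self.ref_index, dtype=np.int64)

    def n_states(self) -> int:
        return int(np.prod([float(d) for d in self.dims]))

    def protonated_mask(self, i: int) -> np.ndarray:
        """Boolean mask over site i's microstates: carries at least the
        reference-or-more protons for basic sites / is the protonated form.
        A microstate counts as protonated if its absolute proton count equals
        the maximum over the site's microstates."""
        counts = np.array([m.proton_count for m in self.microstates[i]])
        return counts == counts.max()

    def permuted(self, order: Sequence[int]) -> "StateEnergyModel":
        """Model with sites re-ordered according to ``order``."""
        order = list(order)
        inv = {o: k for k, o in enumerate(order)}
        pair_w = {}
        for (i, j) in self.pairs:
            ni, nj = inv[i], inv[j]
            w = self.w_dense[i, : self.dims[i], j, : self.dims[j]]
            if ni < nj:
                pair_w[(ni, nj)] = w
            else:
                pair_w[(nj, ni)] = w.T
        return StateEnergyModel(
            [self.site_ids[o] for o in order],
            [self.microstates[o] for o in order],
            [self.pk_int[o] for o in order],
            [self.offsets[o] for o in order],
            pair_w,
            self.temperature,
        )

    @staticmethod
    def from_tsv(path) -> "StateEnergyModel":
        """Load a site-energy table written by the electrostatics module."""
        from .pb_electrostatics import SiteEnergyTable

        return SiteEnergyTable.from_tsv(path).to_model()


@dataclass
class MicrostatePopulations:
    """Per-site, per-microstate populations over a pH grid."""

    ph: np.ndarray
    site_ids: list
    microstates: list
    pops: list  # per site: array (m_i, n_ph)
    stderr: list | None = None  # same layout, MC only
    diagnostics: dict = field(default_factory=dict)

    def site_index(self, site) -> int:
        if isinstance(site, (int, np.integer)):
            return int(site)
        return self.site_ids.index(site)


def _validate_state(x, model: StateEnergyModel) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    if x.shape != (model.n_sites,):
        raise ValueError(f"state vector length {x.shape} != {model.n_sites}")
    for i, xi in enumerate(x):
        if not 0 <= xi < model.dims[i]:
            raise IndexError(f"site {i}: microstate index {xi} out of range")
    return x


def state_energy(x, model: StateEnergyModel, ph: float) -> float:
    """ΔE(x) in kcal/mol at the given pH; zero for the reference vector."""
    x = _validate_state(x, model)
    e = 0.0
    for i, xi in enumerate(x):
        e += model._a[i][xi] + model._b[i][xi] * ph
    for (i, j) in model.pairs:
        e += model.w_dense[i, x[i], j, x[j]]
    return float(e)


def _iter_chunks(dims, chunk):
    total = int(np.prod([float(d) for d in dims]))
    start = 0
    while start < total:
        stop = min(start + chunk, total)
        yield np.unravel_index(np.arange(start, stop), dims)
        start = stop


def populations_exact(
    model: StateEnergyModel,
    ph_grid,
    cap: int = DEFAULT_STATE_CAP,
    chunk: int = 1 << 15,
) -> MicrostatePopulations:
    """Populations by full enumeration of the protonation state space."""
    ph = np.asarray(ph_grid, dtype=float)
    total = model.n_states()
    if total > cap:
        raise StateSpaceTooLarge(
            f"{total} states exceeds the enumeration cap {cap}; "
            "use populations_mc instead"
        )
    kT = kt(model.temperature)

    def chunk_energy(idx):
        a = sum(model._a[i][idx[i]] for i in range(model.n_sites))
        b = sum(model._b[i][idx[i]] for i in range(model.n_sites))
        for (i, j) in model.pairs:
            a = a + model.w_dense[i, idx[i], j, idx[j]]
        return a[:, None] + b[:, None] * ph[None, :]

    emin = np.full(ph.shape, np.inf)
    for idx in _iter_chunks(model.dims, chunk):
        emin = np.minimum(emin, chunk_energy(idx).min(axis=0))

    z = np.zeros(ph.shape)
    acc = [np.zeros((d, ph.size)) for d in model.dims]
    for idx in _iter_chunks(model.dims, chunk):
        w = np.exp(-(chunk_energy(idx) - emin[None, :]) / kT)
        z += w.sum(axis=0)
        for i in range(model.n_sites):
            np.add.at(acc[i], idx[i], w)
    pops = [a / z[None, :] for a in acc]
    return MicrostatePopulations(ph, list(model.site_ids), model.microstates, pops)


@dataclass
class MCConfig:
    """Metropolis sampler settings.

    ``pair_threshold_pk`` selects site pairs with max |W| above the given
    number of pK-unit equivalents (ln10·kT) for additional paired flips.
    """

    sweeps: int = 10_000
    burn_in: int = 1_000
    seed: int = 1
    pair_threshold_pk: float = 2.0
    batches: int = 16
    acceptance_floor: float = 0.02


def _gather_pair_energy(model, i, states_i, x):
    """Σ_j W(i, states_i; j, x_j) for every chain; states_i per chain."""
    wi = model.w_dense[i]  # (mmax, n, mmax)
    g = wi[states_i]  # (n_chain, n, mmax)
    picked = np.take_along_axis(g, x[:, :, None], axis=2)[:, :, 0]
    return picked.sum(axis=1)


def populations_mc(
    model: StateEnergyModel,
    ph_grid,
    mc_config: MCConfig | None = None,
) -> MicrostatePopulations:
    """Populations by Metropolis Monte Carlo over protonation states.

    One independent chain runs per pH grid point.  Single-site flips are
    supplemented with paired flips for strongly coupled site pairs.
    Standard errors come from batch means.  Output is deterministic for a
    fixed seed.
    """
    cfg = mc_config or MCConfig()
    ph = np.asarray(ph_grid, dtype=float)
    nc = ph.size
    n = model.n_sites
    kT = kt(model.temperature)
    rng = np.random.default_rng(cfg.seed)

    single = [model._a[i][:, None] + model._b[i][:, None] * ph[None, :] for i in range(n)]

    lkt = LN10 * kt(model.temperature)
    coupled = []
    for (i, j) in model.pairs:
        w = model.w_dense[i, : model.dims[i], j, : model.dims[j]]
        if np.abs(w).max() > cfg.pair_threshold_pk * lkt:
            coupled.append((i, j))

    x = np.tile(model.reference_vector, (nc, 1))
    chain_idx = np.arange(nc)

    n_batches = cfg.batches
    per_batch = cfg.sweeps // n_batches
    sweeps = per_batch * n_batches
    counts = [np.zeros((n_batches, d, nc)) for d in model.dims]
    accepted = 0
    proposed = 0

    def propose(i, cur):
        # symmetric proposal uniform over the site's other microstates
        step = rng.integers(1, model.dims[i], size=nc)
        return (cur + step) % model.dims[i]

    def metropolis_single(i):
        nonlocal accepted, proposed
        cur = x[:, i].copy()
        new = propose(i, cur)
        de = single[i][new, chain_idx] - single[i][cur, chain_idx]
        de += _gather_pair_energy(model, i, new, x) - _gather_pair_energy(model, i, cur, x)
        acc = rng.random(nc) < np.exp(np.minimum(-de / kT, 0.0))
        x[acc, i] = new[acc]
        moved = acc & (new != cur)
        accepted += int(moved.sum())
        proposed += nc

    def metropolis_pair(i, j):
        nonlocal accepted, proposed
        ci, cj = x[:, i].copy(), x[:, j].copy()
        ni = propose(i, ci)
        nj = propose(j, cj)
        de = (
            single[i][ni, chain_idx] - single[i][ci, chain_idx]
            + single[j][nj, chain_idx] - single[j][cj, chain_idx]
        )
        de += _gather_pair_energy(model, i, ni, x) - _gather_pair_energy(model, i, ci, x)
        # site j's surroundings with site i already moved
        xi_saved = x[:, i].copy()
        x[:, i] = ni
        de += _gather_pair_energy(model, j, nj, x) - _gather_pair_energy(model, j, cj, x)
        x[:, i] = xi_saved
        acc = rng.random(nc) < np.exp(np.minimum(-de / kT, 0.0))
        x[acc, i] = ni[acc]
        x[acc, j] = nj[acc]
        moved = acc & ((ni != ci) | (nj != cj))
        accepted += int(moved.sum())
        proposed += nc

    def sweep():
        for i in range(n):
            metropolis_single(i)
        for (i, j) in coupled:
            metropolis_pair(i, j)

    for _ in range(cfg.burn_in):
        sweep()
    for s in range(sweeps):
        sweep()
        b = s // per_batch
        for i in range(n):
            np.add.at(counts[i][b], (x[:, i], chain_idx), 1.0)

    pops, err = [], []
    # Report a conservative standard error: the upper 95% confidence bound
    # of the batch-means estimate (guards against the chi-square noise of a
    # small batch count).  For microstates that were never or always
    # observed the batch variance is degenerate, so the error is floored at
    # one part per effective sample, where the effective sample count
    # discounts sweeps by the measured acceptance rate (a proxy for the
    # autocorrelation time of the chain).
    from scipy.stats import chi2

    rate = accepted / max(proposed, 1)
    n_eff = max(1.0, sweeps * max(rate, 1.0 / sweeps))
    ucb = math.sqrt((n_batches - 1) / chi2.ppf(0.05, n_batches - 1))
    for i in range(n):
        batch_means = counts[i] / per_batch  # (nb, m, nc)
        pops.append(batch_means.mean(axis=0))
        se = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches)
        err.append(np.maximum(se * ucb, 1.0 / n_eff))
    rate = accepted / max(proposed, 1)
    diagnostics = {
        "acceptance_rate": rate,
        "poor_mixing": rate < cfg.acceptance_floor,
        "coupled_pairs": list(coupled),
        "sweeps": sweeps,
    }
    return MicrostatePopulations(
        ph, list(model.site_ids), model.microstates, pops, stderr=err, diagnostics=diagnostics
    )


def degree_of_deprotonation(populations: MicrostatePopulations, site) -> np.ndarray:
    """θ(pH) = 1 − Σ populations of the site's protonated microstates."""
    i = populations.site_index(site)
    counts = np.array([m.proton_count for m in populations.microstates[i]])
    prot = counts == counts.max()
    return 1.0 - populations.pops[i][prot].sum(axis=0)


def protonated_fraction(populations: MicrostatePopulations, site) -> np.ndarray:
    """Population of the protonated form, 1 − θ(pH)."""
    return 1.0 - degree_of_deprotonation(populations, site)
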