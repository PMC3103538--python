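"""Snapshot averaging, pH-dependent regime weighting and pK₁/₂ extraction.

Titration curves computed per snapshot are arithmetically averaged within
each regime ensemble.  The three regime ensembles — allC (all ionisable
groups charged), glu0 (glutamates neutral) and lys0 (lysines neutral) — are
then combined with pH-dependent weights W_S(pH), Σ_S W_S = 1.  The weights
follow the calculated ionisation of the groups that define each regime: the
mean carboxyl deprotonation in the glu0 set and the mean amino protonation
state in the lys0 set,

    W_glu0(pH) = 1 − ⟨θ_carboxyl⟩_glu0(pH)
    W_lys0(pH) = ⟨θ_amino⟩_lys0(pH)
    W_allC(pH) = 1 − W_glu0 − W_lys0   (clamped at 0 and renormalised)

so that at strongly acidic pH the glu0 set carries unit weight, around
neutrality allC dominates, and at strongly basic pH lys0 takes over.  The
pK₁/₂ of a site is the pH where its averaged, combined protonated-form
population crosses one half.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TitrationCurve",
    "RegimeWeights",
    "PKHalf",
    "PKResult",
    "ensemble_average",
    "regime_weights",
    "combine_regimes",
    "pk_half",
    "chain_average",
]


@dataclass
class TitrationCurve:
    """Population of a tracked microstate class versus pH."""

    ph: np.ndarray
    values: np.ndarray
    site_id: tuple | None = None
    regime: str | None = None
    n_snapshots: int = 1

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ph.shape != self.values.shape:
            raise ValueError("pH grid and values differ in length")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("curve values must lie in [0, 1]")


@dataclass
class RegimeWeights:
    """pH-dependent convex weights of the three regime ensembles."""

    ph: np.ndarray
    weights: Mapping[str, np.ndarray]
    clamped: bool = False

    def __post_init__(self):
        total = sum(self.weights.values())
        if np.abs(total - 1.0).max() > 1e-9:
            raise ValueError("regime weights must sum to 1 at every pH")
        for name, w in self.weights.items():
            if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
                raise ValueError(f"weight {name} outside [0, 1]")


@dataclass
class PKHalf:
    """Midpoint of a titration curve with bookkeeping flags."""

    value: float
    out_of_range: bool = False
    multimodal: bool = False
    crossings: tuple = ()


@dataclass
class PKResult:
    """Per-site pK₁/₂ across chains of a (homo)dimer."""

    site_key: tuple  # (resname, resnum, terminus flag)
    per_chain: dict  # chain -> PKHalf
    pk_mean: float = np.nan
    delta_pk: float = np.nan  # chain A − chain B where both exist


def ensemble_average(per_snapshot_curves: Sequence[TitrationCurve]) -> TitrationCurve:
    """Pointwise arithmetic mean of per-snapshot curves (same site, grid)."""
    if not per_snapshot_curves:
        raise ValueError("no curves to average")
    first = per_snapshot_curves[0]
    for c in per_snapshot_curves[1:]:
        if c.ph.shape != first.ph.shape or np.abs(c.ph - first.ph).max() > 1e-12:
            raise ValueError("curves do not share a pH grid")
        if c.site_id != first.site_id:
            raise ValueError("curves belong to different sites")
    values = np.mean([c.values for c in per_snapshot_curves], axis=0)
    m = sum(c.n_snapshots for c in per_snapshot_curves)
    return TitrationCurve(first.ph, values, first.site_id, first.regime, m)


def regime_weights(
    theta_carboxyl_glu0: TitrationCurve,
    theta_amino_lys0: TitrationCurve,
) -> RegimeWeights:
    """Weights of the three regimes from the defining average ionisations.

    ``theta_carboxyl_glu0`` — mean degree of deprotonation of the
    carboxyl-family sites computed from the glu0 ensemble;
    ``theta_amino_lys0`` — mean degree of deprotonation of the amino-family
    sites from the lys0 ensemble.  If the raw allC weight would be negative
    (strong overlap of the flanking regimes) it is clamped to zero and the
    weights renormalised; this is logged.
    """
    tc, ta = theta_carboxyl_glu0, theta_amino_lys0
    if tc.ph.shape != ta.ph.shape or np.abs(tc.ph - ta.ph).max() > 1e-12:
        raise ValueError("theta curves do not share a pH grid")
    for curve in (tc, ta):
        if np.any(curve.values < 0) or np.any(curve.values > 1):
            raise ValueError("theta values must lie in [0, 1]")
    w_glu0 = 1.0 - tc.values
    w_lys0 = ta.values
    w_allc = 1.0 - w_glu0 - w_lys0
    clamped = bool(np.any(w_allc < 0))
    if clamped:
        logger.info("allC weight clamped to 0 at %d pH points", int((w_allc < 0).sum()))
        w_allc = np.maximum(w_allc, 0.0)
        total = w_glu0 + w_lys0 + w_allc
        w_glu0, w_lys0, w_allc = w_glu0 / total, w_lys0 / total, w_allc / total
    return RegimeWeights(tc.ph, {"allC": w_allc, "glu0": w_glu0, "lys0": w_lys0}, clamped)


def combine_regimes(
    curves_by_regime: Mapping[str, TitrationCurve],
    weights: RegimeWeights,
) -> TitrationCurve:
    """Pointwise convex combination Σ_S W_S(pH)·curve_S(pH)."""
    missing = set(weights.weights) - set(curves_by_regime)
    if missing:
        raise ValueError(f"missing regime curves: {sorted(missing)}")
    first = next(iter(curves_by_regime.values()))
    out = np.zeros_like(first.ph)
    m = 0
    for regime, w in weights.weights.items():
        c = curves_by_regime[regime]
        if np.abs(c.ph - weights.ph).max() > 1e-12:
            raise ValueError("curve and weight pH grids differ")
        out = out + w * c.values
        m += c.n_snapshots
    return TitrationCurve(weights.ph, np.clip(out, 0.0, 1.0), first.site_id, "combined", m)


def pk_half(curve: TitrationCurve, pk_mod: float | None = None) -> PKHalf:
    """pH where the tracked population crosses 0.5 (linear interpolation).

    Multiple crossings: the one nearest ``pk_mod`` is returned and the
    result flagged multimodal.  No crossing: flagged out of range with the
    endpoint nearest 0.5 as the value.
    """
    v = curve.values - 0.5
    ph = curve.ph
    crossings = []
    for k in range(len(ph) - 1):
        a, b = v[k], v[k + 1]
        if a == 0.0:
            crossings.append(float(ph[k]))
        elif a * b < 0:
            crossings.append(float(ph[k] - a * (ph[k + 1] - ph[k]) / (b - a)))
    if v[-1] == 0.0:
        crossings.append(float(ph[-1]))
    # collapse numerically duplicate crossings
    uniq = []
    for c in crossings:
        if not uniq or abs(c - uniq[-1]) > 1e-9:
            uniq.append(c)
    if not uniq:
        value = float(ph[0] if abs(v[0]) < abs(v[-1]) else ph[-1])
        return PKHalf(value, out_of_range=True)
    if len(uniq) == 1:
        return PKHalf(uniq[0], crossings=tuple(uniq))
    anchor = pk_mod if pk_mod is not None else float(np.median(uniq))
    best = min(uniq, key=lambda c: abs(c - anchor))
    return PKHalf(best, multimodal=True, crossings=tuple(uniq))


def chain_average(per_chain: Mapping[str, PKHalf]) -> PKResult:
    """Combine per-chain midpoints of one homologous site.

    The reported pK₁/₂ is the arithmetic mean over chains; for a two-chain
    system ΔpK = pK(first chain) − pK(second chain).
    """
    chains = sorted(per_chain)
    vals = [per_chain[c].value for c in chains if not per_chain[c].out_of_range]
    mean = float(np.mean(vals)) if vals else np.nan
    delta = np.nan
    if len(chains) == 2 and all(not per_chain[c].out_of_range for c in chains):
        delta = per_chain[chains[0]].value - per_chain[chains[1]].value
    return PKResult((), dict(per_chain), mean, delta)
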