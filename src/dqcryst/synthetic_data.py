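"""Generators for toy crystal structures, noisy fractional-intensity sets
and synthetic shieldings, plus an independent brute-force supercell oracle.

Everything is deterministic under a fixed seed.  The oracle deliberately
re-derives pair statistics with a materialized supercell and explicit
loops so it shares no code path with the lattice-translation enumeration
of the main pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import K_HH_PM
from .dipolar import PairCoupling, PairCouplingTable
from .structures import (
    AtomSite,
    CrystalStructure,
    GeometryError,
    ProtonSiteGroup,
    SymmetryOp,
    UnitCell,
)
from .validation import FractionalIntensitySet


@dataclass(frozen=True)
class ToyStructureSpec:
    motif: str  # {"methyl_triangle", "hbond_pair", "lattice_chain", "random_cell"}
    distances_pm: tuple[float, ...] = ()
    cell_ang: float = 30.0
    n_sites: int = 4
    seed: int = 0


@dataclass(frozen=True)
class NoiseSpec:
    model: str = "multiplicative_gaussian"  # or "dirichlet"
    scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.model not in ("multiplicative_gaussian", "dirichlet"):
            raise ValueError(f"unknown noise model {self.model!r}")


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------


def _p1_structure(cell: UnitCell, cart_ang: Sequence[np.ndarray], labels: Sequence[str]) -> CrystalStructure:
    inv = np.linalg.inv(cell.matrix)
    sites = [
        AtomSite(label=lbl, element="H", frac=tuple(np.asarray(pos) @ inv))
        for lbl, pos in zip(labels, cart_ang)
    ]
    return CrystalStructure(cell=cell, symmetry_ops=[SymmetryOp.identity()], sites=sites)


def make_methyl_structure(
    d12_pm: float, d13_pm: float, d23_pm: float, cell_ang: float = 30.0
) -> CrystalStructure:
    """P1 cell with three H forming a triangle of the given side lengths.

    The default 30 Angstrom cubic cell keeps all periodic images beyond a
    1000 pm cutoff.
    """
    for trio in ((d12_pm, d13_pm, d23_pm), (d13_pm, d23_pm, d12_pm), (d23_pm, d12_pm, d13_pm)):
        if trio[0] >= trio[1] + trio[2]:
            raise GeometryError("triangle inequality violated")
    d12, d13, d23 = (d / 100.0 for d in (d12_pm, d13_pm, d23_pm))  # Angstrom
    x3 = (d12**2 + d13**2 - d23**2) / (2.0 * d12)
    y3 = math.sqrt(max(d13**2 - x3**2, 0.0))
    center = np.array([cell_ang / 2.0] * 3)
    pts = [
        center + np.array([0.0, 0.0, 0.0]),
        center + np.array([d12, 0.0, 0.0]),
        center + np.array([x3, y3, 0.0]),
    ]
    cell = UnitCell(cell_ang, cell_ang, cell_ang)
    return _p1_structure(cell, pts, ["H1", "H2", "H3"])


def make_hbond_structure(separation_pm: float, cell_ang: float = 30.0) -> CrystalStructure:
    """Two H sites at the given separation in an otherwise empty large cell."""
    center = np.array([cell_ang / 2.0] * 3)
    pts = [center, center + np.array([separation_pm / 100.0, 0.0, 0.0])]
    cell = UnitCell(cell_ang, cell_ang, cell_ang)
    return _p1_structure(cell, pts, ["HA", "HB"])


def make_chain_structure(spacing_pm: float, cell_ang: float = 30.0) -> CrystalStructure:
    """A single H repeating along ``a`` with period ``spacing_pm``."""
    cell = UnitCell(spacing_pm / 100.0, cell_ang, cell_ang)
    return _p1_structure(cell, [np.zeros(3)], ["H1"])


def make_random_structure(
    n_sites: int, cell_ang: float = 12.0, min_sep_pm: float = 160.0, seed: int = 0
) -> CrystalStructure:
    """Random P1 cell with ``n_sites`` H placed no closer than ``min_sep_pm``
    (including periodic images)."""
    rng = np.random.default_rng(seed)
    cell = UnitCell(
        cell_ang * rng.uniform(0.8, 1.2),
        cell_ang * rng.uniform(0.8, 1.2),
        cell_ang * rng.uniform(0.8, 1.2),
        rng.uniform(80.0, 100.0),
        rng.uniform(80.0, 100.0),
        rng.uniform(80.0, 100.0),
    )
    min_sep = min_sep_pm / 100.0
    fracs: list[np.ndarray] = []
    attempts = 0
    while len(fracs) < n_sites:
        attempts += 1
        if attempts > 20000:
            raise GeometryError("cannot place sites with requested separation")
        cand = rng.uniform(0.0, 1.0, size=3)
        ok = True
        for f in fracs:
            delta = cand - f
            delta -= np.round(delta)
            if np.linalg.norm(cell.to_cartesian(delta)) < min_sep:
                ok = False
                break
        if ok:
            fracs.append(cand)
    sites = [
        AtomSite(label=f"H{i+1}", element="H", frac=tuple(f)) for i, f in enumerate(fracs)
    ]
    return CrystalStructure(cell=cell, symmetry_ops=[SymmetryOp.identity()], sites=sites)


# ---------------------------------------------------------------------------
# brute-force supercell oracle
# ---------------------------------------------------------------------------


def brute_force_pair_distances(
    structure: CrystalStructure,
    groups: Sequence[ProtonSiteGroup],
    cutoff_pm: float = 1000.0,
) -> dict[tuple[str, str], list[float]]:
    """Reference pair-distance lists via an explicit supercell double loop.

    Returns distances (pm) keyed by sorted group-id pair.  The supercell is
    sized from the smallest perpendicular cell width so the central atoms
    see every image within the cutoff.
    """
    cell = structure.cell
    cutoff_ang = cutoff_pm / 100.0
    n = int(math.ceil(cutoff_ang / cell.perpendicular_widths().min())) + 1

    pos = {s.label: np.array(s.frac, dtype=float) for s in structure.sites}
    member_of = {}
    for g in groups:
        for lbl in g.member_labels:
            member_of[lbl] = g.group_id

    # materialize supercell atoms: (label, cell_index_tuple, cartesian)
    supercell = []
    for lbl in member_of:
        for ia in range(-n, n + 1):
            for ib in range(-n, n + 1):
                for ic in range(-n, n + 1):
                    frac = pos[lbl] + np.array([ia, ib, ic], dtype=float)
                    supercell.append((lbl, (ia, ib, ic), cell.to_cartesian(frac)))

    order = {g.group_id: i for i, g in enumerate(groups)}
    member_index = {lbl: i for g in groups for i, lbl in enumerate(g.member_labels)}
    out: dict[tuple[str, str], list[float]] = {}
    for lbl_m in member_of:
        xm = cell.to_cartesian(pos[lbl_m])
        gm = member_of[lbl_m]
        for lbl_n, image, xn in supercell:
            gn = member_of[lbl_n]
            if gm == gn:
                if member_index[lbl_n] < member_index[lbl_m]:
                    continue
                if lbl_n == lbl_m and image == (0, 0, 0):
                    continue
            elif order[gn] < order[gm]:
                continue
            r_ang = float(np.linalg.norm(xn - xm))
            if r_ang > cutoff_ang or r_ang == 0.0:
                continue
            key = tuple(sorted((gm, gn)))
            out.setdefault(key, []).append(r_ang * 100.0)
    return {k: sorted(v) for k, v in out.items()}


def brute_force_coupling_table(
    structure: CrystalStructure,
    groups: Sequence[ProtonSiteGroup],
    cutoff_pm: float = 1000.0,
    mult_tol: float = 0.10,
) -> PairCouplingTable:
    """Ground-truth coupling table from the supercell oracle, with the
    coupling arithmetic written out longhand (no pipeline calls)."""
    motion = {g.group_id: g.motion for g in groups}
    entries = []
    for (gj, gk), dists in brute_force_pair_distances(structure, groups, cutoff_pm).items():
        scale = 1.0
        if gj == gk and motion.get(gj) == "fast_3site":
            scale = 0.25
        b2 = 0.0
        for r in dists:
            b = K_HH_PM / (r * r * r)
            b2 += scale * b * b
        rmin = min(dists)
        m = sum(1 for r in dists if r <= rmin * (1.0 + mult_tol))
        r_eff = (m * K_HH_PM**2 / b2) ** (1.0 / 6.0)
        entries.append(
            PairCoupling(
                j=gj, k=gk, b_eff_sq=b2, m_jk=m, r_eff_pm=r_eff, n_terms=len(dists),
                motion_applied=motion.get(gj, "static") if gj == gk else "static",
            )
        )
    return PairCouplingTable(entries)


def make_toy_crystal(
    spec: ToyStructureSpec,
) -> tuple[CrystalStructure, list[ProtonSiteGroup], PairCouplingTable]:
    """Build a toy structure with its default grouping and the ground-truth
    coupling table from the brute-force oracle."""
    if spec.motif == "methyl_triangle":
        d = spec.distances_pm or (176.0, 178.0, 179.0)
        structure = make_methyl_structure(*d, cell_ang=spec.cell_ang)
        groups = [ProtonSiteGroup("CH3", ("H1", "H2", "H3"), shift=1.0)]
    elif spec.motif == "hbond_pair":
        d = spec.distances_pm or (233.0,)
        structure = make_hbond_structure(d[0], cell_ang=spec.cell_ang)
        groups = [
            ProtonSiteGroup("OHa", ("HA",), shift=9.0),
            ProtonSiteGroup("OHb", ("HB",), shift=12.0),
        ]
    elif spec.motif == "lattice_chain":
        d = spec.distances_pm or (400.0,)
        structure = make_chain_structure(d[0], cell_ang=spec.cell_ang)
        groups = [ProtonSiteGroup("Hchain", ("H1",), shift=5.0)]
    elif spec.motif == "random_cell":
        structure = make_random_structure(spec.n_sites, seed=spec.seed)
        groups = [
            ProtonSiteGroup(f"G{i+1}", (s.label,), shift=float(1 + i))
            for i, s in enumerate(structure.sites)
        ]
    else:
        raise ValueError(f"unknown motif {spec.motif!r}")
    truth = brute_force_coupling_table(structure, groups)
    return structure, groups, truth


# ---------------------------------------------------------------------------
# noise generators
# ---------------------------------------------------------------------------


def perturb_fractions(
    f: FractionalIntensitySet, noise: NoiseSpec
) -> tuple[FractionalIntensitySet, int]:
    """Noisy, renormalized copy of a fraction set; returns the number of
    resampled draws (multiplicative noise driving a fraction negative)."""
    rng = np.random.default_rng(noise.seed)
    keys = sorted(f.fractions)
    vals = np.array([f.fractions[k] for k in keys])
    resampled = 0
    if noise.scale == 0:
        noisy = vals.copy()
    elif noise.model == "multiplicative_gaussian":
        noisy = np.empty_like(vals)
        for i, v in enumerate(vals):
            draw = v * (1.0 + rng.normal(0.0, noise.scale))
            while draw <= 0:
                resampled += 1
                draw = v * (1.0 + rng.normal(0.0, noise.scale))
            noisy[i] = draw
    else:  # dirichlet, concentration 1/scale**2 around the input point
        conc = vals * (1.0 / noise.scale**2)
        noisy = rng.dirichlet(np.maximum(conc, 1e-9))
    noisy = noisy / noisy.sum()
    return (
        FractionalIntensitySet(
            fractions=dict(zip(keys, noisy.tolist())),
            excluded=dict(f.excluded),
            provenance=f.provenance,
        ),
        resampled,
    )


def synth_shieldings(
    delta_true_ppm: Sequence[float],
    sigma_ref_ppm: float,
    noise_sd_ppm: float = 0.0,
    seed: int = 0,
    species: str = "1H",
    anisotropy_ppm: float = 0.0,
) -> list:
    """Synthetic shielding tensors with sigma_iso = ref - delta + noise.

    The three emitted principal values always average exactly to the
    generated sigma_iso.
    """
    from .shifts import ShieldingTensor

    if noise_sd_ppm < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for i, d in enumerate(delta_true_ppm):
        iso = sigma_ref_ppm - d + (rng.normal(0.0, noise_sd_ppm) if noise_sd_ppm else 0.0)
        if anisotropy_ppm:
            p1 = rng.normal(0.0, anisotropy_ppm)
            p2 = rng.normal(0.0, anisotropy_ppm)
            offsets = (p1, p2, -(p1 + p2))
        else:
            offsets = (0.0, 0.0, 0.0)
        out.append(
            ShieldingTensor(
                label=f"S{i+1}",
                sigma_xx=iso + offsets[0],
                sigma_yy=iso + offsets[1],
                sigma_zz=iso + offsets[2],
                species=species,
            )
        )
    return out
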