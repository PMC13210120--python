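"""Linear-regime simulation of 2Q-1Q proton correlation spectra and
rectangular-domain peak integration.

The simulator is linear by construction: each pair contributes a volume
proportional to kappa^2 * b_eff^2, placed as two Gaussian cross peaks
(distinct shifts) or one autocorrelation peak (equal shifts).  Buildup
dynamics versus the excitation interval are deliberately not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dipolar import PairCouplingTable, pair_id
from .structures import ConfigError, ProtonSiteGroup
from .validation import FractionalIntensitySet


@dataclass
class SpectrumConfig:
    kappa: float = 0.5  # recoupling scaling factor, cancels in fractions
    tau_exc_us: float = 16.67
    linewidth_1q: float = 0.3  # Gaussian sigma, ppm
    linewidth_2q: float = 0.4
    n_points: int = 512
    pad_linewidths: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa <= 1.0:
            raise ValueError("kappa must lie in (0, 1]")
        if self.tau_exc_us <= 0:
            raise ValueError("excitation interval must be positive")
        if min(self.linewidth_1q, self.linewidth_2q) <= 0:
            raise ValueError("linewidths must be positive")


@dataclass
class Spectrum2D:
    axis_1q: np.ndarray  # ppm
    axis_2q: np.ndarray  # ppm
    intensity: np.ndarray  # shape (len(axis_2q), len(axis_1q))

    @property
    def cell_area(self) -> float:
        return float(
            abs(self.axis_1q[1] - self.axis_1q[0]) * abs(self.axis_2q[1] - self.axis_2q[0])
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.intensity, index=self.axis_2q, columns=self.axis_1q)


@dataclass(frozen=True)
class Rectangle:
    """Integration rectangle in ppm: [lo_1q, hi_1q] x [lo_2q, hi_2q]."""

    lo_1q: float
    hi_1q: float
    lo_2q: float
    hi_2q: float


@dataclass
class PeakIntensities:
    """Integrated volumes per pair group, with per-rectangle replicates."""

    volumes: dict[str, float]
    replicates: dict[str, list[float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.volumes.values())

    def dispersion(self, key: str) -> float:
        reps = self.replicates.get(key, [])
        return float(np.std(reps)) if len(reps) > 1 else 0.0


def _gaussian_peak(
    ax1: np.ndarray, ax2: np.ndarray, c1: float, c2: float, s1: float, s2: float
) -> np.ndarray:
    """Unit-volume separable 2D Gaussian on the (2Q, 1Q) grid."""
    g1 = np.exp(-0.5 * ((ax1 - c1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = np.exp(-0.5 * ((ax2 - c2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return np.outer(g2, g1)


def simulate_2q1q(
    groups: Sequence[ProtonSiteGroup],
    couplings: PairCouplingTable,
    cfg: SpectrumConfig | None = None,
) -> Spectrum2D:
    """Simulate the short-excitation 2Q-1Q correlation spectrum.

    A pair of distinct groups j, k gives two peaks at {dj+dk, dj} and
    {dj+dk, dk}, each carrying half the pair volume; an equivalent pair
    gives one peak at {2dj, dj} with the full volume.
    """
    cfg = cfg or SpectrumConfig()
    shifts = {g.group_id: g.shift for g in groups}
    for e in couplings:
        if shifts.get(e.j) is None or shifts.get(e.k) is None:
            raise ConfigError(f"pair {e.id} has a group without a chemical shift")

    all_1q = [shifts[g.group_id] for g in groups if g.shift is not None]
    all_2q = [shifts[e.j] + shifts[e.k] for e in couplings]
    pad1 = cfg.pad_linewidths * cfg.linewidth_1q
    pad2 = cfg.pad_linewidths * cfg.linewidth_2q
    ax1 = np.linspace(min(all_1q) - pad1, max(all_1q) + pad1, cfg.n_points)
    ax2 = np.linspace(min(all_2q) - pad2, max(all_2q) + pad2, cfg.n_points)

    intensity = np.zeros((cfg.n_points, cfg.n_points))
    for e in couplings:
        volume = cfg.kappa**2 * e.b_eff_sq
        dj, dk = shifts[e.j], shifts[e.k]
        d2q = dj + dk
        if e.j == e.k:
            intensity += volume * _gaussian_peak(
                ax1, ax2, dj, d2q, cfg.linewidth_1q, cfg.linewidth_2q
            )
        else:
            for d1q in (dj, dk):
                intensity += 0.5 * volume * _gaussian_peak(
                    ax1, ax2, d1q, d2q, cfg.linewidth_1q, cfg.linewidth_2q
                )
    return Spectrum2D(axis_1q=ax1, axis_2q=ax2, intensity=intensity)


def default_regions(
    groups: Sequence[ProtonSiteGroup],
    couplings: PairCouplingTable,
    cfg: SpectrumConfig,
    n_replicates: int = 3,
    jitter: float = 0.10,
    half_widths: float = 5.0,
    seed: int | None = None,
) -> dict[str, list[Rectangle]]:
    """Nominal +/- ``half_widths`` sigma rectangles per pair, with jittered
    replicates standing in for independent manual integrations."""
    rng = np.random.default_rng(seed)
    shifts = {g.group_id: g.shift for g in groups}
    regions: dict[str, list[Rectangle]] = {}
    w1 = half_widths * cfg.linewidth_1q
    w2 = half_widths * cfg.linewidth_2q
    for e in couplings:
        dj, dk = shifts[e.j], shifts[e.k]
        d2q = dj + dk
        centers = [(d2q, dj)] if e.j == e.k else [(d2q, dj), (d2q, dk)]
        rects = []
        for _ in range(n_replicates):
            for c2, c1 in centers:
                j1 = 1.0 + rng.uniform(-jitter, jitter)
                j2 = 1.0 + rng.uniform(-jitter, jitter)
                rects.append(
                    Rectangle(c1 - w1 * j1, c1 + w1 * j1, c2 - w2 * j2, c2 + w2 * j2)
                )
        regions["-".join(e.id)] = rects
    return regions


def integrate_rectangles(
    spec: Spectrum2D,
    regions: Mapping[str, Sequence[Rectangle]],
    n_centers: Mapping[str, int] | None = None,
) -> PeakIntensities:
    """Riemann-sum each rectangle; the group volume is the replicate mean.

    When one group owns several peak centers (a cross pair integrated over
    both of its peaks), ``n_centers`` states how many rectangles form one
    replicate so their volumes are summed, not averaged.
    """
    volumes: dict[str, float] = {}
    replicates: dict[str, list[float]] = {}
    seen: list[Rectangle] = []
    for key, rects in regions.items():
        vals = []
        for r in rects:
            if r.hi_1q <= r.lo_1q or r.hi_2q <= r.lo_2q:
                raise ValueError(f"empty rectangle for group {key!r}")
            m1 = (spec.axis_1q >= r.lo_1q) & (spec.axis_1q <= r.hi_1q)
            m2 = (spec.axis_2q >= r.lo_2q) & (spec.axis_2q <= r.hi_2q)
            vals.append(float(spec.intensity[np.ix_(m2, m1)].sum() * spec.cell_area))
            for other in seen:
                if (
                    r.lo_1q < other.hi_1q
                    and other.lo_1q < r.hi_1q
                    and r.lo_2q < other.hi_2q
                    and other.lo_2q < r.hi_2q
                ):
                    warnings.warn(
                        f"rectangles of group {key!r} overlap another group's "
                        "region; volumes may be double counted",
                        stacklevel=2,
                    )
                    break
        seen.extend(rects)
        per_rep = (n_centers or {}).get(key, 1)
        if per_rep > 1:
            vals = [sum(vals[i : i + per_rep]) for i in range(0, len(vals), per_rep)]
        replicates[key] = vals
        volumes[key] = float(np.mean(vals))
    return PeakIntensities(volumes=volumes, replicates=replicates)


def nmr_fractions(
    intens: PeakIntensities,
    grouping: Mapping[str, Iterable[str]] | None = None,
    exclusions: Iterable[str] = (),
) -> FractionalIntensitySet:
    """Fractional intensities from integrated volumes (retained sum = 1)."""
    merged: dict[str, float] = {}
    claimed: set[str] = set()
    if grouping:
        for label, members in grouping.items():
            members = list(members)
            missing = [m for m in members if m not in intens.volumes]
            if missing:
                raise ConfigError(f"grouping refers to unknown groups {missing}")
            merged[label] = sum(intens.volumes[m] for m in members)
            claimed.update(members)
    for key, v in intens.volumes.items():
        if key not in claimed:
            merged[key] = v
    excl = set(exclusions)
    retained = {k: v for k, v in merged.items() if k not in excl}
    total = sum(retained.values())
    if total <= 0:
        raise ValueError("retained total intensity is zero")
    return FractionalIntensitySet(
        fractions={k: v / total for k, v in retained.items()},
        excluded={k: merged[k] / total for k in excl if k in merged},
        provenance="NMR",
    )
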