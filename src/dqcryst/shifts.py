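"""Chemical-shift validation arm.

Isotropic averaging of shielding/shift tensors, fitting of the
shielding-to-shift reference intercept (slope fixed at -1), constrained
assignment of experimental shifts to calculated sites, and per-site
deviation / rmsd statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structures import ConfigError


@dataclass(frozen=True)
class ShieldingTensor:
    label: str
    sigma_xx: float
    sigma_yy: float
    sigma_zz: float
    species: str = "1H"

    @property
    def sigma_iso(self) -> float:
        return (self.sigma_xx + self.sigma_yy + self.sigma_zz) / 3.0


def isotropic_shift(principal_values: Sequence[float]) -> float:
    """Arithmetic mean of the three principal tensor values (ppm)."""
    vals = tuple(principal_values)
    if len(vals) != 3 or not all(np.isfinite(vals)):
        raise ValueError("need three finite principal values")
    return float(sum(vals) / 3.0)


def fit_shift_reference(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Fit the reference shielding from (delta_exp, sigma_iso_calc) pairs.

    With the slope fixed at -1 the least-squares intercept is simply
    ``mean(delta_exp + sigma_iso)``.  Also returns the R^2 of the
    delta-versus-(sigma_ref - sigma) correlation (1.0 for a single pair
    or a degenerate experimental set).
    """
    if not pairs:
        raise ValueError("need at least one (shift, shielding) pair")
    d = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)
    sigma_ref = float(np.mean(d + s))
    pred = sigma_ref - s
    tss = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(np.sum((d - pred) ** 2)) / tss
    return sigma_ref, r2


def shielding_to_shift(sigma_iso: float, sigma_ref: float) -> float:
    """delta = sigma_ref - sigma_iso (ppm)."""
    return sigma_ref - sigma_iso


def assign_shifts(
    exp_shifts: Sequence[float],
    calc_shifts: Mapping[str, float],
    blocks: Sequence[Sequence[str]] | None = None,
) -> dict[float, str]:
    """Assign experimental shifts to calculated sites within allowed blocks.

    Each block pairs len(block) experimental values (taken in input order
    against the block's position in the concatenated site list) with its
    site labels, choosing the bijection minimizing the sum of squared
    differences.  Blocks of <= 8 sites are solved by exhaustive
    permutation; larger ones fall back to the Hungarian algorithm.
    """
    labels = list(calc_shifts)
    if blocks is None:
        blocks = [labels]
    covered = [l for blk in blocks for l in blk]
    if sorted(covered) != sorted(labels):
        raise ConfigError("blocks must partition the calculated sites")
    if len(exp_shifts) != len(labels):
        raise ConfigError("experimental and calculated site counts differ")

    assignment: dict[float, str] = {}
    offset = 0
    for blk in blocks:
        blk = list(blk)
        exp_blk = list(exp_shifts[offset : offset + len(blk)])
        offset += len(blk)
        calc_blk = [calc_shifts[l] for l in blk]
        if len(blk) <= 8:
            best_cost, best_perm = None, None
            for perm in itertools.permutations(range(len(blk))):
                cost = sum((exp_blk[i] - calc_blk[p]) ** 2 for i, p in enumerate(perm))
                if best_cost is None or cost < best_cost - 1e-15:
                    best_cost, best_perm = cost, perm
            perm = best_perm
        else:
            cost = np.subtract.outer(np.array(exp_blk), np.array(calc_blk)) ** 2
            _, cols = linear_sum_assignment(cost)
            perm = tuple(cols)
        for i, p in enumerate(perm):
            assignment[exp_blk[i]] = blk[p]
    return assignment


@dataclass
class ShiftComparison:
    """Per-site deviations between calculated and experimental shifts."""

    sites: list[str]
    delta_exp: dict[str, float]
    delta_calc: dict[str, float]
    deviations: dict[str, float] = field(init=False)
    rmsd: float = field(init=False)
    alpha_label: str = "DFT"
    species: str = "1H"
    sigma_ref: float | None = None

    def __post_init__(self) -> None:
        self.deviations = {
            s: self.delta_calc[s] - self.delta_exp[s] for s in self.sites
        }
        vals = np.array(list(self.deviations.values()))
        self.rmsd = float(np.sqrt(np.mean(vals**2)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site": self.sites,
                "delta_exp_ppm": [self.delta_exp[s] for s in self.sites],
                "delta_calc_ppm": [self.delta_calc[s] for s in self.sites],
                "deviation_ppm": [self.deviations[s] for s in self.sites],
            }
        )


def shift_deviations(
    delta_exp: Mapping[str, float],
    delta_calc: Mapping[str, float],
    alpha_label: str = "DFT",
    species: str = "1H",
    sigma_ref: float | None = None,
) -> ShiftComparison:
    """Per-site (calc - exp) deviations and their rmsd over the site set.

    Sites sharing one overlapped experimental peak carry the shared
    peak-maximum shift independently; they are not collapsed.
    """
    if set(delta_exp) != set(delta_calc):
        raise ConfigError("experimental and calculated site sets differ")
    sites = sorted(delta_exp)
    return ShiftComparison(
        sites=sites,
        delta_exp=dict(delta_exp),
        delta_calc=dict(delta_calc),
        alpha_label=alpha_label,
        species=species,
        sigma_ref=sigma_ref,
    )
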