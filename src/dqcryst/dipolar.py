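"""Dipolar couplings and their r^-6 aggregates.

The analysis never needs the absolute coupling scale: every fractional
quantity divides it out, and effective distances combine the prefactor with
its own inverse.  Sums are therefore accumulated as ``sum(r^-6)`` in pm
units, with absolute Hz^2 values exposed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import K_HH_PM
from .structures import ConfigError, ProtonSiteGroup, SitePairDistances

DEFAULT_MULT_TOL = 0.10

#: Coupling scale factor for one proton pair inside a rapidly rotating
#: 3-site methyl group (applied to the coupling, i.e. x1/4 on its square).
FAST_3SITE_SCALE = -0.5


class UndefinedDistanceError(ValueError):
    """Raised when an effective distance is requested for zero coupling."""


def dipolar_coupling(r_pm: float) -> float:
    """Dipolar coupling constant (Hz, negative) of two protons at ``r_pm``."""
    if r_pm <= 0:
        raise ValueError("distance must be positive")
    return K_HH_PM / r_pm**3


def effective_coupling_squared(
    pair: SitePairDistances,
    motion_j: str = "static",
    motion_k: str = "static",
) -> float:
    """Squared effective coupling (Hz^2) summed over all listed contacts.

    For an equivalent pair under fast 3-site exchange every intra-group
    coupling is scaled by -1/2 before squaring.  Motion never rescales
    couplings to *external* groups: the static and fast-jump sums coincide
    there, so no factor is applied when ``j != k``.
    """
    r = pair.r_pm
    if r.size == 0:
        raise ValueError("pair has no distances")
    scale_sq = 1.0
    if pair.equivalent and motion_j == "fast_3site":
        scale_sq = FAST_3SITE_SCALE**2
    return float(scale_sq * K_HH_PM**2 * np.sum(r**-6.0))


def multiplicity(pair: SitePairDistances, rel_tol: float = DEFAULT_MULT_TOL) -> int:
    """Number of contacts within ``rel_tol`` of the shortest distance."""
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    r = pair.r_pm
    if r.size == 0:
        raise ValueError("pair has no distances")
    return int(np.sum(r <= r.min() * (1.0 + rel_tol)))


def effective_distance(b_eff_sq: float, m_jk: int) -> float:
    """Effective distance in pm: ``(M * K^2 / b_eff^2)**(1/6)``.

    With a single contact at distance r and M = 1 this returns exactly r.
    """
    if m_jk < 1:
        raise ValueError("multiplicity must be >= 1")
    if b_eff_sq <= 0:
        raise UndefinedDistanceError("effective distance undefined for zero coupling")
    return float((m_jk * K_HH_PM**2 / b_eff_sq) ** (1.0 / 6.0))


# ---------------------------------------------------------------------------
# pair coupling tables
# ---------------------------------------------------------------------------


def pair_id(j: str, k: str) -> tuple[str, str]:
    """Canonical unordered pair-group identifier."""
    return (j, k) if j <= k else (k, j)


@dataclass(frozen=True)
class PairCoupling:
    j: str
    k: str
    b_eff_sq: float  # Hz^2
    m_jk: int
    r_eff_pm: float
    n_terms: int
    motion_applied: str = "static"

    @property
    def id(self) -> tuple[str, str]:
        return pair_id(self.j, self.k)


@dataclass
class PairCouplingTable:
    entries: list[PairCoupling]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def b_eff_sq_tot(self) -> float:
        return sum(e.b_eff_sq for e in self.entries)

    def by_id(self) -> dict[tuple[str, str], PairCoupling]:
        return {e.id: e for e in self.entries}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pair": ["-".join(e.id) for e in self.entries],
                "b_eff_sq_hz2": [e.b_eff_sq for e in self.entries],
                "m_jk": [e.m_jk for e in self.entries],
                "r_eff_pm": [e.r_eff_pm for e in self.entries],
                "n_terms": [e.n_terms for e in self.entries],
                "motion": [e.motion_applied for e in self.entries],
            }
        )


def build_pair_table(
    pairs: Sequence[SitePairDistances],
    groups: Sequence[ProtonSiteGroup],
    mult_tol: float = DEFAULT_MULT_TOL,
) -> PairCouplingTable:
    """Aggregate enumerated distances into couplings and effective distances."""
    motion = {g.group_id: g.motion for g in groups}
    entries = []
    for p in pairs:
        mj = motion.get(p.j, "static")
        mk = motion.get(p.k, "static")
        b2 = effective_coupling_squared(p, mj, mk)
        m = multiplicity(p, mult_tol)
        applied = mj if (p.equivalent and mj == "fast_3site") else "static"
        entries.append(
            PairCoupling(
                j=p.j,
                k=p.k,
                b_eff_sq=b2,
                m_jk=m,
                r_eff_pm=effective_distance(b2, m),
                n_terms=len(p),
                motion_applied=applied,
            )
        )
    return PairCouplingTable(entries)


# ---------------------------------------------------------------------------
# model fractions
# ---------------------------------------------------------------------------


@dataclass
class ModelFractions:
    """Fractional squared couplings per (possibly merged) pair group.

    ``fractions`` holds retained groups normalized to unity; ``excluded``
    holds groups reported on the retained scale but left out of the
    normalizing denominator.
    """

    fractions: dict[str, float]
    excluded: dict[str, float] = field(default_factory=dict)
    b_eff_sq_tot: float = 0.0
    alpha_label: str = "model"

    @property
    def retained_sum(self) -> float:
        return sum(self.fractions.values())


def _merge_b(
    table: PairCouplingTable,
    grouping: Mapping[str, Iterable[tuple[str, str]]] | None,
) -> dict[str, float]:
    """Sum b_eff_sq into (possibly merged) labelled groups.

    ``grouping`` maps a merged label to the pair ids it absorbs; pairs not
    mentioned keep a label of the form ``"j-k"``.
    """
    by_id = {e.id: e.b_eff_sq for e in table}
    merged: dict[str, float] = {}
    claimed: set[tuple[str, str]] = set()
    if grouping:
        for label, members in grouping.items():
            ids = [pair_id(*m) for m in members]
            missing = [i for i in ids if i not in by_id]
            if missing:
                raise ConfigError(f"grouping refers to unknown pairs {missing}")
            merged[label] = sum(by_id[i] for i in ids)
            claimed.update(ids)
    for pid, b in by_id.items():
        if pid not in claimed:
            merged["-".join(pid)] = b
    return merged


def model_fractions(
    table: PairCouplingTable,
    grouping: Mapping[str, Iterable[tuple[str, str]]] | None = None,
    exclusions: Iterable[str] = (),
    alpha_label: str = "model",
) -> ModelFractions:
    """Normalized fractional couplings, with exclusion-and-renormalization.

    Excluded groups are reported relative to the retained total but are
    omitted from the normalizing denominator.
    """
    merged = _merge_b(table, grouping)
    excl = set(exclusions)
    unknown = excl - set(merged)
    if unknown:
        raise ConfigError(f"exclusions refer to unknown groups {sorted(unknown)}")
    retained = {k: v for k, v in merged.items() if k not in excl}
    if not retained:
        raise ConfigError("all pair groups excluded")
    total = sum(retained.values())
    if total <= 0:
        raise ConfigError("retained total coupling is zero")
    return ModelFractions(
        fractions={k: v / total for k, v in retained.items()},
        excluded={k: merged[k] / total for k in excl},
        b_eff_sq_tot=total,
        alpha_label=alpha_label,
    )
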