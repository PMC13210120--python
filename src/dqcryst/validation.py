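"""Model-versus-experiment comparison: the R^2 statistic, NMR-referenced
effective distances, per-pair distance deviations and the full pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import dipolar
from .dipolar import (
    ModelFractions,
    PairCouplingTable,
    UndefinedDistanceError,
    effective_distance,
)
from .structures import (
    ConfigError,
    CrystalStructure,
    ProtonSiteGroup,
    enumerate_pair_distances,
    expand_to_p1,
)


class UndefinedStatisticError(ValueError):
    """Raised when the reference fractions carry no variance."""


@dataclass
class FractionalIntensitySet:
    """Normalized fractional intensities per pair-group id.

    ``fractions`` are the retained values (summing to unity); ``excluded``
    entries are reported on the retained scale but sit outside the
    normalizing denominator.
    """

    fractions: dict[str, float]
    excluded: dict[str, float] = field(default_factory=dict)
    provenance: str = "NMR"

    def __post_init__(self) -> None:
        for k, v in self.fractions.items():
            if v < 0:
                raise ValueError(f"negative fraction for {k!r}")

    @property
    def retained_sum(self) -> float:
        return sum(self.fractions.values())

    def renormalized(self) -> "FractionalIntensitySet":
        s = self.retained_sum
        return FractionalIntensitySet(
            fractions={k: v / s for k, v in self.fractions.items()},
            excluded=dict(self.excluded),
            provenance=self.provenance,
        )


def _aligned(
    f_model: FractionalIntensitySet | ModelFractions,
    f_nmr: FractionalIntensitySet,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    keys_m = set(f_model.fractions)
    keys_n = set(f_nmr.fractions)
    if keys_m != keys_n:
        raise ConfigError(
            f"pair-group ids differ: only-model={sorted(keys_m - keys_n)}, "
            f"only-nmr={sorted(keys_n - keys_m)}"
        )
    keys = sorted(keys_m)
    fm = np.array([f_model.fractions[k] for k in keys])
    fn = np.array([f_nmr.fractions[k] for k in keys])
    return fm, fn, keys


def r_squared(
    f_model: FractionalIntensitySet | ModelFractions,
    f_nmr: FractionalIntensitySet,
) -> float:
    """R^2 = 1 - sum((f_model - f_nmr)^2) / sum((f_nmr - mean)^2).

    The denominator is N times the population variance of the experimental
    fractions, i.e. the total sum of squares.
    """
    fm, fn, keys = _aligned(f_model, f_nmr)
    if len(keys) < 2:
        raise UndefinedStatisticError("need at least two retained pair groups")
    tss = float(np.sum((fn - fn.mean()) ** 2))
    if tss == 0:
        raise UndefinedStatisticError("zero variance in experimental fractions")
    return 1.0 - float(np.sum((fm - fn) ** 2)) / tss


def nmr_effective_distances(
    f_nmr: FractionalIntensitySet,
    reference: ModelFractions,
    m_jk: Mapping[str, int],
) -> dict[str, float]:
    """Convert experimental fractions to effective distances (pm) against a
    reference structure's total coupling and multiplicities.

    The absolute values inherit the bias of the chosen reference; they are
    meaningful only for deviations against that same reference.
    """
    out: dict[str, float] = {}
    for key, f in f_nmr.fractions.items():
        if key not in m_jk:
            raise ConfigError(f"no multiplicity for pair group {key!r}")
        if f == 0:
            out[key] = math.inf
            continue
        b2 = f * reference.b_eff_sq_tot
        out[key] = effective_distance(b2, m_jk[key])
    return out


def distance_deviations(
    r_model: Mapping[str, float],
    r_nmr: Mapping[str, float],
) -> tuple[dict[str, float], float]:
    """Per-pair deviations (model - NMR, pm) and their rmsd.

    Pairs with a non-finite NMR distance (zero experimental fraction) are
    excluded from the rmsd but kept in the per-pair map as +/-inf.
    """
    if set(r_model) != set(r_nmr):
        raise ConfigError("mismatched pair ids between distance sets")
    deltas = {k: r_model[k] - r_nmr[k] for k in r_model}
    finite = [d for d in deltas.values() if math.isfinite(d)]
    if not finite:
        raise ValueError("no finite deviations to aggregate")
    rmsd = float(np.sqrt(np.mean(np.square(finite))))
    return deltas, rmsd


@dataclass
class ValidationConfig:
    cutoff_pm: float = 1000.0
    mult_tol: float = dipolar.DEFAULT_MULT_TOL
    grouping: dict[str, list[tuple[str, str]]] | None = None
    exclusions: tuple[str, ...] = ()
    p1_tol_pm: float = 10.0
    alpha_label: str = "model"


@dataclass
class ValidationReport:
    r2: float
    n_pairs: int
    variance: float
    r_eff_model: dict[str, float]
    r_eff_nmr: dict[str, float]
    delta_r: dict[str, float]
    rmsd_delta_r: float
    f_model: ModelFractions
    f_nmr: FractionalIntensitySet
    pair_table: PairCouplingTable
    config: ValidationConfig

    def to_dict(self) -> dict:
        return {
            "alpha": self.config.alpha_label,
            "R2": self.r2,
            "N_pairs": self.n_pairs,
            "variance_f_nmr": self.variance,
            "rmsd_delta_r_pm": self.rmsd_delta_r,
            "pairs": {
                k: {
                    "f_model": self.f_model.fractions[k],
                    "f_nmr": self.f_nmr.fractions[k],
                    "r_eff_model_pm": self.r_eff_model[k],
                    "r_eff_nmr_pm": self.r_eff_nmr[k],
                    "delta_r_pm": self.delta_r[k],
                }
                for k in sorted(self.f_model.fractions)
            },
            "excluded": {
                k: {"f_model": self.f_model.excluded.get(k)}
                for k in self.f_model.excluded
            },
            "config": {
                "cutoff_pm": self.config.cutoff_pm,
                "mult_tol": self.config.mult_tol,
                "grouping": {
                    k: [list(p) for p in v] for k, v in (self.config.grouping or {}).items()
                },
                "exclusions": list(self.config.exclusions),
                "p1_tol_pm": self.config.p1_tol_pm,
            },
        }


def _merged_multiplicities(
    table: PairCouplingTable,
    grouping: Mapping[str, Iterable[tuple[str, str]]] | None,
    mult_tol: float,
) -> dict[str, int]:
    """Multiplicity per merged group: re-evaluated over the pooled distance
    aggregate, approximated as the member pair with the largest coupling."""
    by_id = {e.id: e for e in table}
    out: dict[str, int] = {}
    claimed: set[tuple[str, str]] = set()
    if grouping:
        for label, members in grouping.items():
            ids = [dipolar.pair_id(*m) for m in members]
            dominant = max(ids, key=lambda i: by_id[i].b_eff_sq)
            out[label] = by_id[dominant].m_jk
            claimed.update(ids)
    for pid, e in by_id.items():
        if pid not in claimed:
            out["-".join(pid)] = e.m_jk
    return out


def validate(
    structure: CrystalStructure,
    groups: Sequence[ProtonSiteGroup],
    f_nmr: FractionalIntensitySet,
    cfg: ValidationConfig | None = None,
) -> ValidationReport:
    """Full pipeline: distances -> couplings -> fractions -> statistics."""
    cfg = cfg or ValidationConfig()
    p1 = expand_to_p1(structure, tol_pm=cfg.p1_tol_pm)
    pairs = enumerate_pair_distances(p1, groups, cutoff_pm=cfg.cutoff_pm)
    table = dipolar.build_pair_table(pairs, groups, mult_tol=cfg.mult_tol)
    fm = dipolar.model_fractions(
        table, grouping=cfg.grouping, exclusions=cfg.exclusions, alpha_label=cfg.alpha_label
    )
    r2 = r_squared(fm, f_nmr)
    m_jk = _merged_multiplicities(table, cfg.grouping, cfg.mult_tol)
    r_model = {
        k: effective_distance(fm.fractions[k] * fm.b_eff_sq_tot, m_jk[k])
        for k in fm.fractions
    }
    r_nmr = nmr_effective_distances(f_nmr, fm, m_jk)
    deltas, rmsd = distance_deviations(r_model, r_nmr)
    fn_vals = np.array(list(f_nmr.fractions.values()))
    return ValidationReport(
        r2=r2,
        n_pairs=len(fm.fractions),
        variance=float(np.var(fn_vals)),
        r_eff_model=r_model,
        r_eff_nmr=r_nmr,
        delta_r=deltas,
        rmsd_delta_r=rmsd,
        f_model=fm,
        f_nmr=f_nmr,
        pair_table=table,
        config=cfg,
    )
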