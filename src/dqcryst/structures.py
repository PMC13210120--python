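"""Crystal-structure handling: CIF ingestion, symmetry expansion and
enumeration of proton-proton distances up to a cutoff.

All Cartesian geometry is carried internally in Angstrom; distances handed
to the coupling analysis are reported in pm.  Site-to-group matching is by
exact, case-sensitive label.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ANGSTROM_PER_PM = 0.01
PM_PER_ANGSTROM = 100.0

#: Minimum credible H...H separation; anything shorter signals a broken model.
MIN_HH_PM = 50.0

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U D".split()
)


class FormatError(ValueError):
    """Raised for malformed or incomplete structure files."""


class ConsistencyError(ValueError):
    """Raised when symmetry expansion produces contradictory positions."""


class ConfigError(ValueError):
    """Raised for invalid group definitions or unresolvable labels."""


class GeometryError(ValueError):
    """Raised for physically impossible geometry."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths (Angstrom) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """Row matrix of the lattice vectors in Angstrom (a along x)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        v = math.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * cg, self.b * sg, 0.0],
                [self.c * cb, self.c * (ca - cb * cg) / sg, self.c * v / sg],
            ]
        )

    @property
    def volume(self) -> float:
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite cell faces along each lattice direction."""
        m = self.matrix
        widths = []
        for i in range(3):
            cross = np.cross(m[(i + 1) % 3], m[(i + 2) % 3])
            widths.append(self.volume / np.linalg.norm(cross))
        return np.array(widths)


@dataclass(frozen=True)
class AtomSite:
    label: str
    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.element not in _ELEMENTS:
            raise FormatError(f"unknown element symbol {self.element!r}")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")
        if not all(math.isfinite(x) for x in self.frac):
            raise ValueError("fractional coordinates must be finite")


@dataclass(frozen=True)
class SymmetryOp:
    """Affine operator in fractional space: x -> R x + t."""

    rotation: tuple[tuple[float, float, float], ...]
    translation: tuple[float, float, float]

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))

    def apply(self, frac: Sequence[float]) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float) @ np.asarray(
            frac, dtype=float
        ) + np.asarray(self.translation, dtype=float)

    @classmethod
    def from_xyz(cls, expr: str) -> "SymmetryOp":
        """Parse a CIF xyz operator such as ``-x, y+1/2, 1/2-z``."""
        parts = [p.strip() for p in expr.lower().split(",")]
        if len(parts) != 3:
            raise FormatError(f"bad symmetry operator {expr!r}")
        rot = []
        trans = []
        for part in parts:
            row = [0.0, 0.0, 0.0]
            shift = Fraction(0)
            for sign, term in re.findall(r"([+-]?)\s*([0-9./]+|[xyz])", part):
                s = -1 if sign == "-" else 1
                if term in "xyz":
                    row["xyz".index(term)] += s
                else:
                    shift += s * (
                        Fraction(term)
                        if "." not in term
                        else Fraction(str(float(term)))
                    )
            rot.append(tuple(float(v) for v in row))
            trans.append(float(shift))
        return cls(tuple(rot), tuple(trans))

    def to_xyz(self) -> str:
        out = []
        for row, t in zip(self.rotation, self.translation):
            terms = []
            for coef, axis in zip(row, "xyz"):
                if coef == 0:
                    continue
                terms.append(("-" if coef < 0 else "+" if terms else "") + axis)
            if t:
                frac = Fraction(t).limit_denominator(48)
                terms.append(f"{'+' if frac > 0 else ''}{frac}")
            out.append("".join(terms) or "0")
        return ",".join(out)


@dataclass
class CrystalStructure:
    cell: UnitCell
    symmetry_ops: list[SymmetryOp]
    sites: list[AtomSite]

    def __post_init__(self) -> None:
        if not self.symmetry_ops:
            self.symmetry_ops = [SymmetryOp.identity()]
        if not any(
            op.rotation == SymmetryOp.identity().rotation
            and op.translation == (0, 0, 0)
            for op in self.symmetry_ops
        ):
            self.symmetry_ops.insert(0, SymmetryOp.identity())
        for s in self.sites:
            if s.occupancy < 1.0:
                warnings.warn(
                    f"site {s.label} has partial occupancy {s.occupancy}; "
                    "pair sums ignore occupancy",
                    stacklevel=2,
                )

    @property
    def is_p1(self) -> bool:
        return len(self.symmetry_ops) == 1

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise ConfigError(f"no site with label {label!r}")

    def h_sites(self) -> list[AtomSite]:
        return [s for s in self.sites if s.element in ("H", "D")]


@dataclass(frozen=True)
class ProtonSiteGroup:
    """A labelled set of chemically equivalent proton positions."""

    group_id: str
    member_labels: tuple[str, ...]
    motion: str = "static"  # {"static", "fast_3site"}
    shift: float | None = None  # ppm

    def __post_init__(self) -> None:
        if len(self.member_labels) < 1:
            raise ConfigError("group needs at least one member")
        if self.motion not in ("static", "fast_3site"):
            raise ConfigError(f"unknown motion model {self.motion!r}")
        if self.motion == "fast_3site" and len(self.member_labels) != 3:
            raise ConfigError("fast_3site requires exactly 3 members")


@dataclass(frozen=True)
class PairDistance:
    """One H...H contact with provenance."""

    r_pm: float
    member_j: str
    member_k: str
    image: tuple[int, int, int]


@dataclass
class SitePairDistances:
    j: str
    k: str
    distances: list[PairDistance]
    equivalent: bool

    @property
    def r_pm(self) -> np.ndarray:
        return np.array([d.r_pm for d in self.distances])

    def __len__(self) -> int:
        return len(self.distances)


# ---------------------------------------------------------------------------
# CIF input / output
# ---------------------------------------------------------------------------

_SYMOP_TAGS = (
    "_symmetry_equiv_pos_as_xyz",
    "_space_group_symop_operation_xyz",
)


def _tokenize_cif(text: str) -> list[str]:
    tokens = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos = 0
        while pos < len(line):
            if line[pos] in "'\"":
                quote = line[pos]
                end = line.find(quote, pos + 1)
                if end == -1:
                    raise FormatError("unterminated quote in CIF")
                tokens.append(line[pos + 1 : end])
                pos = end + 1
            elif line[pos].isspace():
                pos += 1
            else:
                end = pos
                while end < len(line) and not line[end].isspace():
                    end += 1
                tok = line[pos:end]
                if tok.startswith("#"):
                    pos = len(line)
                    break
                tokens.append(tok)
                pos = end
    return tokens


def _strip_su(value: str) -> float:
    """Parse a CIF number, dropping a parenthesized standard uncertainty."""
    value = re.sub(r"\(\d+\)$", "", value)
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"cannot parse numeric CIF value {value!r}") from exc


def parse_structure(path: str | Path) -> CrystalStructure:
    """Read a CIF 1.1 file into a :class:`CrystalStructure`.

    Hydrogen atoms present in the file are preserved verbatim; none are
    added, moved or normalized.  Both common symmetry-operator tags are
    accepted; a file without operators is treated as P1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tokens = _tokenize_cif(path.read_text())

    scalars: dict[str, str] = {}
    loops: list[tuple[list[str], list[list[str]]]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.lower() == "loop_":
            i += 1
            headers = []
            while i < len(tokens) and tokens[i].startswith("_"):
                headers.append(tokens[i].lower())
                i += 1
            rows: list[list[str]] = []
            row: list[str] = []
            while i < len(tokens) and not (
                tokens[i].startswith("_")
                or tokens[i].lower() in ("loop_",)
                or tokens[i].lower().startswith("data_")
            ):
                row.append(tokens[i])
                if len(row) == len(headers):
                    rows.append(row)
                    row = []
                i += 1
            loops.append((headers, rows))
        elif tok.startswith("_"):
            if i + 1 >= len(tokens):
                break
            scalars[tok.lower()] = tokens[i + 1]
            i += 2
        else:
            i += 1  # data_ block names etc.

    try:
        cell = UnitCell(
            a=_strip_su(scalars["_cell_length_a"]),
            b=_strip_su(scalars["_cell_length_b"]),
            c=_strip_su(scalars["_cell_length_c"]),
            alpha=_strip_su(scalars.get("_cell_angle_alpha", "90")),
            beta=_strip_su(scalars.get("_cell_angle_beta", "90")),
            gamma=_strip_su(scalars.get("_cell_angle_gamma", "90")),
        )
    except KeyError as exc:
        raise FormatError(f"missing cell item {exc}") from exc

    ops: list[SymmetryOp] = []
    sites: list[AtomSite] = []
    for headers, rows in loops:
        symtag = next((h for h in headers if h in _SYMOP_TAGS), None)
        if symtag is not None:
            idx = headers.index(symtag)
            ops.extend(SymmetryOp.from_xyz(r[idx]) for r in rows)
        if "_atom_site_fract_x" in headers:
            def col(name: str) -> int | None:
                return headers.index(name) if name in headers else None

            i_label = col("_atom_site_label")
            i_sym = col("_atom_site_type_symbol")
            ix, iy, iz = (
                headers.index("_atom_site_fract_x"),
                headers.index("_atom_site_fract_y"),
                headers.index("_atom_site_fract_z"),
            )
            i_occ = col("_atom_site_occupancy")
            for r in rows:
                label = r[i_label] if i_label is not None else f"X{len(sites)+1}"
                raw_el = r[i_sym] if i_sym is not None else label
                m = re.match(r"([A-Z][a-z]?)", raw_el)
                element = m.group(1) if m else raw_el
                occ = _strip_su(r[i_occ]) if i_occ is not None and r[i_occ] not in (".", "?") else 1.0
                sites.append(
                    AtomSite(
                        label=label,
                        element=element,
                        frac=(_strip_su(r[ix]), _strip_su(r[iy]), _strip_su(r[iz])),
                        occupancy=occ,
                    )
                )

    if not sites:
        raise FormatError("CIF contains no atom sites")
    structure = CrystalStructure(cell=cell, symmetry_ops=ops, sites=sites)
    if not structure.h_sites():
        warnings.warn("structure contains no hydrogen atoms", stacklevel=2)
    return structure


def write_cif(structure: CrystalStructure, path: str | Path, name: str = "dqcryst") -> None:
    """Write a structure back to CIF (operators included verbatim)."""
    c = structure.cell
    lines = [
        f"data_{name}",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        "loop_",
        "_space_group_symop_operation_xyz",
    ]
    lines += [f"'{op.to_xyz()}'" for op in structure.symmetry_ops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for s in structure.sites:
        x, y, z = s.frac
        lines.append(
            f"{s.label} {s.element} {x:.9f} {y:.9f} {z:.9f} {s.occupancy:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------


def _wrap(frac: np.ndarray) -> np.ndarray:
    wrapped = frac - np.floor(frac)
    # guard against 0.9999999999 -> 1.0 after floor noise
    wrapped[np.isclose(wrapped, 1.0, atol=1e-12)] = 0.0
    return wrapped


def expand_to_p1(structure: CrystalStructure, tol_pm: float = 10.0) -> CrystalStructure:
    """Apply all symmetry operators and return the P1 expansion.

    Images of the same orbit closer than ``tol_pm`` are merged (special
    positions); two different elements landing on one position raise
    :class:`ConsistencyError`.
    """
    if structure.is_p1:
        return structure
    cell = structure.cell
    tol_ang = tol_pm * ANGSTROM_PER_PM
    out_sites: list[AtomSite] = []
    out_frac: list[np.ndarray] = []
    out_elem: list[str] = []

    def is_duplicate(frac: np.ndarray, element: str) -> bool:
        for existing, el in zip(out_frac, out_elem):
            delta = frac - existing
            delta -= np.round(delta)
            if np.linalg.norm(cell.to_cartesian(delta)) < tol_ang:
                if el != element:
                    raise ConsistencyError(
                        f"operator maps {element} onto {el} within {tol_pm} pm"
                    )
                return True
        return False

    for site in structure.sites:
        n_images = 0
        for iop, op in enumerate(structure.symmetry_ops):
            frac = _wrap(op.apply(site.frac))
            if is_duplicate(frac, site.element):
                continue
            n_images += 1
            suffix = "" if iop == 0 else f"_s{iop}"
            out_sites.append(
                AtomSite(
                    label=f"{site.label}{suffix}",
                    element=site.element,
                    frac=tuple(frac),
                    occupancy=site.occupancy,
                )
            )
            out_frac.append(frac)
            out_elem.append(site.element)
        if n_images == 0:  # pragma: no cover - orbit always >= 1
            raise ConsistencyError(f"site {site.label} produced no image")

    return CrystalStructure(cell=cell, symmetry_ops=[SymmetryOp.identity()], sites=out_sites)


# ---------------------------------------------------------------------------
# pair-distance enumeration
# ---------------------------------------------------------------------------


def _lattice_translations(cell: UnitCell, cutoff_ang: float) -> np.ndarray:
    """All integer lattice translations whose images can fall within cutoff.

    The search box is derived from the perpendicular cell widths, so
    arbitrarily small cells (many images inside the cutoff sphere) are
    handled correctly.
    """
    widths = cell.perpendicular_widths()
    n = np.ceil(cutoff_ang / widths).astype(int) + 1
    ranges = [np.arange(-ni, ni + 1) for ni in n]
    grid = np.array(np.meshgrid(*ranges, indexing="ij")).reshape(3, -1).T
    return grid


def enumerate_pair_distances(
    structure: CrystalStructure,
    groups: Sequence[ProtonSiteGroup],
    cutoff_pm: float = 1000.0,
) -> list[SitePairDistances]:
    """List all periodic H-H distances per unordered group pair up to cutoff.

    For distinct groups every (m, n, image) combination is counted; for a
    group paired with itself each unordered proton pair is counted once
    (``m < n`` over in-cell partners; for a proton and its own periodic
    images, every non-zero lattice translation contributes one contact).
    """
    if not structure.is_p1:
        raise ConfigError("structure must be expanded to P1 first")
    if cutoff_pm < 200.0:
        raise ConfigError("cutoff must be at least 200 pm")

    cell = structure.cell
    cutoff_ang = cutoff_pm * ANGSTROM_PER_PM
    h_labels = {s.label for s in structure.h_sites()}
    positions: dict[str, np.ndarray] = {}
    for g in groups:
        for lbl in g.member_labels:
            if lbl not in h_labels:
                raise ConfigError(f"group {g.group_id!r}: label {lbl!r} is not an H site")
            positions[lbl] = cell.to_cartesian(np.array(structure.site(lbl).frac))

    trans_frac = _lattice_translations(cell, cutoff_ang)
    trans_cart = trans_frac @ cell.matrix

    results: list[SitePairDistances] = []
    for a in range(len(groups)):
        for b in range(a, len(groups)):
            gj, gk = groups[a], groups[b]
            equivalent = a == b
            contacts: list[PairDistance] = []
            for mi, m_lbl in enumerate(gj.member_labels):
                for ni, n_lbl in enumerate(gk.member_labels):
                    if equivalent and ni < mi:
                        continue
                    same_atom = equivalent and ni == mi
                    vec0 = positions[n_lbl] - positions[m_lbl]
                    dists = np.linalg.norm(vec0 + trans_cart, axis=1)
                    for t_idx in np.nonzero(dists <= cutoff_ang)[0]:
                        image = tuple(int(x) for x in trans_frac[t_idx])
                        if same_atom and image == (0, 0, 0):
                            continue
                        r_pm = dists[t_idx] * PM_PER_ANGSTROM
                        if r_pm <= MIN_HH_PM:
                            raise GeometryError(
                                f"H-H contact of {r_pm:.1f} pm between "
                                f"{m_lbl} and {n_lbl} is below the "
                                f"{MIN_HH_PM} pm sanity floor"
                            )
                        contacts.append(PairDistance(r_pm, m_lbl, n_lbl, image))
            if contacts:
                results.append(
                    SitePairDistances(
                        j=gj.group_id, k=gk.group_id, distances=contacts, equivalent=equivalent
                    )
                )
    return results


# ---------------------------------------------------------------------------
# group configuration I/O
# ---------------------------------------------------------------------------


def load_groups(path: str | Path) -> list[ProtonSiteGroup]:
    """Load proton site groups from JSON (list of dicts or {"groups": [...]})."""
    import json

    raw = json.loads(Path(path).read_text())
    entries = raw["groups"] if isinstance(raw, dict) else raw
    groups = []
    for e in entries:
        groups.append(
            ProtonSiteGroup(
                group_id=e["id"],
                member_labels=tuple(e["members"]),
                motion=e.get("motion", "static"),
                shift=e.get("shift"),
            )
        )
    return groups
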