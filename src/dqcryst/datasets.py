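"""Packaged reference datasets for the three paracetamol-based structures.

The TSVs transcribe the published per-site chemical-shift columns and the
per-pair fractional-intensity / effective-distance columns exactly as
printed (shifts in ppm, distances in integer pm).  Loaders return tidy
pandas frames or the column dictionaries the statistics operations expect.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .validation import FractionalIntensitySet

#: Fitted shielding-to-shift reference intercepts (ppm), calibrated on the
#: plain paracetamol structure and applied to all three systems.
SIGMA_REF_H = 30.44
SIGMA_REF_C = 171.70

STRUCTURES = ("Para", "ParaHCl", "ParaOA")


def _read(name: str) -> pd.DataFrame:
    with resources.files("dqcryst.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_shift_table() -> pd.DataFrame:
    return _read("paracetamol_shifts.tsv")


def load_fraction_table() -> pd.DataFrame:
    return _read("paracetamol_fractions.tsv")


def shift_columns(
    structure: str, species: str, alpha: str
) -> tuple[dict[str, float], dict[str, float]]:
    """(delta_exp, delta_calc) per-site dicts for one structure/species/alpha.

    ``alpha`` is "DFT" or "XRD".
    """
    df = load_shift_table()
    sel = df[(df["structure"] == structure) & (df["species"] == species)]
    if sel.empty:
        raise KeyError(f"no shift data for {structure}/{species}")
    col = {"DFT": "delta_dft", "XRD": "delta_xrd"}[alpha]
    exp = dict(zip(sel["site"], sel["delta_exp"].astype(float)))
    calc = dict(zip(sel["site"], sel[col].astype(float)))
    return exp, calc


def _pair_label(row: pd.Series) -> str:
    return f"{row['group_j']}--{row['group_k']}"


def fraction_columns(structure: str, column: str) -> FractionalIntensitySet:
    """Fraction set for one structure from the printed f columns.

    ``column`` is one of "f_nmr", "f_dft", "f_xrd".  Excluded rows are
    reported outside the normalizing set, matching the printed convention
    (retained printed fractions already sum to 1.000).
    """
    df = load_fraction_table()
    sel = df[df["structure"] == structure]
    if sel.empty:
        raise KeyError(f"no fraction data for {structure}")
    fractions, excluded = {}, {}
    for _, row in sel.iterrows():
        key = _pair_label(row)
        val = float(row[column])
        if int(row["excluded"]):
            excluded[key] = val
        else:
            fractions[key] = val
    prov = {"f_nmr": "NMR", "f_dft": "DFT", "f_xrd": "XRD"}[column]
    return FractionalIntensitySet(fractions=fractions, excluded=excluded, provenance=prov)


def reff_columns(structure: str, alpha: str) -> tuple[dict[str, float], dict[str, float]]:
    """(r_eff_model, r_eff_nmr) column dicts (pm) for one structure/alpha."""
    df = load_fraction_table()
    sel = df[(df["structure"] == structure) & (df["excluded"] == 0)]
    if sel.empty:
        raise KeyError(f"no distance data for {structure}")
    mcol = {"DFT": "r_eff_dft", "XRD": "r_eff_xrd"}[alpha]
    ncol = {"DFT": "r_eff_nmr_dft", "XRD": "r_eff_nmr_xrd"}[alpha]
    model = {}
    nmr = {}
    for _, row in sel.iterrows():
        key = _pair_label(row)
        model[key] = float(row[mcol])
        nmr[key] = float(row[ncol])
    return model, nmr
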