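"""Physicochemical constants loaded from the package's plain-text data files.

All numeric tables used by the chemistry code (amino-acid formulas, the
Kyte-Doolittle hydropathy scale, ionization pK values, atomic masses) live in
``commchem/data/*.tsv`` so that they are auditable and swappable without
touching code.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

#: Canonical order of the 20 amino acids (alphabetical by 3-letter code);
#: also the column order of the reference-proteome TSV format.
AA_CODES: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

ELEMENT_SYMBOLS: tuple[str, ...] = ("C", "H", "N", "O", "S")


def _read_data(name: str) -> pd.DataFrame:
    text = resources.files("commchem.data").joinpath(name).read_text("utf-8")
    return pd.read_csv(StringIO(text), sep="\t", comment="#")


def _load_amino_acids() -> pd.DataFrame:
    df = _read_data("amino_acids.tsv").set_index("code3")
    if list(df.index) != list(AA_CODES):
        raise RuntimeError("amino_acids.tsv does not list the 20 standard amino acids in canonical order")
    return df


AMINO_ACIDS: pd.DataFrame = _load_amino_acids()
TERMINI: pd.DataFrame = _read_data("termini.tsv").set_index("group")
ATOMIC_MASSES: dict[str, float] = _read_data("elements.tsv").set_index("element")["mass"].to_dict()

#: Map any accepted spelling (1-letter, 3-letter, case-insensitive) to the
#: canonical 3-letter code.
AA_ALIASES: dict[str, str] = {}
for _code3, _row in AMINO_ACIDS.iterrows():
    AA_ALIASES[_code3.lower()] = _code3
    AA_ALIASES[str(_row["code1"]).lower()] = _code3

#: Kyte-Doolittle hydropathy values keyed by 3-letter code.
HYDROPATHY: dict[str, float] = AMINO_ACIDS["hydropathy"].astype(float).to_dict()

#: Side-chain pK values: code3 -> (pK, "acid"|"base"), ionizable residues only.
SIDE_CHAIN_PK: dict[str, tuple[float, str]] = {
    code3: (float(row["pk"]), str(row["pk_class"]))
    for code3, row in AMINO_ACIDS.iterrows()
    if row["pk"] != "."
}

#: Terminal-group pK values: ("Nterm"|"Cterm") -> (pK, class).
TERMINAL_PK: dict[str, tuple[float, str]] = {
    group: (float(row["pk"]), str(row["pk_class"])) for group, row in TERMINI.iterrows()
}

#: Free amino-acid elemental formulas: code3 -> {C,H,N,O,S atom counts}.
AA_FORMULAS: dict[str, dict[str, float]] = {
    code3: {sym: float(row[sym.lower()]) for sym in ELEMENT_SYMBOLS}
    for code3, row in AMINO_ACIDS.iterrows()
}

WATER_FORMULA: dict[str, float] = {"C": 0.0, "H": 2.0, "N": 0.0, "O": 1.0, "S": 0.0}
WATER_MASS: float = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]


def _mass(formula: dict[str, float]) -> float:
    return sum(ATOMIC_MASSES[sym] * count for sym, count in formula.items())


#: Average residue masses (free amino acid minus one water), g/mol.
RESIDUE_MASSES: dict[str, float] = {
    code3: _mass(formula) - WATER_MASS for code3, formula in AA_FORMULAS.items()
}
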