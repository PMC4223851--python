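"""Small shared helpers: sequence ops, Roman-numeral normalization, data access."""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_data_table(name: str, **kwargs) -> pd.DataFrame:
    """Read a shipped TSV from the package data directory."""
    ref = resources.files("devtome.data").joinpath(name)
    with ref.open("r") as handle:
        return pd.read_csv(handle, sep="\t", comment="#", **kwargs)


_ROMAN = [
    ("CCC", 300), ("CC", 200), ("C", 100), ("XC", 90), ("L", 50), ("XL", 40),
    ("XXX", 30), ("XX", 20), ("X", 10), ("IX", 9), ("V", 5), ("IV", 4),
    ("III", 3), ("II", 2), ("I", 1),
]


def roman_to_int(roman: str) -> int:
    """Parse a Roman numeral (subset used by CYP family labels)."""
    value, rest = 0, roman.upper()
    for sym, val in _ROMAN:
        while rest.startswith(sym):
            value += val
            rest = rest[len(sym):]
    if rest:
        raise ValueError(f"not a Roman numeral: {roman!r}")
    return value


_CYP_ROMAN = re.compile(r"^CYP([IVXLC]+)", re.IGNORECASE)
_CYP_ARABIC = re.compile(r"^CYP(\d+)", re.IGNORECASE)


def normalize_cyp_family(name: str) -> str | None:
    """Normalize a P450 gene name to its Arabic family label.

    Accepts clan-style names (``Cyp6a2``) and Roman-numeral family labels
    (``CYPVI``); returns e.g. ``"CYP6"``, or None if the name does not look
    like a cytochrome P450.
    """
    name = name.strip()
    m = _CYP_ARABIC.match(name)
    if m:
        return f"CYP{int(m.group(1))}"
    m = _CYP_ROMAN.match(name)
    if m:
        try:
            return f"CYP{roman_to_int(m.group(1))}"
        except ValueError:
            return None
    return None


def truncate_percent(value: float, decimals: int = 2) -> float:
    """Truncate (floor) a percentage to a fixed number of decimals."""
    scale = 10 ** decimals
    return int(value * scale) / scale
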