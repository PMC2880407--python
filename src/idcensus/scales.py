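"""Bundled residue-level constant tables.

Three tables drive the whole census:

* ``TOP_IDP`` — the TOP-IDP disorder-propensity scale (Campen et al., 2008),
  one real number per standard residue, higher meaning more disorder-prone.
  It is the default emission scale of the sliding-window scorer and fixes the
  residue ordering ("increasing disorder tendency") used by composition
  profiles.
* ``KYTE_DOOLITTLE`` — the Kyte & Doolittle (1982) hydropathy scale used by
  the charge-hydropathy (CH) plot.
* ``FDD_COMPOSITION`` — a reference amino-acid composition for fully
  disordered sequence sets.  This table is a synthetic stand-in constructed
  to reproduce the well-known compositional signature of curated disordered
  datasets (rich in E/K/P/S/Q/G, poor in W/C/F/I/Y/V); it is configurable
  everywhere it is used and is never asserted as ground truth by the tests.
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "XBZUO"

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

# Order/disorder-promoting residue sets (depleted vs enriched in disordered
# proteins relative to folded ones).
ORDER_PROMOTING = frozenset("ILVWFYCN")
DISORDER_PROMOTING = frozenset("EKRGQSPA")

# TOP-IDP scale, Campen et al. (2008), Protein Pept Lett 15:956-963.
TOP_IDP = {
    "A": 0.060,
    "C": 0.020,
    "D": 0.192,
    "E": 0.736,
    "F": -0.697,
    "G": 0.166,
    "H": 0.303,
    "I": -0.486,
    "K": 0.586,
    "L": -0.326,
    "M": -0.397,
    "N": -0.007,
    "P": 0.987,
    "Q": 0.318,
    "R": 0.180,
    "S": 0.341,
    "T": 0.059,
    "V": -0.121,
    "W": -0.884,
    "Y": -0.510,
}

# Kyte & Doolittle (1982), J Mol Biol 157:105-132.
KYTE_DOOLITTLE = {
    "A": 1.8,
    "C": 2.5,
    "D": -3.5,
    "E": -3.5,
    "F": 2.8,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "K": -3.9,
    "L": 3.8,
    "M": 1.9,
    "N": -3.5,
    "P": -1.6,
    "Q": -3.5,
    "R": -4.5,
    "S": -0.8,
    "T": -0.7,
    "V": 4.2,
    "W": -0.9,
    "Y": -1.3,
}

# Formal side-chain charge at pH 7; histidine treated as neutral, terminal
# charges ignored.
RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

# Synthetic stand-in reference composition for fully disordered sequence
# sets (see module docstring).  Frequencies sum to 1.
FDD_COMPOSITION = {
    "A": 0.076,
    "C": 0.012,
    "D": 0.058,
    "E": 0.090,
    "F": 0.026,
    "G": 0.072,
    "H": 0.021,
    "I": 0.037,
    "K": 0.081,
    "L": 0.064,
    "M": 0.020,
    "N": 0.040,
    "P": 0.078,
    "Q": 0.043,
    "R": 0.054,
    "S": 0.097,
    "T": 0.055,
    "V": 0.047,
    "W": 0.007,
    "Y": 0.022,
}


def propensity_order(scale: dict[str, float] | None = None) -> tuple[str, ...]:
    """Residues sorted by increasing disorder propensity.

    This is the canonical x-axis ordering of composition profiles: the most
    order-promoting residue (W under TOP-IDP) comes first, the most
    disorder-promoting (P) last.
    """
    values = TOP_IDP if scale is None else scale
    return tuple(sorted(values, key=values.__getitem__))
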